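# locolearn

Supervised training of deep ReLU networks from **layer-local errors**:
every hidden layer carries a small linear classifier with *fixed random*
weights, and that classifier's error — not an error propagated down from
the top of the network — drives the layer's weight updates. The package
is aimed at people studying biologically plausible credit assignment and
at people sizing training hardware, where the scheme's properties
(no backward pass, no stored activations, fixed matrices that live in a
PRNG seed) translate directly into memory-traffic savings.

## The learning rule

For hidden layer *i* with input **x**, weights **W**, bias **b** and ReLU
activation,

```
y  = max(W x + b, 0)          y' = 1[W x + b > 0]
s  = M y                      (M: fixed random C x N classifier)
e_s = dE(t, s)/ds             (cross-entropy or square hinge, true label t)
e_y = (K e_s) ⊙ y'            (K: N x C feedback matrix)
ΔW = -η e_y xᵀ                Δb = -η e_y
```

Four feedback modes select **K**:

| mode    | K                                   | behavior |
|---------|-------------------------------------|----------|
| `SYM`   | Mᵀ (implicit)                       | exact gradient descent on the local loss |
| `SCFB`  | sign(K) = sign(Mᵀ), independent \|K\| | learns nearly as well as `SYM` |
| `INDEP` | fixed, random, independent of M     | fails — accuracy stays near chance |
| `TLC`   | Mᵀ, with M itself trained           | trainable local classifier |

Because no information crosses layers during learning, weights are
updated *during the forward sweep*; intermediate layers double as
early exits at inference time. Feedback-alignment (`fa`) and
backpropagation (`bp`) baselines run over the identical forward stack.

The analytic cost model (`locolearn.cost_model`) compares schemes for a
device that must stream weights/activations through external memory:
local-error training reads and writes `N_e·Σ|Pᵢ|` words against
backpropagation's `N_e·N_b·Σ(2|Pᵢ|+|Aᵢ|)` reads, and needs fewer MACs
exactly when `L·C < 0.5·ΣᵢRᵢ`.

## Worked example

```python
from locolearn import LocalErrorClassifier, SyntheticSpec, gen_synthetic

ds = gen_synthetic(SyntheticSpec("gauss_clusters", n_classes=4,
                                 n_features=20, seed=101))
clf = LocalErrorClassifier(hidden_layer_sizes=(64, 64), epochs=10,
                           feedback_mode="SYM", random_state=0)
clf.fit(ds.X_train, ds.y_train)
print("layer accuracies:", clf.layer_accuracies(ds.X_test, ds.y_test))
print("test accuracy:   ", clf.score(ds.X_test, ds.y_test))
```

prints

```
layer accuracies: [99.1 98.7]
test accuracy:    0.987
```

— layer 1's fixed random classifier already reaches 99.1% on this
linearly separable 4-class task and layer 2 matches it; `predict_layer`
gives the same decisions as an early exit without evaluating layer 2.
Swapping `feedback_mode="INDEP"` collapses accuracy to near the 25%
chance level: with both M and K fixed, nothing can align, and
sign-concordance is the weakest feedback that still carries usable error
information.

The cost model from the shell:

```bash
locolearn cost --net mnist_mlp --epochs 100 --batches 500 --batch-size 100
```

reports per-layer weight words |P| (total 2,784,000 for the
784-1000-1000-1000 stack), post-layer activation words |A| and fanout R,
and both schemes' traffic: local-error reads are `100 × 2,784,000`
words, about 1054× below backpropagation's on the same run shape.

`locolearn train --config cfg.yaml --method lel --seed 0` trains on a
synthetic task and writes `metrics.csv` (epoch × layer × split accuracy
and loss) plus `seeds.tsv`, the ledger from which every fixed matrix of
the run can be regenerated bit-exactly.

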