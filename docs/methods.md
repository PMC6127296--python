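# Methods

## The model

A feed-forward stack of `L` dense or convolutional ReLU layers is
trained for `C`-way classification. Layer `i` computes
`y_i = f(W_i x_i + b_i)` with `f = max(·, 0)` and derivative
`f'(z) = 1[z > 0]`; batch normalization, when enabled, is applied to the
pre-activation (one scale/shift per unit in dense layers, per feature
map in convolutional layers), and max pooling and dropout follow the
nonlinearity in convolutional layers.

Instead of one loss at the top, every layer owns a local loss. A fixed
random matrix `M_i` (`C x N_i`, no bias) maps the layer's flattened
post-pool, post-dropout activity to class scores `s = M_i y`; the score
error `e_s = dE/ds` of a cross-entropy (default) or square-hinge loss is
projected back through a feedback matrix `K_i` and masked by the
activation derivative, `e_y = (K_i e_s) ⊙ y'`, giving the updates
`ΔW = -η e_y x^T`, `Δb = -η e_y`. With `K_i = M_i^T` (the `SYM` mode)
this *is* gradient descent on the local loss, and the package treats
that identity as its central correctness property: the full backward
chain through flattening, dropout, pool-winner routing, the ReLU mask
and batch-norm batch statistics is checked against central finite
differences (relative error ≤ 1e-6 in float64) for dense and
convolutional layers, for trainable-classifier (`TLC`) updates, and for
batch-norm scale/shift updates.

The published error formula multiplies the backprojected error by the
activation vector itself; consistent with the layer's own derivative
definition and with the scheme being exact gradient descent in the
symmetric case, the implementation multiplies by the activation
*derivative* mask and treats the printed form as a typo.

`SCFB` draws `|K|` independently and copies the signs of `M^T`
(a zero sign — measure zero — is resampled to ±1 so no feedback entry is
dead). `INDEP` draws `K` fully independently; since both matrices are
fixed, nothing can align, and the mode serves as the designed failure
control. Mini-batch updates average per-sample gradients, which keeps
`η` transferable across batch sizes.

## Fixed-weight streams

No fixed matrix is ever stored. Each one is regenerated on demand from a
`StreamSpec` (seed, shape, distribution, fan counts); entries are
zero-mean with std `sqrt(2/(n_in + n_out))`, uniform on
`[-√3·std, +√3·std]` or Gaussian. Per-layer seeds come from a
deterministic mixing of one master seed with `(layer_index, role)` via
`numpy.random.SeedSequence` spawn keys, with roles for the classifier
`M`, concordant-feedback magnitudes `K_mag`, feedback-alignment arrays
`FA`, weight init, dropout and shuffling. A counter-based generator
(PCG64) plays the part a hardware LFSR would play; both are
interchangeable sources of uniform variates. Every run writes a
plain-text seed ledger so any fixed matrix is reconstructible bit-for-bit.

## Baselines

Backpropagation and feedback alignment share the forward stack, its
dropout masks and its pool winners, and end in a trainable dense
classifier initialized with the same fan scaling. Feedback alignment
replaces each transposed-weight multiplication with a fixed random array
of the forward weight's shape (random filters for convolutional layers),
keeping derivative masks, winner-only pool routing and exact batch-norm
calculus; setting the feedback equal to the forward weights reproduces
backpropagation to the bit, which the suite asserts. Batch-norm
parameters under feedback alignment are trained by applying exact local
batch-norm calculus to the randomly arriving error — the arriving
direction is random, the within-layer algebra is not.

## Optimization

SGD with Nesterov momentum 0.9 (`v' = μv + g`, `p' = p - η(g + μv')`),
initial rate 0.1 divided by 5 every 25 epochs, mini-batch 100, 100
epochs — these defaults reflect the reference training protocol; the
desk-scale experiments below override epochs. Local-error training
updates each layer immediately during the forward sweep (the activations
handed upward were computed with the pre-update weights); the baselines
update after the backward pass. Training aborts with a diagnostic if the
loss is non-finite for 3 consecutive batches. Training runs default to
float32; all oracle tests use float64.

## Architecture conventions

Convolutions are stride-1, size-preserving ("same"-padded, odd kernels).
Pooling is 3×3/stride 2/pad 1 where that window is specified (the
5-layer image network) and 2×2/stride 2 otherwise (the 10-layer
network, whose window is constrained only by its activation totals);
both halve the spatial size, which the published per-layer counts force.
Max-pool ties break to the first (row-major lowest) index. Dropout is
inverted (train-time 1/(1-rate) scaling) so evaluation is scale-free.
Batch-norm uses ε = 1e-5, biased batch variance for normalization and
running-stat momentum 0.1. Fixed classifiers on convolutional layers are
scaled by the flattened fan-in `N_i` with `n_out = C`.

## Cost model

`account()` counts, per layer, weight words `|P_i|` (biases and
batch-norm parameters excluded — the convention the published totals
force: including biases would give 2,787,000 instead of 2,784,000 for
the dense reference net), post-pool mini-batch activation words `|A_i|`,
and the fanout `R_i` — the number of layer-(i+1) units one layer-i
neuron feeds: the next dense layer's width, or `out_channels ×
kernel_area` for a following convolutional layer (border effects
ignored), with `R_L = C`. Counting activations post-pool makes
`R_i |A_i|` exactly the MAC cost of computing layer i+1 from layer i, so
no pooling-stride correction is needed. One word is 32 bits; counts are
in words.

The closed forms (reads/writes/MACs per scheme) index each layer's
feed-forward and weight-update cost by the *source* layer's fanout and
omit the input layer's own terms (first-layer forward and first-layer
update) and the top-loss evaluation. An instrumented scalar-loop
implementation (`locolearn.counting`) tallies every multiply-accumulate
by operation; after applying exactly those documented exclusions the
analytic and instrumented counts agree as integers. For the local-error
form the per-layer indexing also shifts a `2·C·n_L` boundary term to the
top layer; the identity `analytic = in-scope instrumented + 2·C·n_L·B`
is exact, and when `n_0·n_1 = C·n_L` the raw tally matches the analytic
count with no correction. The traffic model assumes a device buffer of
at least `max_i(|P_i| + N_b|A_i|)` words.

## Synthetic tasks

The generators are first-class, seeded code; task structure (centers,
teacher weights) is drawn once per seed and shared by the train and test
splits.

* `gauss_clusters` — linearly separable control: one spherical Gaussian
  per class, centers at radius 4 on random directions, noise std 1.0
  (default), 2000/1000 train/test, balanced to ±1 sample. A linear
  classifier solves it, so any learning rule that transports usable
  error information should too.
* `xor_rings` — linearly non-separable control: concentric annuli at
  radii 1, 2.5, 4, … (spacing 1.5) with radial noise std 0.25. A fitted
  linear baseline stays ≤ 60%; a two-layer ReLU net exceeds 90%.
* `teacher_net` — labels from a frozen random two-hidden-layer ReLU
  teacher's argmax, rejection-sampled to class balance: hierarchically
  structured but not linearly trivial.

What these tasks do *not* emulate: image statistics, heavy class
overlap, label noise, and the scale of real benchmarks. Passing the
contrast experiments shows the learning rules transport (or fail to
transport) error information as designed; it does not predict benchmark
accuracy, for which the optional MNIST script exists.

## Experiment design (desk scale)

* **Feedback contrast** — 4-class `gauss_clusters`, a 20-64-64 network,
  15 epochs, 5 seeds: symmetric local feedback reaches ≥ 90% mean test
  accuracy while fully independent feedback stays ≤ 35% (chance 25%).
* **Depth benefit** — 2-class `xor_rings`, a deliberately narrow 2-3-16
  network, 20 epochs, 5 seeds: the first layer's three ReLU features
  cannot make rings linearly separable for a fixed random classifier, so
  layer 2's local accuracy exceeds layer 1's (seed-averaged) — the
  hierarchical-composition effect at the smallest size that shows it.
* **Method ordering** — on the same rings task, backpropagation's final
  accuracy is at least feedback alignment's and local-error learning's
  within a 2-point band; at these sizes all methods near saturation, so
  the band absorbs ties.

Problem sizes were chosen so the full suite and the acceptance script
each run in seconds on one CPU while keeping every contrast several
standard errors wide.

## Numerical and design choices

* Mean (not sum) over the mini-batch in all updates.
* Local classifiers have no bias term — scores are a pure random
  projection.
* `TLC` mirrors the fixed-classifier path in every other respect
  (including dropout on the classifier input).
* Training-set order is reshuffled each epoch from the seeded stream;
  identical master seed and config give bit-identical metrics.
* No validation hold-out by default; the per-layer test metrics make the
  early-layer-selection criterion (stop adding layers when held-out
  accuracy stops improving) easy to apply externally.
* The Dale's-law decomposition doubles each layer: unit activities are
  duplicated into excitatory/inhibitory copies with `w = w⁺ - w⁻`,
  outgoing weights of each copy single-signed, and network function
  preserved exactly (checked to 1e-12). It is defined for dense,
  batch-norm-free stacks — a representational statement, not a training
  path.

## Limitations

* No GPU path; convolutional training beyond toy sizes is slow in pure
  numpy, so full-scale image benchmarks are out of desk-scale reach
  (the optional MNIST script covers the dense reference net).
* Strided convolutions, average pooling and residual connections are not
  modeled.
* The cost model counts words and MACs, not energy, DRAM bursts or
  layout effects.
* `INDEP` failure and `SCFB` success are demonstrated on synthetic
  tasks; the magnitude of the gap on natural data will differ.
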