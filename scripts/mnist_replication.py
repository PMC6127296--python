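#!/usr/bin/env python
"""Optional scaled-down MNIST replication (requires network access).

Downloads the four MNIST IDX files (~11 MB) unless already present, then
trains the 784-1000-1000-1000 stack with symmetric local-error learning
for 10 epochs and prints each layer's local-classifier test accuracy.
Expected outcome: the layer-3 local classifier reaches roughly 97-98%
test accuracy, with layers 2 and 3 beating layer 1.

This script is a manual experiment, not part of the test suite: it needs
a dataset download and several minutes of CPU.

Usage:  python scripts/mnist_replication.py [--data-dir mnist] [--epochs 10]
"""

from __future__ import annotations

import argparse
import gzip
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from locolearn.architectures import mnist_mlp
from locolearn.datasets import load_mnist
from locolearn.synth import Dataset
from locolearn.training import TrainConfig, train

MIRROR = "https://ossci-datasets.s3.amazonaws.com/mnist/"
FILES = [
    "train-images-idx3-ubyte",
    "train-labels-idx1-ubyte",
    "t10k-images-idx3-ubyte",
    "t10k-labels-idx1-ubyte",
]


def fetch(data_dir: Path) -> None:
    data_dir.mkdir(parents=True, exist_ok=True)
    for name in FILES:
        target = data_dir / name
        if target.exists():
            continue
        url = MIRROR + name + ".gz"
        print(f"downloading {url}")
        with urllib.request.urlopen(url) as resp:
            target.write_bytes(gzip.decompress(resp.read()))


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("mnist"))
    parser.add_argument("--epochs", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    fetch(args.data_dir)
    X_train, y_train, X_test, y_test = load_mnist(args.data_dir)
    data = Dataset(X_train, y_train, X_test, y_test, 10)

    spec = mnist_mlp()
    cfg = TrainConfig(epochs=args.epochs, batch_size=100,
                      master_seed=args.seed, method="lel", mode="SYM")
    result = train(spec, data, cfg)
    final = result.metrics[(result.metrics.split == "test")
                           & (result.metrics.epoch == args.epochs - 1)]
    print(f"\nLEL(SYM) on MNIST after {args.epochs} epochs:")
    for _, row in final.iterrows():
        print(f"  layer {row['layer']}: test accuracy {row['accuracy']:.2f}%")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
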