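"""YAML config dialect for architectures and training runs.

A config file has two top-level keys::

    network:
      input_shape: 784            # or [3, 32, 32] for images
      num_classes: 10
      layers:
        - {kind: dense, units: 1000, batchnorm: false, dropout: 0.0}
        - {kind: conv, channels: 96, kernel: 5,
           pool: {window: 3, stride: 2, padding: 1},
           batchnorm: true, dropout: 0.0}
    train:
      method: lel                 # lel | fa | bp
      mode: SYM                   # SYM | SCFB | INDEP | TLC
      loss: cross_entropy         # or square_hinge
      lr0: 0.1
      momentum: 0.9
      epochs: 100
      lr_drop_factor: 5
      lr_drop_every: 25
      batch_size: 100
      distribution: uniform       # or gaussian
      seed: 0

Dense ``units`` and conv ``channels`` are output sizes; input sizes are
inferred by shape propagation.  Conv layers are stride-1 and
size-preserving; a square ``kernel`` may be given as one integer.
"""

from __future__ import annotations


from typing import Tuple

import numpy as np
import yaml

from .net_core import ConvSpec, DenseSpec, NetworkSpec, PoolSpec
from .training import TrainConfig

__all__ = ["parse_network", "parse_train_config", "load_config"]


def _as_tuple(v) -> Tuple[int, int]:
    if isinstance(v, int):
        return (v, v)
    return tuple(int(x) for x in v)


def parse_network(cfg: dict) -> NetworkSpec:
    net = cfg["network"]
    input_shape = net["input_shape"]
    if isinstance(input_shape, list):
        input_shape = tuple(int(x) for x in input_shape)
    cur = input_shape
    layers = []
    for entry in net["layers"]:
        kind = entry.get("kind", "dense")
        bn = bool(entry.get("batchnorm", False))
        do = float(entry.get("dropout", 0.0))
        if kind == "dense":
            in_size = cur if isinstance(cur, int) else int(np.prod(cur))
            layer = DenseSpec(in_size, int(entry["units"]), use_batchnorm=bn,
                              dropout_rate=do)
            cur = layer.out_size
        elif kind == "conv":
            if isinstance(cur, int):
                raise ValueError("conv layer after a flat shape")
            pool = None
            if "pool" in entry and entry["pool"]:
                p = entry["pool"]
                pool = PoolSpec(window=int(p.get("window", 2)),
                                stride=int(p.get("stride", 2)),
                                padding=int(p.get("padding", 0)))
            layer = ConvSpec(cur[0], int(entry["channels"]),
                             kernel=_as_tuple(entry.get("kernel", 3)),
                             pool=pool, use_batchnorm=bn, dropout_rate=do)
            c, h, w = cur
            if pool is not None:
                h, w = pool.out_size(h), pool.out_size(w)
            cur = (layer.out_channels, h, w)
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
        layers.append(layer)
    return NetworkSpec(tuple(layers), num_classes=int(net["num_classes"]),
                       input_shape=input_shape)


def parse_train_config(cfg: dict, **overrides) -> TrainConfig:
    t = dict(cfg.get("train", {}))
    t.update({k: v for k, v in overrides.items() if v is not None})
    return TrainConfig(
        lr0=float(t.get("lr0", 0.1)),
        momentum=float(t.get("momentum", 0.9)),
        epochs=int(t.get("epochs", 100)),
        lr_drop_factor=float(t.get("lr_drop_factor", 5)),
        lr_drop_every=int(t.get("lr_drop_every", 25)),
        batch_size=int(t.get("batch_size", 100)),
        master_seed=int(t.get("seed", 0)),
        method=str(t.get("method", "lel")),
        mode=str(t.get("mode", "SYM")),
        loss_kind=str(t.get("loss", "cross_entropy")),
        distribution=str(t.get("distribution", "uniform")),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
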