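"""Seeded, on-the-fly regeneration of every fixed random matrix.

All non-trainable random arrays in a run — the local classifier matrices
``M``, the magnitudes of sign-concordant feedback matrices ``K``, and the
feedback-alignment matrices/filters — are never stored.  Each one is fully
determined by a :class:`StreamSpec` (seed, shape, distribution, fan
counts) and can be regenerated bit-identically at any time, the way a
hardware LFSR would replay a fixed weight stream from its seed.  A
counter-based software generator (PCG64) plays the LFSR's role; both are
just reproducible sources of uniformly distributed numbers.

Per-layer seeds are derived from one master seed by a deterministic
mixing scheme: ``SeedSequence(master_seed, spawn_key=(layer, role_code))``
where the role is one of ``M``, ``K_mag``, ``FA``, ``init``, ``dropout``,
``shuffle``.  A plain-text seed ledger written next to run metrics makes
every fixed matrix reconstructible after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "ROLES",
    "StreamSpec",
    "fan_std",
    "derive_seed",
    "draw_fixed",
    "concordant_signs",
    "sign_concordant_pair",
    "write_seed_ledger",
    "read_seed_ledger",
]

# stable role codes for the seed-mixing scheme; never reorder
ROLES = {"M": 0, "K_mag": 1, "FA": 2, "init": 3, "dropout": 4, "shuffle": 5, "data": 6}


def fan_std(n_in: int, n_out: int) -> float:
    """Initialization scale ``sqrt(2 / (n_in + n_out))``."""
    if n_in < 1 or n_out < 1:
        raise ValueError(f"fan counts must be positive, got ({n_in}, {n_out})")
    return float(np.sqrt(2.0 / (n_in + n_out)))


def derive_seed(master_seed: int, layer_index: int, role: str) -> int:
    """Deterministically mix (master_seed, layer, role) into a 32-bit seed."""
    ss = np.random.SeedSequence(int(master_seed),
                                spawn_key=(int(layer_index), ROLES[role]))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class StreamSpec:
    """Complete recipe for one fixed random array.

    The same spec always yields the bit-identical array: the seed selects
    the stream, ``shape`` and ``distribution`` shape it, and the fan
    counts set the scale via :func:`fan_std`.
    """

    seed: int
    shape: Tuple[int, ...]
    distribution: str = "uniform"  # or "gaussian"
    n_in: int = 1
    n_out: int = 1

    def __post_init__(self):
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def draw_fixed(spec: StreamSpec) -> np.ndarray:
    """Materialize the fixed array described by ``spec``.

    Entries are zero-mean with standard deviation ``fan_std(n_in, n_out)``;
    the uniform variant draws on ``[-sqrt(3)*std, +sqrt(3)*std]`` so its
    std matches the Gaussian one.  Regeneration is idempotent.
    """
    std = fan_std(spec.n_in, spec.n_out)
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.distribution == "gaussian":
        return rng.normal(0.0, std, size=spec.shape)
    lim = np.sqrt(3.0) * std
    return rng.uniform(-lim, lim, size=spec.shape)


def concordant_signs(M_T: np.ndarray, resample_seed: int) -> np.ndarray:
    """Sign pattern for a feedback matrix concordant with ``M.T``.  Zero
    entries (measure zero, but reachable with contrived inputs) get a
    freshly drawn +-1 sign so no feedback entry is dead."""
    signs = np.sign(M_T).astype(float)
    zero = signs == 0
    if zero.any():
        fix = np.random.Generator(np.random.PCG64(resample_seed ^ 0x5EED))
        signs[zero] = fix.choice([-1.0, 1.0], size=int(zero.sum()))
    return signs


def sign_concordant_pair(seed_M: int, seed_mag: int, shape: Tuple[int, int],
                         distribution: str = "uniform",
                         n_in: int = 1, n_out: int = 1):
    """Draw a classifier matrix ``M`` (C x N) and a feedback matrix ``K``
    (N x C) with ``sign(K) = sign(M.T)`` but independent magnitudes.

    This mirrors running two pseudo-random streams in parallel and using
    the sign bits of the first to sign the magnitudes of the second.
    """
    C, N = shape
    M = draw_fixed(StreamSpec(seed_M, (C, N), distribution, n_in, n_out))
    mag = np.abs(draw_fixed(StreamSpec(seed_mag, (N, C), distribution, n_in, n_out)))
    return M, concordant_signs(M.T, seed_mag) * mag


def write_seed_ledger(path, entries: Iterable[Tuple[int, str, int]]) -> None:
    """Write a plain-text seed ledger: one ``layer<TAB>role<TAB>seed`` line
    per fixed matrix, so any of them can be regenerated later."""
    with open(path, "w") as fh:
        fh.write("layer\trole\tseed\n")
        for layer, role, seed in entries:
            fh.write(f"{layer}\t{role}\t{seed}\n")


def read_seed_ledger(path):
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            layer, role, seed = line.rstrip("\n").split("\t")
            out.append((int(layer), role, int(seed)))
    return out
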