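"""Loaders for the MNIST IDX and CIFAR-10 binary formats.

Both are simple headerful binary layouts with no established reader in
the scientific Python stack, so they are parsed directly:

* IDX: big-endian magic ``00 00 <dtype> <ndim>``, then ``ndim`` uint32
  dimensions, then the raw array (dtype code 0x08 = uint8, 0x09 = int8,
  0x0B = int16, 0x0C = int32, 0x0D = float32, 0x0E = float64).  Image
  files use magic 2051 (0x803), label files 2049 (0x801).
* CIFAR-10 batches: 10,000 records of 1 label byte + 3072 image bytes
  (3 x 32 x 32, channel-major).

Standardization subtracts the per-pixel mean and divides by the per-pixel
standard deviation, with statistics computed on the training split only.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Tuple

import numpy as np

__all__ = ["FormatError", "load_idx", "load_mnist", "load_cifar10", "standardize"]

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


class FormatError(ValueError):
    """Malformed file; the message names the offending byte offset."""


def load_idx(path) -> np.ndarray:
    """Read one IDX file into an array (native byte order)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise FormatError(f"{path}: truncated header at offset 0")
    z0, z1, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if z0 != 0 or z1 != 0:
        raise FormatError(f"{path}: bad magic bytes at offset 0 "
                          f"(expected 00 00, got {z0:02x} {z1:02x})")
    if dtype_code not in _IDX_DTYPES:
        raise FormatError(f"{path}: unknown dtype code 0x{dtype_code:02x} at offset 2")
    if len(raw) < 4 + 4 * ndim:
        raise FormatError(f"{path}: truncated dimension list at offset 4")
    dims = struct.unpack(f">{ndim}I", raw[4:4 + 4 * ndim])
    dtype = np.dtype(_IDX_DTYPES[dtype_code])
    offset = 4 + 4 * ndim
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(raw) - offset < expected:
        raise FormatError(f"{path}: truncated data at offset {offset} "
                          f"(need {expected} bytes, have {len(raw) - offset})")
    arr = np.frombuffer(raw, dtype=dtype, count=int(np.prod(dims)), offset=offset)
    return arr.reshape(dims).astype(dtype.newbyteorder("="))


def load_mnist(directory) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load the four standard MNIST IDX files from ``directory``.

    Returns ``(X_train, y_train, X_test, y_test)`` with images flattened
    to float64 vectors in [0, 1].
    """
    directory = Path(directory)
    names = {
        "train_images": "train-images-idx3-ubyte",
        "train_labels": "train-labels-idx1-ubyte",
        "test_images": "t10k-images-idx3-ubyte",
        "test_labels": "t10k-labels-idx1-ubyte",
    }
    arrs = {}
    for key, name in names.items():
        arrs[key] = load_idx(directory / name)
    X_train = arrs["train_images"].reshape(len(arrs["train_images"]), -1) / 255.0
    X_test = arrs["test_images"].reshape(len(arrs["test_images"]), -1) / 255.0
    return X_train, arrs["train_labels"].astype(np.int64), X_test, \
        arrs["test_labels"].astype(np.int64)


def load_cifar10(directory) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load CIFAR-10 from its standard binary batches.

    Returns ``(X_train, y_train, X_test, y_test)`` with images as
    ``(N, 3, 32, 32)`` float64 in [0, 1].
    """
    directory = Path(directory)

    def read_batch(path):
        raw = Path(path).read_bytes()
        rec = 1 + 3072
        if len(raw) % rec != 0:
            raise FormatError(f"{path}: size {len(raw)} is not a multiple of "
                              f"the {rec}-byte record (offset {len(raw) - len(raw) % rec})")
        n = len(raw) // rec
        buf = np.frombuffer(raw, dtype=np.uint8).reshape(n, rec)
        labels = buf[:, 0].astype(np.int64)
        if labels.max() > 9:
            raise FormatError(f"{path}: label byte out of range at record "
                              f"{int(labels.argmax())}")
        images = buf[:, 1:].reshape(n, 3, 32, 32) / 255.0
        return images, labels

    train_parts = [read_batch(directory / f"data_batch_{i}") for i in range(1, 6)]
    X_train = np.concatenate([p[0] for p in train_parts])
    y_train = np.concatenate([p[1] for p in train_parts])
    X_test, y_test = read_batch(directory / "test_batch")
    return X_train, y_train, X_test, y_test


def standardize(X_train: np.ndarray, *others: np.ndarray, eps: float = 1e-8):
    """Per-pixel standardization with statistics from the training split
    only.  Returns the standardized training array followed by the other
    arrays transformed with the same statistics."""
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0) + eps
    out = [(X_train - mean) / std]
    out.extend((X - mean) / std for X in others)
    return out[0] if not others else tuple(out)
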