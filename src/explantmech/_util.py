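"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["as_1d_float", "check_strictly_increasing", "round_sig"]


def as_1d_float(x, name: str) -> np.ndarray:
    """Coerce to a 1-D float array, rejecting non-finite values."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at index {bad}")
    return arr


def check_strictly_increasing(t: np.ndarray, name: str) -> None:
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{name} must be strictly increasing (violated at index {bad})")


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (half away from zero is not
    forced; uses python round, i.e. banker's rounding on exact ties)."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)
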