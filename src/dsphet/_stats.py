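"""Shared log-scale helpers.

Every log or geometric-mean taken on raw counts in this package floors the
counts at 1 first (``max(x, 1)``): zero counts would otherwise send the log to
-inf, and the floor preserves the ordering of all positive counts while making
the degenerate all-zero case collapse to a geometric mean of 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log2_counts", "geomean", "gsd", "log_geomean_sd"]


def log2_counts(x, floor: float = 1.0) -> np.ndarray:
    """log2 of counts floored at ``floor`` (default 1)."""
    return np.log2(np.maximum(np.asarray(x, dtype=float), floor))


def geomean(x, axis=None) -> np.ndarray | float:
    """Geometric mean of counts (floored at 1); NaNs are ignored."""
    return 2.0 ** np.nanmean(log2_counts(x), axis=axis)


def gsd(x, axis=None, ddof: int = 1) -> np.ndarray | float:
    """Geometric standard deviation: 2**sd(log2 counts), sample SD by default."""
    return 2.0 ** np.nanstd(log2_counts(x), axis=axis, ddof=ddof)


def log_geomean_sd(x, axis=None, ddof: int = 1):
    """Mean and sample SD of log2 counts (floored at 1), as a pair."""
    lx = log2_counts(x)
    return np.nanmean(lx, axis=axis), np.nanstd(lx, axis=axis, ddof=ddof)
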