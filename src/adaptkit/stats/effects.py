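"""Effect sizes and simple association measures."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["cohens_d", "pearson_correlation"]


def cohens_d(x, y, paired: bool = False) -> float:
    """Cohen's d: mean difference over the pooled sd.

    ``paired=True`` uses the paired-difference sd variant (d_z).  Returns NaN
    with a warning when the pooled sd is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        sd = np.std(d, ddof=1)
        if sd == 0:
            if np.allclose(d, 0):
                return 0.0
            warnings.warn("zero paired-difference sd; d undefined", UserWarning,
                          stacklevel=2)
            return float("nan")
        return float(np.mean(d) / sd)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per side")
    nx, ny = x.size, y.size
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if pooled == 0:
        if np.mean(x) == np.mean(y):
            return 0.0
        warnings.warn("zero pooled sd; d undefined", UserWarning, stacklevel=2)
        return float("nan")
    return float((np.mean(x) - np.mean(y)) / np.sqrt(pooled))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-tailed p (n >= 3, finite input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input; correlation undefined", UserWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
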