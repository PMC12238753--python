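"""Benjamini-Hochberg step-up false-discovery-rate adjustment.

Families are explicit: callers declare which p-values form one family
(e.g. the ROI contrasts of one outcome within one group); nothing is pooled
silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bh_adjust", "bh_adjust_frame"]


def bh_adjust(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1).

    ``adj_p[(i)] = min_{j >= i} ( p[(j)] * m / j )`` over the sorted family of
    size m; ties and the empty family are handled naturally.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_adjust_frame(df: pd.DataFrame, p_col: str = "p",
                    family_cols: list[str] | None = None,
                    out_col: str = "p_adj") -> pd.DataFrame:
    """Adjust within explicit families given by ``family_cols`` grouping.

    Rows with undefined (NaN) p-values are excluded from their family and
    keep a NaN adjusted value.
    """
    out = df.copy()
    out[out_col] = np.nan

    def _assign(idx):
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if ok.any():
            out.loc[np.asarray(idx)[ok], out_col] = bh_adjust(p[ok])

    if family_cols:
        for _, idx in out.groupby(family_cols, dropna=False).groups.items():
            _assign(np.asarray(idx))
    else:
        _assign(out.index.to_numpy())
    return out
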