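"""Estimated marginal means and pairwise contrasts.

EMMs average model predictions over the cells of the other factors with
equal weights, so under a balanced design the EMM difference equals the raw
cell-mean difference; under imbalance the EMM remains defined from the model
(empty observed cells are flagged, not dropped).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .effects import cohens_d
from .lmm import LinearModelFit

__all__ = ["emm_table", "emm_pairwise"]


def _cell_rows(fit: LinearModelFit, fixed: dict) -> np.ndarray:
    """Average prediction row over the grid cells matching ``fixed``."""
    grid = fit.design.grid()
    for f, lv in fixed.items():
        grid = grid[grid[f] == lv]
    rows = [fit.design.row(cell._asdict() if hasattr(cell, "_asdict") else dict(cell))
            for cell in grid.to_dict(orient="records")]
    return np.mean(rows, axis=0)


def emm_table(fit: LinearModelFit, factor: str, by: str | None = None) -> pd.DataFrame:
    """EMM per level of ``factor`` (optionally within each level of ``by``)."""
    rows = []
    by_levels = fit.design.levels[by] if by else [None]
    for bl in by_levels:
        for lv in fit.design.levels[factor]:
            fixed = {factor: lv}
            if by:
                fixed[by] = bl
            L = _cell_rows(fit, fixed)
            est = float(L @ fit.beta)
            se = float(np.sqrt(L @ fit.cov_beta @ L))
            row = {"factor": factor, "level": lv, "emm": est, "se": se}
            if by:
                row[by] = bl
            rows.append(row)
    return pd.DataFrame(rows)


def emm_pairwise(fit: LinearModelFit, factor: str, by: str | None = None, *,
                 effect_size: bool = True, model_se_d: bool = False) -> pd.DataFrame:
    """Pairwise EMM contrasts for ``factor`` (within ``by`` levels if given).

    Cohen's d is computed from the observed data on the contrast cells
    (pooled-sd formula) by default; set ``model_se_d`` to derive it from the
    model SE instead (both conventions are labelled in the output).
    """
    rows = []
    by_levels = fit.design.levels[by] if by else [None]
    levels = fit.design.levels[factor]
    for bl in by_levels:
        for la, lb in combinations(levels, 2):
            fixed_a, fixed_b = {factor: la}, {factor: lb}
            if by:
                fixed_a[by] = bl
                fixed_b[by] = bl
            L = _cell_rows(fit, fixed_a) - _cell_rows(fit, fixed_b)
            c = fit.contrast(L)
            row = {"factor": factor, "level_a": la, "level_b": lb,
                   "estimate": c["estimate"], "se": c["se"], "df": c["df"],
                   "t": c["t"], "p": c["p"]}
            if by:
                row[by] = bl
            if effect_size:
                row["d"] = _raw_d(fit, factor, la, lb, by, bl,
                                  model_se=model_se_d)
                row["d_basis"] = "model_se" if model_se_d else "pooled_raw"
            # flag empty observed cells (EMM still defined from the model)
            row["empty_cells"] = _count_empty_cells(fit, fixed_a, fixed_b)
            rows.append(row)
    return pd.DataFrame(rows)


def _subset(fit: LinearModelFit, factor: str, level, by, by_level) -> np.ndarray:
    df = fit.data
    m = df[factor] == level
    if by is not None:
        m &= df[by] == by_level
    return df.loc[m, fit.outcome].to_numpy(dtype=float)


def _raw_d(fit, factor, la, lb, by, bl, model_se=False) -> float:
    if model_se:
        fixed_a, fixed_b = {factor: la}, {factor: lb}
        if by:
            fixed_a[by] = bl
            fixed_b[by] = bl
        L = _cell_rows(fit, fixed_a) - _cell_rows(fit, fixed_b)
        c = fit.contrast(L)
        sigma = np.sqrt(fit.sigma2 + (fit.tau2 or 0.0))
        return c["estimate"] / sigma if sigma > 0 else np.nan
    xa = _subset(fit, factor, la, by, bl)
    xb = _subset(fit, factor, lb, by, bl)
    if xa.size < 2 or xb.size < 2:
        return np.nan
    return cohens_d(xa, xb)


def _count_empty_cells(fit, fixed_a, fixed_b) -> int:
    df = fit.data
    empty = 0
    for fixed in (fixed_a, fixed_b):
        m = np.ones(len(df), dtype=bool)
        for f, lv in fixed.items():
            m &= df[f] == lv
        if not m.any():
            empty += 1
    return empty
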