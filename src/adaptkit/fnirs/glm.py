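"""Block-design GLM with a canonical double-gamma haemodynamic response.

One regressor per 30-s block (boxcar convolved with the double-gamma HRF),
plus an intercept and a linear drift column, estimated by ordinary least
squares.  The two block betas of each timepoint are averaged into the
timepoint beta (the alternative single-regressor-per-timepoint model is
available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["HrfParams", "double_gamma_hrf", "build_design", "fit_glm_betas"]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma parameterization (SPM-style).

    Response peak 6 s and undershoot peak 16 s with unit dispersions and a
    1:6 peak-to-undershoot ratio; the paper does not state its convention, so
    these canonical values are configurable.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    duration_s: float = 32.0


def _gamma_pdf(t, shape, scale):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp / scale
                      - gammaln(shape) - shape * np.log(scale))
    return out


def double_gamma_hrf(fs: float, params: HrfParams | None = None) -> np.ndarray:
    """Sampled canonical HRF (peak-normalized to 1)."""
    p = params or HrfParams()
    t = np.arange(0.0, p.duration_s, 1.0 / fs)
    peak = _gamma_pdf(t, p.peak_delay / p.peak_dispersion + 1.0,
                      p.peak_dispersion)
    under = _gamma_pdf(t, p.undershoot_delay / p.undershoot_dispersion + 1.0,
                       p.undershoot_dispersion)
    # shape = delay/dispersion + 1 places each gamma's mode exactly at the
    # stated delay, so the response truly peaks at 6 s (undershoot at 16 s)
    h = peak - under / p.ratio
    return h / h.max()


def build_design(events: pd.DataFrame, n_samples: int, fs: float,
                 hrf_params: HrfParams | None = None, *,
                 per_block: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix: HRF-convolved block regressors + intercept + drift.

    ``events`` needs columns ``timepoint``, ``onset`` (s), ``duration`` (s)
    and, when ``per_block``, a ``block`` column distinguishing the paired
    blocks of each timepoint.
    """
    hrf = double_gamma_hrf(fs, hrf_params)
    cols, names = [], []
    if per_block and "block" not in events.columns:
        events = events.assign(block=events.groupby("timepoint").cumcount() + 1)
    key = ["timepoint", "block"] if per_block else ["timepoint"]
    for label, grp in events.groupby(key, sort=False):
        box = np.zeros(n_samples)
        for _, row in grp.iterrows():
            i0 = int(round(row["onset"] * fs))
            i1 = min(n_samples, i0 + int(round(row["duration"] * fs)))
            if i0 >= n_samples:
                raise ValueError(f"block {label} starts beyond the record")
            box[i0:i1] = 1.0
        reg = np.convolve(box, hrf)[:n_samples]
        cols.append(reg)
        names.append("|".join(str(k) for k in (label if isinstance(label, tuple) else (label,))))
    X = np.column_stack(cols + [np.ones(n_samples),
                                np.linspace(-0.5, 0.5, n_samples)])
    names += ["intercept", "drift"]
    return X, names


def fit_glm_betas(series: np.ndarray, events: pd.DataFrame, fs: float,
                  hrf_params: HrfParams | None = None, *,
                  per_block: bool = True) -> pd.DataFrame:
    """OLS betas per timepoint for one cleaned channel series.

    Per-block betas are averaged within each timepoint.  Refuses
    rank-deficient designs, naming the offending columns.
    """
    y = np.asarray(series, dtype=float)
    X, names = build_design(events, y.size, fs, hrf_params, per_block=per_block)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix rank-deficient; offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rows = []
    for name, b in zip(names, beta):
        if name in ("intercept", "drift"):
            continue
        tp = name.split("|")[0]
        rows.append({"timepoint": tp, "regressor": name, "beta": float(b)})
    per_reg = pd.DataFrame(rows)
    out = per_reg.groupby("timepoint", sort=False)["beta"].mean().reset_index()
    return out
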