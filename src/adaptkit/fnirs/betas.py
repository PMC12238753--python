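"""Beta aggregation into ROIs and task contrasts."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["roi_betas", "compute_contrasts", "channel_wide_beta"]


def channel_wide_beta(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Mean beta over all long channels per timepoint (label 'all')."""
    out = (beta_table.groupby("timepoint", sort=False)["beta"]
           .mean().reset_index())
    out.insert(0, "roi", "all")
    return out


def roi_betas(beta_table: pd.DataFrame, roi_map: dict[str, list[str]]) -> pd.DataFrame:
    """Arithmetic mean of member-channel betas per ROI and timepoint.

    ``beta_table`` has columns ``channel``, ``timepoint``, ``beta`` (long
    channels only).  Empty ROIs yield NaN rows with a warning.
    """
    rows = []
    timepoints = beta_table["timepoint"].unique()
    for roi, members in roi_map.items():
        sub = beta_table[beta_table["channel"].isin(members)]
        if sub.empty:
            warnings.warn(f"ROI {roi} has no member channels with betas",
                          UserWarning, stacklevel=2)
            for tp in timepoints:
                rows.append({"roi": roi, "timepoint": tp, "beta": np.nan})
            continue
        for tp, grp in sub.groupby("timepoint", sort=False):
            rows.append({"roi": roi, "timepoint": tp,
                         "beta": float(grp["beta"].mean())})
    return pd.DataFrame(rows)


def compute_contrasts(beta_table: pd.DataFrame, *, minuend: str = "EarlyAdapt",
                      subtrahend: str = "Baseline",
                      unit_col: str | None = None) -> pd.DataFrame:
    """Per-unit timepoint contrast ``beta(minuend) - beta(subtrahend)``.

    ``unit_col`` selects the grouping column (``channel`` or ``roi``); it is
    inferred when absent.  Units missing either timepoint are skipped (and
    counted in the ``skipped`` attr).
    """
    if unit_col is None:
        unit_col = "channel" if "channel" in beta_table.columns else "roi"
    rows, skipped = [], 0
    for unit, grp in beta_table.groupby(unit_col, sort=False):
        tp = grp.set_index("timepoint")["beta"]
        if minuend not in tp.index or subtrahend not in tp.index:
            skipped += 1
            continue
        rows.append({unit_col: unit,
                     "contrast": float(tp[minuend] - tp[subtrahend])})
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    out.attrs["definition"] = f"{minuend} - {subtrahend}"
    return out
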