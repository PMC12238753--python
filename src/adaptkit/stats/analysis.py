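"""Cohort-level analyses: outcomes table, savings models, fNIRS contrasts.

This is the layer the CLI and the simulation studies drive: it turns trials
(stride series per phase, optionally fNIRS recordings) into per-trial
adaptation outcomes, per-participant savings, mixed-model term tests and
EMM contrast tables with explicit FDR families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..adaptation import (
    PsoConfig,
    compute_outcomes,
    fit_exponential_batch,
    window_means,
)
from ..stride import baseline_adjust
from .emm import emm_pairwise
from .fdr import bh_adjust_frame
from .lmm import fit_lmm, fit_ols, type3_anova

__all__ = [
    "adaptation_outcome_table", "savings_table",
    "analyze_outcome_lmm", "analyze_savings", "analyze_fnirs_contrasts",
]


def adaptation_outcome_table(trials, pso_cfg: PsoConfig | None = None) -> pd.DataFrame:
    """Fit exponentials per trial-phase and derive the outcome table.

    Adaptation (and, when present, deadaptation) series are baseline-adjusted
    against the trial's baseline phase, fitted in one vectorized batch, and
    reduced to window means and outcomes.
    """
    pso_cfg = pso_cfg or PsoConfig()
    adapt_series, deadapt_series, meta = [], [], []
    for t in trials:
        base = t.series["Baseline"]
        adapt_series.append(baseline_adjust(t.series["Adaptation"], base))
        deadapt_series.append(
            baseline_adjust(t.series["Deadaptation"], base)
            if "Deadaptation" in t.series else None)
        meta.append(t)
    adapt_fits = fit_exponential_batch([s.sla for s in adapt_series], pso_cfg)
    have_deadapt = [s for s in deadapt_series if s is not None]
    deadapt_fits = iter(fit_exponential_batch(
        [s.sla for s in have_deadapt], pso_cfg)) if have_deadapt else iter(())

    rows = []
    for t, afit, dseries in zip(meta, adapt_fits, deadapt_series):
        dfit = next(deadapt_fits) if dseries is not None else None
        out = compute_outcomes(afit, dfit, participant=t.participant_id,
                               visit=t.visit, tens=t.tens, group=t.group)
        row = out.as_dict()
        row.update({"fit_a": afit.a, "fit_b": afit.b, "fit_c": afit.c,
                    "fit_sse": afit.sse, "fit_seed": afit.seed,
                    "fit_at_bounds": any(afit.at_bounds)})
        if dfit is not None:
            row.update({"deadapt_fit_a": dfit.a, "deadapt_fit_b": dfit.b,
                        "deadapt_fit_c": dfit.c, "deadapt_fit_sse": dfit.sse})
        rows.append(row)
    return pd.DataFrame(rows)


def savings_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-participant savings (V2 - V1 at Initial and Early Adapt).

    Participants missing either visit are skipped (count stored in attrs).
    """
    rows, skipped = [], 0
    for pid, grp in outcomes.groupby("participant", sort=False):
        v = grp.set_index("visit")
        if 1 not in v.index or 2 not in v.index:
            skipped += 1
            continue
        rows.append({
            "participant": pid,
            "group": v.loc[1, "group"],
            "tens_at_v2": v.loc[2, "tens"],
            "savings_initial": v.loc[2, "initial_adapt"] - v.loc[1, "initial_adapt"],
            "savings_early": v.loc[2, "early_adapt"] - v.loc[1, "early_adapt"],
        })
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def analyze_outcome_lmm(outcomes: pd.DataFrame, outcome: str,
                        factors=("group", "visit", "tens")) -> dict:
    """Mixed model (participant random intercept) + Type III + EMM contrasts."""
    df = outcomes.dropna(subset=[outcome]).copy()
    fit = fit_lmm(df, outcome, list(factors), group_col="participant")
    anova = type3_anova(fit)
    contrasts = []
    for factor in factors:
        by = "group" if factor != "group" else None
        tab = emm_pairwise(fit, factor, by=by)
        tab.insert(0, "contrast_factor", factor)
        contrasts.append(tab)
    emm = pd.concat(contrasts, ignore_index=True)
    # FDR family: within outcome x group where a group split exists
    emm = bh_adjust_frame(emm, family_cols=["contrast_factor", "group"]
                          if "group" in emm.columns else ["contrast_factor"])
    return {"fit": fit, "anova": anova, "emm": emm, "outcome": outcome}


def analyze_savings(savings: pd.DataFrame, outcome: str = "savings_initial") -> dict:
    """Savings model: OLS with group and TENS-at-Visit-2 (no random effect;
    one record per participant), TENS contrast per group with raw-cell d."""
    fit = fit_ols(savings, outcome, ["group", "tens_at_v2"])
    anova = type3_anova(fit)
    emm = emm_pairwise(fit, "tens_at_v2", by="group")
    emm.insert(0, "outcome", outcome)
    emm = bh_adjust_frame(emm, family_cols=["group"])
    return {"fit": fit, "anova": anova, "emm": emm, "outcome": outcome}


def analyze_fnirs_contrasts(contrast_table: pd.DataFrame,
                            unit_col: str = "roi") -> dict:
    """TENS ON-OFF of the EarlyAdapt-Baseline contrast, per unit and group.

    ``contrast_table`` carries one row per trial x unit with columns
    ``participant``, ``group``, ``visit``, ``tens``, ``unit_col`` and
    ``contrast`` (the within-visit EarlyAdapt - Baseline value, c1).  The
    cross-visit TENS difference (c2) is computed per participant, then
    tested against zero within each group per unit; BH correction runs
    across units within each group.
    """
    rows = []
    for (pid, unit), grp in contrast_table.groupby(["participant", unit_col],
                                                   sort=False):
        tens = grp.set_index("tens")["contrast"]
        if "ON" not in tens.index or "OFF" not in tens.index:
            continue
        rows.append({"participant": pid, unit_col: unit,
                     "group": grp["group"].iloc[0],
                     "c2": float(tens["ON"] - tens["OFF"])})
    c2 = pd.DataFrame(rows)
    tests = []
    from scipy import stats as sps
    for (group, unit), grp in c2.groupby(["group", unit_col], sort=False):
        x = grp["c2"].to_numpy(dtype=float)
        if x.size < 2:
            t, p, sd = np.nan, np.nan, 0.0
        else:
            t, p = sps.ttest_1samp(x, 0.0)
            sd = np.std(x, ddof=1)
        tests.append({unit_col: unit, "group": group, "mean_c2": float(np.mean(x)),
                      "t": float(t), "df": x.size - 1, "p": float(p),
                      "d": float(np.mean(x) / sd) if sd > 0 else np.nan,
                      "n": x.size})
    tests = pd.DataFrame(tests)
    tests = bh_adjust_frame(tests, family_cols=["group"])
    return {"c2": c2, "tests": tests}
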