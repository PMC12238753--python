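"""Cohort-level analysis layer: outcomes table, savings, recovery of truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adaptkit.adaptation import PsoConfig
from adaptkit.stats import (
    adaptation_outcome_table,
    analyze_fnirs_contrasts,
    analyze_outcome_lmm,
    analyze_savings,
    savings_table,
)
from adaptkit.synthetic import CohortConfig, generate_cohort

FAST = PsoConfig.fast(seed=0)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = dataclasses.replace(CohortConfig(seed=21), n_pwms=8, n_hc=6,
                              n_strides=300, n_baseline=60,
                              include_deadaptation=True)
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def outcomes(small_cohort):
    return adaptation_outcome_table(small_cohort.trials, FAST)


class TestOutcomeTable:
    def test_one_row_per_trial(self, small_cohort, outcomes):
        assert len(outcomes) == len(small_cohort.trials)

    def test_columns_present(self, outcomes):
        assert {"initial_adapt", "early_adapt", "late_adapt",
                "adaptation_magnitude", "after_effect",
                "early_change_deadapt"} <= set(outcomes.columns)

    def test_recovers_generating_window_means(self, small_cohort, outcomes):
        truth = small_cohort.truth
        merged = outcomes.merge(truth, on=["participant", "visit"])
        n = np.arange(6, 31)
        expected_early = (merged["adapt_a"] * np.mean(np.exp(-0.012 * n))
                          + merged["adapt_c"] - merged["baseline_sla"])
        err = merged["early_adapt"] - expected_early
        assert np.median(np.abs(err)) < 0.01


class TestSavingsTable:
    def test_one_row_per_complete_participant(self, outcomes):
        sav = savings_table(outcomes)
        assert len(sav) == outcomes["participant"].nunique()
        assert sav.attrs["skipped"] == 0

    def test_missing_visit_skipped_and_logged(self, outcomes):
        partial = outcomes[~((outcomes.participant == outcomes.participant.iloc[0])
                             & (outcomes.visit == 2))]
        sav = savings_table(partial)
        assert sav.attrs["skipped"] == 1
        assert outcomes.participant.iloc[0] not in set(sav.participant)


class TestAnalyses:
    def test_savings_model_has_no_random_effect(self, outcomes):
        res = analyze_savings(savings_table(outcomes))
        assert res["fit"].kind == "ols"

    def test_outcome_lmm_reports_terms(self, outcomes):
        res = analyze_outcome_lmm(outcomes, "adaptation_magnitude")
        assert {"group", "visit", "tens"} <= set(res["anova"]["term"])
        assert "p_adj" in res["emm"].columns

    def test_injected_group_gap_recovered(self):
        # generating gap of 0.022 in adaptation magnitude between groups,
        # averaged over replicate cohorts
        gaps = []
        for rep in range(5):
            cfg = dataclasses.replace(CohortConfig(seed=300 + rep),
                                      n_strides=300, n_baseline=60,
                                      include_deadaptation=False)
            cohort = generate_cohort(cfg)
            out = adaptation_outcome_table(cohort.trials,
                                           PsoConfig.fast(seed=rep))
            by_group = out.groupby("group")["adaptation_magnitude"].mean()
            gaps.append(by_group["HC"] - by_group["PwMS"])
        assert np.mean(gaps) == pytest.approx(0.022, abs=0.015)

    def test_fnirs_contrast_c2_recovery(self):
        # injected activation only with TENS OFF: c2 = ON - OFF ~ -0.08
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            for tens in ("ON", "OFF"):
                c1 = (0.08 if tens == "OFF" else 0.0) + rng.normal(0, 0.01)
                rows.append({"participant": f"P{i}",
                             "group": "PwMS" if i < 6 else "HC",
                             "visit": 1 if tens == "ON" else 2, "tens": tens,
                             "roi": "PMd", "contrast": c1})
        res = analyze_fnirs_contrasts(pd.DataFrame(rows))
        assert res["tests"]["mean_c2"].mean() == pytest.approx(-0.08, abs=0.02)
        assert {"p", "p_adj", "d"} <= set(res["tests"].columns)
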