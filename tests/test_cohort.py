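import dataclasses

import numpy as np
import pytest

from adaptkit.synthetic import CohortConfig, generate_cohort, read_stride_table, write_cohort


class TestCohortLayout:
    def test_trial_arithmetic(self, tiny_cohort_config):
        cohort = generate_cohort(tiny_cohort_config)
        assert len(cohort.trials) == (4 + 4) * 2

    def test_default_counts_96_trials(self):
        cfg = dataclasses.replace(CohortConfig(seed=1), n_strides=60,
                                  n_baseline=60, include_deadaptation=False)
        cohort = generate_cohort(cfg)
        assert len(cohort.trials) == 96
        groups = cohort.manifest.groupby("group")["participant"].nunique()
        assert groups["PwMS"] == 28 and groups["HC"] == 20

    def test_counterbalanced_crossover(self, tiny_cohort_config):
        cohort = generate_cohort(tiny_cohort_config)
        for group in ("PwMS", "HC"):
            orders = [p.tens_order for p in cohort.participants
                      if p.group == group]
            assert orders.count("ON-first") == orders.count("ON-second")
        # within participant: one ON and one OFF visit
        for pid, grp in cohort.manifest.groupby("participant"):
            assert set(grp["tens"]) == {"ON", "OFF"}

    def test_invalid_config_refused(self):
        with pytest.raises(ValueError):
            CohortConfig(n_pwms=0)
        with pytest.raises(ValueError):
            CohortConfig(n_strides=50)


class TestDeterminism:
    def test_bit_reproducible(self, tiny_cohort_config):
        c1 = generate_cohort(tiny_cohort_config)
        c2 = generate_cohort(tiny_cohort_config)
        for t1, t2 in zip(c1.trials, c2.trials):
            for phase in t1.series:
                assert np.array_equal(t1.series[phase].sla, t2.series[phase].sla)
        assert c1.truth.equals(c2.truth)

    def test_seed_changes_data(self, tiny_cohort_config):
        c1 = generate_cohort(tiny_cohort_config)
        c2 = generate_cohort(dataclasses.replace(tiny_cohort_config, seed=6))
        t1 = c1.trials[0].series["Adaptation"].sla
        t2 = c2.trials[0].series["Adaptation"].sla
        assert not np.array_equal(t1, t2)


class TestGroundTruth:
    def test_truth_row_per_trial_with_params(self, tiny_cohort_config):
        cohort = generate_cohort(tiny_cohort_config)
        assert len(cohort.truth) == len(cohort.trials)
        assert {"adapt_a", "adapt_b", "adapt_c",
                "stride_noise_sd"} <= set(cohort.truth.columns)

    def test_injected_savings_shift_on_generating_params(self):
        cfg = dataclasses.replace(CohortConfig(seed=3), n_pwms=8, n_hc=2,
                                  n_strides=60, n_baseline=60,
                                  include_deadaptation=False,
                                  participant_a_sd=0.0, visit_a_sd=0.0,
                                  participant_c_sd=0.0,
                                  visit_early_change_shift=0.0)
        cohort = generate_cohort(cfg)
        tr = cohort.truth
        pw = tr[tr.group == "PwMS"]
        on2 = pw[pw.tens_order == "ON-second"]
        off2 = pw[pw.tens_order == "ON-first"]
        gap_v2 = (on2[on2.visit == 2].adapt_a.mean()
                  - off2[off2.visit == 2].adapt_a.mean())
        gap_v1 = (on2[on2.visit == 1].adapt_a.mean()
                  - off2[off2.visit == 1].adapt_a.mean())
        assert gap_v2 == pytest.approx(cfg.tens_savings_shift, abs=1e-12)
        assert gap_v1 == pytest.approx(0.0, abs=1e-12)

    def test_sla_bounded_everywhere(self, tiny_cohort_config):
        cohort = generate_cohort(tiny_cohort_config)
        for t in cohort.trials:
            for s in t.series.values():
                assert np.all(np.abs(s.sla) < 1.0)


class TestIO:
    def test_write_and_read_back(self, tiny_cohort_config, tmp_path):
        cohort = generate_cohort(tiny_cohort_config)
        paths = write_cohort(cohort, tmp_path)
        series = read_stride_table(paths["strides"])
        assert len(series) == sum(len(t.series) for t in cohort.trials)
        first = cohort.trials[0].series["Baseline"]
        back = [s for s in series
                if s.participant == first.participant
                and s.visit == first.visit and s.phase == "Baseline"][0]
        assert np.allclose(back.sla, first.sla, atol=1e-9)

    def test_manifest_written(self, tiny_cohort_config, tmp_path):
        cohort = generate_cohort(tiny_cohort_config)
        paths = write_cohort(cohort, tmp_path)
        assert paths["manifest"].exists()
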