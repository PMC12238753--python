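import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adaptkit.stats import FactorDesign, fit_lmm, fit_ols, type3_anova


def crossover_frame(rng, n_pwms=14, n_hc=10, effect=0.0, tau=1.0, sigma=1.0):
    rows = []
    for i in range(n_pwms + n_hc):
        grp = "PwMS" if i < n_pwms else "HC"
        order = i % 2
        u = rng.normal(0, tau)
        for v in (1, 2):
            tens = "ON" if (v == 1) == (order == 0) else "OFF"
            y = u + effect * (tens == "ON") + rng.normal(0, sigma)
            rows.append(dict(participant=f"P{i}", group=grp, visit=str(v),
                             tens=tens, y=y))
    return pd.DataFrame(rows)


class TestFactorDesign:
    def test_sum_coding_two_level(self):
        d = FactorDesign({"g": ["A", "B"]})
        X = d.matrix(pd.DataFrame({"g": ["A", "B"]}))
        assert np.array_equal(X, [[1, 1], [1, -1]])

    def test_full_factorial_width(self):
        d = FactorDesign({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert d.n_params == 8

    def test_three_level_factor(self):
        d = FactorDesign({"g": ["A", "B", "C"]})
        X = d.matrix(pd.DataFrame({"g": ["A", "B", "C"]}))
        assert np.array_equal(X[:, 1:], [[1, 0], [0, 1], [-1, -1]])

    def test_unknown_level_refused(self):
        d = FactorDesign({"g": ["A", "B"]})
        with pytest.raises(ValueError, match="unknown level"):
            d.matrix(pd.DataFrame({"g": ["Z"]}))


class TestFitLmm:
    def test_reduces_to_oneway_anova_when_no_grouping_variance(self, rng):
        # one observation per participant: random intercept collapses and the
        # group F must equal the classical one-way ANOVA F
        y1 = rng.normal(0, 1, 20)
        y2 = rng.normal(0.8, 1, 20)
        df = pd.DataFrame({
            "participant": [f"P{i}" for i in range(40)],
            "g": ["A"] * 20 + ["B"] * 20,
            "y": np.concatenate([y1, y2]),
        })
        with pytest.warns(UserWarning, match="random-intercept variance"):
            fit = fit_lmm(df, "y", ["g"])
        F_mine = type3_anova(fit).loc[0, "F"]
        F_classic, _ = sps.f_oneway(y1, y2)
        assert F_mine == pytest.approx(float(F_classic), rel=1e-6)
        assert fit.singular

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        df = crossover_frame(rng)
        fit = fit_lmm(df, "y", ["visit", "tens"], max_order=2)
        md = smf.mixedlm("y ~ C(visit, Sum)*C(tens, Sum)", df,
                         groups=df["participant"]).fit(reml=True)
        assert fit.beta[0] == pytest.approx(md.fe_params.iloc[0], abs=1e-5)
        assert fit.sigma2 == pytest.approx(float(md.scale), rel=1e-4)
        assert fit.tau2 == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-3)

    def test_satterthwaite_df_for_crossover(self, rng):
        df = crossover_frame(rng, n_pwms=14, n_hc=10)
        fit = fit_lmm(df, "y", ["group", "visit", "tens"])
        an = type3_anova(fit).set_index("term")
        # within-participant terms in a 24-participant crossover: df near 20
        assert 15 < an.loc["tens", "df2"] < 24
        assert an.loc["tens", "df1"] == 1

    def test_injected_within_effect_detected(self, rng):
        df = crossover_frame(rng, effect=1.5, sigma=0.5)
        an = type3_anova(fit_lmm(df, "y", ["group", "visit", "tens"]))
        assert an.set_index("term").loc["tens", "p"] < 0.001

    def test_power_matches_closed_form_oracle(self, rng):
        # between-group gap equal to the residual sd, one record per
        # participant (degenerates to the two-sample case): empirical power
        # must match the noncentral-t closed form within simulation error
        n_per, n_rep, alpha = 20, 150, 0.05
        ncp = 1.0 / np.sqrt(2.0 / n_per)
        df_ = 2 * n_per - 2
        tcrit = sps.t.ppf(1 - alpha / 2, df_)
        power_oracle = (1 - sps.nct.cdf(tcrit, df_, ncp)
                        + sps.nct.cdf(-tcrit, df_, ncp))
        hits = 0
        for _ in range(n_rep):
            df = pd.DataFrame({
                "participant": [f"P{i}" for i in range(2 * n_per)],
                "g": ["A"] * n_per + ["B"] * n_per,
                "y": np.concatenate([rng.normal(0, 1, n_per),
                                     rng.normal(1, 1, n_per)]),
            })
            with pytest.warns(UserWarning):
                fit = fit_lmm(df, "y", ["g"])
            hits += type3_anova(fit).loc[0, "p"] < alpha
        se = np.sqrt(power_oracle * (1 - power_oracle) / n_rep)
        assert abs(hits / n_rep - power_oracle) < 3.5 * se + 0.01

    def test_rank_deficient_refused(self):
        df = pd.DataFrame({"participant": ["P1", "P2"], "g": ["A", "A"],
                           "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_lmm(df, "y", ["g"])

    def test_diagnostics_emitted(self, rng):
        df = crossover_frame(rng)
        fit = fit_lmm(df, "y", ["visit", "tens"], max_order=2)
        assert "shapiro_p" in fit.diagnostics


class TestFitOls:
    def test_balanced_two_group_matches_ttest(self, rng):
        xa = rng.normal(0, 1, 15)
        xb = rng.normal(1, 1, 15)
        df = pd.DataFrame({"g": ["A"] * 15 + ["B"] * 15,
                           "y": np.concatenate([xa, xb])})
        fit = fit_ols(df, "y", ["g"])
        an = type3_anova(fit)
        t, p = sps.ttest_ind(xa, xb)
        assert an.loc[0, "F"] == pytest.approx(float(t) ** 2, rel=1e-9)
        assert an.loc[0, "p"] == pytest.approx(float(p), rel=1e-9)
        assert an.loc[0, "df2"] == 28

    def test_interaction_term_present(self, rng):
        df = pd.DataFrame({
            "g": ["A", "A", "B", "B"] * 8,
            "t": ["X", "Y"] * 16,
            "y": rng.normal(size=32),
        })
        an = type3_anova(fit_ols(df, "y", ["g", "t"]))
        assert set(an["term"]) == {"g", "t", "g:t"}
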