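"""Change scores, t-tests, ANOVA, correlations, mixed models and LRTs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from groovetap.cohort_stats import (
    LMESpec,
    change_scores,
    correlations,
    fit_lme,
    lrt,
    one_way_anova,
    paired_t,
    tukey_hsd,
    welch_t,
    welch_t_from_summaries,
)
from groovetap.io_formats import UPDRSRecord


def make_records(pre_totals, post_totals=None):
    recs = []
    for i, tot in enumerate(pre_totals):
        recs.append(UPDRSRecord(f"p{i}", "pre", 2, 12, min(108, tot - 17), 3))
    if post_totals:
        for i, tot in enumerate(post_totals):
            if tot is not None:
                recs.append(UPDRSRecord(f"p{i}", "post", 2, 12, min(108, tot - 17), 3))
    return recs


class TestChangeScores:
    def test_delta_sign_convention(self):
        recs = make_records([30, 40, 50], [21, 38, 45])
        table = change_scores(recs)
        assert table.loc[table.participant_id == "p0", "delta"].item() == -9

    def test_z_scores_standardized(self):
        recs = make_records([30, 40, 50, 60], [25, 38, 45, 50])
        table = change_scores(recs)
        assert table["z_delta"].mean() == pytest.approx(0.0, abs=1e-9)
        assert table["z_delta"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_non_completers_excluded(self):
        recs = make_records([30, 40, 50], [25, 38, None])
        table = change_scores(recs)
        assert len(table) == 2

    def test_zero_variance_errors(self):
        recs = make_records([30, 40], [25, 35])  # both deltas -5
        with pytest.raises(ValueError, match="variance"):
            change_scores(recs)


class TestTTests:
    def test_paired_identical_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_paired_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)
        res = paired_t(x, y)
        t, p = stats.ttest_rel(x, y)
        assert res["t"] == pytest.approx(t)
        assert res["p"] == pytest.approx(p)

    def test_welch_reduces_to_pooled_for_equal_groups(self, rng):
        a = rng.normal(0, 1, 20)
        b = a + 0.5  # identical variance, equal n
        res = welch_t(a, b)
        assert res["df"] == pytest.approx(2 * 20 - 2)

    def test_welch_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 2, 15)
        res = welch_t(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(t)
        assert res["p"] == pytest.approx(p)

    def test_group_dprime_summary_comparison(self):
        # PD 1.70 +- 0.962 (n=30) vs control 2.29 +- 0.795 (n=19):
        # Welch t ~ -2.34 on ~43.6 fractional df
        res = welch_t_from_summaries(1.70, 0.962, 30, 2.29, 0.795, 19)
        assert res["t"] == pytest.approx(-2.34, abs=0.02)
        assert res["df"] == pytest.approx(43.6, abs=0.5)


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        res = one_way_anova([g, g, g])
        assert res["F"] == pytest.approx(0.0)

    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        res = one_way_anova([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res["F"] == pytest.approx(t**2)

    def test_ss_decomposition(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.0)]
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        assert ss_between + ss_within == pytest.approx(ss_total, abs=1e-9)
        res = one_way_anova(groups)
        assert res["F"] == pytest.approx(
            (ss_between / 2) / (ss_within / (len(allv) - 3))
        )

    def test_tukey_intervals_contain_raw_difference(self, rng):
        groups = {k: rng.normal(m, 1, 15) for k, m in
                  [("a", 0.0), ("b", 0.6), ("c", 1.2)]}
        frame = tukey_hsd(groups)
        for _, row in frame.iterrows():
            raw = groups[row["group2"]].mean() - groups[row["group1"]].mean()
            assert row["lwr"] <= raw <= row["upr"]
            assert row["diff"] == pytest.approx(raw, abs=1e-9)


class TestCorrelations:
    def test_identity_perfect_both_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlations(x, x, "pearson")["r"] == pytest.approx(1.0)
        assert correlations(x, x, "spearman")["r"] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(1, 5, 20)
        y = x**3
        assert correlations(x, y, "spearman")["r"] == pytest.approx(1.0)
        assert correlations(x, y, "pearson")["r"] < 1.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            correlations(np.ones(5), np.arange(5.0))

    def test_parameter_recovery(self, rng):
        # generate with a target association and recover it within the CI
        n, rho = 200, 0.5
        x = rng.normal(0, 1, n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        res = correlations(x, y, "pearson")
        se = 1 / np.sqrt(n - 3)
        z = np.arctanh(res["r"])
        assert abs(z - np.arctanh(rho)) < 2.5 * se


def simulate_lme_table(rng, n_participants=50, n_trials=16,
                       intercept_sd=np.sqrt(0.5), resid_sd=1.0, beta_groove=0.0):
    rows = []
    for i in range(n_participants):
        u = rng.normal(0, intercept_sd)
        for j in range(n_trials):
            groove = "high" if j % 2 == 0 else "low"
            y = 1.0 + u + (beta_groove if groove == "low" else 0.0) \
                + rng.normal(0, resid_sd)
            rows.append({"participant_id": f"p{i}", "groove": groove, "log_H": y})
    return pd.DataFrame(rows)


class TestLME:
    def test_variance_components_recovered(self, rng):
        # a single 50-group fit estimates the intercept variance with
        # ~20% sampling error, so average the estimates over replicates
        re_vars, resids = [], []
        for _ in range(5):
            table = simulate_lme_table(rng)
            fit = fit_lme(table, LMESpec("log_H", ()))
            re_vars.append(float(fit.cov_re.iloc[0, 0]))
            resids.append(float(fit.scale))
        assert np.mean(re_vars) == pytest.approx(0.5, rel=0.2)
        assert np.mean(resids) == pytest.approx(1.0, rel=0.2)

    def test_zero_between_variance_boundary(self, rng):
        table = simulate_lme_table(rng, intercept_sd=0.0)
        fit = fit_lme(table, LMESpec("log_H", ()))
        assert float(fit.cov_re.iloc[0, 0]) < 0.05

    def test_extra_predictor_never_decreases_loglik(self, rng):
        table = simulate_lme_table(rng, n_participants=20, n_trials=8)
        table["noise"] = rng.normal(0, 1, len(table))
        base = fit_lme(table, LMESpec("log_H", ()))
        ext = fit_lme(table, LMESpec("log_H", ("noise",)))
        assert ext.llf >= base.llf - 1e-6

    def test_singular_design_names_columns(self, rng):
        table = simulate_lme_table(rng, n_participants=10, n_trials=4)
        table["copy1"] = 1.0  # aliased with the intercept
        with pytest.raises(ValueError, match="singular"):
            fit_lme(table, LMESpec("log_H", ("copy1",)))


class TestLRT:
    def test_identical_models_chi_zero(self, rng):
        table = simulate_lme_table(rng, n_participants=15, n_trials=6)
        base = fit_lme(table, LMESpec("log_H", ()))
        ext = fit_lme(table, LMESpec("log_H", ("groove",)))
        res = lrt(base, ext)
        assert res.chi_sq >= 0
        assert res.df == 1

    def test_strong_effect_detected(self, rng):
        table = simulate_lme_table(rng, beta_groove=1.0,
                                   n_participants=30, n_trials=10)
        base = fit_lme(table, LMESpec("log_H", ()))
        ext = fit_lme(table, LMESpec("log_H", ("groove",)))
        assert lrt(base, ext).p < 1e-6

    def test_non_nested_rejected(self, rng):
        table = simulate_lme_table(rng, n_participants=10, n_trials=4)
        table["x"] = rng.normal(0, 1, len(table))
        a = fit_lme(table, LMESpec("log_H", ("groove",)))
        b = fit_lme(table, LMESpec("log_H", ("x",)))
        with pytest.raises(ValueError):
            lrt(a, b)
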