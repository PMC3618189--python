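"""Descriptive tests, covariate screening, adjusted comparison, Holm correction."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trabmri import (adjusted_group_comparison, compare_battery,
                     descriptive_tests, holm_adjust, screen_covariate)
from trabmri.stats import DegenerateCovariateWarning, StatsError
from trabmri.synthgen import CohortSpec, generate_cohort

from oracles import holm_stepdown

PUBLISHED_RAW_P = [0.172, 0.010, 0.225, 0.263, 0.661, 0.206, 0.119, 0.221, 0.566]


class TestDescriptive:
    def test_identical_groups_give_p_one(self):
        out = descriptive_tests(([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_summary_mode_reproduces_bmi_comparison(self):
        """Group BMI 34.6 (7.6) vs 27.9 (5.5), n=30/30 → p < 0.001."""
        out = descriptive_tests(kind="continuous",
                                summary={"mean": (34.6, 27.9),
                                         "sd": (7.6, 5.5), "n": (30, 30)})
        assert out["p"] < 0.001

    def test_categorical_chi_square(self):
        out = descriptive_tests([[11, 14], [4, 26]], kind="categorical")
        assert 0 < out["p"] < 0.05
        with pytest.raises(StatsError):
            descriptive_tests([[0, 0], [4, 26]], kind="categorical")

    def test_constant_variable_fails(self):
        with pytest.raises(StatsError):
            descriptive_tests(([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_null_rejection_rate_near_alpha(self):
        """Permuting labels under the null rejects at ≈ α."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=40)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            perm = rng.permutation(values)
            out = descriptive_tests((perm[:20], perm[20:]))
            rejections += out["p"] < 0.05
        rate = rejections / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestScreen:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        s = screen_covariate(x, x)
        assert s.correlation_r == pytest.approx(1.0)
        assert s.included

    def test_independent_covariate_rarely_included(self):
        rng = np.random.default_rng(1)
        included = sum(
            screen_covariate(rng.normal(size=35), rng.normal(size=35)).included
            for _ in range(500))
        assert included / 500 < 0.10

    def test_zero_variance_excluded_with_warning(self):
        with pytest.warns(DegenerateCovariateWarning):
            s = screen_covariate(np.ones(10), np.arange(10.0))
        assert not s.included

    def test_emulated_ethnicity_association_recovered(self):
        """Cohorts built with the ethnicity effect show r ≈ −0.36 on the
        primary outcome at the emulated Caucasian fractions."""
        rs = []
        for seed in range(40):
            out = generate_cohort(CohortSpec(n_diabetes=14, n_control=21,
                                             seed=seed))
            truth = out["truth"]
            if truth.caucasian.nunique() < 2:
                continue        # degenerate draw: covered by the zero-variance test
            rs.append(screen_covariate(
                truth.caucasian.astype(float),
                truth.pct_hole_size).correlation_r)
        assert np.mean(rs) == pytest.approx(-0.364, abs=0.15)


class TestAdjustedComparison:
    def test_no_covariates_reduces_to_pooled_t(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(0, 1, 14), rng.normal(1, 1, 21)])
        groups = ["diabetes"] * 14 + ["control"] * 21
        res = adjusted_group_comparison(y, groups)
        from scipy import stats as sps
        t, p = sps.ttest_ind(y[:14], y[14:], equal_var=True)
        assert res.raw_p == pytest.approx(p, abs=1e-10)
        assert res.adjusted_mean_diabetes == pytest.approx(y[:14].mean(), abs=1e-10)
        assert res.adjusted_mean_control == pytest.approx(y[14:].mean(), abs=1e-10)

    def test_balanced_covariate_leaves_difference_unchanged(self):
        rng = np.random.default_rng(4)
        cov = np.tile(rng.normal(size=12), 2)
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(2, 1, 12)])
        groups = ["diabetes"] * 12 + ["control"] * 12
        unadj = adjusted_group_comparison(y, groups)
        adj = adjusted_group_comparison(y, groups,
                                        pd.DataFrame({"c": cov}))
        assert adj.difference == pytest.approx(unadj.difference, abs=1e-10)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        y = rng.normal(size=20)
        with pytest.raises(StatsError, match="collinear"):
            adjusted_group_comparison(y, ["diabetes"] * 10 + ["control"] * 10,
                                      cov)

    def test_degenerate_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        groups = ["diabetes"] * 10 + ["control"] * 10
        with pytest.warns(DegenerateCovariateWarning):
            res = adjusted_group_comparison(y, groups,
                                            pd.DataFrame({"c": np.ones(20)}))
        assert res.covariates == ()

    def test_minimum_group_size_enforced(self):
        with pytest.raises(StatsError):
            adjusted_group_comparison([1.0, 2.0, 3.0, 4.0],
                                      ["diabetes", "diabetes",
                                       "control", "control"],
                                      pd.DataFrame({"c": [1.0, 2, 3, 4]}))

    def test_planted_effect_recovered_in_expectation(self):
        """Mean estimated group difference over replicates ≈ planted effect."""
        effect = 17.2
        diffs, ses = [], []
        for seed in range(60):
            out = generate_cohort(CohortSpec(
                n_diabetes=14, n_control=21, seed=seed,
                effect_pct_change={"hole_count": effect}))
            truth = out["truth"]
            res = adjusted_group_comparison(
                truth.pct_hole_count, truth.group,
                pd.DataFrame({"caucasian": truth.caucasian.astype(float)}))
            diffs.append(res.difference)
            ses.append(res.se_difference)
        se_mean = np.mean(ses) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(effect, abs=2 * np.mean(ses))
        assert abs(np.mean(diffs) - effect) < 4 * se_mean


class TestHolm:
    def test_published_nine_pvalue_family(self):
        adj = dict(zip(PUBLISHED_RAW_P, holm_adjust(PUBLISHED_RAW_P)))
        assert adj[0.010] == pytest.approx(0.090)
        assert adj[0.119] == pytest.approx(0.952)
        for p in PUBLISHED_RAW_P:
            if p >= 0.172:
                assert adj[p] == 1.0

    def test_single_p_unchanged(self):
        assert holm_adjust([0.042])[0] == pytest.approx(0.042)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            holm_adjust([0.2, 1.4])
        with pytest.raises(StatsError):
            holm_adjust([])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_equals_stepdown_oracle_and_statsmodels(self, pvals):
        got = holm_adjust(pvals)
        np.testing.assert_allclose(got, holm_stepdown(pvals), atol=1e-12)
        from statsmodels.stats.multitest import multipletests
        _, sm_adj, _, _ = multipletests(pvals, method="holm")
        np.testing.assert_allclose(got, sm_adj, atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_monotonicity_and_bounds(self, pvals):
        p = np.asarray(pvals)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBattery:
    def test_battery_reports_all_variables_with_holm(self):
        out = generate_cohort(CohortSpec(n_diabetes=8, n_control=8, seed=1))
        table = out["truth"].assign(caucasian=lambda d: d.caucasian.astype(float))
        from trabmri.morphometry import VARIABLES
        res = compare_battery(table, variables=VARIABLES,
                              covariate_cols=["caucasian"])
        assert list(res.variable) == list(VARIABLES)
        assert np.all(res.holm_p >= res.raw_p - 1e-12)
        assert np.all(res.holm_p <= 1.0)
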