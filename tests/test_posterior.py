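"""Posterior summaries, ICC, per-line CVs, fold ranges, rank correlations."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fecvar
from fecvar.posterior import (
    CorrelationResult,
    UsageError,
    cross_environment_cv,
    fold_range,
    icc_sd_scale,
    icc_variance_scale,
    line_summaries,
    mean_cv_relationship,
    spearman_correlation,
    summarize_trace,
)
from fecvar.simulate import LogNormalSDLaw, SyntheticConfig, generate_dataset


class TestSummarizeTrace:
    def test_constant_sequence(self):
        s = summarize_trace(np.full(100, 3.5))
        assert (s.mean, s.sd, s.ci_low, s.ci_high, s.mc_error) == (3.5, 0, 3.5, 3.5, 0)

    def test_uniform_grid_order_statistics(self):
        n = 10000
        s = summarize_trace(np.arange(1, n + 1))
        # linear-interpolation percentiles of the grid 1..n in closed form
        assert s.ci_low == pytest.approx(1 + 0.025 * (n - 1))
        assert s.ci_high == pytest.approx(1 + 0.975 * (n - 1))
        assert s.mean == pytest.approx((n + 1) / 2)
        assert s.sd == pytest.approx(math.sqrt(n * (n + 1) / 12))

    def test_normal_sequence_quantiles(self):
        rng = np.random.default_rng(0)
        s = summarize_trace(rng.standard_normal(400000))
        assert s.ci_low == pytest.approx(-1.96, abs=0.02)
        assert s.ci_high == pytest.approx(1.96, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            summarize_trace([])


class TestICC:
    def test_published_dispersions_on_both_scales(self):
        # SD-scale shares match the published percentages; variance-scale
        # follows the stated formula
        assert round(100 * icc_sd_scale(108.4, 57.5)) == 65
        assert round(100 * icc_sd_scale(256.4, 65.8)) == 80
        assert round(100 * icc_variance_scale(108.4, 57.5)) == 78
        assert round(100 * icc_variance_scale(256.4, 65.8)) == 94

    def test_degenerate_cases(self):
        assert icc_sd_scale(0.0, 5.0) == 0.0
        assert icc_variance_scale(0.0, 5.0) == 0.0
        assert icc_sd_scale(5.0, 5.0) == 0.5
        assert icc_variance_scale(5.0, 5.0) == 0.5

    @given(st.floats(1.0, 100.0), st.floats(1.0, 100.0), st.floats(0.01, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_among_dispersion(self, among, resid, bump):
        for icc in (icc_sd_scale, icc_variance_scale):
            assert icc(among + bump, resid) > icc(among, resid)

    def test_variance_components_from_fit(self, bp_fit2):
        vc = fecvar.variance_components(bp_fit2)
        assert 0 <= vc.icc_sd_scale <= vc.icc_variance_scale <= 1
        assert vc.sigma_among.ci_low <= vc.sigma_among.mean <= vc.sigma_among.ci_high

    def test_wrong_model_rejected(self, bp_fit3):
        with pytest.raises(UsageError):
            fecvar.variance_components(bp_fit3)


class TestLineSummaries:
    def test_hand_computed_line(self):
        df = pd.DataFrame(
            {
                "line_id": ["L"] * 3,
                "block": [1, 2, 3],
                "food": "f",
                "replicate": 1,
                "lifetime_fecundity": [10.0, 20.0, 30.0],
            }
        )
        out = line_summaries(fecvar.Dataset(df))
        row = out.iloc[0]
        assert (row["mean_lf"], row["sd_lf"], row["cv"]) == (20.0, 10.0, 0.5)

    def test_single_observation_cv_flagged(self, tiny_df):
        df = pd.concat(
            [tiny_df, pd.DataFrame([{"line_id": "C", "block": 1, "food": "e_coli",
                                     "replicate": 1, "lifetime_fecundity": 5.0}])],
            ignore_index=True,
        )
        out = line_summaries(fecvar.Dataset(df)).set_index("line_id")
        assert not out.loc["C", "cv_defined"]
        assert np.isnan(out.loc["C", "cv"])
        assert out.loc["A", "cv_defined"]

    def test_model3_posteriors_attached(self, bp_data, bp_fit3):
        out = line_summaries(bp_data, bp_fit3)
        assert {"within_var_mean", "within_var_ci_low", "within_var_ci_high"} <= set(
            out.columns
        )
        assert (out["within_var_ci_low"] <= out["within_var_mean"]).all()

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=30)
    def test_cv_scale_invariance(self, c):
        df = pd.DataFrame(
            {
                "line_id": "L",
                "block": 1,
                "food": "f",
                "replicate": range(1, 6),
                "lifetime_fecundity": [11.0, 14.0, 9.0, 22.0, 17.0],
            }
        )
        base = line_summaries(fecvar.Dataset(df)).iloc[0]["cv"]
        scaled_df = df.assign(lifetime_fecundity=df["lifetime_fecundity"] * c)
        scaled = line_summaries(fecvar.Dataset(scaled_df)).iloc[0]["cv"]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestFoldRange:
    def test_published_endpoints(self):
        assert fold_range([525.8, 11310.0]) == pytest.approx(21.5, abs=0.05)
        assert fold_range([473.6, 13180.0]) == pytest.approx(27.8, abs=0.05)

    def test_constant_values(self):
        assert fold_range([5.0, 5.0, 5.0]) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(UsageError):
            fold_range([2.0, 0.0])


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        assert spearman_correlation(x, np.exp(x)).rho == 1.0
        assert spearman_correlation(x, -(x**3)).rho == -1.0

    def test_eight_point_permutation_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0, 8.0, 6.0])
        res = spearman_correlation(x, y)
        # no ties: classical rank-difference formula
        d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        n = len(x)
        rho_formula = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
        assert res.rho == pytest.approx(rho_formula, rel=1e-12)
        # brute-force enumeration of all 8! permutations
        count = 0
        total = 0
        for perm in permutations(range(n)):
            dd = np.arange(n) - np.array(perm)
            r = 1 - 6 * (dd**2).sum() / (n * (n**2 - 1))
            count += abs(r) >= abs(rho_formula) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, rel=1e-12)

    def test_t_approximation_close_to_exact_for_n9(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(9)
        y = x + rng.standard_normal(9)
        exact = spearman_correlation(x, y)
        approx = spearman_correlation(x, y, exact_below=4)
        assert approx.rho == pytest.approx(exact.rho, rel=1e-9)
        assert abs(approx.p_value - exact.p_value) < 0.05

    def test_constant_input_degenerate(self):
        res = spearman_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res == CorrelationResult(rho=0.0, p_value=1.0, n=4, degenerate=True)

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            spearman_correlation([1, 2, 3, 4], [1, 2, 3])

    @given(st.permutations(list(range(10))))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transform_of_y(self, perm):
        x = np.arange(10.0)
        y = np.array(perm, dtype=float)
        base = spearman_correlation(x, y)
        trans = spearman_correlation(x, np.expm1(y / 3.0))
        assert trans.rho == pytest.approx(base.rho, rel=1e-9)


class TestMeanCVRelationship:
    def test_negative_coupling_detected(self):
        cfg = SyntheticConfig(
            grand_mean=100.0,
            sigma_among=25.0,
            within_sd_law=LogNormalSDLaw(median_sd=30.0, sigma_log=0.2),
            mean_cv_coupling=-0.03,
            n_lines=21,
            n_blocks=1,
            n_replicates=100,
        )
        data = generate_dataset(cfg, seed=23)
        res = mean_cv_relationship(line_summaries(data))
        assert res.rho < 0
        assert res.p_value < 0.05

    def test_null_coupling_weak_correlation(self):
        cfg = SyntheticConfig(
            grand_mean=100.0,
            sigma_among=10.0,
            within_sd_law=LogNormalSDLaw(median_sd=30.0, sigma_log=0.5),
            mean_cv_coupling=0.0,
            n_lines=200,
            n_blocks=1,
            n_replicates=200,
        )
        data = generate_dataset(cfg, seed=24)
        res = mean_cv_relationship(line_summaries(data))
        assert abs(res.rho) < 0.2

    def test_constant_cvs_degenerate(self):
        summaries = pd.DataFrame(
            {
                "line_id": list("abcd"),
                "mean_lf": [10.0, 20.0, 30.0, 40.0],
                "cv": [0.5, 0.5, 0.5, 0.5],
                "cv_defined": True,
            }
        )
        res = mean_cv_relationship(summaries)
        assert res.degenerate and res.rho == 0.0


class TestCrossEnvironmentCV:
    def test_identical_environments(self, bp_data):
        s = line_summaries(bp_data)
        res = cross_environment_cv(s, s)
        assert res.rho == 1.0

    def test_correlated_environments_positive(self):
        cfg = SyntheticConfig(
            grand_mean=100.0,
            sigma_among=10.0,
            within_sd_law=LogNormalSDLaw(median_sd=30.0, sigma_log=0.5),
            n_lines=21,
            n_blocks=1,
            n_replicates=200,
        )
        paired = fecvar.PairedEnvironmentConfig(cfg, cfg, cv_correlation=0.9)
        d1, d2 = fecvar.generate_paired_environments(paired, seed=31)
        res = cross_environment_cv(line_summaries(d1), line_summaries(d2))
        assert res.rho > 0.4
        assert res.p_value < 0.05

    def test_independent_environments_weak(self):
        cfg = SyntheticConfig(
            grand_mean=100.0,
            sigma_among=10.0,
            within_sd_law=LogNormalSDLaw(median_sd=30.0, sigma_log=0.5),
            n_lines=200,
            n_blocks=1,
            n_replicates=100,
        )
        paired = fecvar.PairedEnvironmentConfig(cfg, cfg, cv_correlation=0.0)
        d1, d2 = fecvar.generate_paired_environments(paired, seed=32)
        res = cross_environment_cv(line_summaries(d1), line_summaries(d2))
        assert abs(res.rho) < 0.15

    def test_unmatched_lines_named(self, bp_data):
        s1 = line_summaries(bp_data)
        s2 = s1[s1["line_id"] != "21"]
        with pytest.raises(UsageError, match="21"):
            cross_environment_cv(s1, s2)
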