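"""Space-time local regression: kernels, local solves, AICc, selection."""

import numpy as np
import pytest

from gtwrkit import synth
from gtwrkit.errors import AICcUndefinedError, InvalidArgumentError
from gtwrkit.global_models import hat_trace_aicc, ols_fit
from gtwrkit.gtwr import (
    GTWRConfig,
    classify_strength,
    coefficient_summary,
    combined_weights,
    fit,
    local_fit,
    residual_moran,
    select_bandwidths,
    spatial_weight,
    temporal_weight,
)
from gtwrkit.weights import queen_weights, row_standardize


class TestKernels:
    def test_spatial_kernel_at_origin(self):
        assert spatial_weight(0.0, 74.8) == 1.0

    def test_spatial_kernel_at_one_bandwidth(self):
        # d = b gives exp(-1/2), evaluated at the 74.8 km scale
        assert spatial_weight(74.8, 74.8) == pytest.approx(np.exp(-0.5))
        assert spatial_weight(74.8, 74.8) == pytest.approx(0.6065, abs=1e-4)

    def test_spatial_kernel_far_field(self):
        b = 10.0
        assert spatial_weight(3 * b, b) == pytest.approx(np.exp(-9 / 2))

    def test_spatial_kernel_monotone_decreasing(self):
        d = np.linspace(0, 100, 50)
        w = spatial_weight(d, 30.0)
        assert np.all(np.diff(w) < 0)

    def test_temporal_kernel_values(self):
        assert temporal_weight(2020, 2020, 3.2) == 1.0
        assert temporal_weight(2021, 2020, 3.2) == pytest.approx(np.exp(-1 / 3.2))
        assert temporal_weight(2021, 2020, 3.2) == pytest.approx(0.7316, abs=1e-4)

    def test_temporal_kernel_symmetric(self):
        assert temporal_weight(2020, 2022, 1.7) == temporal_weight(2022, 2020, 1.7)

    def test_nonpositive_bandwidths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spatial_weight(1.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            temporal_weight(0, 1, -1.0)
        with pytest.raises(InvalidArgumentError):
            GTWRConfig(b=0.0, h=1.0)

    def test_combined_is_product_of_kernels(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, (10, 2))
        times = rng.integers(2020, 2023, 10).astype(float)
        cfg = GTWRConfig(b=40.0, h=2.0)
        w = combined_weights(3, coords, times, cfg)
        assert w[3] == pytest.approx(1.0)
        for j in range(10):
            d = np.hypot(*(coords[j] - coords[3]))
            assert w[j] == pytest.approx(
                spatial_weight(d, 40.0) * temporal_weight(times[j], times[3], 2.0)
            )

    def test_flat_kernels_give_unit_weights(self):
        coords = np.array([[0.0, 0.0], [50.0, 10.0], [120.0, 40.0]])
        times = np.array([2020.0, 2021.0, 2022.0])
        w = combined_weights(0, coords, times, GTWRConfig(b=1e12, h=1e12))
        assert np.allclose(w, 1.0)


class TestLocalFit:
    def test_unit_weights_reduce_to_ols(self, design13):
        X, y, *_ = design13
        beta, _, _ = local_fit(X, y, np.ones(len(y)), i=0)
        assert np.allclose(beta, ols_fit(X, y).params, atol=1e-8)

    def test_indicator_weights_fit_the_subset(self, design13):
        X, y, *_ = design13
        w = np.zeros(len(y))
        w[:20] = 1.0
        beta, _, _ = local_fit(X, y, w, i=0)
        assert np.allclose(beta, ols_fit(X[:20], y[:20]).params, atol=1e-8)

    def test_matches_weighted_normal_equation_oracle(self, design13):
        X, y, *_ = design13
        rng = np.random.default_rng(2)
        w = rng.uniform(0.05, 1.0, len(y))
        beta, _, _ = local_fit(X, y, w, i=0)
        Wm = np.diag(w)
        oracle = np.linalg.solve(X.T @ Wm @ X, X.T @ Wm @ y)
        assert np.allclose(beta, oracle, atol=1e-10)


class TestFit:
    def test_global_limit_matches_ols(self, design13):
        X, y, coords, times, names = design13
        res = fit(X, y, coords, times, GTWRConfig(b=1e9, h=1e9), names=names)
        ols = ols_fit(X, y, names=names)
        assert np.max(np.abs(res.beta - ols.params)) < 1e-6
        assert res.trace_s == pytest.approx(X.shape[1], abs=1e-6)
        assert res.r2 == pytest.approx(ols.r2, abs=1e-6)

    def test_fitted_plus_residual_is_exact(self, design13):
        X, y, coords, times, names = design13
        res = fit(X, y, coords, times, GTWRConfig(b=50.0, h=2.0), names=names)
        assert np.allclose(res.fitted + res.residuals, y, atol=1e-12)

    def test_hat_trace_bounds(self, design13):
        X, y, coords, times, _ = design13
        res = fit(X, y, coords, times, GTWRConfig(b=40.0, h=1.5))
        assert X.shape[1] - 1e-8 <= res.trace_s <= len(y)

    def test_aicc_reproduces_hand_computation(self):
        # n=20, sigma=0.5, tr(S)=4:
        # 2*20*ln(0.5) + 20*ln(2pi) + 20*(24/14)
        val = hat_trace_aicc(20, 0.5, 4.0)
        expect = 40 * np.log(0.5) + 20 * np.log(2 * np.pi) + 20 * (24 / 14)
        assert val == pytest.approx(expect, rel=1e-12)

    def test_aicc_undefined_when_df_exhausted(self):
        with pytest.raises(AICcUndefinedError):
            hat_trace_aicc(10, 1.0, 9.0)

    def test_gtwr_r2_dominates_ols(self, design13):
        X, y, coords, times, names = design13
        b, h, _ = select_bandwidths(X, y, coords, times, refine=False)
        res = fit(X, y, coords, times, GTWRConfig(b=b, h=h), names=names)
        assert res.r2 >= ols_fit(X, y).r2 - 1e-9


class TestBandwidthSelection:
    def test_single_point_grid_returned(self, design13):
        X, y, coords, times, _ = design13
        b, h, surface = select_bandwidths(
            X, y, coords, times, b_grid=[80.0], h_grid=[2.0], refine=False
        )
        assert (b, h) == (80.0, 2.0)
        assert len(surface) == 1

    def test_argmin_contract(self, design13):
        X, y, coords, times, _ = design13
        b, h, surface = select_bandwidths(X, y, coords, times, refine=False)
        chosen = surface.loc[(surface["b"] == b) & (surface["h"] == h), "aicc"].iloc[0]
        assert chosen <= surface["aicc"].min() + 1e-12

    def test_stationary_truth_prefers_global_smoothing(self):
        """With spatially constant true coefficients, locality buys nothing:
        the widest grid bandwidth must be AICc-competitive with the minimum
        in every replicate, and the selector should land in the upper half
        of the grid in most replicates."""
        years = [2020, 2021, 2022]
        specs = {
            "intercept": synth.GradientSpec(a=1.0),
            "x1": synth.GradientSpec(a=0.8),
            "x2": synth.GradientSpec(a=-0.5),
            "x3": synth.GradientSpec(a=0.3),
        }
        b_grid = np.geomspace(20, 2000, 8)
        wide_picks = 0
        for seed in range(6):
            regions = synth.generate_region_lattice(13, seed=seed)
            panel = synth.generate_covariate_panel(
                regions, years, seed=seed + 100, n_covariates=3, collinear_pair=False
            )
            surfaces = synth.generate_coefficient_surfaces(regions, years, specs)
            y = synth.generate_outcome(panel, surfaces, noise_sd=0.25, seed=seed + 200)
            X = np.column_stack(
                [np.ones(len(panel)), panel[["x1", "x2", "x3"]].to_numpy()]
            )
            b, _, surface = select_bandwidths(
                X, y, panel[["u", "v"]].to_numpy(), panel["year"].to_numpy(),
                b_grid=b_grid, h_grid=[0.5, 2.0, 8.0, 32.0], refine=False,
            )
            aicc_widest = surface.loc[surface["b"] == b_grid[-1], "aicc"].min()
            assert aicc_widest <= surface["aicc"].min() + 3.0
            wide_picks += b >= b_grid[len(b_grid) // 2]
        assert wide_picks >= 3


class TestSummaries:
    def test_constant_estimates_degenerate_moments(self, design13):
        X, y, coords, times, names = design13
        res = fit(X, y, coords, times, GTWRConfig(b=1e9, h=1e9), names=names)
        summ = coefficient_summary(res)
        row = summ[summ["predictor"] == "x1"].iloc[0]
        assert row["sd"] == pytest.approx(0.0, abs=1e-6)
        assert row["min"] == pytest.approx(row["max"], abs=1e-6)

    def test_moments_match_explicit_loop(self, design13):
        X, y, coords, times, names = design13
        res = fit(X, y, coords, times, GTWRConfig(b=50.0, h=2.0), names=names)
        summ = coefficient_summary(res, t_cutoff=1.96).set_index("predictor")
        k = names.index("x2")
        b = res.beta[:, k]
        assert summ.loc["x2", "mean"] == pytest.approx(sum(b) / len(b))
        assert summ.loc["x2", "min"] == pytest.approx(min(b))
        assert summ.loc["x2", "max"] == pytest.approx(max(b))
        n_sig = sum(abs(t) >= 1.96 for t in res.tvalues[:, k])
        assert summ.loc["x2", "pct_significant"] == pytest.approx(100 * n_sig / len(b))

    def test_min_mean_max_ordered(self, design13):
        X, y, coords, times, names = design13
        res = fit(X, y, coords, times, GTWRConfig(b=50.0, h=2.0), names=names)
        summ = coefficient_summary(res)
        assert (summ["min"] <= summ["mean"] + 1e-12).all()
        assert (summ["mean"] <= summ["max"] + 1e-12).all()


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "beta,label",
        [
            (0.0, "none"),
            (0.1, "weak positive"),
            (0.3, "moderate positive"),
            (0.25, "moderate positive"),  # right-open bins
            (0.7, "strong positive"),
            (1.2, "very strong positive"),
            (-0.3, "moderate negative"),
            (-1.2, "very strong negative"),
        ],
    )
    def test_bins(self, beta, label):
        assert classify_strength(beta) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_strength(float("nan"))


class TestResidualMoran:
    def test_white_noise_residuals_nonsignificant_on_average(self, regions13, design13):
        X, y, coords, times, names = design13
        W = row_standardize(queen_weights(regions13))
        res = fit(
            X, y, coords, times, GTWRConfig(b=60.0, h=2.0), names=names,
            region_ids=tuple(np.repeat([r.region_id for r in regions13], 3)),
        )
        out = residual_moran(res, W, by_year=True, n_perm=199, seed=0)
        assert set(out) == {"pooled", "2020", "2021", "2022"}
        assert np.isfinite(out["pooled"].I)

    def test_clustered_residuals_detected(self, regions13):
        """Inject an east-west residual gradient and confirm a small p."""
        from gtwrkit.moran import global_moran

        W = row_standardize(queen_weights(regions13))
        u = np.array([r.centroid[0] for r in regions13])
        x = u + np.random.default_rng(1).normal(0, 5, 13)
        res = global_moran(x, W, n_perm=999, seed=2)
        assert res.p_perm < 0.05
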