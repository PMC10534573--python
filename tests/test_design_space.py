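import copy

import numpy as np
import pytest

import chromdoe as cd
from chromdoe.design_space import DEFAULT_CMA_SET, CMACriterion, perturb_coefficients

from .conftest import WORKING_POINT, WORKING_POINT_CODED


class TestGrid:
    def test_study_discretization_has_4851_points(self, full_grid):
        assert full_grid.shape == (21, 21, 11)
        assert full_grid.n_points == 4851

    def test_levels_inclusive_endpoints(self, full_grid):
        lv = full_grid.levels("methanol_initial")
        assert lv[0] == 35.0 and lv[-1] == 40.0 and len(lv) == 21

    def test_degenerate_single_point(self):
        g = cd.GridSpec({"a": (1.0, 0.5, 1.0), "b": (2.0, 1.0, 2.0), "c": (3.0, 1.0, 3.0)})
        assert g.n_points == 1
        np.testing.assert_allclose(g.points(), [[1.0, 2.0, 3.0]])

    def test_non_integral_span_rejected(self):
        with pytest.raises(ValueError, match="not integral"):
            cd.GridSpec({"a": (0.0, 0.3, 1.0)}).levels("a")

    def test_point_order_last_factor_fastest(self, small_grid):
        pts = small_grid.points()
        assert pts[0, 2] != pts[1, 2]  # third coordinate varies first
        assert pts[0, 0] == pts[1, 0]


class TestPerturbation:
    def test_zero_se_returns_estimates(self, fitted):
        res = copy.copy(fitted["t_imp_V"])
        res.bse = res.bse * 0.0
        draws = perturb_coefficients(res, np.random.default_rng(0), 50)
        np.testing.assert_array_equal(draws, np.tile(res.params.to_numpy(), (50, 1)))

    def test_none_mode_returns_estimates(self, fitted):
        res = fitted["t_imp_V"]
        draws = perturb_coefficients(res, np.random.default_rng(0), 5, "none")
        np.testing.assert_array_equal(draws, np.tile(res.params.to_numpy(), (5, 1)))

    def test_draws_stay_within_one_se(self, fitted):
        res = fitted["t_imp_V"]
        draws = perturb_coefficients(res, np.random.default_rng(1), 2000)
        lo = res.params.to_numpy() - res.bse.to_numpy()
        hi = res.params.to_numpy() + res.bse.to_numpy()
        assert np.all(draws >= lo) and np.all(draws <= hi)

    def test_mean_converges_to_estimate(self, fitted):
        # uniform on +/-SE has variance SE^2/3, so the mean of n draws has
        # standard deviation SE / sqrt(3 n); 4 sigma keeps the joint check
        # over all 10 coefficients at a negligible failure probability
        res = fitted["t_imp_V"]
        n = 100_000
        draws = perturb_coefficients(res, np.random.default_rng(2), n)
        tol = 4.0 * res.bse.to_numpy() / np.sqrt(3 * n)
        assert np.all(np.abs(draws.mean(axis=0) - res.params.to_numpy()) < tol)

    def test_fullwidth_mode_halves_support(self, fitted):
        res = fitted["t_imp_V"]
        draws = perturb_coefficients(res, np.random.default_rng(3), 2000, "uniform_fullwidth_se")
        assert np.all(np.abs(draws - res.params.to_numpy()) <= res.bse.to_numpy() / 2)


class TestCriteria:
    def test_working_point_satisfies_all(self, design_space):
        flags = design_space.cma_satisfied(WORKING_POINT_CODED)
        assert flags == {"t_imp_V": True, "t_range": True, "S": True, "W_USP": True}

    def test_long_gradient_low_final_methanol_violates_retention(self, design_space):
        # run 11 of the study observed t_imp_V = 18.14 min at this setting
        flags = design_space.cma_satisfied(np.array([0.0, -1.0, 1.0]))
        assert not flags["t_imp_V"]

    def test_infinite_threshold_always_true(self, fitted, factors):
        crit = CMACriterion("any", "<", np.inf, response="t_imp_V")
        space = cd.DesignSpace(fitted, factors, (crit,))
        assert space.cma_satisfied(np.array([1.0, -1.0, 1.0]))["any"]

    def test_missing_model_named(self, fitted, factors):
        crit = CMACriterion("x", "<", 1.0, response="nonexistent")
        with pytest.raises(KeyError, match="nonexistent"):
            cd.DesignSpace(fitted, factors, (crit,))

    def test_difference_criterion_uses_two_models(self, design_space):
        values = design_space.predict_cmas(WORKING_POINT_CODED)
        direct = (design_space.models["t_b_imp_III"].predict(WORKING_POINT_CODED)
                  - design_space.models["t_e_imp_x"].predict(WORKING_POINT_CODED))
        assert values["S"] == pytest.approx(direct, abs=1e-12)
        assert values["S"] == pytest.approx(0.0219, abs=1e-4)


class TestProbabilityMap:
    def test_no_perturbation_matches_brute_force_indicator(self, design_space, small_grid):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(1, 0, "none"))
        assert set(np.unique(pg.pi)) <= {0.0, 1.0}
        # independent slow oracle: per-point scalar evaluation
        expected = []
        for natural in small_grid.points():
            coded = design_space.to_coded(natural)[0]
            values = design_space.predict_cmas(coded)
            ok = (values["t_imp_V"] < 15.5 and values["t_range"] < 12.0
                  and values["S"] >= 0.0 and values["W_USP"] <= 0.235)
            expected.append(1.0 if ok else 0.0)
        np.testing.assert_array_equal(pg.pi.ravel(), expected)

    def test_same_seed_bit_identical(self, design_space, small_grid):
        mc = cd.MonteCarloConfig(400, 42)
        a = design_space.probability_map(small_grid, mc)
        b = design_space.probability_map(small_grid, mc)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_two_seeds_agree_within_binomial_error(self, design_space, small_grid):
        n = 2000
        a = design_space.probability_map(small_grid, cd.MonteCarloConfig(n, 11))
        b = design_space.probability_map(small_grid, cd.MonteCarloConfig(n, 12))
        bound = 5 * np.sqrt(0.25 / n)
        assert np.max(np.abs(a.pi - b.pi)) <= bound

    def test_joint_at_most_min_marginal(self, design_space, small_grid):
        joint, marginals = design_space.probability_map(
            small_grid, cd.MonteCarloConfig(500, 5), per_criterion=True
        )
        stacked = np.stack([m.pi for m in marginals.values()])
        assert np.all(joint.pi <= stacked.min(axis=0) + 1e-12)

    def test_shrinking_se_approaches_indicator(self, fitted, factors, small_grid):
        space = cd.DesignSpace(fitted, factors)
        indicator = space.probability_map(small_grid, cd.MonteCarloConfig(1, 0, "none")).pi
        mean_gap = []
        for f in (1.0, 0.1, 0.01):
            scaled = {}
            for r, res in fitted.items():
                res_f = copy.copy(res)
                res_f.bse = res.bse * f
                scaled[r] = res_f
            pi = cd.DesignSpace(scaled, factors).probability_map(
                small_grid, cd.MonteCarloConfig(1000, 7)).pi
            mean_gap.append(np.abs(pi - indicator).mean())
        assert mean_gap[0] > mean_gap[1] > mean_gap[2]
        assert mean_gap[2] < 0.02

    def test_long_format_round_trip(self, design_space, small_grid, tmp_path):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(100, 9))
        df = pg.to_frame()
        assert list(df.columns) == ["methanol_initial", "methanol_final",
                                    "gradient_duration", "pi"]
        assert len(df) == small_grid.n_points
        assert df["pi"].to_numpy().reshape(pg.pi.shape) == pytest.approx(pg.pi)


class TestDesignSpaceExtraction:
    def test_threshold_zero_includes_all(self, design_space, small_grid):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(200, 4))
        assert pg.design_space(0.0).n_points == small_grid.n_points

    def test_mask_monotone_in_threshold(self, design_space, small_grid):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(200, 4))
        counts = [pg.design_space(p).n_points for p in (0.0, 0.25, 0.5, 0.8, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold_rejected(self, design_space, small_grid):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(10, 4))
        with pytest.raises(ValueError):
            pg.design_space(1.0 + 1e-9)

    def test_bounding_box_covers_members(self, design_space, small_grid):
        pg = design_space.probability_map(small_grid, cd.MonteCarloConfig(500, 4))
        region = pg.design_space(0.5)
        if region.n_points:
            box = region.bounding_box
            assert box["methanol_initial"][0] >= 35.0
            assert box["gradient_duration"][1] <= 20.0


class TestSlice:
    def test_slice_at_grid_level_reproduces_3d_plane(self, design_space, small_grid):
        mc = cd.MonteCarloConfig(500, 13)
        pg3 = design_space.probability_map(small_grid, mc)
        grid2 = cd.GridSpec({n: small_grid.axes[n] for n in
                             ("methanol_initial", "methanol_final")})
        pg2 = design_space.slice_2d("gradient_duration", 17.5, grid2, mc)
        k = list(small_grid.levels("gradient_duration")).index(17.5)
        np.testing.assert_array_equal(pg2.pi, pg3.pi[:, :, k])

    def test_off_grid_fixed_value_supported(self, design_space):
        grid2 = cd.GridSpec({"methanol_initial": (37.0, 0.5, 39.0),
                             "methanol_final": (76.0, 1.0, 80.0)})
        pg = design_space.slice_2d("gradient_duration", 16.25, grid2,
                                   cd.MonteCarloConfig(300, 8))
        assert pg.pi.shape == (5, 5)
        assert pg.fixed == {"gradient_duration": 16.25}

    def test_fixed_value_outside_range_rejected(self, design_space, small_grid):
        grid2 = cd.GridSpec({n: small_grid.axes[n] for n in
                             ("methanol_initial", "methanol_final")})
        with pytest.raises(ValueError, match="outside experimental range"):
            design_space.slice_2d("gradient_duration", 25.0, grid2)

    def test_unknown_fixed_factor_rejected(self, design_space, small_grid):
        grid2 = cd.GridSpec({n: small_grid.axes[n] for n in
                             ("methanol_initial", "methanol_final")})
        with pytest.raises(KeyError):
            design_space.slice_2d("flow_rate", 1.0, grid2)


class TestWorkingPointReport:
    def test_all_criteria_pass_at_working_point(self, design_space):
        report = design_space.working_point_report(WORKING_POINT)
        assert len(report) == len(DEFAULT_CMA_SET)
        assert report["pass"].all()

    def test_observed_values_reported_not_asserted(self, design_space):
        observed = {"t_imp_V": 15.351, "S": 0.02, "W_USP": 0.233, "t_range": 11.033}
        report = design_space.working_point_report(WORKING_POINT, observed)
        assert "delta" in report.columns
        row = report[report["criterion"].str.startswith("t_imp_V")].iloc[0]
        assert row["observed"] == 15.351
        assert row["delta"] == pytest.approx(15.351 - 15.234, abs=2e-3)

    def test_corner_point_fails_retention_criterion(self, design_space):
        report = design_space.working_point_report((35.0, 75.0, 20.0))
        failing = report.loc[~report["pass"], "criterion"].tolist()
        assert any(c.startswith("t_imp_V") for c in failing)

    def test_point_outside_range_rejected(self, design_space):
        with pytest.raises(ValueError, match="outside"):
            design_space.working_point_report((50.0, 77.5, 16.25))
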