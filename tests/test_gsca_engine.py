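import numpy as np
import pandas as pd
import pytest

import iggsca as ig
from iggsca.gsca_engine import EstimationConfig, NonConvergenceWarning, als_fit
from iggsca.model_spec import ConstructDef, PathModel

from conftest import chain_model, gaussian_table, multi_predictor_model


def composite_model(k1=2, k2=3):
    """Two multi-indicator composites predicting a single-indicator outcome."""
    return PathModel(
        constructs=(
            ConstructDef("A", "composite", tuple(f"a{i}" for i in range(k1))),
            ConstructDef("B", "composite", tuple(f"b{i}" for i in range(k2))),
            ConstructDef("Y", "outcome", ("y",)),
        ),
        edges=(("A", "Y"), ("B", "Y")),
    )


def composite_data(n=400, seed=0, k1=2, k2=3):
    rng = np.random.default_rng(seed)
    fa, fb = rng.standard_normal(n), rng.standard_normal(n)
    cols = {f"a{i}": 0.9 * fa + 0.45 * rng.standard_normal(n) for i in range(k1)}
    cols.update({f"b{i}": 0.8 * fb + 0.6 * rng.standard_normal(n) for i in range(k2)})
    cols["y"] = 0.5 * fa - 0.3 * fb + rng.standard_normal(n)
    return ig.standardize(pd.DataFrame(cols))


class TestClosedFormOracles:
    def test_chain_paths_equal_ols_slopes(self):
        """On single-indicator models at lambda=0, ALS reproduces the
        standardized regression slopes computed from the correlation matrix."""
        model = chain_model()
        corr = [[1.0, 0.5, 0.3], [0.5, 1.0, 0.6], [0.3, 0.6, 1.0]]
        Z = ig.standardize(gaussian_table(model, corr, 300, seed=2))
        fit = als_fit(Z, model, EstimationConfig(ridge_lambda=0.0))
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        ps = fit.path_series()
        assert ps[("X", "M")] == pytest.approx(R[0, 1], abs=1e-8)
        assert ps[("M", "Y")] == pytest.approx(R[1, 2], abs=1e-8)

    def test_two_predictor_paths_equal_normal_equations(self):
        model = multi_predictor_model(2)
        corr = [[1.0, 0.4, 0.5], [0.4, 1.0, 0.35], [0.5, 0.35, 1.0]]
        Z = ig.standardize(gaussian_table(model, corr, 250, seed=3))
        fit = als_fit(Z, model, EstimationConfig(ridge_lambda=0.0))
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        beta = np.linalg.solve(R[:2, :2], R[:2, 2])
        ps = fit.path_series()
        assert ps[("X1", "Y")] == pytest.approx(beta[0], abs=1e-8)
        assert ps[("X2", "Y")] == pytest.approx(beta[1], abs=1e-8)

    def test_r_squared_matches_multiple_correlation(self):
        model = multi_predictor_model(2)
        corr = [[1.0, 0.4, 0.5], [0.4, 1.0, 0.35], [0.5, 0.35, 1.0]]
        Z = ig.standardize(gaussian_table(model, corr, 250, seed=3))
        fit = als_fit(Z, model, EstimationConfig(ridge_lambda=0.0))
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        expected = R[:2, 2] @ np.linalg.solve(R[:2, :2], R[:2, 2])
        r2 = ig.r_squared(fit)
        assert r2["Y"] == pytest.approx(expected, abs=1e-8)

    def test_r_squared_degenerate_limits(self):
        model = chain_model(("X", "Y"))
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        Z = ig.standardize(pd.DataFrame({"x": x, "y": x}))
        fit = als_fit(Z, model)
        assert ig.r_squared(fit)["Y"] == pytest.approx(1.0, abs=1e-10)
        zeroed = fit
        zeroed.paths[:] = 0
        assert ig.r_squared(zeroed)["Y"] == pytest.approx(0.0, abs=1e-10)


class TestComponents:
    def test_single_indicator_score_is_standardized_indicator(self):
        model = chain_model(("X", "Y"))
        Z = ig.standardize(gaussian_table(model, [[1, 0.3], [0.3, 1]], 50, seed=1))
        fit = als_fit(Z, model)
        np.testing.assert_allclose(fit.scores[:, 0], Z["x"], atol=1e-10)
        # weight = loading = 1 for single-indicator constructs
        assert fit.weight_series()[("X", "x")] == pytest.approx(1.0)
        assert fit.loading_series()[("X", "x")] == pytest.approx(1.0)

    def test_equal_weight_prenormalization_variance_closed_form(self):
        """Equal weights on two indicators with correlation r give a composite
        of variance (1+r)/2 before unit-variance rescaling."""
        rng = np.random.default_rng(4)
        f = rng.standard_normal(500)
        Z = ig.standardize(pd.DataFrame({
            "a0": f + 0.5 * rng.standard_normal(500),
            "a1": f + 0.5 * rng.standard_normal(500),
        }))
        r = np.corrcoef(Z["a0"], Z["a1"])[0, 1]
        w = np.full(2, 0.5)  # equal mean weights
        raw = Z.to_numpy() @ w
        assert raw.var() == pytest.approx((1 + r) / 2, abs=1e-10)

    def test_interaction_score_standardized_product(self):
        model = PathModel(
            constructs=(
                ConstructDef("G", "observed", ("g",)),
                ConstructDef("E", "observed", ("e",)),
                ConstructDef("GxE", "interaction", parents=("G", "E")),
                ConstructDef("Y", "outcome", ("y",)),
            ),
            edges=(("G", "Y"), ("E", "Y"), ("GxE", "Y")),
        )
        rng = np.random.default_rng(5)
        n = 100_000
        Z = ig.standardize(pd.DataFrame({
            "g": rng.standard_normal(n), "e": rng.standard_normal(n),
            "y": rng.standard_normal(n),
        }))
        fit = als_fit(Z, model)
        j = fit.construct_names.index("GxE")
        score = fit.scores[:, j]
        assert abs(score.mean()) < 1e-12
        assert score.std() == pytest.approx(1.0, abs=1e-12)
        # raw product of two independent standard normals has variance ~ 1
        m, s = fit.interaction_center["GxE"]
        assert s == pytest.approx(1.0, abs=0.02)
        assert m == pytest.approx(0.0, abs=0.02)


class TestAlsProperties:
    def test_criterion_monotone_without_interactions(self):
        Z = composite_data(seed=6)
        fit = als_fit(
            Z, composite_model(),
            EstimationConfig(init_mode="random", seed=11, convergence_tolerance=1e-12,
                             max_iterations=200),
        )
        trace = np.array(fit.criterion_trace)
        assert np.all(np.diff(trace) <= 1e-10 * np.abs(trace[:-1]))

    def test_converges_with_interactions(self, small_model, small_roi_map):
        ds, _ = ig.simulate_dataset(
            ig.SimConfig(n_samples=231, seed=8), roi_map=small_roi_map, model=small_model
        )
        Z = ig.standardize(ds.indicator_table().loc[:, small_model.indicator_names])
        fit = als_fit(Z, small_model, EstimationConfig(ridge_lambda=5.0))
        assert fit.converged
        last_change = abs(fit.criterion_trace[-2] - fit.criterion_trace[-1])
        assert last_change < 1e-6 * abs(fit.criterion_trace[-2])

    def test_loadings_equal_indicator_component_correlations(self):
        Z = composite_data(seed=7)
        fit = als_fit(Z, composite_model())
        for (construct, ind), loading in fit.loading_series().items():
            j = fit.construct_names.index(construct)
            r = np.corrcoef(Z[ind], fit.scores[:, j])[0, 1]
            assert loading == pytest.approx(r, abs=1e-10)

    def test_unit_variance_scores(self):
        Z = composite_data(seed=9)
        fit = als_fit(Z, composite_model())
        np.testing.assert_allclose(fit.scores.std(axis=0), 1.0, atol=1e-10)

    def test_sign_flip_invariance_at_lambda_zero(self):
        Z = composite_data(seed=10)
        Zf = Z.copy()
        Zf["a0"] = -Zf["a0"]
        tight = EstimationConfig(convergence_tolerance=1e-13, max_iterations=1000)
        fit = als_fit(Z, composite_model(), tight)
        fit_f = als_fit(Zf, composite_model(), tight)
        np.testing.assert_allclose(
            np.abs(fit.path_series()), np.abs(fit_f.path_series()), atol=1e-7
        )
        np.testing.assert_allclose(
            np.abs(fit.loading_series()), np.abs(fit_f.loading_series()), atol=1e-7
        )

    def test_loading_sum_positive_orientation(self):
        Z = composite_data(seed=12)
        fit = als_fit(Z, composite_model(), EstimationConfig(init_mode="random", seed=3))
        loads = fit.loading_series()
        for construct in ("A", "B"):
            assert loads[construct].sum() > 0

    def test_ridge_shrinkage_monotone(self):
        Z = composite_data(seed=13)
        model = composite_model()
        norms = []
        for lam in (0.0, 1.0, 10.0, 100.0, 1000.0):
            fit = als_fit(Z, model, EstimationConfig(ridge_lambda=lam))
            norms.append(float(np.sum(fit.paths**2)))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_huge_penalty_kills_paths_keeps_loadings(self):
        Z = composite_data(seed=14)
        model = composite_model()
        fit0 = als_fit(Z, model, EstimationConfig(ridge_lambda=0.0))
        fit9 = als_fit(Z, model, EstimationConfig(ridge_lambda=1e9))
        assert np.abs(fit9.paths).max() < 1e-6
        np.testing.assert_allclose(
            fit9.loading_series(), fit0.loading_series(), atol=0.02
        )

    def test_nonconvergence_warns_with_trace(self):
        Z = composite_data(seed=15)
        with pytest.warns(NonConvergenceWarning):
            fit = als_fit(
                Z, composite_model(),
                EstimationConfig(max_iterations=1, convergence_tolerance=1e-15,
                                 init_mode="random", seed=1),
            )
        assert not fit.converged
        assert len(fit.criterion_trace) >= 2
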