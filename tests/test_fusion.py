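import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog, nnls

from popfuse.fusion import (DesignMatrix, FusionCoefficients, build_design,
                            cross_validate, fit_glm_bounded, fit_qrm_bounded,
                            median_composite, predict_pixels, select_model)
from popfuse.grids import COUNT, GridGeometry, PopulationGrid
from popfuse.harmonize import CensusTable, ProductStack


def _design(X, y, year=2000, products=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    products = products or [f"P{i}" for i in range(X.shape[1])]
    return DesignMatrix(year=year, products=products, X_train=X, y_train=y,
                        train_codes=[f"c{i}" for i in range(len(y))],
                        X_test=np.empty((0, X.shape[1])), y_test=np.empty(0),
                        test_codes=[])


def _qrm_lp_oracle(X, y, tau=0.5):
    """Exact LP for non-negative quantile regression (pinball loss)."""
    n, p = X.shape
    # variables: a (p), u+ (n), u- (n); X a + u+ - u- = y
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=[(0, None)] * (p + 2 * n),
                  method="highs")
    assert res.success
    return res.x[:p], res.fun


class TestGlmBounded:
    def test_exact_representable_solution(self, rng):
        X = rng.uniform(1, 100, size=(10, 2))
        y = 2.0 * X[:, 0]
        fit = fit_glm_bounded(_design(X, y))
        assert fit.weights == pytest.approx([2.0, 0.0], abs=1e-6)

    def test_negative_target_clamps_to_zero(self, rng):
        # Y = -X1 with positively correlated columns: NNLS optimum is all-zero
        base = rng.uniform(1, 10, size=12)
        X = np.column_stack([base, base * rng.uniform(0.9, 1.1, size=12)])
        y = -X[:, 0]
        fit = fit_glm_bounded(_design(X, y))
        oracle, _ = nnls(X, y)
        assert fit.weights == pytest.approx(oracle, abs=1e-8)
        assert fit.weights == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_interior_optimum_matches_ols(self, rng):
        X = rng.uniform(10, 100, size=(30, 3))
        y = X @ np.array([0.5, 1.0, 2.0]) + rng.normal(0, 1.0, size=30)
        fit = fit_glm_bounded(_design(X, y))
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert (ols > 0).all()  # interior: bounds inactive
        assert fit.weights == pytest.approx(ols, rel=1e-6)

    def test_matches_nnls_oracle_on_random_designs(self, rng):
        for _ in range(20):
            X = rng.uniform(0, 50, size=(15, 4))
            y = rng.normal(0, 100, size=15)
            fit = fit_glm_bounded(_design(X, y))
            oracle, _ = nnls(X, y)
            obj = lambda a: np.sum((y - X @ a) ** 2)
            assert obj(fit.weights) <= obj(oracle) * (1 + 1e-8) + 1e-9

    def test_objective_beats_zero_vector(self, rng):
        X = rng.uniform(1, 10, size=(12, 3))
        y = rng.uniform(0, 100, size=12)
        fit = fit_glm_bounded(_design(X, y))
        assert np.sum((y - X @ fit.weights) ** 2) <= np.sum(y**2) + 1e-9

    def test_too_few_rows_rejected(self, rng):
        X = rng.random((3, 3))
        with pytest.raises(ValueError, match="training countries"):
            fit_glm_bounded(_design(X, np.ones(3)))


class TestQrmBounded:
    def test_noiseless_single_product(self, rng):
        X = rng.uniform(1e3, 1e6, size=(7, 2))
        y = 3.0 * X[:, 0]
        fit = fit_qrm_bounded(_design(X, y), tau=0.5)
        assert fit.weights == pytest.approx([3.0, 0.0], abs=1e-4)

    def test_matches_lp_oracle(self, rng):
        for _ in range(5):
            X = rng.uniform(1, 100, size=(20, 3))
            y = X @ np.array([0.2, 0.8, 0.0]) + rng.normal(0, 2.0, size=20)
            y = np.abs(y)
            fit = fit_qrm_bounded(_design(X, y), tau=0.5)
            a_lp, f_lp = _qrm_lp_oracle(X, y, tau=0.5)
            pinball = lambda a: np.sum(np.abs(y - X @ a)
                                       * np.where(y - X @ a >= 0, 0.5, 0.5))
            assert pinball(fit.weights) <= pinball(a_lp) * (1 + 1e-3) + 1e-6

    def test_robust_to_gross_outlier(self, rng):
        X = rng.uniform(1e3, 1e5, size=(15, 2))
        y = X @ np.array([0.6, 0.4])
        clean_q = fit_qrm_bounded(_design(X, y)).weights
        clean_g = fit_glm_bounded(_design(X, y)).weights
        X_out = np.vstack([X, [5e4, 5e4]])
        y_out = np.append(y, 5e7)  # one gross outlier country
        dirty_q = fit_qrm_bounded(_design(X_out, y_out)).weights
        dirty_g = fit_glm_bounded(_design(X_out, y_out)).weights
        assert dirty_q == pytest.approx(clean_q, rel=1e-3)
        assert not np.allclose(dirty_g, clean_g, rtol=1e-2)

    def test_consistency_under_symmetric_noise(self, rng):
        n = 500
        X = rng.uniform(1e4, 1e6, size=(n, 3))
        planted = np.array([0.3, 0.5, 0.2])
        y = X @ planted * (1 + rng.normal(0, 0.1, size=n))
        fit = fit_qrm_bounded(_design(X, y), tau=0.5)
        assert fit.weights == pytest.approx(planted, rel=0.05)

    def test_invalid_tau_rejected(self, rng):
        with pytest.raises(ValueError, match="tau"):
            fit_qrm_bounded(_design(rng.random((8, 2)), np.ones(8)), tau=1.5)


class TestInvariants:
    def test_weights_always_nonnegative(self, rng):
        for _ in range(10):
            X = rng.uniform(0, 100, size=(12, 3))
            y = rng.normal(0, 50, size=12)
            assert (fit_glm_bounded(_design(X, y)).weights >= 0).all()
            assert (fit_qrm_bounded(_design(X, np.abs(y))).weights >= 0).all()

    def test_joint_scale_invariance(self, rng):
        X = rng.uniform(1, 100, size=(15, 3))
        y = X @ np.array([0.4, 0.3, 0.3]) * (1 + rng.normal(0, 0.05, size=15))
        base = fit_glm_bounded(_design(X, y)).weights
        scaled = fit_glm_bounded(_design(X * 1e4, y * 1e4)).weights
        assert scaled == pytest.approx(base, rel=1e-4)

    def test_response_scaling_scales_weights(self, rng):
        X = rng.uniform(1, 100, size=(15, 3))
        y = X @ np.array([0.4, 0.3, 0.3]) * (1 + rng.normal(0, 0.05, size=15))
        base = fit_glm_bounded(_design(X, y)).weights
        scaled = fit_glm_bounded(_design(X, y * 7.0)).weights
        assert scaled == pytest.approx(7.0 * base, rel=1e-4)

    def test_negative_weight_assignment_rejected(self):
        with pytest.raises(AssertionError):
            FusionCoefficients(year=2000, products=["A"], weights=[-0.1],
                               model_tag="GLM")


class TestCrossValidate:
    def test_noiseless_design_perfect_cv(self, rng):
        X = rng.uniform(1, 100, size=(20, 2))
        y = X @ np.array([1.5, 0.5])
        fit = cross_validate(_design(X, y), model="GLM", folds=10, restarts=3,
                             seed=0)
        assert fit.cv_score == pytest.approx(0.0, abs=1e-10)
        assert fit.weights == pytest.approx([1.5, 0.5], rel=1e-5)

    def test_restart_count_irrelevant_for_convex_problem(self, rng):
        X = rng.uniform(1, 100, size=(20, 2))
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 5, size=20)
        one = cross_validate(_design(X, y), model="GLM", restarts=1, seed=3)
        many = cross_validate(_design(X, y), model="GLM", restarts=50, seed=3)
        assert many.weights == pytest.approx(one.weights, abs=1e-6)

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(1, 100, size=(20, 3))
        y = np.abs(X @ np.array([1.0, 0.5, 0.1]) + rng.normal(0, 10, size=20))
        a = cross_validate(_design(X, y), model="QRM", restarts=5, seed=11)
        b = cross_validate(_design(X, y), model="QRM", restarts=5, seed=11)
        assert np.array_equal(a.weights, b.weights)
        assert a.cv_score == b.cv_score

    def test_folds_exceeding_rows_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError, match="folds"):
            cross_validate(_design(X, np.ones(5)), folds=10)


class TestSelectModel:
    def _fits_and_design(self, rng, qrm_better=True):
        X_test = rng.uniform(1, 100, size=(5, 2))
        y_test = X_test @ np.array([1.0, 1.0])
        good = np.array([1.0, 1.0])
        bad = np.array([2.0, 0.0])
        glm = FusionCoefficients(2000, ["A", "B"], bad if qrm_better else good,
                                 "GLM", cv_score=1.0)
        qrm = FusionCoefficients(2000, ["A", "B"], good if qrm_better else bad,
                                 "QRM", cv_score=2.0)
        design = DesignMatrix(2000, ["A", "B"], np.empty((0, 2)), np.empty(0),
                              [], X_test, y_test, [f"t{i}" for i in range(5)])
        return glm, qrm, design

    def test_qrm_wins_on_test_rmse(self, rng):
        glm, qrm, design = self._fits_and_design(rng, qrm_better=True)
        assert select_model(glm, qrm, design).model_tag == "QRM"

    def test_glm_wins_when_better(self, rng):
        glm, qrm, design = self._fits_and_design(rng, qrm_better=False)
        assert select_model(glm, qrm, design).model_tag == "GLM"

    def test_forced_qrm_overrides(self, rng):
        glm, qrm, design = self._fits_and_design(rng, qrm_better=False)
        assert select_model(glm, qrm, design, force_qrm=True).model_tag == "QRM"

    def test_tie_breaks_to_qrm(self, rng):
        glm, qrm, design = self._fits_and_design(rng, qrm_better=True)
        qrm.weights = glm.weights.copy()
        assert select_model(glm, qrm, design).model_tag == "QRM"

    def test_empty_test_set_falls_back_to_cv(self, rng):
        glm, qrm, design = self._fits_and_design(rng)
        design.X_test, design.y_test = np.empty((0, 2)), np.empty(0)
        assert select_model(glm, qrm, design).model_tag == "GLM"  # cv 1.0 < 2.0


def _stack(arrays, year=2000):
    geometry = GridGeometry(west=0.0, north=5.0, dx=1.0, dy=1.0)
    grids = {}
    pids = []
    for i, a in enumerate(arrays):
        pid = f"P{i}"
        pids.append(pid)
        grids[(pid, year)] = PopulationGrid(values=np.asarray(a, float),
                                            geometry=geometry, unit=COUNT,
                                            year=year, product_id=pid)
    return ProductStack(grids=grids, epoch_table={year: pids})


class TestPredictPixels:
    def test_projection_weight(self, rng):
        arrays = [rng.random((5, 5)) for _ in range(3)]
        stack = _stack(arrays)
        coeffs = FusionCoefficients(2000, ["P0", "P1", "P2"], [1.0, 0.0, 0.0], "GLM")
        fused = predict_pixels(stack, coeffs, 2000)
        assert np.allclose(fused.values, arrays[0])

    def test_half_half_identical_grids(self, rng):
        a = rng.random((5, 5))
        stack = _stack([a, a.copy()])
        coeffs = FusionCoefficients(2000, ["P0", "P1"], [0.5, 0.5], "QRM")
        assert np.allclose(predict_pixels(stack, coeffs, 2000).values, a)

    def test_matches_per_pixel_loop(self, rng):
        arrays = [rng.random((4, 4)) for _ in range(3)]
        w = rng.random(3)
        stack = _stack(arrays)
        coeffs = FusionCoefficients(2000, ["P0", "P1", "P2"], w, "GLM")
        fused = predict_pixels(stack, coeffs, 2000).values
        for i in range(4):
            for j in range(4):
                expected = sum(w[k] * arrays[k][i, j] for k in range(3))
                assert fused[i, j] == pytest.approx(expected, rel=1e-9)

    def test_nodata_rules(self, rng):
        a = rng.random((3, 3))
        b = rng.random((3, 3))
        a[0, 0] = np.nan
        b[0, 0] = np.nan
        a[1, 1] = np.nan  # partial: treated as zero
        stack = _stack([a, b])
        coeffs = FusionCoefficients(2000, ["P0", "P1"], [1.0, 1.0], "GLM")
        fused = predict_pixels(stack, coeffs, 2000).values
        assert np.isnan(fused[0, 0])
        assert fused[1, 1] == pytest.approx(b[1, 1])

    def test_product_order_mismatch_rejected(self, rng):
        stack = _stack([rng.random((3, 3)), rng.random((3, 3))])
        coeffs = FusionCoefficients(2000, ["P1", "P0"], [1.0, 0.0], "GLM")
        with pytest.raises(ValueError, match="match"):
            predict_pixels(stack, coeffs, 2000)


class TestMedianComposite:
    def test_three_values(self):
        stack = _stack([np.full((2, 2), 1.0), np.full((2, 2), 2.0),
                        np.full((2, 2), 9.0)])
        assert (median_composite(stack, 2000).values == 2.0).all()

    def test_identical_grids(self, rng):
        a = rng.random((4, 4))
        stack = _stack([a, a.copy(), a.copy()])
        assert np.allclose(median_composite(stack, 2000).values, a)

    def test_matches_sort_oracle_even_count(self, rng):
        arrays = [rng.random((4, 4)) for _ in range(4)]
        med = median_composite(_stack(arrays), 2000).values
        for i in range(4):
            for j in range(4):
                vals = sorted(a[i, j] for a in arrays)
                assert med[i, j] == pytest.approx((vals[1] + vals[2]) / 2, rel=1e-12)


class TestBuildDesign:
    def _inputs(self, n=10, invalid=()):
        codes = [f"C{i:02d}" for i in range(n)]
        sums = {p: pd.Series(np.linspace(1e5, 1e6, n), index=codes)
                for p in ("P0", "P1")}
        census = CensusTable(records=pd.DataFrame(
            {"unit_code": codes, "year": 2000,
             "population": np.linspace(1e5, 1e6, n)}))
        rows = []
        for code in codes:
            for p in ("P0", "P1"):
                rows.append({"unit_code": code, "product_id": p, "year": 2000,
                             "cluster_label": 0,
                             "valid": (code, p) not in invalid})
        return sums, census, pd.DataFrame(rows)

    def test_all_valid_all_train(self):
        design = build_design(*self._inputs(10), year=2000)
        assert len(design.train_codes) == 10 and len(design.test_codes) == 0

    def test_partially_invalid_become_test(self):
        design = build_design(
            *self._inputs(10, invalid={("C00", "P0"), ("C01", "P1")}), year=2000)
        assert len(design.train_codes) == 8
        assert sorted(design.test_codes) == ["C00", "C01"]

    def test_empty_training_set_rejected(self):
        invalid = {(f"C{i:02d}", "P0") for i in range(10)}
        with pytest.raises(ValueError, match="empty training set"):
            build_design(*self._inputs(10, invalid=invalid), year=2000)
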