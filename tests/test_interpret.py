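import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import sromics as s
from sromics.expr_core import Node

from conftest import make_dataset


def model_from(expr, params, task="classification"):
    tree = s.parse_model_string(expr, task=task)
    return s.FittedModel(tree, np.asarray(params, float), 0.5, 1.0, 1.0, 100, task=task)


class TestMutualInformation:
    def test_discrete_self_information_is_entropy(self):
        # 4 equiprobable levels: MI(X;X) = H(X) = ln 4
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 50)
        assert s.mutual_information(x, x) == pytest.approx(math.log(4.0), abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=2000)
        y = rng.uniform(size=2000)
        assert s.mutual_information(x, y) < 0.05

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        n = 20000
        rho = 0.8
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        mi = s.mutual_information(z[:, 0], z[:, 1])
        assert mi == pytest.approx(-0.5 * math.log(1 - rho**2), abs=0.1)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        assert s.mutual_information(x, y) == pytest.approx(
            s.mutual_information(y, x), abs=1e-12
        )
        assert s.mutual_information(x, y) >= 0

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        y = rng.binomial(1, expit(x)).astype(float)
        assert s.mutual_information(np.exp(x), y) == pytest.approx(
            s.mutual_information(x, y), abs=1e-12
        )

    def test_permuted_argument_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.binomial(1, expit(2 * x)).astype(float)
        assert s.mutual_information(x, y) > 0.1
        assert s.mutual_information(x, rng.permutation(y)) < 0.05

    def test_constant_vector_gives_zero(self):
        assert s.mutual_information(np.ones(100), np.arange(100.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(s.ValidationError):
            s.mutual_information(np.ones(5), np.ones(6))


class TestSignalFlow:
    def test_single_leaf_root_equals_feature_mi(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1000)
        y = rng.binomial(1, expit(2 * x)).astype(float)
        data = make_dataset({"x": x, "y": y})
        model = model_from("logreg(x)", [1.7, 0.3])
        flow = s.signal_flow(model, data)
        assert len(flow.nodes) == 1
        assert flow.model_mi == pytest.approx(s.mutual_information(x, y), abs=1e-12)

    def test_combination_accumulates_signal(self):
        # target depends only on x1 + x2: the root node's MI exceeds each leaf's
        rng = np.random.default_rng(6)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = rng.binomial(1, expit(2 * (x1 + x2))).astype(float)
        data = make_dataset({"x1": x1, "x2": x2, "y": y})
        model = model_from("logreg(x1 + x2)", [0.0, 1.0, 0.0, 1.0, 0.0])
        flow = s.signal_flow(model, data)
        leaf_mis = [r.mutual_information for r in flow.nodes if r.is_leaf]
        assert flow.model_mi >= max(leaf_mis)
        assert all(r.mutual_information >= 0 for r in flow.nodes)

    def test_every_node_appears_once(self):
        rng = np.random.default_rng(7)
        n = 200
        data = make_dataset(
            {"a": rng.normal(size=n), "b": rng.normal(size=n),
             "y": rng.integers(0, 2, n).astype(float)}
        )
        model = model_from("logreg(tanh(a)*b)", np.ones(7))
        flow = s.signal_flow(model, data)
        assert len(flow.nodes) == model.tree.n_nodes
        assert sorted(r.index for r in flow.nodes) == list(range(model.tree.n_nodes))

    def test_independent_target_all_nodes_near_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        data = make_dataset(
            {"a": rng.normal(size=n), "b": rng.normal(size=n),
             "y": rng.integers(0, 2, n).astype(float)}
        )
        model = model_from("logreg(a + b)", [0.0, 1.0, 0.0, 1.0, 0.0])
        flow = s.signal_flow(model, data)
        assert all(r.mutual_information < 0.05 for r in flow.nodes)


class TestPartialDependence:
    def test_increasing_weight_gives_increasing_curve(self):
        model = model_from("logreg(x)", [2.0, 0.0])
        curve = s.partial_dependence(model, "x", fixed={}, grid_range=(-3, 3))
        assert np.all(np.diff(curve.predictions) > 0)
        assert curve.threshold_crossing == pytest.approx(0.0, abs=6.0 / 99)

    def test_crossing_shifts_analytically_with_fixed_covariate(self):
        # logreg(wa*a + wb*b + c): crossing in a solves wa*a = -(wb*b + c)
        wa, wb, c = 1.5, 2.0, 0.3
        model = model_from("logreg(a + b)", [c, wa, 0.0, wb, 0.0])
        for b_fix in (-1.0, 0.0, 1.0):
            curve = s.partial_dependence(
                model, "a", fixed={"b": b_fix}, grid_range=(-10, 10), grid_size=4001
            )
            expected = -(wb * b_fix + c) / wa
            assert curve.threshold_crossing == pytest.approx(
                expected, abs=20.0 / 4000 + 1e-9
            )

    def test_zero_weight_gives_flat_curve(self):
        model = model_from("logreg(a + b)", [0.0, 0.0, 0.0, 1.0, 0.0])
        curve = s.partial_dependence(model, "a", fixed={"b": 0.7}, grid_range=(-5, 5))
        assert np.ptp(curve.predictions) == 0.0

    def test_predictions_are_exact_model_evaluations(self):
        model = model_from("logreg(a + b)", [0.05, 1.0, 0.2, -1.0, 0.1])
        curve = s.partial_dependence(model, "a", fixed={"b": 0.4}, grid_range=(-2, 2))
        again = model.predict(
            {"a": curve.grid, "b": np.full(curve.grid.size, 0.4)}
        )
        assert np.array_equal(curve.predictions, again)

    def test_unknown_varied_feature_rejected(self):
        model = model_from("logreg(a)", [1.0, 0.0])
        with pytest.raises(s.ValidationError):
            s.partial_dependence(model, "nope", fixed={}, grid_range=(0, 1))

    def test_missing_fixed_assignment_rejected(self):
        model = model_from("logreg(a + b)", [1.0, 0.0, 1.0, 0.0, 0.0])
        with pytest.raises(s.ValidationError, match="b"):
            s.partial_dependence(model, "a", fixed={}, grid_range=(0, 1))


class TestDecisionBoundary:
    def test_additive_model_boundary_is_a_line(self):
        model = model_from("logreg(x + y)", [0.0, 1.0, 0.0, 1.0, 0.0], task="classification")
        db = s.decision_boundary_2d(
            model, "x", "y", fixed={}, grid=(80, 80), x_range=(-2, 2), y_range=(-2, 2)
        )
        assert db.boundary_cells
        step = 4.0 / 79
        for ix, iy in db.boundary_cells:
            cx = (db.xs[ix] + db.xs[ix + 1]) / 2
            cy = (db.ys[iy] + db.ys[iy + 1]) / 2
            assert abs(cx + cy) < 2.5 * step

    def test_multiplicative_model_boundary_is_a_hyperbola(self):
        # logreg(x*y - 1): the 0.5 level set is x*y = 1, the hotspot geometry
        model = model_from("logreg(x*y)", [-1.0, 1.0, 0.0, 1.0, 0.0])
        db = s.decision_boundary_2d(
            model, "x", "y", fixed={}, grid=(100, 100),
            x_range=(0.3, 3.0), y_range=(0.3, 3.0),
        )
        assert db.boundary_cells
        for ix, iy in db.boundary_cells:
            cx = (db.xs[ix] + db.xs[ix + 1]) / 2
            cy = (db.ys[iy] + db.ys[iy + 1]) / 2
            assert abs(cx * cy - 1.0) < 0.25

    def test_gaussian_peak_gives_closed_elliptical_boundary(self):
        # 2*exp(-x^2 - y^2) - 0.5 crosses zero on x^2 + y^2 = ln 4
        model = model_from("logreg(exp(-x - y))", [2.0, -0.5, 1.0, 0.0, 1.0, 0.0])
        db = s.decision_boundary_2d(
            model, "x", "y", fixed={}, grid=(120, 120),
            x_range=(-3, 3), y_range=(-3, 3),
        )
        assert db.boundary_cells
        r2 = math.log(4.0)
        for ix, iy in db.boundary_cells:
            cx = (db.xs[ix] + db.xs[ix + 1]) / 2
            cy = (db.ys[iy] + db.ys[iy + 1]) / 2
            assert cx * cx + cy * cy == pytest.approx(r2, abs=0.3)

    def test_matrix_entries_are_exact_evaluations(self):
        model = model_from("logreg(x*y)", [0.3, 0.7, 0.1, -1.1, 0.2])
        db = s.decision_boundary_2d(
            model, "x", "y", fixed={}, grid=(7, 5), x_range=(-1, 1), y_range=(-1, 1)
        )
        gx, gy = np.meshgrid(db.xs, db.ys)
        again = model.predict({"x": gx.ravel(), "y": gy.ravel()}).reshape(5, 7)
        assert np.array_equal(db.predictions, again)

    def test_same_feature_twice_rejected(self):
        model = model_from("logreg(x + y)", np.zeros(5))
        with pytest.raises(s.ValidationError):
            s.decision_boundary_2d(model, "x", "x", fixed={}, grid=(5, 5),
                                   x_range=(0, 1), y_range=(0, 1))


class TestClassDensity:
    def test_identical_distributions_overlap_near_one(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=1000)
        labels = np.array([0.0, 1.0] * 500)
        d = s.class_density_summary(v, labels)
        assert d.overlap > 0.9

    def test_disjoint_supports_overlap_near_zero(self):
        v = np.concatenate([np.linspace(0, 1, 200), np.linspace(100, 101, 200)])
        labels = np.concatenate([np.zeros(200), np.ones(200)])
        d = s.class_density_summary(v, labels)
        assert d.overlap < 0.02

    def test_two_sigma_apart_normals_closed_form(self):
        # overlap of N(0,1) and N(2,1) is 2*Phi(-1) ~ 0.3173
        rng = np.random.default_rng(10)
        v = np.concatenate([rng.normal(0, 1, 4000), rng.normal(2, 1, 4000)])
        labels = np.concatenate([np.zeros(4000), np.ones(4000)])
        d = s.class_density_summary(v, labels)
        assert d.overlap == pytest.approx(2 * norm.cdf(-1.0), abs=0.05)

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=600)
        labels = (rng.uniform(size=600) > 0.4).astype(float)
        d = s.class_density_summary(v, labels)
        assert np.trapezoid(d.density_0, d.grid) == pytest.approx(1.0, abs=1e-3)
        assert np.trapezoid(d.density_1, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(s.ValidationError):
            s.class_density_summary(np.arange(10.0), np.zeros(10))


def test_feature_correlations_utility():
    rng = np.random.default_rng(12)
    x = rng.normal(size=300)
    data = make_dataset(
        {"a": x, "b": -x + 0.05 * rng.normal(size=300), "c": rng.normal(size=300),
         "y": rng.integers(0, 2, 300).astype(float)}
    )
    corr = s.feature_correlations(data)
    assert corr.loc["a", "b"] > 0.95  # absolute value
    assert corr.loc["a", "c"] < 0.2
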