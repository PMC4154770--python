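"""RAM construction, implied covariance, ML discrepancy and fitting.

The fitting checks are anchored to independent oracles: closed-form OLS for
the single-path model, a seeded global optimizer for a mediation model, and
covariance algebra done by hand for the implied-covariance cases.
"""

import numpy as np
import pytest
from scipy import optimize

from grasslandsem.fit import (
    SampleMoments,
    _is_admissible,
    fit_indices,
    fit_ml,
    ml_discrepancy,
)
from grasslandsem.models import default_rh_model
from grasslandsem.ram import build_ram, implied_covariance
from grasslandsem.semspec import SEMModelSpec, SpecificationError
from grasslandsem.synth import default_truth, simulate_plot_table


def two_var_spec():
    return SEMModelSpec(name="xy", observed=("x", "y"), paths=(("x", "y"),))


def mediation_spec():
    # x -> m -> y with no direct path: one df to test against
    return SEMModelSpec(name="med", observed=("x", "m", "y"), paths=(("x", "m"), ("m", "y")))


class TestBuildRam:
    def test_saturated_two_var_counting(self):
        ram = build_ram(two_var_spec())
        assert ram.n_free == 3  # one path + two variances = p(p+1)/2

    def test_rh_fixed_mowing_loading_in_a(self):
        rh = default_rh_model()
        ram = build_ram(rh)
        i = rh.variables.index("mowing")
        j = rh.variables.index("land_use")
        assert ram.a_fixed[i, j] == 1.0
        assert all(p.name != "land_use=~mowing" for p in ram.parameters)

    def test_overparameterized_rejected(self):
        spec = SEMModelSpec(
            name="bad", observed=("x", "y"),
            paths=(("x", "y"),), covariances=(("x", "y"),),
        )
        with pytest.raises(SpecificationError, match="free parameters"):
            build_ram(spec)


class TestImpliedCovariance:
    def test_no_structure_gives_diagonal(self):
        spec = SEMModelSpec(name="d", observed=("x", "y"))
        ram = build_ram(spec)
        Sigma = implied_covariance(ram, np.array([1.0, 1.0]))
        np.testing.assert_allclose(Sigma, np.eye(2))

    def test_single_path_covariance_algebra(self):
        ram = build_ram(two_var_spec())
        theta = np.zeros(3)
        theta[ram.index_of("x", "y")] = 0.7
        theta[[k for k, p in enumerate(ram.parameters) if p.kind == "variance"]] = 1.0
        Sigma = implied_covariance(ram, theta)
        idx = {v: i for i, v in enumerate(ram.spec.observed)}
        assert Sigma[idx["y"], idx["y"]] == pytest.approx(0.7**2 + 1.0)
        assert Sigma[idx["x"], idx["y"]] == pytest.approx(0.7)

    def test_variable_order_permutes_conformably(self):
        a = SEMModelSpec(name="a", observed=("x", "y"), paths=(("x", "y"),))
        b = SEMModelSpec(name="b", observed=("y", "x"), paths=(("x", "y"),))
        ra, rb = build_ram(a), build_ram(b)
        ta = np.zeros(3)
        ta[ra.index_of("x", "y")] = 0.5
        ta[[k for k, p in enumerate(ra.parameters) if p.kind == "variance"]] = 1.0
        tb = np.zeros(3)
        tb[rb.index_of("x", "y")] = 0.5
        tb[[k for k, p in enumerate(rb.parameters) if p.kind == "variance"]] = 1.0
        Sa = implied_covariance(ra, ta)
        Sb = implied_covariance(rb, tb)
        np.testing.assert_allclose(Sa, Sb[np.ix_([1, 0], [1, 0])])


class TestMLDiscrepancy:
    def test_zero_at_equality(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_hand_value(self):
        assert ml_discrepancy(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(
            1.0 - np.log(2.0)
        )

    def test_non_negative_on_random_pd_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = int(rng.integers(2, 6))
            A = rng.normal(size=(p, p + 2))
            B = rng.normal(size=(p, p + 2))
            S = A @ A.T / (p + 2)
            Sigma = B @ B.T / (p + 2)
            assert ml_discrepancy(S, Sigma) >= -1e-12

    def test_non_pd_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError):
            ml_discrepancy(np.eye(2), S)


class TestFitML:
    def test_saturated_model_reproduces_sample(self):
        S = np.array([[2.0, 0.8], [0.8, 1.5]])
        moments = SampleMoments(("x", "y"), S, 100)
        fit = fit_ml(two_var_spec(), moments, seed=0)
        assert fit.converged
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.implied, S, atol=1e-6)
        est = dict(zip(fit.params["name"], fit.params["estimate"]))
        assert est["x->y"] == pytest.approx(0.8 / 2.0, abs=1e-6)

    def test_single_path_equals_correlation_on_standardized_data(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400)
        X = np.column_stack([x, y])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        S = np.cov(X, rowvar=False, ddof=1)
        moments = SampleMoments(("x", "y"), S, 400)
        fit = fit_ml(two_var_spec(), moments, seed=0)
        beta = fit.params.set_index("name").loc["x->y", "estimate"]
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert beta == pytest.approx(r, abs=1e-8)

    def test_mediation_matches_brute_force_minimizer(self):
        truth_beta = {"x->m": 0.5, "m->y": -0.4}
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        m = truth_beta["x->m"] * x + rng.normal(size=300)
        y = truth_beta["m->y"] * m + rng.normal(size=300)
        S = np.cov(np.column_stack([x, m, y]), rowvar=False, ddof=1)
        moments = SampleMoments(("x", "m", "y"), S, 300)
        spec = mediation_spec()
        fit = fit_ml(spec, moments, seed=0)

        ram = build_ram(spec)

        def f(theta):
            try:
                return ml_discrepancy(S, implied_covariance(ram, theta))
            except np.linalg.LinAlgError:
                return 1e6

        res = optimize.differential_evolution(
            f, bounds=[(-3, 3)] * 2 + [(1e-3, 5)] * 3, seed=1, tol=1e-12,
            polish=True, maxiter=2000,
        )
        np.testing.assert_allclose(fit.theta, res.x, atol=1e-4)

    def test_chi_square_invariant_to_rescaling(self, rh_truth):
        table = simulate_plot_table(rh_truth, 300, seed=21)
        S = np.cov(table.to_numpy(), rowvar=False, ddof=1)
        fit1 = fit_ml(rh_truth.spec, SampleMoments(rh_truth.spec.observed, S, 300), seed=0)
        D = np.diag([10.0 if i % 2 else 0.1 for i in range(S.shape[0])])
        fit2 = fit_ml(
            rh_truth.spec, SampleMoments(rh_truth.spec.observed, D @ S @ D, 300), seed=0
        )
        assert fit2.chi_square == pytest.approx(fit1.chi_square, abs=1e-5)
        std1 = fit1.params.set_index("name")["std_estimate"]
        std2 = fit2.params.set_index("name")["std_estimate"]
        free = fit1.params[fit1.params["kind"] == "path"]["name"]
        np.testing.assert_allclose(std1[free], std2[free], atol=1e-5)

    def test_optimum_is_local_minimum(self, rh_truth, rh_moments):
        fit = fit_ml(rh_truth.spec, rh_moments, seed=0)
        from grasslandsem.fit import _objective

        f = _objective(fit.ram, fit.moments.S)
        rng = np.random.default_rng(13)
        f0 = f(fit.theta)
        for _ in range(100):
            assert f(fit.theta + rng.normal(scale=1e-3, size=len(fit.theta))) >= f0 - 1e-10

    def test_heywood_theta_flagged(self):
        ram = build_ram(two_var_spec())
        theta = np.array([0.5, 1.0, -0.2])  # negative y residual variance
        assert not _is_admissible(ram, theta)


class TestFitIndices:
    def test_perfect_fit_values(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        fit = fit_ml(two_var_spec(), SampleMoments(("x", "y"), S, 50), seed=0)
        gof, aic, aicc = fit_indices(fit)
        assert gof == pytest.approx(1.0, abs=1e-8)
        assert aic == pytest.approx(2 * 3, abs=1e-6)
        assert aicc == pytest.approx(aic + 2 * 3 * 4 / (50 - 3 - 1), abs=1e-6)

    def test_aicc_reduces_to_chi_square_without_parameters(self):
        # no free parameters at all: fixed-variance latent-free null model
        spec = SEMModelSpec(name="null", observed=("x",))
        ram = build_ram(spec)
        assert ram.n_free == 1  # the variance is always free; check formulas instead
        fit = fit_ml(spec, SampleMoments(("x",), np.array([[2.0]]), 30), seed=0)
        assert fit.aic == pytest.approx(fit.chi_square + 2 * 1)

    def test_standardized_loading_not_one_in_general(self, rh_truth, rh_moments):
        fit = fit_ml(rh_truth.spec, rh_moments, seed=0)
        fixed = fit.params[fit.params["fixed"]]
        assert len(fixed) == 1
        assert fixed["estimate"].iloc[0] == 1.0
        assert abs(fixed["std_estimate"].iloc[0] - 1.0) > 1e-3
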