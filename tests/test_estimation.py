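"""FOCE-I engine: conditional modes, objective, oracles, and shrinkage."""

import math

import numpy as np
import pytest

import ivmpk as pk
from ivmpk.dataio import Dataset
from ivmpk.estimation import (
    FitOptions,
    ToySubject,
    estimate_ebes,
    fit_population,
    foce_objective,
    marginal_likelihood_quadrature,
)

LINEAR_EXPECTED = math.log(2.0) + 0.5  # exact -2 log marginal of the linear toy


def linear_toy():
    """One subject, one observation y=1, mean = eta, omega2 = 1, additive sd = 1.

    The marginal is Normal(0, 2), so the exact objective (2*pi omitted) is
    log 2 + 1/2; FOCE is exact for models linear in eta.
    """
    m = pk.PopulationModel(
        theta=np.ones(7), omega=np.diag([1.0, 0, 0, 0, 0, 0, 0]),
        sigma_add=1.0, sigma_prop=0.0,
    )
    s = ToySubject(sid="lin", y=[1.0], predict_fn=lambda etas: etas[:, [0]])
    return m, s


def nonlinear_toy(omega2=0.3, y=(8.5, 3.0)):
    """One-compartment bolus with a random effect on the elimination rate."""
    ts = np.array([1.0, 5.0])

    def f(etas):
        k = 0.2 * np.exp(etas[:, [0]])
        return 10.0 * np.exp(-k * ts[None, :])

    m = pk.PopulationModel(
        theta=np.ones(7), omega=np.diag([omega2, 0, 0, 0, 0, 0, 0]),
        sigma_add=0.5, sigma_prop=0.1,
    )
    return m, ToySubject(sid="nl", y=list(y), predict_fn=f, times=ts)


class TestEstimateEbes:
    def test_prior_dominates_when_omega_vanishes(self, ref_model, small_dataset):
        m = ref_model.copy()
        m.omega = np.diag(np.full(7, 1e-12))
        eta, _ = estimate_ebes(m, small_dataset.subjects[0])
        assert np.max(np.abs(eta)) < 1e-3

    def test_linear_toy_posterior_mode(self):
        # mode of (1-eta)^2 + eta^2 is 1/2
        m, s = linear_toy()
        eta, _ = estimate_ebes(m, s)
        assert eta[0] == pytest.approx(0.5, abs=1e-6)

    def test_mirrored_subjects_have_opposite_modes(self):
        # mean = eta with additive error: the conditional objective is exactly
        # symmetric under (y, eta) -> (-y, -eta)
        m = pk.PopulationModel(
            theta=np.ones(7), omega=np.diag([0.2, 0, 0, 0, 0, 0, 0]),
            sigma_add=1.0, sigma_prop=0.0,
        )
        f = lambda etas: etas[:, [0]] * np.ones((1, 2))
        up = ToySubject(sid="u", y=[0.8, 1.2], predict_fn=f, times=np.array([1.0, 2.0]))
        down = ToySubject(sid="d", y=[-0.8, -1.2], predict_fn=f, times=np.array([1.0, 2.0]))
        eta_u, _ = estimate_ebes(m, up)
        eta_d, _ = estimate_ebes(m, down)
        assert eta_u[0] == pytest.approx(-eta_d[0], abs=1e-6)
        assert eta_u[0] > 0.0


class TestFoceObjective:
    def test_linear_toy_exact(self):
        m, s = linear_toy()
        ofv = foce_objective(m, Dataset(subjects=[s], lloq=1e-9))
        assert ofv == pytest.approx(LINEAR_EXPECTED, abs=1e-6)

    def test_no_random_effects_reduces_to_weighted_least_squares(self, ref_model, small_dataset):
        m = ref_model.copy()
        m.omega = np.zeros((7, 7))
        ofv = foce_objective(m, small_dataset)
        expected = 0.0
        for s in small_dataset.subjects:
            f = pk.subject_prediction(m, s, np.zeros(7))
            v = pk.residual_variance(m, f)
            expected += float(np.sum((s.obs_values - f) ** 2 / v + np.log(v)))
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_subject_order(self, ref_model, small_dataset):
        ofv = foce_objective(ref_model, small_dataset)
        reordered = Dataset(subjects=list(reversed(small_dataset.subjects)), lloq=0.1)
        assert foce_objective(ref_model, reordered) == pytest.approx(ofv, abs=1e-6)

    @pytest.mark.parametrize("omega2,y", [(0.3, (8.5, 3.0)), (0.4, (9.5, 2.2)), (0.1, (7.0, 4.0))])
    def test_close_to_quadrature_on_nonlinear_toys(self, omega2, y):
        m, s = nonlinear_toy(omega2, y)
        ofv = foce_objective(m, Dataset(subjects=[s], lloq=1e-9))
        exact = marginal_likelihood_quadrature(m, s, nodes=64)
        assert abs(ofv - exact) < 0.5

    def test_two_random_effects_toy_vs_quadrature(self):
        ts = np.array([0.5, 2.0, 8.0])

        def f(etas):
            k = 0.3 * np.exp(etas[:, [0]])
            v = 2.0 * np.exp(etas[:, [1]])
            return (10.0 / v) * np.exp(-k * ts[None, :])

        m = pk.PopulationModel(
            theta=np.ones(7), omega=np.diag([0.2, 0.15, 0, 0, 0, 0, 0]),
            sigma_add=0.3, sigma_prop=0.05,
        )
        s = ToySubject(sid="2d", y=[3.5, 2.4, 0.4], predict_fn=f, times=ts)
        ofv = foce_objective(m, Dataset(subjects=[s], lloq=1e-9))
        exact = marginal_likelihood_quadrature(m, s, nodes=64)
        assert abs(ofv - exact) < 0.5


class TestQuadratureOracle:
    def test_linear_toy_closed_form(self):
        m, s = linear_toy()
        assert marginal_likelihood_quadrature(m, s, nodes=64) == pytest.approx(
            LINEAR_EXPECTED, abs=1e-8
        )

    def test_node_doubling_converged(self):
        m, s = nonlinear_toy()
        q32 = marginal_likelihood_quadrature(m, s, nodes=32)
        q64 = marginal_likelihood_quadrature(m, s, nodes=64)
        assert abs(q64 - q32) < 1e-6

    def test_zero_variance_equals_fixed_effect_likelihood(self):
        m, s = nonlinear_toy()
        m0 = m.copy()
        m0.omega = np.zeros((7, 7))
        q = marginal_likelihood_quadrature(m0, s, nodes=32)
        f = np.asarray(s.predict_fn(np.zeros((1, 7))))[0]
        v = m.sigma_add**2 + (m.sigma_prop * f) ** 2
        expected = float(np.sum((s.y - f) ** 2 / v + np.log(v)))
        assert q == pytest.approx(expected, abs=1e-8)

    def test_rejects_high_dimension(self, ref_model, small_dataset):
        with pytest.raises(pk.DomainError):
            marginal_likelihood_quadrature(ref_model, small_dataset.subjects[0])


class TestFitPopulation:
    def test_descent_from_truth(self, ref_model, small_dataset):
        opts = FitOptions(estimate_omega=False, estimate_sigma=False, maxiter=8)
        fit = fit_population(ref_model, small_dataset, opts)
        assert fit.ofv <= fit.initial_ofv + 1e-9

    def test_single_subject_runs_with_missing_cv(self, ref_model, study_dataset):
        ds1 = Dataset(subjects=[study_dataset.subjects[0]], lloq=0.1)
        mask = [True] + [False] * 6  # CL only; 1-subject data cannot support more
        opts = FitOptions(estimate_theta=mask, estimate_omega=False,
                          estimate_sigma=False, maxiter=5)
        fit = fit_population(ref_model, ds1, opts)
        assert np.isfinite(fit.ofv)
        # shrinkage SD undefined for a single subject
        assert all(np.isnan(v) for v in fit.eta_shrinkage_pct.values())

    def test_recovers_theta_on_small_cohort_and_reports_cv(self):
        m = pk.reference_model()
        spec = pk.CohortSpec(
            n_subjects=12, schedule=(1.0, 3.0, 6.0, 12.0, 36.0, 96.0), n_missing_last=0, seed=9
        )
        ds = pk.generate_dataset(spec, m)
        mask = [True, False, True, False, False, False, False]  # CL, Vc
        opts = FitOptions(estimate_theta=mask, estimate_covariates=False,
                          estimate_omega=False, estimate_sigma=False,
                          maxiter=30, compute_se=True)
        m0 = m.copy()
        m0.theta = m.theta * np.array([1.3, 1, 0.8, 1, 1, 1, 1.0])
        fit = fit_population(m0, ds, opts)
        # at n=12 the MLE tracks theta * exp(mean realized eta); bounds allow
        # ~2.5 population standard errors around the generating values
        assert fit.estimates.theta[0] == pytest.approx(7.02, rel=0.45)
        assert fit.estimates.theta[2] == pytest.approx(138.0, rel=0.60)
        assert fit.se_cv is not None
        assert 0.0 < fit.se_cv["CL"] < 50.0
        assert 0.0 < fit.se_cv["Vc"] < 50.0


class TestShrinkage:
    def test_all_modes_zero_gives_full_shrinkage(self, ref_model):
        fit = pk.FitResult(
            estimates=ref_model, ofv=0.0, initial_ofv=0.0, se_cv=None,
            ebes={str(i): np.zeros(7) for i in range(10)},
            eta_shrinkage_pct={}, eps_shrinkage_pct=None,
            converged=True, n_iter=0, n_obj_evals=0,
        )
        shr = pk.eta_shrinkage(fit)
        for name, value in shr.items():
            assert value == pytest.approx(100.0)

    def test_mode_spread_equal_to_omega_gives_zero_shrinkage(self, ref_model):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(2000)
        draws = (draws - draws.mean()) / draws.std(ddof=1)  # exact unit SD
        m = ref_model.copy()
        m.omega = np.diag([1.0, 0, 0, 0, 0, 0, 0])
        ebes = {str(i): np.array([d, 0, 0, 0, 0, 0, 0.0]) for i, d in enumerate(draws)}
        fit = pk.FitResult(
            estimates=m, ofv=0.0, initial_ofv=0.0, se_cv=None, ebes=ebes,
            eta_shrinkage_pct={}, eps_shrinkage_pct=None,
            converged=True, n_iter=0, n_obj_evals=0,
        )
        assert pk.eta_shrinkage(fit)["CL"] == pytest.approx(0.0, abs=1e-9)
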