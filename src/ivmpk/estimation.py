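"""FOCE-I estimation of the population model.

The marginal likelihood of each subject's data is approximated by the
first-order conditional method with interaction: the model is linearised in
the random effects at each subject's conditional mode (empirical Bayes
estimate, EBE), and the residual variance is evaluated at that mode.  With
``f_i`` the subject prediction, ``G_i = df_i/deta`` at the mode ``eta_i``,
``v_i`` the combined-error variances at the mode, and
``C_i = G_i Omega G_i' + diag(v_i)``, the objective is

    OFV = sum_i [ log|C_i| + r_i' C_i^{-1} r_i ],
    r_i = y_i - f_i(eta_i) + G_i eta_i,

with all 2*pi constants omitted (the usual pharmacometric convention, so
absolute OFVs differ from fully-normalised -2 log L by n*log(2*pi) but OFV
differences between nested models do not).

An adaptive Gauss-Hermite quadrature routine over 1-2 random effects is
provided as an independent accuracy oracle for the FOCE approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .dataio import Dataset, SubjectRecord
from .population import (
    DomainError,
    PopulationModel,
    covariate_multipliers,
    residual_variance,
)
from .structural import PARAM_NAMES, predict_concentrations_multi

_LOG_2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-12
_ETA_FD_STEP = 1e-4  # central-difference step for G = df/deta
_PENALTY = 1e10


# ---------------------------------------------------------------------------
# Per-subject working data
# ---------------------------------------------------------------------------

class _SubjectData:
    """Cached arrays for one subject (times, observations, doses, covariates)."""

    __slots__ = ("sid", "times", "y", "doses", "covariates", "predict_fn")

    def __init__(self, s: SubjectRecord):
        self.sid = s.subject_id
        self.times = s.obs_times
        self.y = s.obs_values
        self.doses = tuple((float(t), float(a)) for t, a in s.dose_events)
        self.covariates = s.covariates
        self.predict_fn = None

    @classmethod
    def wrap(cls, s) -> "_SubjectData":
        return s if hasattr(s, "predict_fn") else cls(s)


@dataclass
class ToySubject:
    """A subject whose mean function is supplied directly.

    ``predict_fn(full_etas)`` maps a (k, 7) array of random-effect vectors to
    a (k, n_obs) array of means.  Lets the estimator be verified against
    models with known analytic marginals (linear Gaussian, one-compartment
    bolus) independently of the structural model.
    """

    sid: str
    y: np.ndarray
    predict_fn: object
    times: np.ndarray = None
    doses: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.times is None:
            self.times = np.arange(self.y.size, dtype=float)


def _predict_batch(
    m: PopulationModel, sd, etas: np.ndarray, support: np.ndarray, base=None
) -> np.ndarray:
    """Predictions (k, n_obs) for a batch of support-space eta vectors.

    ``base`` is the subject's fixed-effect parameter vector
    (theta * covariate multipliers), precomputable once per model evaluation.
    """
    k = etas.shape[0]
    full = np.zeros((k, 7))
    full[:, support] = etas
    if sd.predict_fn is not None:
        return np.asarray(sd.predict_fn(full), dtype=float)
    if base is None:
        base = m.theta * covariate_multipliers(m, sd.covariates)
    params = base[None, :] * np.exp(np.clip(full, -60.0, 60.0))
    doses = sd.doses if type(sd.doses) is tuple else tuple(sd.doses)
    return predict_concentrations_multi(params, doses, sd.times)


def subject_prediction(m: PopulationModel, s, eta: Sequence[float]) -> np.ndarray:
    """Model prediction at a subject's design for a full 7-vector eta."""
    sd = _SubjectData.wrap(s)
    eta = np.asarray(eta, dtype=float)
    if sd.predict_fn is not None:
        return np.asarray(sd.predict_fn(eta[None, :]), dtype=float)[0]
    base = m.theta * covariate_multipliers(m, sd.covariates)
    params = (base * np.exp(eta))[None, :]
    return predict_concentrations_multi(params, sd.doses, sd.times)[0]


# ---------------------------------------------------------------------------
# Conditional (inner) problem: empirical Bayes estimates
# ---------------------------------------------------------------------------

def _omega_inverse(m: PopulationModel, support: np.ndarray) -> np.ndarray:
    om = m.omega[np.ix_(support, support)]
    try:
        return np.linalg.inv(om)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(om)


def _conditional_objective_batch(
    m: PopulationModel,
    sd: _SubjectData,
    etas: np.ndarray,
    support: np.ndarray,
    om_inv: np.ndarray,
    base=None,
) -> np.ndarray:
    f = _predict_batch(m, sd, etas, support, base)
    v = np.maximum(residual_variance(m, f), _VAR_FLOOR)
    data_part = np.sum((sd.y[None, :] - f) ** 2 / v + np.log(v), axis=1)
    prior_part = np.einsum("ki,ij,kj->k", etas, om_inv, etas)
    return data_part + prior_part


def estimate_ebes(
    m: PopulationModel,
    s,
    start: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    base=None,
) -> Tuple[np.ndarray, float]:
    """Conditional mode of a subject's random effects.

    Minimises  sum_j [(y_j - f_j)^2 / v_j + log v_j] + eta' Omega^{-1} eta
    over the parameters with non-degenerate IIV; returns a full 7-vector
    (zeros off-support) and the conditional objective value.  Quasi-Newton
    from zero (or a warm start) with perturbed restarts on failure.
    """
    sd = _SubjectData.wrap(s)
    if sd.y.size == 0:
        raise DomainError(f"subject {sd.sid} has no observations")
    support = m.iiv_support()
    d = support.size
    if d == 0:
        return np.zeros(7), float(
            _conditional_objective_batch(m, sd, np.zeros((1, 0)), support, np.zeros((0, 0)), base)[0]
        )
    om_inv = _omega_inverse(m, support)

    def solve(x0):
        return _solve_conditional(m, sd, support, om_inv, np.asarray(x0, float), base, tol)

    best_x, best_f = None, np.inf
    cold_starts = [np.zeros(d), 0.1 * np.ones(d), -0.1 * np.ones(d)]
    if start is not None:
        # warm path: the conditional mode moves continuously with the outer
        # parameters, so the previous mode is a reliable single start
        x, fval, ok = solve(np.asarray(start, dtype=float)[support])
        if ok and np.isfinite(fval):
            eta = np.zeros(7)
            eta[support] = x
            return eta, float(fval)
        best_x, best_f = x, float(fval)
    # cold path: the conditional objective can be multimodal, so compare
    # several deterministic starts and keep the best mode
    for x0 in cold_starts:
        x, fval, _ = solve(x0)
        if np.isfinite(fval) and fval < best_f:
            best_x, best_f = x, float(fval)
    eta = np.zeros(7)
    eta[support] = best_x
    return eta, best_f


def _solve_conditional(
    m: PopulationModel,
    sd: _SubjectData,
    support: np.ndarray,
    om_inv: np.ndarray,
    x0: np.ndarray,
    base,
    tol: float,
) -> Tuple[np.ndarray, float, bool]:
    """Damped Gauss-Newton minimisation of the conditional objective.

    The objective is a penalised weighted least-squares criterion, so the
    Gauss-Newton matrix  2 G' diag(1/v) G + 2 Omega^{-1}  is a natural PSD
    curvature; Levenberg damping guards the nonlinear/interaction terms.
    Falls back to scipy's L-BFGS-B if the iteration stalls.
    """
    d = support.size
    eye_h = _ETA_FD_STEP * np.eye(d)
    sp2 = m.sigma_prop**2

    def eval_obj(x: np.ndarray) -> float:
        val = _conditional_objective_batch(m, sd, x[None, :], support, om_inv, base)[0]
        return float(val) if np.isfinite(val) else _PENALTY

    x = x0.copy()
    lam = 0.0
    fx = None
    converged = False
    for it in range(40):
        steps = np.vstack([x[None, :], x + eye_h, x - eye_h])
        preds = _predict_batch(m, sd, steps, support, base)
        f0 = preds[0]
        G = ((preds[1 : d + 1] - preds[d + 1 :]) / (2.0 * _ETA_FD_STEP)).T  # (n_obs, d)
        v = np.maximum(residual_variance(m, f0), _VAR_FLOOR)
        r = sd.y - f0
        fx = float(np.sum(r * r / v + np.log(v)) + x @ om_inv @ x)
        if not np.isfinite(fx):
            fx = _PENALTY
            break
        # gradient and curvature of g(u) = (y-u)^2/v(u) + log v(u) per
        # observation, including the interaction (v depends on f) terms;
        # only the model's second derivative d2f/deta2 is dropped
        dv = 2.0 * sp2 * f0        # v'
        d2v = 2.0 * sp2            # v''
        w1 = -2.0 * r / v + (1.0 / v - r * r / (v * v)) * dv
        grad = G.T @ w1 + 2.0 * om_inv @ x
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < 1e-7:
            converged = True
            break
        w2 = (
            2.0 / v
            + 4.0 * r * dv / (v * v)
            + (d2v / v) * (1.0 - r * r / v)
            + (dv * dv / (v * v)) * (2.0 * r * r / v - 1.0)
        )
        H = (G.T * np.maximum(w2, 0.0)) @ G + 2.0 * om_inv
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(d), -grad)
            except np.linalg.LinAlgError:
                lam = max(10.0 * lam, 1e-4)
                continue
            f_new = eval_obj(x + step)
            if f_new < fx - 1e-12:
                x = x + step
                lam = lam / 3.0 if lam > 1e-10 else 0.0
                if fx - f_new < tol:
                    converged = True
                fx = f_new
                accepted = True
                break
            lam = max(10.0 * lam, 1e-4)
        if converged:
            break
        if not accepted:
            # stalled: either at a flat point or the quadratic model fails
            converged = gnorm < 1e-4
            break

    if not converged and fx is not None and fx < _PENALTY:
        # robust fallback for the rare hard subject
        def fun_and_grad(z: np.ndarray):
            steps = np.vstack([z[None, :], z + eye_h, z - eye_h])
            vals = _conditional_objective_batch(m, sd, steps, support, om_inv, base)
            fz = float(vals[0]) if np.isfinite(vals[0]) else _PENALTY
            gz = (vals[1 : d + 1] - vals[d + 1 :]) / (2.0 * _ETA_FD_STEP)
            return fz, np.where(np.isfinite(gz), gz, 0.0)

        res = optimize.minimize(
            fun_and_grad, x, jac=True, method="L-BFGS-B",
            options={"ftol": tol * 1e-2, "gtol": 1e-7, "maxiter": 200},
        )
        if np.isfinite(res.fun) and res.fun <= fx:
            return res.x, float(res.fun), bool(res.success)
    return x, float(fx if fx is not None else _PENALTY), converged


# ---------------------------------------------------------------------------
# FOCE-I linearisation and objective
# ---------------------------------------------------------------------------

@dataclass
class _Linearization:
    """Per-subject FOCE-I pieces shared by the OFV and by CWRES."""

    eta: np.ndarray          # full 7-vector conditional mode
    f_hat: np.ndarray        # prediction at the mode
    G: np.ndarray            # df/deta (n_obs, d) on the IIV support
    v_hat: np.ndarray        # residual variances at the mode (interaction)
    C: np.ndarray            # G Omega G' + diag(v_hat)
    chol: np.ndarray         # lower Cholesky factor of C
    r: np.ndarray            # y - f_hat + G eta_support
    support: np.ndarray

    @property
    def ofv_contribution(self) -> float:
        logdet = 2.0 * float(np.sum(np.log(np.diag(self.chol))))
        z = np.linalg.solve(self.chol, self.r)
        return logdet + float(z @ z)

    @property
    def cwres(self) -> np.ndarray:
        return np.linalg.solve(self.chol, self.r)


def _linearize_subject(
    m: PopulationModel, sd: _SubjectData, eta: np.ndarray, base=None
) -> _Linearization:
    support = m.iiv_support()
    d = support.size
    eta_s = eta[support]
    if d:
        steps = np.vstack(
            [eta_s[None, :], eta_s + _ETA_FD_STEP * np.eye(d), eta_s - _ETA_FD_STEP * np.eye(d)]
        )
        preds = _predict_batch(m, sd, steps, support, base)
        f_hat = preds[0]
        G = ((preds[1 : d + 1] - preds[d + 1 :]) / (2.0 * _ETA_FD_STEP)).T  # (n_obs, d)
    else:
        f_hat = _predict_batch(m, sd, eta_s[None, :], support, base)[0]
        G = np.zeros((f_hat.size, 0))
    v_hat = np.maximum(residual_variance(m, f_hat), _VAR_FLOOR)
    om = m.omega[np.ix_(support, support)]
    C = G @ om @ G.T + np.diag(v_hat)
    jitter = 0.0
    for _ in range(4):
        try:
            chol = np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * float(np.trace(C)) / C.shape[0])
    else:
        raise np.linalg.LinAlgError(
            f"FOCE covariance not positive definite for subject {sd.sid}"
        )
    r = sd.y - f_hat + G @ eta_s
    return _Linearization(eta=eta, f_hat=f_hat, G=G, v_hat=v_hat, C=C, chol=chol, r=r, support=support)


def foce_components(
    m: PopulationModel,
    ds: Dataset,
    eta_start: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[float, Dict[str, _Linearization]]:
    """OFV plus per-subject linearisations (one code path for OFV and CWRES)."""
    total = 0.0
    lins: Dict[str, _Linearization] = {}
    for s in ds.subjects:
        sd = _SubjectData.wrap(s)
        base = (
            None
            if sd.predict_fn is not None
            else m.theta * covariate_multipliers(m, sd.covariates)
        )
        start = None if eta_start is None else eta_start.get(sd.sid)
        eta, _ = estimate_ebes(m, sd, start=start, base=base)
        lin = _linearize_subject(m, sd, eta, base=base)
        total += lin.ofv_contribution
        lins[sd.sid] = lin
    return total, lins


def foce_objective(
    m: PopulationModel, ds: Dataset, eta_start: Optional[Dict[str, np.ndarray]] = None
) -> float:
    """FOCE-I objective function value (-2 log approx. marginal, 2*pi omitted)."""
    ofv, _ = foce_components(m, ds, eta_start)
    return ofv


# ---------------------------------------------------------------------------
# Quadrature oracle (1-2 random effects)
# ---------------------------------------------------------------------------

def marginal_likelihood_quadrature(m: PopulationModel, s, nodes: int = 64) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Test-scale oracle for the FOCE approximation; supports at most two
    random-effect dimensions.  Returned on the same convention as the FOCE
    OFV: the residual (2*pi)^(n/2) normalisation is omitted.
    """
    sd = _SubjectData.wrap(s)
    support = m.iiv_support()
    d = support.size
    if d > 2:
        raise DomainError("quadrature oracle supports at most 2 random effects")
    if nodes < 16:
        raise DomainError("use at least 16 quadrature nodes")
    n = sd.y.size
    om = m.omega[np.ix_(support, support)]
    om_inv = _omega_inverse(m, support)
    sign, logdet_om = np.linalg.slogdet(om)

    def h(etas: np.ndarray) -> np.ndarray:
        """-log[p(y|eta) p(eta)] for a batch of support-space etas."""
        g = _conditional_objective_batch(m, sd, etas, support, om_inv)
        return 0.5 * (g + logdet_om + (n + d) * _LOG_2PI)

    if d == 0:
        return float(2.0 * h(np.zeros((1, 0)))[0] - n * _LOG_2PI)

    eta_mode, _ = estimate_ebes(m, sd)
    mode = eta_mode[support]
    # Hessian of h at the mode (central differences)
    step = 1e-4
    H = np.zeros((d, d))
    h0 = h(mode[None, :])[0]
    for i in range(d):
        for j in range(i, d):
            ei = np.eye(d)[i] * step
            ej = np.eye(d)[j] * step
            if i == j:
                vals = h(np.vstack([mode + ei, mode - ei]))
                H[i, i] = (vals[0] - 2.0 * h0 + vals[1]) / step**2
            else:
                pts = np.vstack([mode + ei + ej, mode + ei - ej, mode - ei + ej, mode - ei - ej])
                vals = h(pts)
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4.0 * step**2)
    # guard: fall back to the prior precision if curvature is not PD
    try:
        np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        H = om_inv.copy()
    L = np.linalg.cholesky(np.linalg.inv(H))

    z1, w1 = np.polynomial.hermite.hermgauss(nodes)
    if d == 1:
        Z = z1[:, None]
        logw = np.log(w1)
    else:
        Z = np.array([[a, b] for a in z1 for b in z1])
        logw = np.add.outer(np.log(w1), np.log(w1)).ravel()
    etas = mode[None, :] + math.sqrt(2.0) * (Z @ L.T)
    hv = h(etas)
    log_terms = logw - hv + np.sum(Z**2, axis=1)
    log_max = float(np.max(log_terms))
    integral_log = log_max + math.log(float(np.sum(np.exp(log_terms - log_max))))
    sign_L, logdet_L = np.linalg.slogdet(L)
    log_marginal = 0.5 * d * math.log(2.0) + logdet_L + integral_log
    return float(-2.0 * log_marginal - n * _LOG_2PI)


# ---------------------------------------------------------------------------
# Outer problem: population fit
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_population`.

    Components can be frozen at their initial values (``estimate_* = False``)
    to fit reduced problems; finite differences use relative step
    ``fd_rel_step`` on the transformed (log / Cholesky) scale.
    """

    estimate_theta: Sequence[bool] | bool = True
    estimate_covariates: bool = True
    estimate_omega: Sequence[bool] | bool = True
    estimate_sigma: bool = True
    maxiter: int = 150
    fd_rel_step: float = 1e-4
    outer_jac: str = "3-point"  # central differences; "2-point" halves the cost
    compute_se: bool = False

    @staticmethod
    def _mask(value, what: str) -> np.ndarray:
        if isinstance(value, (bool, np.bool_)):
            return np.full(7, bool(value))
        mask = np.asarray(value, dtype=bool)
        if mask.shape != (7,):
            raise DomainError(f"{what} mask must have 7 entries")
        return mask

    def theta_mask(self) -> np.ndarray:
        return self._mask(self.estimate_theta, "estimate_theta")

    def omega_mask(self) -> np.ndarray:
        return self._mask(self.estimate_omega, "estimate_omega")


class _ParamCoder:
    """Bijection between a PopulationModel and the unconstrained fit vector.

    Typical values and residual SDs are log-transformed; covariate
    coefficients are untransformed; the IIV covariance is parameterised by
    its Cholesky factor on the support (log-diagonal, raw off-diagonal for
    the full-block structure), which keeps Omega PSD throughout.
    """

    def __init__(self, m0: PopulationModel, opts: FitOptions):
        self.template = m0.copy()
        self.opts = opts
        self.theta_idx = np.flatnonzero(opts.theta_mask())
        self.n_eff = len(m0.covariate_effects) if opts.estimate_covariates else 0
        self.support = m0.iiv_support()
        self.full_block = m0.omega_structure == "full"
        omega_mask = opts.omega_mask()
        if self.full_block and omega_mask.any() and not omega_mask.all():
            raise DomainError("full-block omega is estimated all-or-nothing")
        # subset of the IIV support whose variances are estimated
        self.omega_idx = np.array(
            [i for i in self.support if omega_mask[i]], dtype=int
        )
        self.est_omega = self.omega_idx.size > 0
        self.sigma_flags = (
            (m0.sigma_add > 0.0, m0.sigma_prop > 0.0) if opts.estimate_sigma else (False, False)
        )
        self.names: List[str] = [PARAM_NAMES[i] for i in self.theta_idx]
        self.names += [
            f"{e.covariate}_on_{e.parameter}" for e in m0.covariate_effects[: self.n_eff]
        ]
        if self.est_omega:
            if self.full_block:
                d = self.support.size
                self.names += [
                    f"omega_chol_{i}_{j}"
                    for i in range(d)
                    for j in range(i + 1)
                ]
            else:
                self.names += [f"omega_sd_{PARAM_NAMES[i]}" for i in self.omega_idx]
        if self.sigma_flags[0]:
            self.names.append("sigma_add")
        if self.sigma_flags[1]:
            self.names.append("sigma_prop")

    def encode(self, m: PopulationModel) -> np.ndarray:
        x: List[float] = [math.log(m.theta[i]) for i in self.theta_idx]
        x += [m.covariate_effects[k].coefficient for k in range(self.n_eff)]
        if self.est_omega:
            if self.full_block:
                om = m.omega[np.ix_(self.support, self.support)]
                L = np.linalg.cholesky(om + 1e-10 * np.eye(om.shape[0]))
                for i in range(om.shape[0]):
                    for j in range(i + 1):
                        x.append(math.log(L[i, i]) if i == j else L[i, j])
            else:
                x += [0.5 * math.log(m.omega[i, i]) for i in self.omega_idx]
        if self.sigma_flags[0]:
            x.append(math.log(m.sigma_add))
        if self.sigma_flags[1]:
            x.append(math.log(m.sigma_prop))
        return np.array(x, dtype=float)

    def decode(self, x: np.ndarray) -> PopulationModel:
        m = self.template.copy()
        pos = 0
        theta = m.theta.copy()
        for i in self.theta_idx:
            theta[i] = math.exp(x[pos]); pos += 1
        m.theta = theta
        if self.n_eff:
            from dataclasses import replace as _replace

            effects = list(m.covariate_effects)
            for k in range(self.n_eff):
                effects[k] = _replace(effects[k], coefficient=float(x[pos])); pos += 1
            m.covariate_effects = effects
        if self.est_omega:
            om = m.omega.copy()
            if self.full_block:
                d = self.support.size
                L = np.zeros((d, d))
                for i in range(d):
                    for j in range(i + 1):
                        L[i, j] = math.exp(x[pos]) if i == j else x[pos]
                        pos += 1
                om[np.ix_(self.support, self.support)] = L @ L.T
            else:
                for i in self.omega_idx:
                    om[i, i] = math.exp(2.0 * x[pos]); pos += 1
            m.omega = om
        if self.sigma_flags[0]:
            m.sigma_add = math.exp(x[pos]); pos += 1
        if self.sigma_flags[1]:
            m.sigma_prop = math.exp(x[pos]); pos += 1
        return m


@dataclass
class FitResult:
    """Final estimates with fit diagnostics."""

    estimates: PopulationModel
    ofv: float
    initial_ofv: float
    se_cv: Optional[Dict[str, float]]
    ebes: Dict[str, np.ndarray]
    eta_shrinkage_pct: Dict[str, float]
    eps_shrinkage_pct: Optional[float]
    converged: bool
    n_iter: int
    n_obj_evals: int
    message: str = ""


def fit_population(
    m0: PopulationModel,
    ds: Dataset,
    opts: Optional[FitOptions] = None,
    eta_start: Optional[Dict[str, np.ndarray]] = None,
) -> FitResult:
    """Maximum-likelihood (FOCE-I) fit of the population model to a dataset.

    Outer quasi-Newton optimisation over log/Cholesky-transformed parameters
    with nested per-subject EBE updates (warm-started between objective
    evaluations).  ``eta_start`` seeds the conditional modes (e.g. from a
    previously fitted nested model, which keeps likelihood-ratio comparisons
    on one set of inner modes).  The returned OFV never exceeds the initial
    one.
    """
    opts = opts or FitOptions()
    if m0.sigma_add == 0.0 and m0.sigma_prop == 0.0:
        raise DomainError("cannot fit a model with no residual error")
    coder = _ParamCoder(m0, opts)
    x0 = coder.encode(m0)
    eta_cache: Dict[str, np.ndarray] = dict(eta_start or {})
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            m = coder.decode(x)
            ofv, lins = foce_components(m, ds, eta_cache)
        except (DomainError, np.linalg.LinAlgError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(ofv):
            return _PENALTY
        for sid, lin in lins.items():
            eta_cache[sid] = lin.eta
        return ofv

    initial_ofv = objective(x0)
    if x0.size == 0:
        raise DomainError("no parameters selected for estimation")
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        jac=opts.outer_jac,
        options={
            "maxiter": opts.maxiter,
            "ftol": 5e-8,
            "gtol": 1e-3,
            "finite_diff_rel_step": opts.fd_rel_step,
        },
    )
    x_best = res.x if res.fun <= initial_ofv else x0
    final_ofv = float(min(res.fun, initial_ofv))
    m_final = coder.decode(x_best)
    _, lins = foce_components(m_final, ds, eta_cache)
    ebes = {sid: lin.eta for sid, lin in lins.items()}

    eta_shr = _eta_shrinkage_from(m_final, ebes)
    eps_shr = _eps_shrinkage_from(m_final, lins)

    se_cv = None
    if opts.compute_se:
        se_cv = _estimate_cv(objective, x_best, coder, m_final)

    return FitResult(
        estimates=m_final,
        ofv=final_ofv,
        initial_ofv=float(initial_ofv),
        se_cv=se_cv,
        ebes=ebes,
        eta_shrinkage_pct=eta_shr,
        eps_shrinkage_pct=eps_shr,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_obj_evals=n_evals,
        message=str(res.message),
    )


def evaluate_model(m: PopulationModel, ds: Dataset) -> FitResult:
    """Evaluate a model on a dataset without optimising the population parameters.

    Computes the FOCE-I objective, the empirical Bayes estimates and the
    shrinkage diagnostics at the given parameter values — the posthoc step
    used for diagnostics of a fixed (e.g. published) model.
    """
    ofv, lins = foce_components(m, ds)
    ebes = {sid: lin.eta for sid, lin in lins.items()}
    return FitResult(
        estimates=m.copy(),
        ofv=float(ofv),
        initial_ofv=float(ofv),
        se_cv=None,
        ebes=ebes,
        eta_shrinkage_pct=_eta_shrinkage_from(m, ebes),
        eps_shrinkage_pct=_eps_shrinkage_from(m, lins),
        converged=True,
        n_iter=0,
        n_obj_evals=1,
        message="posthoc evaluation (no outer optimisation)",
    )


def _estimate_cv(objective, x: np.ndarray, coder: _ParamCoder, m: PopulationModel):
    """CV% of the fixed effects from the inverse finite-difference Hessian.

    The OFV carries small noise from the nested conditional optimisations, so
    several finite-difference step sizes are tried; the first that yields a
    positive-definite Hessian wins.  Returns None when none does (CV%
    reported as missing, the fit itself is unaffected).
    """
    n = x.size
    f0 = objective(x)
    cov = None
    for h_rel in (1e-3, 3e-3, 1e-2):
        h = h_rel * np.maximum(np.abs(x), 1.0)
        H = np.zeros((n, n))
        try:
            for i in range(n):
                ei = np.zeros(n); ei[i] = h[i]
                fp, fm = objective(x + ei), objective(x - ei)
                H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
                for j in range(i + 1, n):
                    ej = np.zeros(n); ej[j] = h[j]
                    fpp = objective(x + ei + ej)
                    fpm = objective(x + ei - ej)
                    fmp = objective(x - ei + ej)
                    fmm = objective(x - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
            cand = 2.0 * np.linalg.inv(H)  # OFV = -2 log L  =>  var = 2 * H^{-1}
        except np.linalg.LinAlgError:
            continue
        if np.all(np.diag(cand) > 0.0):
            cov = cand
            break
    if cov is None:
        return None
    se_x = np.sqrt(np.diag(cov))
    out: Dict[str, float] = {}
    pos = 0
    for i in coder.theta_idx:
        out[PARAM_NAMES[i]] = 100.0 * se_x[pos]; pos += 1  # log scale: CV% ~ 100*SE
    for k in range(coder.n_eff):
        e = m.covariate_effects[k]
        denom = abs(e.coefficient)
        out[f"{e.covariate}_on_{e.parameter}"] = (
            float("nan") if denom == 0.0 else 100.0 * se_x[pos] / denom
        )
        pos += 1
    return out


# ---------------------------------------------------------------------------
# Shrinkage
# ---------------------------------------------------------------------------

def _eta_shrinkage_from(m: PopulationModel, ebes: Dict[str, np.ndarray]) -> Dict[str, float]:
    out: Dict[str, float] = {}
    etas = np.array(list(ebes.values()))
    for i in m.iiv_support():
        w = math.sqrt(m.omega[i, i])
        if etas.shape[0] < 2 or w <= 0.0:
            out[PARAM_NAMES[i]] = float("nan")
        else:
            out[PARAM_NAMES[i]] = 100.0 * (1.0 - float(np.std(etas[:, i], ddof=1)) / w)
    return out


def _eps_shrinkage_from(m: PopulationModel, lins: Dict[str, _Linearization]) -> Optional[float]:
    # IWRES = (y - f(eta_hat)) / sqrt(v(eta_hat)); note r - G eta = y - f_hat
    pieces = [
        (lin.r - lin.G @ lin.eta[lin.support]) / np.sqrt(lin.v_hat) for lin in lins.values()
    ]
    iwres = np.concatenate(pieces) if pieces else np.array([])
    if iwres.size < 2:
        return None
    return 100.0 * (1.0 - float(np.std(iwres, ddof=1)))


def eta_shrinkage(fit: FitResult) -> Dict[str, float]:
    """Per-parameter eta shrinkage, 100*(1 - SD(EBE)/omega)."""
    return _eta_shrinkage_from(fit.estimates, fit.ebes)


def eps_shrinkage(fit: FitResult, ds: Dataset) -> Optional[float]:
    """Epsilon shrinkage, 100*(1 - SD(IWRES)) at the conditional modes."""
    _, lins = foce_components(fit.estimates, ds, dict(fit.ebes))
    return _eps_shrinkage_from(fit.estimates, lins)
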