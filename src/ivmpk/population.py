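"""Population layer: typical values, covariate effects, IIV, and residual error.

Individual parameters are built multiplicatively from typical values:

    P_i = theta_P * (WT_i / WT_ref)^k * prod(covariate multipliers) * exp(eta_P)

with fixed allometric exponents (0.75 on the clearances CL/F and Q/F, 1 on the
volumes Vc/F and Vp/F), power-law effects for continuous covariates
``(cov / cov_ref)^coef`` and exponential effects for 0/1 categorical
covariates ``exp(coef * cat)``.  Between-subject variability (IIV) is
log-normal with covariance ``omega`` on the log scale; residual error is the
combined additive + proportional model ``var = sd_add^2 + (sd_prop * f)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .structural import PARAM_NAMES, DomainError, StructuralParams

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Default fixed allometric exponents: 0.75 for clearances, 1 for volumes.
ALLOMETRIC_EXPONENTS = {"CL": 0.75, "Q": 0.75, "Vc": 1.0, "Vp": 1.0}

CONTINUOUS_POWER = "continuous-power"
CATEGORICAL_EXPONENTIAL = "categorical-exponential"


def allometric_factor(wt: float, ref: float, exponent: float) -> float:
    """Weight-standardisation multiplier (wt / ref) ** exponent."""
    if wt <= 0.0 or ref <= 0.0:
        raise DomainError(f"weights must be positive (wt={wt}, ref={ref})")
    return (wt / ref) ** exponent


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship in the multiplicative model."""

    parameter: str
    covariate: str
    kind: str
    coefficient: float
    reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.parameter not in _PARAM_INDEX:
            raise DomainError(f"unknown parameter {self.parameter!r}")
        if self.kind not in (CONTINUOUS_POWER, CATEGORICAL_EXPONENTIAL):
            raise DomainError(f"unknown covariate-effect kind {self.kind!r}")
        if self.kind == CONTINUOUS_POWER:
            if self.reference is None or self.reference <= 0.0:
                raise DomainError(
                    f"continuous effect on {self.parameter} needs a positive reference"
                )


def continuous_covariate_multiplier(e: CovariateEffect, value: float) -> float:
    """(value / reference) ** coefficient for a continuous covariate."""
    if e.kind != CONTINUOUS_POWER:
        raise DomainError("effect is not continuous-power")
    if value <= 0.0:
        raise DomainError(f"continuous covariate {e.covariate} must be positive, got {value}")
    return (value / e.reference) ** e.coefficient


def categorical_covariate_multiplier(e: CovariateEffect, category: int) -> float:
    """exp(coefficient * category) for a 0/1 categorical covariate."""
    if e.kind != CATEGORICAL_EXPONENTIAL:
        raise DomainError("effect is not categorical-exponential")
    if category not in (0, 1):
        raise DomainError(f"categorical covariate {e.covariate} must be 0 or 1, got {category}")
    return math.exp(e.coefficient * category)


@dataclass
class PopulationModel:
    """Typical values + covariate model + random-effect structure.

    ``theta`` is ordered as :data:`ivmpk.structural.PARAM_NAMES`
    (CL, Q, Vc, Vp, Ka, Tk0, Tlag).  ``omega`` is the 7x7 log-scale IIV
    covariance; ``omega_structure`` records whether off-diagonals are
    estimated ("diagonal" or "full").  ``sigma_add`` (ng/mL) and
    ``sigma_prop`` (fraction) are the residual-error standard deviations.
    """

    theta: np.ndarray
    omega: np.ndarray
    sigma_add: float
    sigma_prop: float
    covariate_effects: list = field(default_factory=list)
    allometric_ref_weight: Optional[float] = None
    allometric_exponents: Mapping[str, float] = field(
        default_factory=lambda: dict(ALLOMETRIC_EXPONENTS)
    )
    omega_structure: str = "diagonal"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape != (7,):
            raise DomainError("theta must have 7 entries (CL, Q, Vc, Vp, Ka, Tk0, Tlag)")
        if np.any(self.theta <= 0.0) or not np.all(np.isfinite(self.theta)):
            raise DomainError("typical values must be strictly positive")
        if self.omega.shape != (7, 7):
            raise DomainError("omega must be 7x7")
        if not np.allclose(self.omega, self.omega.T):
            raise DomainError("omega must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.omega).min())
        if eigmin < -1e-10:
            raise DomainError("omega must be positive semidefinite")
        if self.sigma_add < 0.0 or self.sigma_prop < 0.0:
            raise DomainError("residual SDs must be >= 0")
        if self.sigma_add == 0.0 and self.sigma_prop == 0.0:
            # allowed for noiseless simulation; estimation rejects it explicitly
            pass
        if self.omega_structure not in ("diagonal", "full"):
            raise DomainError("omega_structure must be 'diagonal' or 'full'")

    # -- convenience ---------------------------------------------------------
    def theta_of(self, name: str) -> float:
        return float(self.theta[_PARAM_INDEX[name]])

    def omega2_of(self, name: str) -> float:
        i = _PARAM_INDEX[name]
        return float(self.omega[i, i])

    def iiv_support(self, tol: float = 1e-12) -> np.ndarray:
        """Indices of parameters with non-degenerate IIV variance."""
        return np.flatnonzero(np.diag(self.omega) > tol)

    def copy(self) -> "PopulationModel":
        return PopulationModel(
            theta=self.theta.copy(),
            omega=self.omega.copy(),
            sigma_add=self.sigma_add,
            sigma_prop=self.sigma_prop,
            covariate_effects=list(self.covariate_effects),
            allometric_ref_weight=self.allometric_ref_weight,
            allometric_exponents=dict(self.allometric_exponents),
            omega_structure=self.omega_structure,
        )

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        m = self.copy()
        m.covariate_effects = list(self.covariate_effects) + [effect]
        return m


def covariate_multipliers(m: PopulationModel, covariates: Mapping[str, float]) -> np.ndarray:
    """Combined fixed-effect multiplier per parameter (allometry + covariates)."""
    mult = np.ones(7)
    if m.allometric_ref_weight is not None:
        wt = float(covariates["WT"])
        for name, expo in m.allometric_exponents.items():
            mult[_PARAM_INDEX[name]] *= allometric_factor(wt, m.allometric_ref_weight, expo)
    for e in m.covariate_effects:
        value = float(covariates[e.covariate])
        if e.kind == CONTINUOUS_POWER:
            f = continuous_covariate_multiplier(e, value)
        else:
            f = categorical_covariate_multiplier(e, int(round(value)))
        mult[_PARAM_INDEX[e.parameter]] *= f
    return mult


def individual_parameter_vector(
    m: PopulationModel, covariates: Mapping[str, float], eta: Sequence[float]
) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (7,):
        raise DomainError("eta must have 7 entries")
    if not np.all(np.isfinite(eta)):
        raise DomainError("eta must be finite")
    return m.theta * covariate_multipliers(m, covariates) * np.exp(eta)


def individual_parameters(
    m: PopulationModel, covariates: Mapping[str, float], eta: Sequence[float]
) -> StructuralParams:
    """Individual PK parameters: theta x allometry x covariates x exp(eta)."""
    return StructuralParams.from_array(individual_parameter_vector(m, covariates, eta))


def residual_variance(m: PopulationModel, f) -> np.ndarray:
    """Combined-error variance sd_add^2 + (sd_prop * f)^2 at prediction(s) f."""
    if m.sigma_add == 0.0 and m.sigma_prop == 0.0:
        raise DomainError("degenerate residual model: both error SDs are zero")
    f = np.asarray(f, dtype=float)
    return m.sigma_add**2 + (m.sigma_prop * f) ** 2


def omega_sqrt(omega: np.ndarray) -> np.ndarray:
    """Square root of a PSD IIV covariance for sampling (eta = S @ z).

    Uses an eigendecomposition with small negative eigenvalues clipped to
    zero, so exactly-zero variances produce exactly-zero random effects.
    """
    w, u = np.linalg.eigh(np.asarray(omega, dtype=float))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise DomainError("omega is not positive semidefinite")
    return u @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def cv_percent_from_omega2(omega2: float) -> float:
    """Log-normal CV%% of a parameter with log-scale variance ``omega2``.

    CV% = 100 * sqrt(exp(omega2) - 1); this is the convention under which the
    reported IIV variances convert to their published CV% values.
    """
    if omega2 < 0.0:
        raise DomainError(f"omega-squared must be >= 0, got {omega2}")
    return 100.0 * math.sqrt(math.expm1(omega2))


# ---------------------------------------------------------------------------
# Published final-model estimates (single-dose oral ivermectin, adult cohort
# from an LF-endemic region; 200 ug/kg with food).  Typical values refer to a
# subject at the reference body weight; the sex effect acts on Vp/F.
# ---------------------------------------------------------------------------

#: Final-model typical values, ordered (CL, Q, Vc, Vp, Ka, Tk0, Tlag).
REFERENCE_THETA = np.array([7.02, 9.11, 138.0, 424.33, 0.71, 3.73, 0.75])

#: Final-model IIV variances (log scale), same ordering.
REFERENCE_OMEGA2 = np.array([0.25, 0.19, 0.23, 0.17, 0.55, 0.11, 0.35])

REFERENCE_SIGMA_ADD = 0.46
REFERENCE_SIGMA_PROP = 0.22

#: Sex (male = 1) coefficient on Vp/F: Vp_i = 424.33 * exp(-0.74 * SEX).
REFERENCE_SEX_ON_VP = -0.74

#: Male typical Vp/F as printed in the source report (424.33 * exp(-0.74)
#: evaluates to 202.5 L; the reported table prints 200.4 L, consistent with an
#: unrounded coefficient near -0.75).
REFERENCE_VP_MALE_PRINTED = 200.4

#: Base-model (pre-covariate) IIV variance of Vp/F, for the IIV-reduction
#: diagnostic 1 - 0.17/0.30.
REFERENCE_VP_OMEGA2_BASE = 0.30

#: Default reference ("average") body weight for allometric standardisation
#: when simulating from the published estimates, kg.
DEFAULT_REF_WEIGHT = 64.0


def reference_model(
    ref_weight: float = DEFAULT_REF_WEIGHT,
    omega_structure: str = "diagonal",
    with_sex_effect: bool = True,
) -> PopulationModel:
    """The published final covariate model.

    Only the IIV variances were reported, so the returned ``omega`` is
    diagonal even though the covariance structure was estimated as a full
    block; set ``omega_structure='full'`` to let a refit estimate the
    off-diagonals.
    """
    effects = []
    if with_sex_effect:
        effects.append(
            CovariateEffect(
                parameter="Vp",
                covariate="SEX",
                kind=CATEGORICAL_EXPONENTIAL,
                coefficient=REFERENCE_SEX_ON_VP,
            )
        )
    return PopulationModel(
        theta=REFERENCE_THETA.copy(),
        omega=np.diag(REFERENCE_OMEGA2.copy()),
        sigma_add=REFERENCE_SIGMA_ADD,
        sigma_prop=REFERENCE_SIGMA_PROP,
        covariate_effects=effects,
        allometric_ref_weight=ref_weight,
        omega_structure=omega_structure,
    )


def model_to_dict(m: PopulationModel) -> dict:
    """Serialisable form of a model (used by the YAML config round trip)."""
    return {
        "theta": {name: float(m.theta[i]) for i, name in enumerate(PARAM_NAMES)},
        "omega": [[float(v) for v in row] for row in m.omega],
        "omega_structure": m.omega_structure,
        "sigma": {"additive": float(m.sigma_add), "proportional": float(m.sigma_prop)},
        "allometric": (
            None
            if m.allometric_ref_weight is None
            else {
                "ref_weight": float(m.allometric_ref_weight),
                "exponents": {k: float(v) for k, v in m.allometric_exponents.items()},
            }
        ),
        "covariate_effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "kind": e.kind,
                "coefficient": float(e.coefficient),
                "reference": None if e.reference is None else float(e.reference),
            }
            for e in m.covariate_effects
        ],
    }


def model_from_dict(d: Mapping) -> PopulationModel:
    theta = np.array([d["theta"][name] for name in PARAM_NAMES], dtype=float)
    omega_spec = d.get("omega")
    if omega_spec is None:
        omega = np.zeros((7, 7))
    else:
        omega = np.asarray(omega_spec, dtype=float)
        if omega.ndim == 1:
            omega = np.diag(omega)
    allo = d.get("allometric")
    effects = [
        CovariateEffect(
            parameter=e["parameter"],
            covariate=e["covariate"],
            kind=e["kind"],
            coefficient=float(e["coefficient"]),
            reference=None if e.get("reference") is None else float(e["reference"]),
        )
        for e in d.get("covariate_effects", [])
    ]
    sigma = d.get("sigma", {})
    return PopulationModel(
        theta=theta,
        omega=omega,
        sigma_add=float(sigma.get("additive", 0.0)),
        sigma_prop=float(sigma.get("proportional", 0.0)),
        covariate_effects=effects,
        allometric_ref_weight=None if allo is None else float(allo["ref_weight"]),
        allometric_exponents=(
            dict(ALLOMETRIC_EXPONENTS)
            if allo is None or "exponents" not in allo
            else {k: float(v) for k, v in allo["exponents"].items()}
        ),
        omega_structure=d.get("omega_structure", "diagonal"),
    )
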