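"""Virtual study cohorts emulating the single-dose ivermectin trial design.

The default :class:`CohortSpec` mirrors the adult cohort the model was built
on: 56 subjects, 57% male, body weight from a truncated normal anchored at
the reported median 61.6 kg and range 51-135 kg, ages 18-66, 57% LF-infected,
200 ug/kg dosing after food, and plasma sampling pre-dose and at
1, 2, 3, 4, 6, 8, 12, 24, 36, 48, 72 and 168 h with LLOQ 0.1 ng/mL.
Liver/renal labs (ALT, AST, SCR) are drawn uniformly within the reported
ranges; the source analysis found no effect of them, so they act as realistic
null candidates for covariate selection.

Observed concentrations are generated from the structural model with
log-normal IIV and combined additive + proportional residual error; draws
that land below zero are re-drawn (counted, rare at study-like parameters).
Pre-dose samples of treatment-naive subjects are recorded as MDV=1 rows with
DV below the LLOQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dataio import Dataset, SubjectRecord
from .population import DomainError, PopulationModel, individual_parameter_vector, omega_sqrt
from .structural import predict_concentrations_multi

#: Post-dose sampling times (h) of the index study design.
STUDY_SCHEDULE = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0, 168.0)

#: Post-dose sampling times (h) of the external-validation design (0-72 h).
EXTERNAL_SCHEDULE = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)


@dataclass
class CohortSpec:
    """Design of a virtual cohort (defaults = the index study)."""

    n_subjects: int = 56
    sex_ratio: float = 0.57
    weight_mean: float = 64.0
    weight_sd: float = 11.0
    weight_bounds: Tuple[float, float] = (51.0, 135.0)
    age_range: Tuple[float, float] = (18.0, 66.0)
    infection_prevalence: float = 0.57
    alt_range: Tuple[float, float] = (14.0, 67.0)
    ast_range: Tuple[float, float] = (15.0, 53.0)
    scr_range: Tuple[float, float] = (0.6, 1.6)
    schedule: Sequence[float] = STUDY_SCHEDULE
    dose_per_kg: float = 200.0  # ug/kg
    lloq: float = 0.1
    n_missing_last: int = 4  # subjects missing the final sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0 or not 0.0 <= self.infection_prevalence <= 1.0:
            raise DomainError("fractions must lie in [0, 1]")
        lo, hi = self.weight_bounds
        if not (0.0 < lo < hi):
            raise DomainError("weight bounds must be positive and ordered")
        if hi < self.weight_mean - 6.0 * self.weight_sd or lo > self.weight_mean + 6.0 * self.weight_sd:
            raise DomainError("weight truncation bounds exclude mean +- 6 SD")
        sched = tuple(float(t) for t in self.schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])) or (sched and sched[0] <= 0.0):
            raise DomainError("schedule must be strictly increasing and post-dose")
        if self.n_missing_last > self.n_subjects:
            raise DomainError("n_missing_last exceeds cohort size")


def external_validation_spec(seed: int = 0) -> CohortSpec:
    """Built-in preset for the external-validation design (25 subjects, 0-72 h)."""
    return CohortSpec(
        n_subjects=25, schedule=EXTERNAL_SCHEDULE, n_missing_last=0, seed=seed
    )


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def generate_demographics(spec: CohortSpec, rng: Optional[np.random.Generator] = None):
    """Per-subject covariate records (WT, SEX, AGE, ALT, AST, SCR, INF)."""
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sex = (rng.random(n) < spec.sex_ratio).astype(int)
    wt = _truncnorm(rng, spec.weight_mean, spec.weight_sd, *spec.weight_bounds, size=n)
    age = rng.uniform(*spec.age_range, size=n)
    inf = (rng.random(n) < spec.infection_prevalence).astype(int)
    alt = rng.uniform(*spec.alt_range, size=n)
    ast = rng.uniform(*spec.ast_range, size=n)
    scr = rng.uniform(*spec.scr_range, size=n)
    return [
        {
            "WT": round(float(wt[i]), 1),
            "SEX": int(sex[i]),
            "AGE": round(float(age[i]), 1),
            "ALT": round(float(alt[i]), 1),
            "AST": round(float(ast[i]), 1),
            "SCR": round(float(scr[i]), 2),
            "INF": int(inf[i]),
        }
        for i in range(n)
    ]


def generate_dataset(
    spec: CohortSpec,
    truth: PopulationModel,
    rng: Optional[np.random.Generator] = None,
    name: str = "synthetic",
) -> Dataset:
    """Simulate one study dataset from a known ("truth") population model.

    Each subject receives ``dose_per_kg * WT`` ug at time zero, has a random
    effect vector eta ~ MVN(0, Omega), and is observed at the schedule times
    with combined residual error.  The last-time sample is dropped for
    ``spec.n_missing_last`` subjects (chosen reproducibly), echoing subjects
    lost to the final visit.  Observed DVs below the LLOQ are recorded as
    MDV=1 rows rather than discarded.
    """
    rng = rng or np.random.default_rng(spec.seed)
    demo = generate_demographics(spec, rng)
    n = spec.n_subjects
    chol = omega_sqrt(truth.omega)
    etas = rng.standard_normal((n, 7)) @ chol.T
    missing_last = set(rng.choice(n, size=spec.n_missing_last, replace=False).tolist())

    times = np.asarray(spec.schedule, dtype=float)
    n_redraws = 0
    subjects = []
    for i in range(n):
        cov = demo[i]
        dose = spec.dose_per_kg * cov["WT"]  # ug
        params = individual_parameter_vector(truth, cov, etas[i])
        t_i = times[:-1] if i in missing_last else times
        f = predict_concentrations_multi(params[None, :], [(0.0, dose)], t_i)[0]
        dv = np.empty_like(f)
        for j, fj in enumerate(f):
            for _ in range(100):
                eps_p = rng.standard_normal()
                eps_a = rng.standard_normal()
                val = fj * (1.0 + truth.sigma_prop * eps_p) + truth.sigma_add * eps_a
                if val >= 0.0 or (truth.sigma_add == 0.0 and truth.sigma_prop == 0.0):
                    break
                n_redraws += 1
            dv[j] = round(max(val, 0.0), 6)
        obs = [(float(t), float(v)) for t, v in zip(t_i, dv) if v >= spec.lloq]
        below = [(float(t), float(v)) for t, v in zip(t_i, dv) if v < spec.lloq]
        subjects.append(
            SubjectRecord(
                subject_id=str(i + 1),
                dose_events=[(0.0, round(dose, 6))],
                observations=obs,
                covariates=dict(cov),
                excluded=[(0.0, 0.0)] + below,  # pre-dose anchor + any BLQ draws
            )
        )
    ds = Dataset(subjects=subjects, lloq=spec.lloq, name=name)
    ds.n_error_redraws = n_redraws  # type: ignore[attr-defined]
    return ds
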