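"""Model diagnostics and validation: GOF tables, VPC, nonparametric bootstrap.

CWRES is computed from exactly the same per-subject linearisation (same
``C_i`` and residual ``r_i``) that the FOCE-I objective uses, so residual
diagnostics and the likelihood always agree about the model being judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dataio import Dataset, SubjectRecord
from .estimation import (
    FitOptions,
    FitResult,
    fit_population,
    foce_components,
    subject_prediction,
)
from .population import DomainError, PopulationModel, omega_sqrt, residual_variance
from .structural import PARAM_NAMES


def gof_table(fit: FitResult, ds: Dataset) -> pd.DataFrame:
    """Goodness-of-fit table: DV, PRED, IPRED, IWRES, CWRES per observation.

    PRED is the population prediction (eta = 0), IPRED the prediction at the
    subject's conditional mode.
    """
    m = fit.estimates
    if not fit.ebes:
        raise DomainError("fit has no empirical Bayes estimates")
    _, lins = foce_components(m, ds, dict(fit.ebes))
    rows = []
    zero = np.zeros(7)
    for s in ds.subjects:
        lin = lins[s.subject_id]
        pred = subject_prediction(m, s, zero)
        ipred = lin.f_hat
        iwres = (s.obs_values - ipred) / np.sqrt(lin.v_hat)
        cwres = lin.cwres
        for j, (t, dv) in enumerate(s.observations):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "time": t,
                    "DV": dv,
                    "PRED": pred[j],
                    "IPRED": ipred[j],
                    "IWRES": iwres[j],
                    "CWRES": cwres[j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VpcResult:
    """Observed percentiles and simulated prediction bands per time bin."""

    bins: np.ndarray                       # nominal times (h)
    observed: pd.DataFrame                 # columns p5, p50, p95 per bin
    bands: pd.DataFrame                    # columns {p5,p50,p95}_{lo,hi} per bin
    n_replicates: int
    merged_bins: List[float] = field(default_factory=list)

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their 95% band."""
        inside = 0
        total = 0
        for q in ("p5", "p50", "p95"):
            obs = self.observed[q].to_numpy()
            lo = self.bands[f"{q}_lo"].to_numpy()
            hi = self.bands[f"{q}_hi"].to_numpy()
            ok = np.isfinite(obs)
            inside += int(np.sum((obs[ok] >= lo[ok]) & (obs[ok] <= hi[ok])))
            total += int(np.sum(ok))
        return inside / total if total else float("nan")


def _simulate_observations(
    m: PopulationModel,
    subjects: List[SubjectRecord],
    n_rep: int,
    rng: np.random.Generator,
    with_residual: bool = True,
) -> Dict[str, np.ndarray]:
    """(n_rep, n_times) simulated DV matrices per subject at the observed design."""
    chol = omega_sqrt(m.omega)
    from .population import covariate_multipliers
    from .structural import predict_concentrations_multi

    out = {}
    for s in subjects:
        etas = rng.standard_normal((n_rep, 7)) @ chol.T
        base = m.theta * covariate_multipliers(m, s.covariates)
        params = base[None, :] * np.exp(etas)
        f = predict_concentrations_multi(params, s.dose_events, s.obs_times)
        if with_residual and (m.sigma_add > 0.0 or m.sigma_prop > 0.0):
            v = residual_variance(m, f)
            f = f + np.sqrt(v) * rng.standard_normal(f.shape)
        out[s.subject_id] = np.maximum(f, 0.0)
    return out


_PCTL = (5.0, 50.0, 95.0)


def vpc(
    m: PopulationModel,
    ds: Dataset,
    n_rep: int = 1000,
    seed: int = 0,
    lloq_censor: bool = False,
    min_bin_count: int = 1,
) -> VpcResult:
    """Visual predictive check at the observed design.

    Simulates ``n_rep`` replicate datasets (same subjects, covariates, doses
    and times), computes the 5th/50th/95th percentile per nominal-time bin in
    each replicate, and returns the 2.5-97.5% band of each percentile next to
    the observed percentiles.  The design uses a common nominal schedule, so
    bins are the exact observation times; bins thinner than ``min_bin_count``
    are merged into their left neighbour (recorded in ``merged_bins``).
    With ``lloq_censor`` simulated values below the dataset LLOQ are excluded
    from the percentiles (observed data here contain no BLQ values).
    """
    if n_rep < 100:
        raise DomainError("use at least 100 VPC replicates")
    rng = np.random.default_rng(seed)
    all_times = sorted({t for s in ds.subjects for t, _ in s.observations})
    bins = np.array(all_times)

    # map observations / simulated columns to bins
    obs_by_bin: Dict[float, List[float]] = {t: [] for t in all_times}
    sim_cols_by_bin: Dict[float, List[np.ndarray]] = {t: [] for t in all_times}
    sims = _simulate_observations(m, ds.subjects, n_rep, rng)
    for s in ds.subjects:
        sim = sims[s.subject_id]
        for j, (t, dv) in enumerate(s.observations):
            obs_by_bin[t].append(dv)
            sim_cols_by_bin[t].append(sim[:, j])

    merged: List[float] = []
    kept: List[float] = []
    for t in all_times:
        if len(obs_by_bin[t]) < min_bin_count and kept:
            prev = kept[-1]
            obs_by_bin[prev] += obs_by_bin.pop(t)
            sim_cols_by_bin[prev] += sim_cols_by_bin.pop(t)
            merged.append(t)
        else:
            kept.append(t)

    obs_rows, band_rows = [], []
    for t in kept:
        obs = np.array(obs_by_bin[t])
        sim = np.column_stack(sim_cols_by_bin[t])  # (n_rep, n_obs_in_bin)
        if lloq_censor:
            sim = np.where(sim >= ds.lloq, sim, np.nan)
            pct = np.nanpercentile(sim, _PCTL, axis=1)
        else:
            pct = np.percentile(sim, _PCTL, axis=1)  # (3, n_rep)
        obs_rows.append({"time": t, "n": obs.size,
                         "p5": np.percentile(obs, 5), "p50": np.percentile(obs, 50),
                         "p95": np.percentile(obs, 95)})
        row = {"time": t}
        for k, q in enumerate(("p5", "p50", "p95")):
            lo, hi = np.nanpercentile(pct[k], [2.5, 97.5])
            row[f"{q}_lo"], row[f"{q}_hi"] = lo, hi
        band_rows.append(row)

    return VpcResult(
        bins=np.array(kept),
        observed=pd.DataFrame(obs_rows),
        bands=pd.DataFrame(band_rows),
        n_replicates=n_rep,
        merged_bins=merged,
    )


def vpc_stratified(
    m: PopulationModel, ds: Dataset, by: str, n_rep: int = 1000, seed: int = 0, **kw
) -> Dict[float, VpcResult]:
    """VPC per level of a categorical covariate (e.g. ``by='SEX'``)."""
    levels = sorted({s.covariates[by] for s in ds.subjects})
    out = {}
    for lev in levels:
        sub = Dataset(
            subjects=[s for s in ds.subjects if s.covariates[by] == lev],
            lloq=ds.lloq,
            name=f"{ds.name}[{by}={lev}]",
        )
        out[lev] = vpc(m, sub, n_rep=n_rep, seed=seed, **kw)
    return out


# ---------------------------------------------------------------------------
# Nonparametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    summary: pd.DataFrame      # parameter, median, p2.5, p97.5
    n_replicates: int
    n_failures: int
    unstable: bool

    def interval(self, parameter: str) -> Tuple[float, float, float]:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["p2.5"]), float(row["median"]), float(row["p97.5"])


def _collect_estimates(m: PopulationModel) -> Dict[str, float]:
    out = {name: float(m.theta[i]) for i, name in enumerate(PARAM_NAMES)}
    for e in m.covariate_effects:
        out[f"{e.covariate}_on_{e.parameter}"] = float(e.coefficient)
    for i in m.iiv_support():
        out[f"omega2_{PARAM_NAMES[i]}"] = float(m.omega[i, i])
    out["sigma_add"] = float(m.sigma_add)
    out["sigma_prop"] = float(m.sigma_prop)
    return out


def bootstrap(
    m0: PopulationModel,
    ds: Dataset,
    n_boot: int = 1000,
    seed: int = 0,
    fit_options: Optional[FitOptions] = None,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the model estimates.

    Each replicate resamples subjects with replacement to the original n and
    refits, warm-starting from ``m0`` (pass the final estimates for the
    conventional stability check).  Failed or non-converged replicates are
    retried once from a perturbed start, then excluded and counted; more
    than 20% failures flags the result unstable.
    """
    if n_boot < 50:
        raise DomainError("use at least 50 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(ds.subjects)
    rows: List[Dict[str, float]] = []
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        subjects = []
        for k, i in enumerate(idx):
            s = ds.subjects[i]
            subjects.append(
                SubjectRecord(
                    subject_id=f"b{b}_{k}",
                    dose_events=list(s.dose_events),
                    observations=list(s.observations),
                    covariates=dict(s.covariates),
                    excluded=list(s.excluded),
                )
            )
        bds = Dataset(subjects=subjects, lloq=ds.lloq, name=f"boot{b}")
        fit = None
        for attempt, start in enumerate((m0, _perturbed(m0, rng))):
            try:
                cand = fit_population(start, bds, fit_options)
            except Exception:
                continue
            if cand.converged or attempt == 1:
                fit = cand
                break
            fit = cand
        if fit is None:
            failures += 1
            continue
        rows.append(_collect_estimates(fit.estimates))
    if not rows:
        raise DomainError("all bootstrap replicates failed")
    frame = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "parameter": frame.columns,
            "median": frame.median().to_numpy(),
            "p2.5": frame.quantile(0.025).to_numpy(),
            "p97.5": frame.quantile(0.975).to_numpy(),
        }
    )
    return BootstrapResult(
        summary=summary,
        n_replicates=len(rows),
        n_failures=failures,
        unstable=failures > 0.2 * n_boot,
    )


def _perturbed(m: PopulationModel, rng: np.random.Generator) -> PopulationModel:
    out = m.copy()
    out.theta = m.theta * np.exp(rng.normal(0.0, 0.1, size=7))
    return out
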