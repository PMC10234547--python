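"""Stepwise covariate model building by likelihood-ratio thresholds.

Forward addition: each remaining candidate effect is added singly to the
current model; the candidate with the largest objective-function drop is
included if the drop exceeds the chi-square threshold (default p < 0.01 with
1 df, i.e. 6.635).  Backward elimination: each included effect is removed in
turn and is dropped if its removal raises the objective by less than the
stricter threshold (default p < 0.001, i.e. 10.828).  One effect carries one
degree of freedom.  Creatinine clearance is deliberately not in the default
candidate set: ivermectin is eliminated almost entirely in faeces, so renal
function is not a plausible driver of its clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from scipy import stats

from .dataio import Dataset
from .estimation import FitOptions, fit_population
from .population import CovariateEffect, DomainError, PopulationModel


def lrt_threshold(p: float, df: int = 1) -> float:
    """Delta-OFV significance threshold: upper-p chi-square quantile with df."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"significance level must be in (0, 1), got {p}")
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.ppf(1.0 - p, df))


@dataclass
class SelectionStep:
    effect: CovariateEffect
    delta_ofv: Optional[float]
    accepted: bool
    direction: str  # "forward" | "backward"
    note: str = ""


@dataclass
class SelectionTrace:
    steps: List[SelectionStep] = field(default_factory=list)
    final_effects: List[CovariateEffect] = field(default_factory=list)


def _default_fitter(fit_options: Optional[FitOptions]):
    def fitter(m: PopulationModel, ds: Dataset, eta_start=None):
        return fit_population(m, ds, fit_options, eta_start=eta_start)

    return fitter


def _key(e: CovariateEffect) -> Tuple[str, str]:
    return (e.parameter, e.covariate)


def _call_fitter(fitter, m, ds, eta_start):
    try:
        return fitter(m, ds, eta_start=eta_start)
    except TypeError:
        return fitter(m, ds)


def stepwise_select(
    base: PopulationModel,
    ds: Dataset,
    candidates: Sequence[CovariateEffect],
    p_fwd: float = 0.01,
    p_bwd: float = 0.001,
    fit_options: Optional[FitOptions] = None,
    fitter: Optional[Callable] = None,
) -> Tuple[PopulationModel, SelectionTrace]:
    """Forward-addition / backward-elimination covariate search.

    ``fitter(model, ds)`` must return an object with ``ofv`` and
    ``estimates`` attributes (default: :func:`fit_population`); injecting a
    surrogate makes the selection logic testable without full refits.  Ties
    break by larger OFV drop, then candidate declaration order.  A fit
    failure skips that step and is recorded in the trace.
    """
    fitter = fitter or _default_fitter(fit_options)
    thr_fwd = lrt_threshold(p_fwd, 1)
    thr_bwd = lrt_threshold(p_bwd, 1)
    trace = SelectionTrace()

    base_fit = _call_fitter(fitter, base, ds, None)
    current_model = base_fit.estimates
    current_ofv = float(base_fit.ofv)
    current_etas = getattr(base_fit, "ebes", None)
    included: List[CovariateEffect] = []
    remaining = list(candidates)

    # forward addition
    while remaining:
        round_results = []
        for idx, cand in enumerate(remaining):
            try:
                fit = _call_fitter(fitter, current_model.with_effect(cand), ds, current_etas)
                delta = current_ofv - float(fit.ofv)
                round_results.append((delta, -idx, cand, fit))
            except Exception as exc:  # failed step: recorded, not fatal
                trace.steps.append(
                    SelectionStep(cand, None, False, "forward", f"fit failed: {exc}")
                )
        if not round_results:
            break
        round_results.sort(key=lambda r: (r[0], r[1]), reverse=True)
        best_delta, _, best_cand, best_fit = round_results[0]
        for delta, _, cand, _fit in round_results:
            if cand is not best_cand:
                trace.steps.append(SelectionStep(cand, delta, False, "forward"))
        if best_delta > thr_fwd:
            trace.steps.append(SelectionStep(best_cand, best_delta, True, "forward"))
            included.append(best_cand)
            remaining = [c for c in remaining if _key(c) != _key(best_cand)]
            current_model = best_fit.estimates
            current_ofv = float(best_fit.ofv)
            current_etas = getattr(best_fit, "ebes", None)
        else:
            trace.steps.append(
                SelectionStep(best_cand, best_delta, False, "forward", "below threshold")
            )
            break

    # backward elimination
    changed = True
    while changed and included:
        changed = False
        removals = []
        for idx, eff in enumerate(included):
            reduced_effects = [e for e in current_model.covariate_effects if _key(e) != _key(eff)]
            reduced = current_model.copy()
            reduced.covariate_effects = reduced_effects
            try:
                fit = _call_fitter(fitter, reduced, ds, current_etas)
                increase = float(fit.ofv) - current_ofv
                removals.append((increase, idx, eff, fit))
            except Exception as exc:
                trace.steps.append(
                    SelectionStep(eff, None, False, "backward", f"fit failed: {exc}")
                )
        if not removals:
            break
        removals.sort(key=lambda r: (r[0], r[1]))
        increase, _, eff, fit = removals[0]
        if increase < thr_bwd:
            trace.steps.append(SelectionStep(eff, increase, True, "backward"))
            included = [e for e in included if _key(e) != _key(eff)]
            current_model = fit.estimates
            current_ofv = float(fit.ofv)
            current_etas = getattr(fit, "ebes", None)
            changed = True
        else:
            for increase_i, _, eff_i, _fit in removals:
                trace.steps.append(
                    SelectionStep(eff_i, increase_i, False, "backward", "retained")
                )

    trace.final_effects = list(included)
    return current_model, trace
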