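"""Stepwise covariate selection: thresholds, search logic, and null behaviour."""

from types import SimpleNamespace

import numpy as np
import pytest

import ivmpk as pk
from ivmpk.covariates import lrt_threshold, stepwise_select

SEX_ON_VP = pk.CovariateEffect("Vp", "SEX", pk.CATEGORICAL_EXPONENTIAL, 0.0)
INF_ON_CL = pk.CovariateEffect("CL", "INF", pk.CATEGORICAL_EXPONENTIAL, 0.0)
AGE_ON_CL = pk.CovariateEffect("CL", "AGE", pk.CONTINUOUS_POWER, 0.0, reference=40.0)


class TestLrtThreshold:
    @pytest.mark.parametrize(
        "p,df,expected",
        [(0.01, 1, 6.635), (0.001, 1, 10.828), (0.05, 1, 3.841), (0.01, 2, 9.210)],
    )
    def test_chi_square_quantiles(self, p, df, expected):
        assert lrt_threshold(p, df) == pytest.approx(expected, abs=1e-3)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(pk.DomainError):
            lrt_threshold(0.0, 1)
        with pytest.raises(pk.DomainError):
            lrt_threshold(0.01, 0)


class StubFitter:
    """Canned OFVs per covariate-effect set: isolates the search logic."""

    def __init__(self, ofv_by_keys):
        self.ofv_by_keys = ofv_by_keys
        self.calls = []

    def __call__(self, m, ds, eta_start=None):
        key = frozenset((e.parameter, e.covariate) for e in m.covariate_effects)
        self.calls.append(key)
        if key not in self.ofv_by_keys:
            raise RuntimeError(f"no fit available for {sorted(key)}")
        return SimpleNamespace(ofv=self.ofv_by_keys[key], estimates=m, ebes={})


def base_model():
    m = pk.reference_model()
    m.covariate_effects = []
    return m


class TestStepwiseLogic:
    def test_strong_effect_survives_both_directions(self):
        fitter = StubFitter({
            frozenset(): 1000.0,
            frozenset({("Vp", "SEX")}): 980.0,          # drop 20 > 6.635
            frozenset({("CL", "INF")}): 998.0,          # drop 2, not significant
            frozenset({("Vp", "SEX"), ("CL", "INF")}): 979.0,
        })
        final, trace = stepwise_select(base_model(), None, [SEX_ON_VP, INF_ON_CL], fitter=fitter)
        assert [(e.covariate, e.parameter) for e in trace.final_effects] == [("SEX", "Vp")]
        backward = [s for s in trace.steps if s.direction == "backward"]
        assert backward and not backward[-1].accepted  # retained at backward

    def test_between_thresholds_effect_removed_backward(self):
        # forward drop 8 (> 6.635) but removal increase 8 (< 10.828): dropped
        fitter = StubFitter({
            frozenset(): 1000.0,
            frozenset({("Vp", "SEX")}): 992.0,
            frozenset({("CL", "INF")}): 999.5,
        })
        final, trace = stepwise_select(base_model(), None, [SEX_ON_VP, INF_ON_CL], fitter=fitter)
        assert trace.final_effects == []
        fwd = [s for s in trace.steps if s.direction == "forward" and s.accepted]
        bwd = [s for s in trace.steps if s.direction == "backward" and s.accepted]
        assert len(fwd) == 1 and fwd[0].delta_ofv == pytest.approx(8.0)
        assert len(bwd) == 1 and bwd[0].delta_ofv == pytest.approx(8.0)

    def test_tie_breaks_by_declaration_order(self):
        fitter = StubFitter({
            frozenset(): 1000.0,
            frozenset({("Vp", "SEX")}): 990.0,
            frozenset({("CL", "AGE")}): 990.0,
            frozenset({("Vp", "SEX"), ("CL", "AGE")}): 989.9,
        })
        _, trace = stepwise_select(base_model(), None, [SEX_ON_VP, AGE_ON_CL], fitter=fitter)
        first_accept = next(s for s in trace.steps if s.accepted)
        assert (first_accept.effect.covariate, first_accept.effect.parameter) == ("SEX", "Vp")

    def test_failed_candidate_fit_recorded_and_skipped(self):
        fitter = StubFitter({
            frozenset(): 1000.0,
            frozenset({("Vp", "SEX")}): 980.0,
            # INF fit intentionally missing -> raises
            frozenset({("Vp", "SEX"), ("CL", "INF")}): 1.0e9,
        })
        final, trace = stepwise_select(base_model(), None, [SEX_ON_VP, INF_ON_CL], fitter=fitter)
        failed = [s for s in trace.steps if "fit failed" in s.note]
        assert failed and failed[0].effect.covariate == "INF"
        assert [(e.covariate,) for e in trace.final_effects] == [("SEX",)]

    def test_deterministic_given_same_inputs(self):
        table = {
            frozenset(): 1000.0,
            frozenset({("Vp", "SEX")}): 980.0,
            frozenset({("CL", "INF")}): 995.0,
            frozenset({("Vp", "SEX"), ("CL", "INF")}): 979.0,
        }
        r1 = stepwise_select(base_model(), None, [SEX_ON_VP, INF_ON_CL], fitter=StubFitter(table))
        r2 = stepwise_select(base_model(), None, [SEX_ON_VP, INF_ON_CL], fitter=StubFitter(table))
        assert [(s.direction, s.accepted, s.delta_ofv) for s in r1[1].steps] == [
            (s.direction, s.accepted, s.delta_ofv) for s in r2[1].steps
        ]


class TestStepwiseOnData:
    def test_null_data_selects_nothing(self, ref_model):
        """No covariate reaches the threshold on data simulated without effects."""
        truth = ref_model.copy()
        truth.covariate_effects = []  # no sex effect in the generating model
        spec = pk.CohortSpec(n_subjects=24, n_missing_last=0, seed=31)
        ds = pk.generate_dataset(spec, truth)
        tmask = [False] * 7
        tmask[0] = tmask[3] = True  # CL, Vp
        omask = [False] * 7
        omask[3] = True
        opts = pk.FitOptions(estimate_theta=tmask, estimate_omega=omask,
                             estimate_sigma=False, maxiter=25)
        final, trace = stepwise_select(
            truth.copy(), ds, [SEX_ON_VP, INF_ON_CL], fit_options=opts
        )
        assert trace.final_effects == []
        for step in trace.steps:
            assert step.delta_ofv is None or step.delta_ofv < 6.635

    def test_nested_delta_nonnegative_within_tolerance(self, ref_model):
        """Adding a parameter to a fitted nested pair cannot worsen the OFV."""
        truth = ref_model.copy()
        truth.covariate_effects = []
        spec = pk.CohortSpec(n_subjects=16, schedule=(2.0, 6.0, 24.0, 72.0, 168.0),
                             n_missing_last=0, seed=17)
        ds = pk.generate_dataset(spec, truth)
        tmask = [False] * 7
        tmask[3] = True
        opts = pk.FitOptions(estimate_theta=tmask, estimate_omega=False,
                             estimate_sigma=False, maxiter=25)
        base_fit = pk.fit_population(truth.copy(), ds, opts)
        richer = base_fit.estimates.with_effect(SEX_ON_VP)
        rich_fit = pk.fit_population(richer, ds, opts, eta_start=base_fit.ebes)
        assert base_fit.ofv - rich_fit.ofv >= -1e-4
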