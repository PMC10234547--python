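# Methods

`ivmpk` implements a population pharmacokinetic (PopPK) analysis of a single
oral dose of ivermectin, taken with food, in adults from a lymphatic
filariasis (LF)–endemic setting.  The package covers the full pharmacometric
workflow: structural model, nonlinear mixed-effects estimation (FOCE-I),
covariate model building, model validation, and Monte Carlo dose-exposure
simulation.  No clinical data ship with the package; every pipeline stage is
exercised on synthetic cohorts whose design mirrors the original study.

## Structural model

Drug disposition follows a two-compartment model with first-order linear
elimination.  Absorption is described by a lagged zero-order input into a
depot compartment that simultaneously drains into the central compartment at
first-order rate `Ka`: after the lag `Tlag`, dose enters the depot at the
constant rate `Dose/Tk0` for `Tk0` hours while `Ka` empties it throughout.
This mixed zero-order/first-order input reproduces the shoulder often seen
in ivermectin absorption profiles (consistent with partial lymphatic uptake
of a highly lipophilic drug).  The "simultaneous" (fill-while-draining)
variant was chosen over a sequential one because it is the natural reading
of a depot with one inflow and one outflow arrow; the choice is isolated in
the structural module.

All volumes and clearances are apparent (bioavailability-scaled, per-F):
oral bioavailability is not separately identifiable from single-dose oral
data.  Units are chosen so that no conversion factors appear anywhere:
amounts in µg, volumes in L, so amount/volume is ng/mL directly.

The system is linear, so it is solved exactly rather than integrated
numerically.  The unit-bolus response of the central compartment is a
tri-exponential with rates `alpha`, `beta` (disposition roots) and `Ka`, and
the zero-order input window is an analytic convolution of that response.
`beta` is computed as `k10*k21/alpha` to avoid subtractive cancellation, and
near-degenerate rate constants (|Ka − alpha| below ~1e-8 relative) fall back
to a piecewise matrix-exponential path.  The matrix-exponential path also
exposes all compartment amounts for mass-balance testing.  A stiff ODE
integration of the same system is kept in the test suite as an independent
oracle; the two agree to better than 1e-6 relative, and mass balance holds
to 1e-8.

## Population model

Individual parameters are multiplicative:

    P_i = theta_P * (WT_i / WT_ref)^k * prod(covariate multipliers) * exp(eta_P,i)

* **Allometric scaling** uses fixed exponents: 0.75 on the clearances CL/F
  and Q/F, 1 on the volumes Vc/F and Vp/F.  The reference weight is the
  "average body weight" of the cohort; since the source estimates do not
  report it, the default for simulations from published values is 64 kg
  (configurable), consistent with a cohort of median 61.6 kg and range
  51–135 kg.  Per-kg dosing summaries are sensitive to this choice
  (roughly ±7% per ±6 kg); fixed-dose summaries much less so.
* **Continuous covariates** enter as power functions
  `(cov/cov_ref)^coef`; **categorical covariates** (sex, infection status,
  coded 0/1) as `exp(coef * cat)`.  The final published model has one
  effect: sex (male) on Vp/F with coefficient −0.74, i.e. male peripheral
  volume ≈ 48% of female.  Physiologically this tracks body-composition
  differences for a lipophilic drug.
* **IIV** is log-normal on all seven parameters.  `omega` is a full 7×7
  covariance; the estimation layer supports a diagonal structure or a full
  Cholesky-parameterised block (kept positive semidefinite by
  construction).  Published IIV estimates are variances only, so simulation
  from the published model uses a diagonal `omega` — published CV% values
  are reproduced by `CV% = 100*sqrt(exp(omega²)−1)`, the log-normal
  convention, which matches every reported CV%.
* **Residual error** is combined additive + proportional:
  `var = sd_add² + (sd_prop · f)²` with published values 0.46 ng/mL and
  0.22.

## FOCE-I estimation

The marginal likelihood is approximated by first-order conditional
estimation with interaction.  Per subject, the conditional mode `eta_i`
(empirical Bayes estimate) minimises

    g(eta) = sum_j [ (y_ij − f_ij(eta))² / v_ij(eta) + log v_ij(eta) ] + eta' Omega^{-1} eta

and the objective is

    OFV = sum_i [ log|C_i| + r_i' C_i^{-1} r_i ],
    C_i = G_i Omega G_i' + diag(v_i(eta_i)),   r_i = y_i − f_i(eta_i) + G_i eta_i

with `G_i = df_i/deta` at the mode (central differences, step 1e-4) and the
residual variance evaluated at the mode (the "interaction").  All `2π`
constants are omitted, the common pharmacometric convention; OFV
*differences* between nested models are unaffected.

**Inner problem.**  The conditional objective is minimised by a damped
Newton iteration whose curvature is the penalised weighted-least-squares
matrix including the exact interaction terms (only `d²f/deta²` is dropped),
with Levenberg damping and an L-BFGS-B fallback for stubborn subjects.
Fresh solves compare three deterministic starts (0, ±0.1) because the
conditional objective can be multimodal; within an outer optimisation the
previous mode warm-starts the next solve.  Convergence: objective
improvement below 1e-8.

**Outer problem.**  Quasi-Newton (L-BFGS-B) over transformed parameters:
log typical values, raw covariate coefficients, log IIV standard deviations
(diagonal) or a Cholesky factor with log diagonal (full block), log residual
SDs.  Gradients by central finite differences with relative step 1e-4
(forward differences available for cheap reduced fits).  Any component can
be frozen (`FitOptions`), which the reduced-scale experiments in the test
suite use.  The returned OFV never exceeds the initial OFV.

**Precision and shrinkage.**  CV% of fixed effects comes from the inverse
finite-difference Hessian of the OFV (delta method on the transformed
scale); several step sizes are tried because the nested optimisations leave
small noise on the OFV, and CV% is reported missing if no step yields a
positive-definite Hessian.  Eta shrinkage is `100·(1 − SD(EBE_p)/omega_p)`,
epsilon shrinkage `100·(1 − SD(IWRES))`.

**Verification.**  FOCE-I is exact for models linear in eta; the suite
checks `OFV = log 2 + 1/2` on a one-observation linear Gaussian toy to
1e-6.  On nonlinear one/two-eta toys the OFV is compared against an
adaptive Gauss–Hermite quadrature of the true marginal (mode-centred,
curvature-scaled, ≥64 nodes, node-doubling convergence below 1e-6), with
agreement required within 0.5 per subject.

## Covariate selection

Stepwise forward addition / backward elimination on OFV likelihood-ratio
thresholds: a candidate enters if it drops the OFV by more than the
chi-square(1) upper-1% quantile (6.635) and survives elimination if its
removal raises the OFV by at least the upper-0.1% quantile (10.828).  One
effect = one degree of freedom; candidates are tested singly per round;
ties break by larger drop, then declaration order.  Creatinine clearance is
excluded from the default candidate set because ivermectin is eliminated
almost entirely in faeces.  The search accepts an injectable fitter, so the
logic is unit-tested against canned OFV tables, and nested candidate fits
are seeded with the current model's conditional modes so likelihood-ratio
comparisons share one set of inner modes.

A replicate experiment in the test suite simulates cohorts at the study
design (56 subjects, 12 post-dose samples) with the −0.74 sex effect and
measures forward-step power: about 80% of replicates exceed the 6.635
threshold, consistent with the effect being detectable but not
overwhelmingly so at n = 56.  Realisations in which the apparent (EBE-level)
sex contrast is diluted by eta_Q/eta_Vp trade-off account for the misses.

## Validation machinery

* **GOF**: PRED (eta = 0), IPRED (at the mode), IWRES, and CWRES.  CWRES is
  `L_i^{-1} r_i` with `L_i L_i' = C_i` taken from the same linearisation
  object the OFV uses — one code path, asserted by construction.  Under the
  true model CWRES behaves as approximately standard normal; a
  Wald–Wolfowitz runs check on its time profile flags structural misfit
  (demonstrated in the suite by collapsing the peripheral compartment).
* **VPC**: replicate simulation at the observed design; 5th/50th/95th
  percentiles per nominal-time bin; 2.5–97.5% band of each percentile.
  Bins are the exact nominal times because the study uses a common
  schedule; empty bins merge leftwards.  Simulated values below the LLOQ
  are retained by default (the data contain none) with an optional
  censoring switch.  On self-simulated data ≥ ~90% of observed percentile
  points fall inside their bands (checked at 1000 replicates).
* **Bootstrap**: subjects resampled with replacement to the original n,
  refit warm-started from the point estimates (one perturbed retry on
  failure), summarised as median and 2.5/97.5 percentiles; > 20% failures
  flags instability.  A scaled-down coverage experiment (10 subjects,
  5 samples, 50 replicates, typical values only) shows ≥ 6/7 typical values
  inside their intervals; the exact median-equals-point-estimate limit is
  checked separately on identical-subject resampling.

## Exposure simulation

Monte Carlo cohorts of 1000 virtual subjects per dosing arm (200 µg/kg,
18 mg, 36 mg): sex ~ Bernoulli(0.57), weight ~ normal(64, 11) truncated to
[51, 135] kg, parameters with IIV and the sex effect, residual error off
(exposure describes the model-predicted profile).  Demographic and
random-effect draws are shared across arms, making dose-linearity
comparisons exactly paired.  Profiles are evaluated on a dense 0–168 h grid
(0.25 h steps through absorption, hourly after), and summarised
noncompartmentally: Cmax/Tmax from the grid, AUC0–t by linear-up/log-down
trapezoid to the last concentration ≥ LLOQ (0.1 ng/mL; with typical
parameters the 168-h concentration is ~2–4 ng/mL, so AUC0–t ≈ AUC0–168h),
AUC0–inf by terminal log-linear regression with an adjusted-R²-maximising
tail of ≥3 points after Tmax.

Against the published medians, the simulated fixed-dose arms agree within a
few percent and the per-kg arm within ~10%; the per-kg offset is the
expected signature of the unreported weight distribution and reference
weight, and the full-block IIV correlations (not published) are a further
unquantifiable difference.

## Synthetic cohorts

The default cohort reproduces the study design: 56 subjects, 57% male, 57%
LF-infected, ages 18–66, weights as above, 200 µg/kg dosing, sampling
pre-dose and at 1, 2, 3, 4, 6, 8, 12, 24, 36, 48, 72, 168 h, LLOQ
0.1 ng/mL, and 4 subjects missing the 168-h sample — 56×13 − 4 = 724 sample
records, of which the 56 pre-dose rows are MDV=1 anchors and 668 (minus any
below-LLOQ draws) are fit-eligible.  ALT/AST/serum creatinine are drawn
uniformly within the reported ranges purely as null covariates for
selection experiments.  An external-validation preset (25 subjects, 0–72 h
schedule) is built in.

Negative observed concentrations (possible near the LLOQ under additive
error) are re-drawn rather than truncated, preserving the error model's
scale; the re-draw count is recorded on the dataset.  At study-like
parameters re-draws are ~4% of samples, essentially all at the 1-h sample
where the prediction is comparable to the additive SD.  What the generator
does **not** emulate: assay batch effects, dosing-time or food-intake
variability, correlated IIV (no published correlations), BLQ-rich designs,
or dropout beyond the missed final visit — so passing tests demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to real-data pathologies.

## Problem sizes in the test suite

Estimation-heavy checks run at sizes chosen for a single-CPU run and stated
in each test: the recovery check fits one full 56-subject cohort; the
selection-power check runs 3 replicates of the forward-step likelihood
ratio at full study size with estimation reduced to the parameters the step
compares (Vp/F typical value, its IIV, the candidate coefficient); the
bootstrap coverage check uses 10 subjects × 5 samples × 50 replicates with
typical values free and variance components fixed at truth.  The
acceptance script simulates 1000 subjects per arm and refits one 56-subject
cohort with all components free.

## Known limitations

* FOCE-I is an approximation; its error is bounded in tests only on low-
  dimensional toys.  No SAEM/Bayesian estimation, no Laplace beyond FOCE-I.
* CV% uses the plain inverse Hessian, not a sandwich estimator, and the
  commercial tool used for the original analysis does not document its
  covariance step — published CV% values are context, not targets.
* Single-dose oral regimens only (superposition of additional oral doses is
  supported by the solver but untested against data); no BLQ likelihood
  methods (M3), no inter-occasion variability, no transit-compartment
  absorption, no saturable elimination.
* The published male typical Vp/F (200.4 L) differs by ~1% from
  424.33·exp(−0.74) = 202.5 L, consistent with an unrounded coefficient
  near −0.75; the package stores both the equation and the printed value
  and does not force either.
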