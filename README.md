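# ivmpk — population pharmacokinetics of single-dose oral ivermectin

Ivermectin is a cornerstone of mass drug administration (MDA) against
lymphatic filariasis, dosed at 200 µg/kg as part of the
ivermectin + diethylcarbamazine + albendazole (IDA) triple therapy.  Its
exposure varies several-fold between adults, which matters both for
efficacy against microfilariae and for the practical question of whether a
fixed tablet dose (18 or 36 mg) could replace weight-based dosing in the
field.  `ivmpk` is a complete, tested implementation of the population
pharmacokinetic (PopPK) analysis behind those questions, aimed at
pharmacometricians who want a transparent, scriptable alternative to
commercial NLME tools for this model family.

## The model

Plasma concentration after an oral dose follows a two-compartment
disposition model with linear elimination and a mixed absorption process:
after a lag *T*<sub>lag</sub>, the dose enters the absorption compartment at
a zero-order rate for *T*<sub>k0</sub> hours while first-order absorption
*K*<sub>a</sub> transfers it onward.  All parameters are apparent
(bioavailability-scaled).  Individual parameters are

  *P*<sub>i</sub> = *θ*<sub>P</sub> · (WT<sub>i</sub>/WT<sub>ref</sub>)<sup>k</sup> · e<sup>Cov·E·cat</sup> · e<sup>η<sub>P,i</sub></sup>

with fixed allometric exponents (k = 0.75 for CL/F and Q/F, 1 for
V<sub>c</sub>/F and V<sub>p</sub>/F), log-normal between-subject variability
η, and a combined additive + proportional residual error.  The final
covariate model contains a single effect — sex on the peripheral volume,
V<sub>p</sub>/F<sub>i</sub> = 424.3 · e<sup>−0.74·SEX</sup> — i.e. roughly
half the peripheral volume in men.  Estimation is by the first-order
conditional method with interaction (FOCE-I); model building uses ΔOFV
likelihood-ratio thresholds (6.635 forward, 10.828 backward); validation
uses goodness-of-fit residuals (CWRES), visual predictive checks, and a
nonparametric bootstrap; and dose-exposure questions are answered by Monte
Carlo simulation with noncompartmental AUC/Cmax summaries.

The linear structural system is solved exactly (tri-exponential closed form
with analytic convolution of the input window), not by a numerical ODE
integrator; a stiff integrator survives in the test suite as an independent
oracle.

Because the clinical dataset is not public, the package ships a synthetic
cohort generator that reproduces the study design (56 adults, 57% male,
weights 51–135 kg, sampling 1–168 h, LLOQ 0.1 ng/mL), so every stage —
fitting, selection, validation, simulation — runs end to end out of the
box.  See `docs/methods.md` for the full methods note.

## Worked example

Simulate the three MDA dosing regimens from the final model (1000 virtual
subjects per arm, shared random draws across arms) and summarise exposure:

```python
import ivmpk as pk

model = pk.reference_model()                 # published final estimates
cfg = pk.SimulationConfig(n_per_arm=1000, seed=2024)
metrics, summary = pk.simulate_exposure(model, cfg)
print(summary[summary.sex == "all"][["arm", "AUC0t_median", "Cmax_median"]]
      .to_string(index=False))
```

```
     arm  AUC0t_median  Cmax_median
200ug/kg   1564.942944    58.239565
    18mg   2121.786288    78.843793
    36mg   4243.572576   157.687586
```

Reading the table: the median adult receiving the weight-based 200 µg/kg
dose is predicted to see an AUC<sub>0–t</sub> of ≈ 1.57 µg·h/mL and a
C<sub>max</sub> of ≈ 58 ng/mL; a fixed 18 mg tablet gives a modestly
*higher* median exposure (≈ 2.1 µg·h/mL), and 36 mg doubles it exactly —
the model is dose-linear, and the paired draws make the 2.00 ratio exact.
That pattern (fixed dose ≥ weight-based dose in the median adult, linear
scaling) is the quantitative case for fixed-dose MDA rounds.

Fit the model to a synthetic cohort and inspect recovery:

```python
truth = pk.reference_model()
data = pk.generate_dataset(pk.CohortSpec(seed=123), truth)   # 56 subjects
fit = pk.fit_population(truth, data, pk.FitOptions(maxiter=100))
print(round(fit.estimates.theta[0], 2), "L/h")               # CL/F
```

which prints `7.4 L/h` for this seed — the generating value is 7.02 L/h,
and recovery within ±15% is part of the acceptance checks.

A command-line interface mirrors the library
(`ivmpk generate | fit | select-covariates | vpc | bootstrap | simulate`);
run `ivmpk --help`.

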