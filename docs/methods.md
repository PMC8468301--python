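# Methods

This note documents the models, algorithms, parameter choices and numerical
details behind `ifxmipd`, and what the synthetic-data experiments do and do
not demonstrate.

## Pharmacokinetic model family

All supported models are linear mammillary models with zero-order IV-infusion
input and first-order elimination — one or two disposition compartments.
Infliximab kinetics in the therapeutic range are adequately linear, so
target-mediated (nonlinear) elimination is deliberately out of scope, as are
absorption compartments.

Individual parameters are built multiplicatively:

    P_i(t) = P_pop · Π_k m_k(cov_k(t)) · exp(η_P) · [exp(κ_occ) for CL]

with covariate multipliers `m_k` of five forms: power (allometric scaling and
similar, `(cov/ref)^θ`), proportional (`1 + θ·(cov − ref)`), exponential,
binary multiplier (the standard handling of ADA positivity on clearance), and
a piecewise-in-time multiplier that approximates published "time-varying
clearance / risk of immunization" components by a step at a configurable
onset time. η is multivariate normal with covariance Ω (log scale, so
parameters stay positive); κ is a per-dosing-interval normal perturbation of
CL with variance π². Residual error is the combined model
`y = f·(1+ε_p) + ε_a`.

Typical values may be declared per day and are converted to hours on load;
everything internal is hours/mg/L, making central concentrations mg/L ≡ µg/mL.

### Exact piecewise propagation

Within any span where parameters and the total infusion rate are constant,
the two-compartment amount vector obeys `A' = MA + b` with a 2×2 disposition
matrix `M` whose eigenvalues are real, negative and (off a measure-zero
parameter set) distinct. The engine advances the state with the analytic
spectral form of `e^{Mτ}` and the particular solution `−M⁻¹b`, splitting time
at dose starts/stops, covariate breakpoints and occasion boundaries, and
carrying the amounts in both compartments across each breakpoint. This is
exact (verified against adaptive ODE integration to < 10⁻⁶ relative error)
and, because every operation is element-wise, vectorizes over whole batches
of parameter sets — which is what makes 500–1000 VPC replicates cheap. A
repeated-eigenvalue guard nudges the discriminant by 10⁻¹² relative; the
affected parameter set (k12 = 0 with k10 = k21) cannot arise from a validated
model. Negative simulated concentrations are truncated at zero.

Covariate breakpoints are placed at covariate measurement times; how the
original NONMEM analyses handled mid-interval covariate changes is not
documented, and this is the natural convention.

## MAP estimation and forecasting

The anchor concentration is each patient's first retained sample. The MAP
objective with η–ε interaction is

    OFV(η, κ) = Σ_j [(y_j − f_j)²/g_j² + ln g_j²] + ηᵀΩ⁻¹η + Σ_occ κ²/π²,
    g_j² = σ_add² + σ_prop²·f_j²,

where `f_j` is the individual prediction. The `ln g²` term is kept even for a
purely additive error model (a constant offset that does not move the
optimum). Only the κ of the occasion containing the anchor is estimated —
with a single observation no other occasion is informed; other occasions'
κ are fixed at zero.

Minimisation is multi-start local search: the prior mode (all zeros) plus
four starts drawn from the prior (scaled 0.7, fixed substream), each refined
by L-BFGS-B with finite-difference gradients, `ftol 1e-8`. The reported
estimate never exceeds the prior-mode objective (the zero start guarantees
it). On a two-parameter toy problem the optimum matches an exhaustive grid
search at 10⁻³ resolution; under vanishing Ω the estimate collapses to zero;
on 200 simulated rich-sampling patients the regression of estimated on true
η_CL has slope ≈ 0.8 (the familiar empirical-Bayes shrinkage) with median
bias ≈ 0.

For prediction, κ is set to zero ("IOV in, IOV out"): an occasion-specific
clearance shift must not be extrapolated to future occasions. Covariate
policy `locf_at_anchor` freezes every covariate — including derived ADA
positivity — at its last value at or before the anchor; policy `full` uses
the measured time courses, which is the variant that lets a continuous-ADA
model benefit from later ADA measurements. A patient with no ADA measurement
(yet) counts as ADA-negative.

## Evaluation layer

ζ and SSPB follow Morley's definitions on the log accuracy ratio
`ln(y/x)`; both are scale-invariant, ζ is invariant and SSPB antisymmetric
under swapping observation and prediction, and `ζ ≥ |SSPB|` since
`median|z| ≥ |median z|`. Pairs with a non-positive member are dropped with a
logged warning rather than failing a batch. Strata: predictions of
ADA-negative patients are split at 30 and 183 days after the anchor ("1
month", "6 months" — calendar-month lengths are a convention choice);
ADA-positive patients' predictions are split relative to their first
ADA-positive sample (before; within 30 days; later). `all_pred` pools
everything except the anchor record, which is kept separately (`cmap`).

Dose-escalation classification uses the 5 µg/mL trough target with
"escalation needed" (trough < target) as the positive class; the boundary
value 5.0 counts as "no escalation" on both axes. Accuracy is
`(TP+TN)/total`, reported to one decimal.

## pvcVPC

Each replicate redraws η per patient, κ per occasion and ε per sample at the
study's exact dosing, covariate and sampling design; the typical prediction
PRED (all random effects zero) is computed once per observation. Within
quantile bins of time after the most recent dose (8 bins by default; bins
with fewer than two observations are merged into a neighbour), each value is
prediction-corrected by `bin-median(PRED)/PRED_ij` and then
variability-corrected by scaling its residual from the bin-median PRED with
`bin-median(SD)/SD_ij`, where `SD_ij` is the across-replicate SD of the
prediction-corrected simulations at that observation (zero SD falls back to
prediction correction alone, logged). Percentile bands (5/50/95) of the
corrected observations are compared with the median and central 95% interval
of the same percentile across replicates. On data simulated from the model
itself the observed median falls inside the 95% CI in ≥ 6 of 8 bins (seeded,
500 replicates) — a calibration check, not a proof of correctness on real
data.

## Synthetic cohort

The generator matches *marginal* summaries of a routine-monitoring IBD
cohort; family choices where only summaries are known are the implementer's:

| quantity | distribution | calibration |
|---|---|---|
| dose | log-normal around 5.5 mg/kg (log-SD 0.105) | median 5.5, IQR 5.1–5.9 |
| dosing interval | log-normal around 8 wk (log-SD 0.08) | median 8.0, IQR 7.7–8.6 |
| weight | log-normal, median 70 kg, truncated 47–115 | IQR 59–80 |
| albumin | normal 4.35 ± 0.31 g/dL, truncated 2.53–5.08 | median 4.35 |
| CRP | log-normal median 0.29 (log-SD 1.1), truncated | IQR 0.11–0.49 |
| samples/patient | geometric (p 0.35) truncated 1–12 | median 2, range 1–12 |
| sex / CD / IMM | Bernoulli 0.48 / 0.72 / 0.16 | cohort fractions |
| ADA-positive patients | Bernoulli 0.21 | prevalence 21 % |
| ADA onset | exponential (mean 180 d) truncated to the sampling window | — |

Samples sit at interval midpoints (40–60% of the interval) or troughs
(95–99.5%), the protocol-free jitter being a design choice. ADA onset is
truncated to each patient's sampling window so that configured prevalence is
observable in the measured ADA series; after onset ADA concentrations exceed
the 6.6 U/mL positivity threshold and the generating model's binary ADA
multiplier (×1.6 on CL in the reference model) switches on. Albumin and CRP
are constant within patient — the generator does not emulate disease flares,
assay error in covariates, induction-phase kinetics, dropout, or dosing-
record errors beyond the cascade fixture. Consequently, passing tests show
the estimator and metrics behave correctly under the stated generative
assumptions; they do not certify performance on clinical data.

The reference generating model (CL 0.3 L/day, Vc 3.5 L, Q 0.1 L/day, Vp
1.5 L, allometric weight scaling, albumin power −1 on CL, ω²_CL 0.09, ω²_Vc
0.0625, π² 0.04, σ_prop 0.2, σ_add 0.05 µg/mL) is a plausible generic
monoclonal-antibody parameterization defined by this package for testing; it
is intentionally not a transcription of any published infliximab model, and
the twelve published-model stubs refuse to load until their placeholders are
transcribed from the original papers.

### Exclusion-cascade fixture

The deterministic fixture (124 patients, 400 concentrations) is engineered so
the four stages remove exactly 11 patients/33 samples (a dose without a time
stamp), 3 below-LLOQ samples, 28 implausible samples, and 8 uninformative
patients, retaining 336 concentrations from 105 patients. Because the
implausibility rule removes the *later* member of a violating pair (the
earlier sample of a patient can never be removed at that stage), the eight
uninformative patients are constructed as three whose single sample is
below the LLOQ plus five with dosing records but no concentration samples —
the only composition consistent with those per-stage counts under this rule.

## Numerical and design choices

* The implausibility scan removes the later member of each non-decreasing
  pair (≥ 7 days apart, within one dosing interval) and re-scans until no
  violation remains; a dosing interval is the half-open span between
  consecutive doses, the last one unbounded. The cascade is idempotent and
  attributes every removed record to exactly one stage.
* Randomness flows from one top-level integer seed through named substreams
  (`cohort`, `vpc-eta`, `vpc-eps`, `map-multistart`), so changing one stage's
  draw count cannot perturb another stage.
* Problem sizes in the test-suite and acceptance script — 105-patient
  cohorts, 200 recovery fits, 500 VPC replicates, 40-patient VPC cohorts —
  were chosen as the smallest sizes at which the checked statistics are
  stable across seeds.

## Known limitations

* Below-LLOQ handling is M1 (discard) only; no censored-likelihood variants.
* Population parameters are always fixed; there is no population fitting
  (FOCE/SAEM) — by design, since external evaluation uses published values.
* The piecewise-time multiplier is a coarse stand-in for continuous
  time-varying-clearance models.
* Classification metrics ignore *how far* a prediction is from the observed
  trough; a prediction of 4.9 against an observation of 5.1 counts as a
  false positive.
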