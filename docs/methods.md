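# Methods

## Model

Recurrence-free survival — time from initial surgery to the first of local
recurrence, metastatic recurrence, or a second primary breast tumour — is
modelled with an accelerated-failure-time regression on the log-time scale,

    ln T = β₀ + βᵀx + σ W,

with the error `W` standardized generalized gamma with shape κ. The family
nests the log-normal (κ = 0), Weibull (κ = 1) and exponential (κ = σ = 1),
and its hazard can rise and then fall, the shape seen for breast-cancer
recurrence. Death without recurrence from unrelated causes and loss to
follow-up are right-censoring; the composite end point does not distinguish
recurrence subtypes (an input column for the subtype is accepted and
ignored). Times are stored in days, with 365.25 days per reporting year.

The linear predictor uses: `ln(nodes + offset)` (offset 1 by default —
the log shape must admit node-negative women; every coefficient file records
the offset it assumes), `size²` and `size²·ln size` (the repeated-power-2
fractional polynomial; its stationary point `exp(−(2a+b)/(2b))` is where the
size effect reverses, ≈7 cm under the shipped coefficients), linear grade
(one ordinal coefficient) and age, binary ER status, three treatment
indicators, and ER×hormone, age×chemo, ln(nodes)×chemo interactions.
Grade and age are not centred; centring would shift only the intercept.

### Ancillary-parameter convention

The shipped coefficient table prints the two ancillary parameters as 1.698
and 0.567. The loader's default reads them directly as σ = 1.698,
κ = 0.567, because the special-case conditions attached to them (both equal
to 1 → exponential; the second equal to 0 → log-normal) only make sense on
the original scale. Since the covariate rows are exponentiated, the
alternative reading κ = ln 0.567 ≈ −0.567 cannot be excluded;
`published_coefficients(ancillary_scale="exponentiated")` provides it. None
of the package's headline computations depend on the choice.

### The missing intercept

The published model's constant was never printed, so
`published_coefficients()` has `intercept=None` and refuses absolute
prediction. Two remedies: supply an intercept, or anchor one with
`with_anchored_intercept(reference, p, horizon)`, which solves for the
constant making the reference patient's treatment-free survival equal `p` at
the horizon. The default reference is the average development-cohort
patient (56.6 years, 1.2 positive nodes, grade 2, ER-positive, 2.2 cm).
The published prognostic-index cut points (6.42/7.59/8.32/8.86) are shipped
as metadata only: without the true constant and the original data they are
not recomputable, and indices computed under an anchored intercept are on a
shifted scale relative to them.

## Estimation

The censored log-likelihood Σ_events ln f + Σ_censored ln S is maximized
over (β₀, β, ln σ, κ) — (β₀, β, ln σ) for the log-normal and log-logistic
candidates, the latter with S(t) = 1/(1 + (t/e^μ)^{1/σ}). Optimization is
BFGS from a log-normal moment start (up to three jittered restarts — the
generalized-gamma likelihood can be multimodal in κ), followed by damped
Newton steps with numerical gradient and Hessian: the κ direction is nearly
flat and quasi-Newton alone stalls there. Convergence is declared at Newton
decrement < 1e-6; a decrement above 1e-2 raises. The gamma log-density is
evaluated in the rearrangement `ln|κ| + A(γ) − γ(expm1(κz) − κz)` with
`A(γ) = γ ln γ − ln Γ(γ) − γ` (Stirling series above γ = 1e7), which is
stable through κ → 0; below |κ| = 1e-7 the log-normal branch is used, a
switch continuous to well under 1e-6. Standard errors come from the inverse
numerical Hessian; AIC = 2k − 2 ln L with k counting all free parameters.
Family selection fits all three candidates and takes the smallest AIC, ties
within 2 broken deterministically gamma > log-normal > log-logistic and
flagged.

Fractional-polynomial search for one covariate scans FP1 and FP2 over powers
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (power 0 = ln; a repeated power p gives x^p
and x^p·ln x) and applies the standard closed test at α = 0.05: best FP2
against the covariate-free model (4 df), against linear (3 df), then against
best FP1 (2 df), stopping at the first non-significant step. Deviance
differences are referred to central χ² distributions.

## Multiple imputation

Missing ER status (and treatment indicators, if missing) are imputed by
chained equations: each incomplete binary field gets a logistic regression on
age, ln(nodes+1), grade, size, the other indicators, the event indicator and
ln follow-up time — outcome-inclusive predictors, standard for survival MI.
Parameters are drawn from the asymptotic posterior (normal around the MLE)
before each stochastic draw, so the between-imputation variance is honest;
chains run 10 burn-in sweeps, and m = 3 completed cohorts are produced by
default. A degenerate conditional model (separation, collinearity) falls
back to a beta-binomial intercept-only draw. Per-imputation fits are pooled
by Rubin's rules on the estimation scale (β, ln σ, κ): estimates average;
total variance T = W + (1 + 1/m)B with W the mean within-fit variance and B
the between-fit sample variance.

## Prognostic indices and grouping

The prognostic index is the treatment-free linear predictor (dropping
treatment terms is algebraically identical to zeroing the indicators; the
interactions vanish either way). Without an intercept the centred index is
returned — rankings and groupings are unaffected. The NPI comparator is
node stage (1 for 0 nodes, 2 for 1–3, 3 for ≥4) + grade + 0.2·size(cm).
Group intervals are closed on the upper end for both indices.

Cox's information loss `L = Σ_g (n_g/n)·Var_g / Var_total` uses population
(divide-by-n) variances so that L ∈ [0, 1] exactly and is invariant to
affine rescaling of the index. Empirical optimal grouping is exact dynamic
programming over boundaries between sorted observations (ties broken toward
the lexicographically smallest cut vector); for a normal index a Lloyd-style
fixed point — each cut converges to the midpoint of the adjacent group
conditional means — gives the analytic optimum, e.g. shares of 10.7 / 24.4 /
29.8 / 24.4 / 10.7 % for five groups.

## Treatment adjustment

External randomized hazard ratios act proportionally on the baseline
cumulative hazard: `S_adj(t) = S_base(t)^HR`, combined HR the product over
received treatments with the hormone-therapy HR conditional on ER status.
The shipped default table (radiotherapy 0.70, hormone 0.58/0.94 by ER,
chemotherapy 0.74) is a configurable placeholder in the spirit of the large
adjuvant-therapy meta-analyses, not a clinical recommendation; any analysis
should substitute current evidence via `TreatmentEffectTable`.

## Validation at a fixed horizon

Every patient is classified at the horizon: event by then, event-free at it
(follow-up reaching the horizon without a prior event; a censoring exactly at
the horizon counts as observed), or unobservable (censored earlier — such
women were recurrence-free when last seen). The three classes partition the
cohort. Calibration — mean predicted survival over observed Kaplan–Meier
survival at the horizon, ×100, reported rounded to integer percent with the
unrounded value retained — uses the full cohort, which forces the
censoring-aware KM estimate. Brier score (with naive s.e. = sample
s.d./√n), overall C (ties ½; DeLong-component CI, bootstrap optional) and
the grouped fit test use evaluable patients only, with the outcome treated as
binary at the horizon. The grouped test bins predicted risk into deciles,
sums (O−E)²/(E(1−E/n_g)), and uses g−2 degrees of freedom — the convention
for a model fitted to the data; groups with degenerate expected counts are
merged into a neighbour.

## Synthetic cohorts

No patient-level data accompany the published model, so the generator
emulates a UK hospital series: age truncated-normal (mean 56.6, sd 11,
bounds 25–92), node count zero-inflated negative binomial (mean 1.2, 55%
structural zeros, dispersion 0.9), size log-normal (median 2.2 cm, log-sd
0.45, clipped to 0.2–10 cm), grade categorical (0.22/0.46/0.32, mode 2), ER
positive with probability 0.75. Nodes, size and grade share a Gaussian
copula with equicorrelation 0.3 — the real joint distribution is
unpublished, so this severity correlation is an explicit non-estimated knob.
Event times are drawn from the generalized-gamma AFT model at each woman's
full linear predictor, the true coefficient set defaulting to the published
time ratios with an intercept anchored so the average patient's 5-year
baseline recurrence-free probability is 0.70 (a fixture choice). Treatment
assignment is confounded by indication when enabled: chemotherapy
probability rises as the prognostic index falls (log-odds slope 1.5),
reproducing the bias that motivates external treatment effects; hormone
therapy tracks ER status. Censoring combines other-cause death (exponential,
0.010/year), loss to follow-up (8% of women, uniform over 0.5–18 years) and
staggered administrative end of follow-up (uniform 6–22 years); these
defaults yield an observed event fraction near 31%, the rate of the
development series. ER missingness can be MCAR or MAR (older women — the
pre-screening era proxy — missing more).

What the generator does not emulate: registry data-quality artefacts
(under-staging, assay changeover between ligand-binding and
immunohistochemical ER), competing-risk structure beyond independent
censoring, calendar-time trends in treatment, and the true covariate
correlations. Passing self-consistency tests therefore demonstrates
internal correctness of estimation and validation, not transportability to
real cohorts.

## Problem sizes used by the test suite

Parameter-recovery coverage uses 50 replicates of n = 2000; family-selection
and transform-selection simulations use n = 3000 and n = 1200 over small seed
panels with majority criteria (each closed-test stage has ~5% type-I error
per draw); the self-consistency calibration check uses one n = 5000 cohort;
the grouped-test type-I-error study uses 1000 replicates of n = 400 with a
logistic model refitted per replicate, matching the g−2 degrees-of-freedom
convention. Exact-equivalence checks against brute-force oracles run on
cohorts of at most 25 patients.

## Known limitations

* The intercept and therefore the published index cut points are not
  recoverable; anchored predictions are calibrated by construction at the
  anchor point only.
* The C statistic is the binary-outcome AUC at the horizon among evaluable
  patients, not a time-dependent or IPCW concordance; the Brier score is
  likewise unweighted, mirroring the evaluable-patients convention.
* Treatment adjustment assumes proportional hazards of the external effects
  over the generalized-gamma baseline.
* The imputation engine covers binary fields (ER, treatment indicators);
  continuous prognostic factors are assumed complete.
* Simulation draws event times from the gamma family only — the family the
  shipped coefficients belong to.
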