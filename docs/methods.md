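# Methods

## Index definitions and numerical choices

All indices operate on a participant's time-ordered FBG series (times in
days, values in mmol/L, at least three visits after filtering; two
suffice mathematically for every index except the trivial mean).

**SD** uses the sample (n−1) denominator throughout — the usual
convention for between-visit variability; the population (n) variant
would shrink every SD-derived index by the same factor and change no
ranking.

**VIM** requires a cohort-level calibration: the exponent β is the OLS
slope of ln(SD) on ln(mean) across participants with SD > 0.
Participants with SD = 0 cannot enter the log-log fit and are assigned
VIM = 0 (a constant trajectory has no variability on any scale). When
fewer than two participants have positive SD the calibration is
undefined; `compute_all_indices` then returns a NaN calibration and
VIM = 0 for the constant participants rather than failing, so degenerate
toy cohorts still flow through the pipeline.

**ARV** is the mean absolute successive difference in mmol/L. Because
cohort reports conventionally tabulate ARV on a percent scale, a
normalized variant (`arv_pct` = 100·ARV/mean) is computed alongside and
is the default term in the model grid; both columns are always present.

**Cumulative FBG load** is the area of the piecewise-linear interpolant
in excess of the glycemic threshold (default 5.6 mmol/L, the prediabetes
cut-off), divided by the total area under the curve, times 100.
Threshold crossings are solved analytically on each linear segment, so
the integral is exact for the interpolant — no quadrature error — and a
dense-grid Riemann oracle agrees to 1e-6 relative error in tests.
Integration runs over each participant's own [first, last] visit window;
there is no extrapolation. The ratio lies in [0, 100) because the curve
is positive. An alternative reading of the numerator — the area under
the curve itself restricted to supra-threshold sub-intervals rather than
the excess above the threshold line — is available via
`excess_area=False`; the excess-area reading is the default because it
is the one consistent with the cumulative-burden literature and with
the magnitude of published cohort values (a group with mean FBG
~8.5 mmol/L has a load near (8.5−5.6)/8.5 ≈ 34%, matching the excess
reading).

A monotonicity caveat worth recording: the load *ratio* is not monotone
in a single visit value. Raising a sub-threshold value inflates the
denominator integral without touching the numerator, so the load can
decrease. The monotone quantities are the excess-area numerator
(always), and the ratio once the entire curve sits at or above
threshold; the tests assert exactly these.

## Cohort handling

Eligibility mirrors a five-wave screening design with the outcome graded
at the final wave: ≥3 FBG measurements, an FBG test in the final
screening window, and a non-missing outcome, applied in that order and
logged per criterion. The final-window requirement is carried as a
per-participant boolean; real data can derive it from a
`(start, end)` day window at read time, which avoids baking calendar
dates into the library.

Imputation is deliberately simple single-value replacement, matching the
source analysis rather than best current practice: continuous covariates
get the cohort mean, 0/1-coded covariates the median of the coding
(equivalently the mode for binary variables; an exact 0.5 tie rounds
down — the tie rule must be explicit to make runs reproducible).
Observed values are never altered, and a covariate missing for everyone
is an error rather than a silent constant.

Comorbidity flags use standard clinical definitions (hypertension:
SBP ≥ 140 or DBP ≥ 90 mmHg or history or antihypertensive use;
dyslipidemia: LDL-C ≥ 3.37, HDL-C < 1.04, TC ≥ 5.18 or TG ≥ 1.7 mmol/L
or history or lipid-lowering use) with three-valued logic: any criterion
true ⇒ 1; all observed criteria false ⇒ 0; nothing observed ⇒ missing,
left for imputation. Pre-supplied flags always win over derivation.

## Models and comparison statistics

The outcome is binary, so the risk models are ordinary maximum-
likelihood logistic regressions (statsmodels Newton fits; a two-category
multinomial fit would be identical). Odds ratios use Wald 95% intervals
— cheaper than profile likelihood and the convention in cohort
reporting. Age and BMI enter linearly; BMI is part of the default
adjustment set. Per-1-SD scaling divides a predictor by its cohort
sample SD without centering, which leaves the Wald z unchanged and makes
OR_perSD = OR_perUnit^SD an exact identity (tested numerically).

The model grid holds 18 specifications: classical risk factors alone,
classical plus each of the seven indices, and ten pre-registered
combinations built around baseline FBG and the cumulative load. The
default comparison reference is classical + baseline FBG, i.e. the
question "what does a longitudinal index add beyond a snapshot?".

ΔAUC inference uses DeLong's structural-components method for correlated
ROC curves (ties weighted ½). The implementation is checked three ways:
an O(n²) pair-enumeration oracle for the point estimate, a re-derivation
of the component covariance in the tests, and frozen reference values
from R's pROC on a fixed small dataset. IDI is the difference in
discrimination slopes with the paired-difference SE combined across
cases and controls; categorical NRI uses the standard asymptotic
variance and returns both reclassification cross-tabulations. NRI
categories default to predicted risks of 5% and 15% — a conventional
three-category layout for a low-prevalence outcome — and are fully
configurable, since published analyses rarely state their cuts; results
that depend on them are exercised only on synthetic data. All p-values
are two-sided with no multiplicity correction across the grid. IDI
bootstrap CIs (optional) resample within outcome class with a seeded
generator.

Baseline-table test selection: Welch t-test by default, switching to the
Wilcoxon rank-sum when the D'Agostino–Pearson normality check rejects at
α = 0.05 in either group (only applied at group size ≥ 20, below which
the check is uninformative); chi-square without continuity correction,
switching to Fisher's exact test when any expected cell is below 5.
These switch rules are conventions, stated here because published
reports name both tests without a rule.

## The synthetic cohort

The generator emulates a middle-aged community screening cohort with
five waves over ~7.5 years (days 0, 550, 1280, 2000, 2750; attendance
0.95/0.80/0.80/0.80/0.85, at least one wave forced). Glycemia is a
three-class mixture — normoglycemic/prediabetic/diabetic at
0.55/0.35/0.10 with levels 5.15/6.00/8.00 mmol/L (between-participant SD
0.30/0.45/1.30, visit noise 0.40/0.55/1.10, drift 0/0.03/0.08 mmol/L per
year) — chosen so the cohort mean FBG sits near 5.8 mmol/L and the
overall visit-to-visit SD near 0.5, i.e. the marginals of a realistic
general-population cohort. Values are truncated below at 3.0 mmol/L
(fasting hypoglycemia below that is rare outside clinical settings).
Visit noise is independent by default; an AR(1) option exists because
real glycemia is autocorrelated, and the default is the simpler model
whose parameter-recovery behaviour is easiest to reason about.

Covariates match the target marginals (age 46.3 ± 11.4, 52% female, 29%
lower education, 81% lower income, 17.6% smoking, 21.7% drinking, 26.5%
hypertension, 57.8% dyslipidemia, BMI 24.6 ± 3.45) with mild
dependencies: smoking and drinking concentrate in men (sex-specific
rates solved to preserve the marginal), hypertension rises with age and
dyslipidemia with BMI, lower education rises with age.

The outcome is drawn from a logistic model whose linear predictor
combines the participant's *true* cumulative load (computed from their
actual generated visits) with the covariates: 0.08 log-odds per % load,
0.045/year age, −0.35 female, 0.04/kg·m⁻² BMI, 0.50 lower education,
0.25 lower income, 0.30 smoking, 0.25 drinking, 0.55 hypertension, 0.45
dyslipidemia. The intercept (−8.506) was calibrated once by root-finding
on a large simulated linear predictor so that prevalence lands near
3.1%, and then frozen. Generating the outcome from the load (rather than
from a variability index) gives the model-comparison machinery a known
truth: the load model *should* win, and tests assert that ordering
rather than any particular AUC value. Alternative drivers (M-FBG, SD)
are selectable to probe the comparison in other regimes. Small default
fractions of missing outcome labels (2%) and missing covariates (2%)
exercise the filter and imputation stages.

What the generator does **not** emulate: within-participant correlation
between glycemia and covariates beyond the outcome model (a real
diabetic subgroup is older and heavier), seasonal or assay effects,
informative dropout, and any joint covariate structure beyond the mild
dependencies above. Passing tests therefore demonstrate the *machinery*
— index math, fitting, inference, ordering detection — under a known
truth, not that any particular published effect size generalises.

## Problem sizes

The test suite runs the correlation and ordering checks at the study
scale of 5,054 participants (50 seeds for the replicate-averaged
claims), coefficient recovery at n = 50,000, DeLong type-I calibration
over 1,000 null simulations at n = 150 (30 cases), and Wald coverage
over 200 replicates at n = 5,000 — sizes at which the asymptotic
approximations under test are expected to hold and the whole suite stays
fast.

## Known limitations

- Wald (not profile) intervals; sparse-outcome strata can make them
  optimistic.
- The quasi-separation guard is a coefficient-magnitude heuristic
  (|log-odds| > 50) on top of statsmodels' own detection.
- Single-value imputation understates variance by construction; it is
  implemented for fidelity to the replicated analysis, not endorsed.
- The NRI depends on category cuts that published analyses rarely
  report; cross-study NRI comparisons with this package are only
  meaningful at matched cuts.
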