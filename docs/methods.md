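# Methods

## The estimation problem

Birth weight is the strongest routine indicator of neonatal survival, and
deviations from the normal-delivery band (2500–3999 g) call for early
intervention. Where ultrasound machines and sonographers are unavailable,
the measurable proxies of foetal size at an antenatal visit are the
maternal symphysis-fundal height (FH, cm), the gestational age (GA, weeks)
and the foetal station (FS, the head's position relative to the ischial
spines). This package implements weight prediction from those inputs, plus
the statistical machinery used to develop and rank such predictors.

## Growth-standard imputation

Foetal head circumference (HC) and abdominal circumference (AC) are the
two most informative biometric predictors of weight, but they require
ultrasound. The package substitutes population growth standards: curves
mapping GA to the median HC or AC (millimetres). Three published standards
are registered — Australian (valid 11–41 wk), UK (13–42 wk) and the
INTERGROWTH-21st international standard (14–42 wk).

The international curves are the published closed forms
(HC = −28.2849 + 1.69267·GA² − 0.397485·GA²·ln GA;
AC = −81.3243 + 11.6772·GA − 0.000561865·GA³). The Australian and UK
curves are quadratic representations fitted once to the published chart
medians and frozen into `data/growth_standards.yaml`; they reproduce the
charts to a few millimetres over 14–40 weeks and are monotone through
42 weeks. Because they are reconstructions rather than transcriptions of
the original regression tables, downstream statistics that depend on the
fine shape of the curves (the HC reliability ICC, the imputed-design VIF)
should be read as close approximations of what the original formula sets
give, not as exact reproductions.

Units: all curve outputs are canonical millimetres; centimetre display is
a formatting concern. GA is decimal weeks; integer "completed weeks"
inputs are taken verbatim (no +0.5 adjustment), matching how registers
record GA.

## Weight models

The four proposed models (see the README table) are linear in FH, with
GA, imputed HC or imputed AC as a second predictor. The imputation uses
the Australian standard by default, since it correlates best with
neonatal measurements in the target population; the standard is
selectable per call. Predictions are delivery-weight estimates at the
measurement GA — no growth extrapolation is applied between measurement
and birth (the intended use is measurement at or very near delivery).

Comparators are transcribed into `data/weight_formulas.yaml` with their
source units explicit. Johnson-Toshach uses a two-level station category
(above vs at/below the ischial spines) selecting the subtractor (12 vs
11); a missing station is an error, never silently defaulted, because
station assessment is subjective and the choice changes the estimate by
155 g. Ultrasonic comparators (Hadlock 1984, Stirnemann, ...) accept
recorded ultrasound HC/AC when present and otherwise fall back to the
GA-imputed values — the only way such formulas can run in an
ultrasound-free setting. Entries whose original coefficient tables could
not be obtained are approximate reconstructions consistent with published
accuracy comparisons and are marked `provenance: reconstructed`; exact
agreement with the original publications should not be assumed for those.

## Reliability screen

Whether the three growth standards can be used interchangeably is decided
by treating them as three raters scoring the same GA values and computing
the single-rating, consistency, two-way random-effects intraclass
correlation ICC(C,1) from the two-way ANOVA mean squares. The consistency
form deliberately ignores rater-specific constant offsets (a standard
whose curve is uniformly 5 mm higher is still perfectly consistent);
ICC(A,1), which penalises offsets, is provided but not the default.
Ratings grids with missing cells are rejected rather than imputed. On a
synthetic GA sample matching the cohort (truncated normal, mean 38.6, SD
1.5, on [32, 41] weeks, n = 127), the three standards' ICC is ≈ 0.94 for
HC and ≈ 0.999 for AC — the "excellent reliability" regime in the
conventional ICC interpretation bands.

## Model selection

Development regresses the *recorded* midwife EFW (not birth weight) on
candidate predictors; validation then scores predictions against actual
birth weight (ABW). This asymmetry is deliberate and preserved: the
recorded EFW is the quantity available during pregnancy, while ABW is the
ground truth only obtainable at delivery.

`best_subsets` fits every non-empty subset up to `max_size` (exhaustive,
capped at 15 candidates) and ranks: subsets flagged for severe
multicollinearity last, then minimal residual SD *S*, then Mallows Cp
closest to the parameter count, then fewer predictors. VIF thresholds are
the conventional warn > 10 and hard-exclude > 100, both configurable. The
Cp reference model uses all candidates minus any perfectly collinear
columns; with quadratic growth curves, GA together with *both* imputed
circumferences is exactly rank deficient, so such subsets are skipped
while the (FH, HC_est, AC_est) design — near-collinear, max VIF in the
hundreds — is fitted and flagged excluded. This reproduces the screen
that rejects the three-predictor imputed model.

Residual normality uses the Anderson–Darling test (Shapiro–Wilk
available). With n ≈ 90 training records, statistically significant
non-normality of gram-scale residuals is expected and is reported, not
fatal. Significance annotations use the 0.0005 / 0.05 / 0.1 tiers.

## Validation protocol

Records are assigned to training independently with probability 0.7
(Bernoulli split, seeded; realized sizes are logged, and degenerate
splits warn rather than fail). Accuracy metrics follow the conventions:

- MPE = mean(ABW − EFW), grams, signed: positive = under-prediction;
- MAPE = mean |100·(ABW − EFW)/ABW|; MEDAPE = median of the same
  absolute percentages (robust to the occasional extreme error);
- within-10%: fraction with |ABW − EFW| ≤ 0.10·ABW, boundary inclusive;
- Welch's t (unequal variances) compares predicted and actual weights;
  the pooled-variance form is available by flag.

Medians interpolate the two central order statistics for even n. Each
model is scored on the test records satisfying its own predictors
(complete-case per model, each report carrying its own n), since formulas
with different inputs are being compared on the same test set. GA
stratification uses completed weeks (floor), reported for weeks 35–41.
The per-model error-normality p-value is reported per model; pooling
across a model family is not attempted.

## Synthetic cohort generator

The generator emulates a term pregnancy register from a primary health
care centre:

- FH ~ truncated normal(32.2, 2.4) on [27, 36] cm; GA ~ truncated
  normal(38.6, 1.5) on [32, 41] wk, coupled by a Gaussian copula
  (ρ = 0.3, configurable) so FH and GA are mildly positively related.
- Recorded EFW = −1538.3 + 150.3·FH + ε₁, with σ(ε₁) from the closed form
  σ = |b|·SD(FH)·√(1/r² − 1) so corr(FH, EFW_r) = 0.952.
- ABW = EFW_r + shift + ε₂, redrawn into [2600, 4000) g, with σ(ε₂)
  targeted at corr(FH, ABW) = 0.795 and the shift recentring the cohort
  mean to 3252.8 g. Because the band truncation attenuates both the
  correlation and the mean, the closed-form σ(ε₂) and shift are refined
  by a short deterministic Monte-Carlo loop (fixed child seed, 40 000
  draws, 3 iterations) inside `generate_cohort`; cohorts remain
  byte-identical under a fixed seed. Setting `abw_mean=None` skips the
  recentring, leaving ABW exactly centred on the FH backbone (useful when
  exact unbiasedness of the backbone model is the property under study —
  the printed cohort mean and exact backbone unbiasedness differ by
  ~19 g and cannot both hold).
- Maternal covariates are independent truncated normals at their
  marginals; BMI is derived from height and weight. Neonatal HC/AC are
  drawn marginally with only weak GA-linked correlation (ρ = 0.2 / 0.08),
  mirroring the weak interclass correlation between imputed and neonatal
  circumferences. Foetal station is engaged with probability 0.7 at term.
- `GeneratorConfig.register_mix()` injects an ineligible fraction
  (default 19/146) with defects in the ratio 3:2:6:8 — missing core
  fields, GA > 41 wk, complication referral, abnormal birth weight —
  and `apply_eligibility` removes them with one reason each, first
  matching rule wins.

What the generator does **not** emulate: measurement rounding (registers
record FH and GA as integers; the generator keeps them continuous),
heteroscedastic midwife error, preterm/macrosomic outcome processes, the
exact joint distribution of all covariates (only the FH-driven structure
is calibrated), and any secular or operator effects. Tests passing on
this process therefore demonstrate the correctness of the statistical
machinery and the internal consistency of the published coefficients —
not clinical performance on real registers, which can only be assessed
prospectively.

The generator's calibration anchors corr(FH, EFW_r) = 0.952 rather than
the reported development-set R² band of 0.883–0.888; in a one-predictor
Gaussian model the two imply different noise levels (0.952² ≈ 0.906) and
cannot both hold, and the correlation is the better-attested anchor.

## Problem sizes and numerical choices

Default analyses use cohorts of n = 10 000 (correlation and VIF checks),
n = 20 000 (coefficient recovery, where the FH slope's Monte-Carlo SE is
≈ 0.35 g/cm) and 100 replicates of n = 127 for the ICC screen — sizes at
which Monte-Carlo error is comfortably inside the comparison tolerances
while everything runs in seconds. Exact collinearity is detected by rank
computation, reported as named columns in errors and as +inf in VIF
output. Predictions carry full floating precision internally; report
tables round to 0.01.
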