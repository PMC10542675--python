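# Methods

## Risk scoring

Each of the nine behaviour domains is classified low / medium / high from
raw survey answers using established clinical cut points (see the table in
`drisk.scoring`).  Conventions worth stating explicitly:

- **BMI** is weight(kg)/height(m)²; bands are half-open — low [18, 25),
  medium [25, 30) or below 18, high [30, ∞) — so printed bounds such as
  "24.9" leave no gap for values like 24.95.
- **Alcohol** is high above 14 standard drinks/week; within that weekly
  limit it is medium when more than 2 standard drinks are taken on an
  occasion, and low otherwise (or for abstainers).  A missing
  per-occasion answer with a within-limit weekly total is 'unknown',
  because the low/medium split cannot be resolved.
- **MIND diet** adherence sums 14 scoreable components (wine excluded),
  each 0 / 0.5 / 1, giving the 0–14 range; low ≥ 12, medium [7.5, 12),
  high < 7.5.
- **Physical activity** uses weekly MET-minutes with intensity weights
  3.3 (light), 4 (moderate), 8 (vigorous); ≥ 600 is sufficient.  This and
  cognitive activity (11 frequency codes 0–5, sufficient at a sum of 33,
  anchored at 'several times a month' = 3) are two-level domains: low or
  high only.
- **Cardiometabolic management** (applied identically to hypertension,
  cholesterol, diabetes): low = no diagnosis with regular check-ups or a
  medically managed diagnosis; medium = unsure-but-checked or
  diagnosed-checked-working-toward; high = diagnosed without check-ups or
  management, or no diagnosis and no check-ups.  Combinations that cannot
  be resolved because an input is missing are 'unknown'.

Domain weights (low 0, medium 0.5, high 1) sum to the DRP total in
[0, 9].  Any unknown domain leaves the total undefined for that
observation; such rows are excluded from continuous-outcome models but
their known domains still enter the categorical analyses.

## Instruments

KoDeRR subscales are correct-answer counts; MCHLB-DRR dimensions are item
sums.  Item structure is configuration, not code, because the published
ranges pin down bounds but not items: defaults use susceptibility 5 × 1–4,
severity 6 × 1–4, benefits/barriers/cues/general-health 5 × 1–4, and
self-efficacy 2 × 1–5.  The severity default tops out at 24 inside its
declared 6–25 bound — no integer item scheme of six items can reach 25 —
and the default item counts total 33; both follow from honouring the
published per-dimension ranges, which take precedence here over the
instrument's published total item count.  Incomplete dimensions score as
missing; no prorating rule is applied.

## Panel assembly

Time in study is the whole-month difference from the baseline survey
(first risk-report exposure), entering models as log(months + 1) (natural
log).  The report is released immediately after each completed survey, so
the exposure count attached to a wave's outcome is the number of completed
waves *before* that wave: baseline rows carry 0, and a participant with
baseline plus only the final annual survey has one exposure at that final
row.  A skipped intermediate wave simply contributes no exposure (count of
completed prior waves).  Course engagement is a 0/1 flag from the first
wave at/after completing module 1; pre-enrolled participants are excluded
by default or, with `retain_pre_enrolled`, kept with the flag fixed at 1
from baseline.  Annual-wave eligibility requires baseline at least five
whole months before that October.

## Trajectory models

Continuous outcomes use random-intercept linear mixed models fitted by
REML (statsmodels `MixedLM`), with exposures and log-time entered jointly
(a config switch fits either alone).  Fixed-effect inference uses the
normal approximation — Satterthwaite degrees of freedom are not available
in the backend — and is labelled as such in the result object.
Standardized coefficients are b_s = b·SD(x)/SD(y) for continuous
predictors and b/SD(y) for binary ones, with SDs from the estimation
sample (the exposure×course product column uses the continuous rule).
Estimated marginal means evaluate the fixed-effect design at grid values
with remaining covariates averaged over the estimation sample; all
pairwise grid contrasts are Tukey-adjusted via the studentized-range
distribution with family size equal to the number of grid points, with no
correction across models.  Variance explained is summarised by the
Nakagawa decomposition: marginal R² = var(Xβ)/(var(Xβ)+σ²_u+σ²_e);
conditional adds σ²_u to the numerator.

Risk-level transitions (baseline → final wave, reference level low) use
multinomial logistic regression with baseline level and optional
demographic covariates.  When a sparse or separated cell makes the ML fit
singular, a lightly L1-penalised fit (α = 1e-3) keeps the coefficients
finite; SEs may be undefined for the affected terms and surface as NaN
CIs.  By default "final" is the latest annual wave; a flag substitutes
each participant's own last available wave.

## Mediation

Variables are z-scored on the analysis sample, so paths are in SD units.
The half-longitudinal design regresses M_fu ~ X + M_bl (a) and
Y_fu ~ X + M_fu + Y_bl (b, c′); each follow-up outcome is adjusted for its
own baseline, and M_bl is deliberately not added to the Y-model (a config
flag includes it).  The indirect effect is a·b; the total effect is
defined by the path decomposition c = c′ + a·b, as in SEM software; the
separately regressed total (Y_fu ~ X + Y_bl) is reported alongside as
`c_marginal` — the two agree exactly only when X and M_bl are orthogonal,
because the M-model conditions on M_bl while the marginal regression does
not.  The proportion mediated a·b/(a·b + c′) is reported in percent and
flagged (not silently reported) under inconsistent mediation, i.e. when
the direct and indirect effects oppose and |a·b| exceeds |c|.

Inference is a nonparametric case bootstrap (default 5000 resamples;
percentile CIs; SE = bootstrap SD).  Failing resamples (e.g. a constant
column) are redrawn and counted.  Under the `em_normal` missing-data
policy the five-variable mean and covariance are estimated by EM under
multivariate normality — a computational route to the same ML estimates
that full-information likelihood targets — and paths derive from the
estimated correlation matrix; with no missing data this reproduces the
complete-case coefficients exactly, and the bootstrap re-runs EM per
resample.

Global fit compares the recursive path model (saturated exogenous block;
two omitted paths and an omitted residual covariance give df = 2) with
the saturated and independence models through the ML discrepancy
χ² = n·(ln|Σ̂| + tr(SΣ̂⁻¹) − ln|S| − p).  CFI and RMSEA use the standard
noncentrality forms; the RMSEA 90% CI inverts the noncentral-χ²
distribution (Brent root-finding on the CDF).

## Synthetic cohort generator

The generator emulates a rolling-baseline online cohort aged 50+:
enrolment dates decay exponentially across the Oct-2019..Jun-2022 window
(time constant 5 months), annual October follow-ups are offered to
participants whose baseline is at least five months old, and per-wave
response rates (0.82 / 0.70 / 0.985) were chosen so expected wave sizes
match the published cohort's wave sizes given the eligibility structure.
Demographics, the course-engagement rate (0.588), and the baseline DRP
mean (2.17) are anchored to published descriptives.

Each observation's DRP total is generated latent-continuous-then-
categorical:

1. A latent total follows the linear mixed model with configured raw-scale
   effects (defaults: exposure −0.05, time −0.10 per log-month, course
   −0.10, interaction −0.04; person SD 0.95, residual SD 0.70).  To keep
   the conditional mean exactly on the linear predictor despite the [0, 9]
   bounds, person effects are symmetric truncated normals and the residual
   is truncated symmetrically to the distance from the nearer bound
   (variance shrinks near the bounds; the mean does not move).  Only
   conditional means below 0 — about 2% of observations under the
   defaults — are floored, the one place a small attenuation can enter.
2. The latent value is stochastically rounded to the 0.5 grid
   (mean-preserving) and decomposed into nine domain levels by weighted
   escalation, with propensities anchored to the published baseline level
   proportions so domain marginals are realistic.
3. Raw survey responses are drawn uniformly within the response region of
   each assigned level (with safety margins at cut points against
   reporting-precision rounding), so scoring the generated tables
   reproduces the assigned levels exactly — the scoring round-trip the
   tests rely on.

Knowledge (misconception discernment) carries the mediation wiring: course
engagement shifts knowledge by `a` (0.41 knowledge-SD) and knowledge feeds
into the DRP by `b` (−0.05 outcome-SD per knowledge-SD); the generator
nets the implied a·b and slope feed-through out of the course and exposure
coefficients so the configured betas remain the marginal trajectory truth
while the (a, b, c′ = β_course − a·b) decomposition holds.  A companion
direct path-equation generator (`simulate_mediation_panel`) produces
five-variable datasets with exact standardized-path truth for estimator
recovery work.  Unknown codes are injected MCAR at per-domain rates taken
from the published baseline 'unknown' proportions.  Every participant
draws from a substream keyed by (seed, participant index), so enlarging a
cohort never changes earlier participants.

What the generator does *not* emulate: self-selection into the course
(engagement is independent of baseline risk, unlike the real cohort),
pandemic-era shocks, item-level instrument response processes (items are
rendered to match target subscale scores), and informative attrition.
Passing recovery tests therefore demonstrate estimator correctness under
the assumed data-generating process, not robustness to those features of
real data.

## Problem sizes and numerical choices

Recovery studies in the test suite use 200 cohorts of n = 2000 for the
trajectory estimator and 100 datasets of n = 3000 (500 bootstrap
replicates) for mediation — sizes at which Monte-Carlo noise is small
relative to the bias tolerances being asserted while the suite stays
quick.  EM convergence is declared at a max-change of 1e-8 (500-iteration
cap, error with trace on failure).  Mixed-model optimisation tries
gradient-based methods first and falls back to derivative-free search
when the group variance collapses to the boundary.  Bootstrap resampling,
cohort generation and the CLI pipeline are deterministic given seeds;
report timestamps are injectable so rendered documents compare
byte-for-byte.

## Known limitations

- Mixed-model p-values/CIs use z-inference; for small cohorts they are
  mildly anticlimactic relative to Satterthwaite/Kenward-Roger.
- The EM route handles the five observed mediation variables under joint
  normality; a binary exposure is treated as numeric, which matches the
  linear-path estimand but is not a general categorical missing-data
  model (the exposure itself is never imputed in practice since the
  default panels have it fully observed).
- Proportion mediated is unstable when the total effect is near zero;
  the inconsistent-mediation flag marks the cases where it should not be
  interpreted.
- The multinomial fallback's penalised coefficients are finite but their
  SEs can be undefined under separation; affected CIs are NaN rather than
  fabricated.
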