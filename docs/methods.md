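# Methods

## The model

The package analyzes ex vivo combinatorial drug-sensitivity screens in
which a patient sample is exposed to a predesigned array of drug-dose
combinations and the phenotypic readout is normalized cell viability
(NCV): luminescence rescaled against on-plate controls so vehicle wells
read 1 and background wells read 0. The central object is a full
second-order polynomial in coded dose levels,

    NCV(x) = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j,

where `x_i` in {0, 1, 2} codes the three tested doses of drug `i`
(absent, IC10, IC20). For 12 drugs the model has 91 terms. Regression
runs on coded levels rather than micromolar doses, so unequal dose
spacing across drugs is absorbed by the coding; an affine recoding of
levels changes coefficients but not fitted values (the model space is
identical), which the tests verify to 1e-10.

Fitting is ordinary least squares on replicate-level observations
(statsmodels OLS). No weighting or robust loss is used; with balanced
technical duplicates this is equivalent to fitting run means. A fit is
refused if the expanded basis is rank-deficient on the observed runs.

## The design

Quadratic estimability from ~155 wells comes from an orthogonal array
composite design:

* 128 runs: a resolution-IV 2^(12-5) fractional factorial at the
  extreme coded levels {0, 2}. The five generator words
  (8=1234, 9=1235, 10=1267, 11=1456, 12=3457 in letter notation over
  base factors 1-7) were selected by exhaustive search over 4-letter
  words for resolution IV with minimum aberration and are frozen as a
  documented constant.
* 27 runs: the canonical L27(3^13) orthogonal array (lexicographic
  GF(3) construction) restricted to its first 12 columns, levels
  {0, 1, 2}, each level appearing 9 times per column. The mid-level
  runs separate pure-quadratic curvature from linear effects, which the
  two-level portion alone cannot do.

The 155x91 expanded basis has full column rank with condition number
~260. `validate_design` recomputes run counts, level balance, duplicate
rows and basis rank and is the gate `fit_quadratic` points to on
failure.

## Normalization and quality control

NCV = (raw − mean_neg)/(mean_pos − mean_neg) per well, with positive
controls interpreted as vehicle-treated cells and negative controls as
background. NCV is not clipped; values outside [-0.2, 1.5] are counted
and flagged but retained, since OLS handles modest excursions and
clipping would bias the fit. Sample standard deviations (ddof=1) are
used throughout.

Assay quality: Z' = 1 − 3(sd_pos + sd_neg)/|mean_pos − mean_neg| and
SSMD = (mean_pos − mean_neg)/sqrt(var_pos + var_neg). The Z' gate
defaults to 0.5 (the conventional "excellent assay" threshold,
inclusive) and is configurable; SSMD is reported but not gated on.
Cohort accounting separates pre-assay exclusions (insufficient
material) from QC failures, and the report yield is
reported/collected.

## Enumeration, ranking and reports

A therapy is a set of 1-3 drugs; each permutation assigns its active
drugs levels in {1, 2} with every other drug at 0 (absence of drug;
the IC0 level is taken as literally zero effect). A therapy is
summarized by the mean and sample SD of its permutation predictions
(2 values for one drug, 4 for a pair, 8 for a triple); averaging only
nonzero permutations keeps orders distinct — including level 0 would
collapse a pair into its constituent single agents. Therapies are
ranked ascending by mean NCV (rank 1 = greatest predicted kill) with a
deterministic lexicographic tie-break on drug indices. The rank by
best single permutation is also exported, since "top combination"
lists can reasonably use either convention. Predictions are not
clipped; a therapy whose mean prediction is negative is flagged as
model extrapolation in reports.

Response-surface maps evaluate the fitted polynomial over [0, 2]^2 for
one pair with all other drugs at 0 (matrix export; plotting is left to
the caller). Per-sample reports are plain JSON and byte-reproducible
from the same inputs.

## Dose-response curves

Two families: the four-parameter logistic
`y = bottom + (top − bottom)/(1 + (D/ic50)^hill)` for IC50/IC10/IC20
derivation, and the median-effect line
`log10(fa/(1−fa)) = m log10 D − m log10 Dm` (fa = 1 − NCV) that
underlies combination-index analysis. The 4PL fit uses bounded
nonlinear least squares with a multi-start grid (hill in {0.5, 1, 2, 4}
crossed with IC50 at half-decades of the tested range); bounds are
bottom in [−0.1, 0.5], top in [0.5, 1.2], hill in (0.1, 10]. Flat data
raise an unidentifiability error rather than returning an arbitrary
IC50. Effect inversion uses the closed form
`D = ic50 (e/(1−e))^(1/hill)` with the effect defined on the
top-bottom span. For median-effect fits, fa values of exactly 0 or 1
carry no logit information and are excluded with a warning; interior
values are clamped to [1e-6, 1−1e-6].

## Synergy

Combination index (Chou-Talalay, mutually exclusive form): with
median-effect fits of each single agent and of the constant-ratio
combination fitted on total dose, CI(fa) = d1/Dx_A + d2/Dx_B where
(d1, d2) split the combination dose by the fixed ratio (taken from the
panel doses of the pair). CI < 1 synergy, = 1 additivity, > 1
antagonism; a self-combination yields CI = 1 identically, which serves
as an exact internal check. Non-constant-ratio designs are out of
scope.

Bliss independence: inhibition is clamped to [0, 1] (clamp counts
recorded), expected combined inhibition is iA + iB − iA·iB from the
zero-dose margins, and the summary score is the unweighted mean excess
(observed − expected, percentage points) over cells with both doses
positive. Scores > 10 classify as synergistic and < −10 as
antagonistic (strict inequalities), otherwise additive.

## Concordance statistics

Clinical responders are PR or SD under RECIST; screen-defined
responders are cases whose therapy mean NCV falls below the NCV
cutoff. ROC analysis scores by −NCV, computes AUC by the rank
(Mann-Whitney) formulation with midrank tie correction, the p-value by
the two-sided Wilcoxon-Mann-Whitney test, the AUC 95% CI by the
Hanley-McNeil approximation, and the operating cutoff as the midpoint
threshold maximizing Youden's J (ties resolved toward the smaller
cutoff — deterministic and conservative for calling responders).

The 2x2 analysis reports OR = ad/bc, a two-sided Fisher exact p by
summing hypergeometric point probabilities not exceeding the observed
table's, TPV (overall accuracy, (a+d)/N), sensitivity a/(a+c) and
specificity d/(b+d) with clinical status as truth. The OR interval is
the Woolf logit CI with Haldane +0.5 correction on zero cells; a
conditional-MLE interval is available behind `or_ci_method`. Group
comparisons use the equal-variance Student's t (two-tailed) by
default, Welch and paired variants behind flags, with zero-variance
degeneracies resolved by convention (equal means: t = 0, p = 1;
constant nonzero difference: p = 0, flagged).

In vivo helpers implement the ellipsoid tumor volume
V = pi/6 · A^2 · B (A = smallest, B = largest superficial diameter) and
the linear growth rate (last − first volume)/days.

## The synthetic-data generator

No raw screen data is publicly deposited, so every pipeline stage is
exercised against generated data with known ground truth.

Surfaces. A ground-truth surface is the quadratic model itself, so
noiseless recovery is exact by construction. Coefficients are drawn
under a total kill budget (0.95 of the viability range): planted
synergistic pairs claim their share first (interaction coefficient in
[−1.1, −1.0]·effect_scale at each planted pair — never shrunk, so the
planted-effect guarantee holds); per-drug top-dose inhibitions split
85% of the remainder by a symmetric Dirichlet draw, giving samples
uneven potency profiles; the mid-dose inhibition is 55-80% of the
top-dose value, producing saturating (positive-curvature) single-drug
profiles; non-planted interactions are uniform on ±0.01. A final exact
guard — the surface minimum over [0, 2]^F sits at a corner of
{0, 2}^F because pure-quadratic terms are convex — shrinks non-planted
interactions geometrically until the minimum clears 0.01. The budget
exists because an unconstrained 12-drug quadratic with realistic
per-drug effects dips far below zero at high-dose corners, which no
control-anchored fit to bounded viability data could produce and which
would make simulated luminescence unphysical. The cost is that
single-drug effects are smaller than a literal reading of "IC20 = 20%
inhibition" would give; the recovery tests exercise identifiability,
not absolute effect magnitude, and are insensitive to this.

Plates. Treatment wells read neg_mean + NCV·(pos_mean − neg_mean) plus
additive Gaussian noise of SD `noise_sd` (default 0.02) on the NCV
scale; control wells scatter around their means (defaults 1e6 and 1e4
arbitrary luminescence units) with the same noise; raw values truncate
at zero, which never binds on noiseless plates. Technical duplicates
(2 replicates of all 155 runs) and 8 wells per control are the
defaults. The noise magnitude is a documented guess — the protocol the
package models does not publish one — exposed as a parameter.

Cohorts. Each sample gets its own surface and plate. Treatment
outcomes pick a case and a 1-2-drug therapy with drug probability
proportional to the sample's per-drug top-dose inhibition: clinically
evaluated therapies skew toward drugs that look active, and this is
what gives outcome NCVs a realistic spread across the responder cutoff
(uniform drug choice leaves nearly all outcomes near NCV 1). The
responder probability is logistic, 1/(1 + exp(k(NCV − c))) (defaults
c = 0.8, k = 25), responders split PR/SD at random, and the responder
call flips with probability `label_noise` (default 0.05). k = inf
degenerates to a hard threshold. With these defaults the median
ROC-recovered cutoff over 200 seeded 27-outcome cohorts lies within
0.03 of c, and mean AUC increases monotonically in k.

What the generator does not emulate: tumor biology or subtype
structure, pharmacokinetics, plate-position artifacts (edge or drift
effects), dispenser errors, or non-quadratic dose-response saturation
within the design region. Passing recovery tests therefore demonstrate
correctness of the analysis pipeline under its own model assumptions,
not robustness to real-plate artifacts.

## Problem sizes and runtime choices

The test suite and the acceptance script run everything at the scale
the analysis actually uses: the full 155-run/91-term design, 100
seeded noisy screens for planted-pair recovery, 200 seeded 27-outcome
cohorts for cutoff recovery, 66-pair brute-force oracles, 99-point CI
grids and 5x5 Bliss matrices. Cohort simulations that never touch raw
luminescence skip plate generation (`with_plates=False`). The whole
suite completes in well under a minute on one CPU.

## Known limitations

* Only the 12-factor OACD is registered; other factor counts need a
  suitable fractional-factorial/orthogonal-array pairing.
* No regularized or stepwise term selection; the full 91-term model is
  always fitted.
* No dose optimization beyond the three tested levels, and no
  Loewe-surface/ZIP/HSA synergy models.
* The Youden cutoff on small cohorts is a step function of the data;
  with widely separated NCV clusters it sits at the single midpoint
  spanning the gap, so its variance is driven by the extreme cases.
* The OR confidence interval method matters for small tables: Woolf
  and conditional-MLE intervals differ noticeably at N = 27.
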