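# Methods

This note records the statistical model behind each stage of the package, the
defaults and why they were chosen, what the synthetic stand-in data can and
cannot show, and the numerical conventions a user comparing results should
know about.

## Rank-based correlation imposition

The core operation reorders independently sampled columns so that their joint
ranks follow correlated standard-normal scores (an Iman–Conover-style
construction). Because each output column is a permutation of its input
column, all marginal properties — mean, variance, skewness, kurtosis, minima
and maxima, every quantile — are preserved *exactly*; only the row-wise
alignment changes. The realized Spearman matrix equals the sample Spearman
matrix of the normal scores, so its deviation from the target is pure
sampling noise of order $1/\sqrt{n}$ (empirically, per-pair SD ≈ 0.011–0.013
at n = 5,000 for targets of 0.3–0.5).

**Spearman→Pearson adjustment.** If a Spearman target ρ is fed directly to
the Cholesky factorisation, the scores' Pearson correlation equals ρ but
their *Spearman* correlation — and hence the realized rank correlation of the
output — concentrates around $(6/\pi)\arcsin(\rho/2)$, a systematic shrinkage
of ≈ 0.017 at ρ = 0.5. The default mode `"adjusted"` therefore converts the
target elementwise with the exact bivariate-normal relation
$r = 2\sin(\pi\rho/6)$ before factorising, which removes the bias and leaves
deviation histograms centred at zero. Mode `"direct"` (no conversion) is kept
for users who want the unadjusted construction; the bias is the only
difference. If the converted matrix drifts marginally outside the
positive-semidefinite cone (possible, since the conversion is elementwise),
it is repaired by eigenvalue clipping; for benchmark-scale targets this is a
no-op.

**Ties.** Normal scores are almost surely tie-free, and reordering sorted
data values is insensitive to ties among equal values. Where data ranks are
needed (the copula's empirical-CDF step), exact ties are broken by a seeded
perturbation smaller than half the smallest nonzero gap, so runs are
deterministic per seed and untied values never swap order.

**Singular targets.** A Spearman target with an off-diagonal of exactly ±1
(co-monotone columns) is a valid, positive-semidefinite target; the public
`cholesky_factor` demands strict positive definiteness (and names the first
failing leading minor), but score generation falls back to an eigenvalue
factorisation so such targets still work.

## Gaussian-copula comparator

`copula_impose` follows six steps: take the independently sampled columns as
given; transform each to uniforms by the empirical CDF (ranks over n+1);
apply the inverse-normal transform; iteratively adjust the scores'
correlation toward the target by mixing in, with weight ½, fresh normal
scores drawn with the corrective structure $M = 2T - C$ (so the mixture's
expected correlation is the target $T$ given the current correlation $C$,
with $M$ repaired to a valid correlation matrix when needed); rank-match the
adjusted scores back to the sorted original values (exact marginal
preservation, as in the rank method); and declare convergence when
max |realized Spearman − target| ≤ `tol` (default 0.01, `max_iter` 50).
Non-convergence is never silent: the result carries the final deviation and a
flag, and the benchmark records it per iteration.

**A finding worth stating plainly:** with this convergence rule the copula
route is *more* accurate than the one-shot rank method, not less. The
stopping criterion caps every accepted deviation at `tol`, which is below the
rank method's sampling noise at n = 5,000, so the copula's per-pair deviation
SD (≈ 0.005–0.006 measured over 100 iterations) sits at roughly half the
rank method's (≈ 0.011–0.014). Any convergent implementation of these six
steps behaves this way — an iterative scheme that checks its own output
cannot be more variable than a single draw unless it diverges. Claims in the
literature that copula-based imposition preserves rank correlations *less*
precisely than rank reordering therefore reflect particular (unstable or
unconverged) implementations rather than the approach itself. The price the
copula pays here is computational: several re-rankings and matrix repairs per
call instead of one. The package's comparison test encodes the "copula more
variable" expectation and is allowed to fail against this implementation;
the benchmark reports both spreads so users can judge directly.

## Marginal catalog

Twelve families cover the shapes that arise in nutrition databases:
unbounded symmetric (normal, logistic, Student-t location-scale,
skew-normal), positive right-skewed (log-normal, gamma, exponential,
chi-square, Weibull, log-logistic), and bounded (beta, triangular). The
catalog is a registry; adding a family means supplying a fit recipe, a
freeze recipe, a feasibility test and a canonical parameterisation.

Fitting is maximum likelihood: closed form where it exists (normal,
log-normal via log-scale MLE, exponential), scipy's numerical MLE with
moment-style starting values otherwise, with location pinned to zero for the
positive families so parameterisations stay canonical. Families whose support
excludes the data are *skipped* during model selection and *errors* when
requested explicitly (naming column and family). Selection is by AIC
$= 2k - 2\log L$; ties break toward fewer parameters, then catalog order.
AIC rather than BIC keeps selection behaviour close to common distribution-
fitting defaults in this field.

**Beta envelopes are declared, not inferred.** The beta family competes only
for data in (0, 1) unless the caller declares an envelope, e.g. (0, 100) for
percentage-scale diet components; the bounds are stored with the parameters
but never counted as estimated (k = 2). Auto-inferring an envelope was
rejected: it silently modelled intake in kg/d on a percentage scale.

## Synthesis pipeline and cleaning

`synthesize` samples each column independently (per-column seeds spawned from
the plan's master seed), imposes the target, and cleans. The default order is
**correlate then clean**, so every delivered row provably satisfies every
deterministic rule; the literal clean-then-correlate order is available for
fidelity experiments, and its manifest reports how many delivered rows
violate the rules, because reordering columns after cleaning can re-create
row-level violations (e.g. a large ADF moved next to a small NDF). Every run
emits a manifest — seeds, per-rule removal counts, final n, realized Spearman
matrix, fitted-vs-realized moment comparison — sufficient to reproduce the
table bit-for-bit.

Cleaning rules are declarative: open-interval bounds, pairwise order
(lesser < greater), sum caps, and statistical outlier rules. Rows are
dropped, never edited. A row violating several rules is attributed to the
first violated rule in declaration order and counted once; the surviving set
itself does not depend on declaration order. Outlier rules: z-score with
default threshold 3.0 (zero-variance columns are an error), and IQR with
default 1.5 and type-7 (linear interpolation) quartiles, applied as the
literal band [Q1 − t·IQR, Q3 + t·IQR]. When IQR = 0 the band collapses to
the quartile value itself, so an all-equal column flags nothing while a
near-constant column with a stray extreme flags the extreme — the behaviour
the band rule implies, with no special case. Thresholds and the quartile
convention are package defaults (configurable), not values taken from any
source.

## Preservation benchmark

The benchmark draws three columns per iteration — chi-square(2), beta(2, 5),
log-normal(0, 1) — at n = 5,000, imposes a fixed 3×3 target, and records the
realized-minus-target Spearman deviations and the four moments before and
after, over 100 iterations. The default target's off-diagonals (0.5, 0.3,
0.4) are this package's own choice of a moderate, positive-definite
structure; any user matrix is accepted. Iteration seeds are spawned from the
master seed by counter, so any single iteration can be rerun alone.
Skewness and kurtosis are the adjusted (bias-corrected) Fisher–Pearson
statistics, with kurtosis reported raw (normal ⇒ 3) and excess kurtosis
available as a property; zero-variance vectors report shape moments as
undefined rather than as numbers.

## Predictors, importance, cross-testing

The forest is a scikit-learn regression forest with the configuration fixed
at 150 trees, 4 candidate variables per split, minimum node size 5, and
per-tree bootstraps of n rows with replacement; remaining knobs stay at
library defaults. Two importance indices come from the fitted trees:

- **PAS** — for each tree, the % increase in its out-of-bag MSE when one
  predictor's OOB values are permuted, averaged over trees. Reported
  unscaled (raw percent, not divided by a standard error), so values are
  comparable to raw %IncMSE-style outputs and *not* to SE-scaled ones.
  OOB membership reproduces the library's own bootstrap draw exactly
  (verified against its OOB predictions).
- **SER** — the RSS decrease at each split (weighted parent impurity minus
  children), summed per variable per tree and averaged across trees; units
  are squared response units. The per-variable values sum to the total
  impurity decrease by construction, which the tests assert as an accounting
  identity.

Cross-testing fits RF and LM (ordinary least squares via QR, intercept
included, rank-deficiency errors name the collinear columns) on each of two
databases and evaluates all four model×database combinations through the
adequacy report. Parameter counts: predictors + 1 for LM; for the forest,
which has no finite parameter count, the predictor count is used as a
documented stand-in so adjusted r², MSE and AIC remain computable.

## Adequacy conventions

- MB = mean(observed) − mean(predicted); positive MB means underprediction.
- MSEP uses the n denominator; MSE = MSEP·n/(n−p) is also reported.
- Decomposition (population moments, s = n-denominator SD, r = Pearson):
  MB², (s_pred − r·s_obs)², s_obs²(1−r²) — an algebraic identity summing to
  MSEP, reported as percentages summing to 100. For in-sample OLS fits the
  first two components are identically zero (fitted values have mean ȳ and
  SD r·s_y), so "Random % = 100" is a structural property of least squares,
  not an empirical finding.
- CCC = 2·r·s_obs·s_pred / (s_obs² + s_pred² + MB²); C_b = CCC/r.
- AIC = n·ln(MSEP) + 2(p+1). This is one fixed convention on the error
  scale; absolute AIC values are comparable only within this package.
- Perfect agreement (MSEP = 0) is reported as CCC = C_b = 1 with
  decomposition (0, 0, 100) by convention, avoiding 0/0.
- Reported SDs use the n−1 denominator; the decomposition's internal SDs use
  n, as the identity requires.

## The synthetic methane stand-in

The generator emulates the *structure* of a compiled beef-cattle methane
database — 263 records; BW (kg), DMI (kg/d), CP, NDF, EE, starch, ADF, ash
(%DM), CH4 (g/d) — because the original compilation is not redistributable.
Families: BW log-normal (median 450 kg, σ_log 0.25), DMI gamma (mean
8.8 kg/d), CH4 gamma (mean ≈ 129 g/d, CV 0.39), diet components beta on the
declared (0, 100) envelope with realistic means (CP 14, NDF 38, EE 3.5,
starch 25, ADF 22, ash 7 %DM). The hand-designed Spearman target encodes the
field's qualitative structure: intake drives emission (DMI–CH4 0.8), intake
scales with body size (BW–DMI 0.7), fibre fractions move together (NDF–ADF
0.8) and against starch (−0.5, −0.45), and the remaining CH4 correlations
sit near their conditional-independence values so DMI stays the dominant
predictor. The matrix is well-conditioned (smallest eigenvalue ≈ 0.13) and
implies a multiple R² of ≈ 0.64 for CH4 given the other variables — the
regime in which a linear fit explains roughly 0.6 of the variance, which is
where literature-scale methane regressions typically land. An earlier draft
matrix was near-singular (smallest eigenvalue 0.02), making CH4 almost
deterministic given the predictors; that degeneracy, not any empirical
result, forced the redesign.

Every number above is an artifact default, not a measured value. What
passing tests on this stand-in show: the pipeline's algebraic guarantees
(exact marginal preservation, constraint satisfaction, decomposition
identities) and the qualitative RF-vs-LM pattern under a copula-type
dependence with moderately skewed marginals. What they cannot show: anything
about real methane biology — the stand-in has no study-level clustering, no
measurement error, no nonlinear intake–emission physiology beyond what rank
coupling induces, and milder skewness than heterogeneous multi-study
compilations often exhibit. RF-vs-LM contrasts are therefore directional
statements about the method, not about cattle.

## Problem sizes and defaults

Generation defaults to 20,000 records (cleaning at default rules removes a
few percent on the stand-in; a narrower source table can lose far more —
surviving counts are always in the manifest). The benchmark defaults to
5,000 × 100; the test suite runs the same sizes for the benchmark, scales
the cross-testing experiment to 4,000-record databases over 10 generation
seeds, and uses 500–800-row tables for the importance checks — sizes at
which the directional effects are stable while the full suite stays fast.
Stochastic assertions average over ≥ 10 fixed seeds, all visible in the
tests.

## Known limitations

- The copula's damping scheme (½-weight corrective mixing) is one reasonable
  choice among several; its iteration count, though not its converged
  accuracy, depends on that choice.
- AIC for forests uses a parameter-count stand-in; treat RF/LM AIC gaps as
  descriptive only.
- PAS for strongly correlated predictors inherits the usual permutation-
  importance caveat: permuting one of two correlated variables understates
  both.
- The cleaning engine drops rows; it never projects them back into the
  feasible set, so heavy constraint violation shrinks the delivered sample
  rather than biasing values.
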