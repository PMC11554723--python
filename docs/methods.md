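# Methods

This note records the modelling choices behind `corsinorm`: what each stage
assumes, which parameters matter, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Raw-session scoring

**Corsi Span.** A block of three equal-length target sequences is passed
when at least two responses reproduce their targets exactly (order- and
identity-sensitive comparison).  The span is the length of the last passed
block.  Administration stops after the first failed block — a universal
span-task convention that the scoring code enforces: responses recorded
beyond a failed block raise a protocol-order error rather than being
silently ignored.  Failing the starting block (default length 2,
configurable) scores one less than its length.  The target paths shipped in
`config/span_protocol.yaml` are a synthetic, editable fixture: the official
notation-protocol sequences are distributed with the test materials, not
with this package.

**Supraspan learning and recall.** Only the first eight touches of a
response count.  Each response is classified deterministically into exactly
one category — exact match; single transposition (the target with one pair
of positions swapped); ordered overlap of length k (longest common
subsequence with the target, k = 1..7); or no credit — and the category is
mapped to a partial score by a `TrialScoreTable`.  The correct-response
score is pinned at 1.62 by the administration protocol, so an 18-trial
session is bounded by 18 × 1.62 = 29.16 exactly; when the
three-consecutive-correct criterion is met at trial k, trials k+1..18 are
credited 1.62 each.  The intermediate partial scores in
`config/trial_scores.yaml` are a synthetic fixture ordered by the chance
probability of each response class (rarer reproductions earn more); the
protocol's official table should replace them for clinical scoring.  The
classifier precedence (exact > transposition > overlap) makes the category
set exhaustive and unambiguous; its agreement with a brute-force
enumeration over permutations and subsequences is tested.

## Norming engine

All fits are ordinary least squares with an intercept.  AIC is computed as
2k − 2·loglik with the full Gaussian likelihood and the error variance
counted in k; since every model shares n, any convention that drops
additive constants or the variance parameter produces the same rankings
(tested).  Ties break toward fewer predictors, then listed predictor order.

*Transform family*: identity, natural log, square root, reciprocal — the
four re-expressions that appear in published correction equations for
these tests.  Log and square root require strictly positive input;
education 0 is rejected as a validation error rather than silently offset.

*Significance gate*: the selected model's omnibus F test must reach
p < 0.05; if no subset qualifies, selection fails loudly.

*Coefficient reversal*: the selected model is refitted on deviations of
each transformed predictor (and the score) from its sample mean.  Centering
leaves slopes unchanged, so the correction coefficients are exactly the
negated slopes, and the correction of a participant at the sample means is
identically zero — an invariant the tests assert exactly.

*Power analysis*: the minimum N for the omnibus F test uses the noncentral
F distribution with numerator df u, denominator df N − u − 1 and
noncentrality λ = f²·N (the G*Power convention; λ = f²·(N − u − 1) yields a
different N and is deliberately not used).  At f² = 0.04, u = 4, α = 0.05,
power = 0.80 this gives N = 304, cross-checked by a vectorized Monte-Carlo
power simulation.

**A caveat on bivariate transform screening.** The transform for each
predictor is chosen from *bivariate* fits, as in the published procedure.
When predictors are correlated (age and education correlate at −0.60 in
the normative population), the bivariate fit sees the marginal, confounded
relation, and the omitted correlated predictor can bend its shape away
from the generating transform — in simulation, data generated with a
log(age) effect plus a correlated education effect are better fitted
marginally by √age even at very large n.  Parameter-recovery and
transform-recovery tests therefore use cohorts with uncorrelated
demographics, where the search recovers the generating transforms in a
clear majority of seeds; with correlated demographics only the selected
*model* (not the screening transform) is identified.  This is a property
of bivariate pre-screening itself, worth keeping in mind when interpreting
any transform chosen by this procedure on real data.

## Correction grids

Grids evaluate a correction equation on the printed lattice (ages 20–85 by
5, educations {5, 8, 13, 16, 18, 21}, spans 2–8 for the supraspan tests)
and round half-away-from-zero to two decimals for display; all downstream
computation uses the unrounded equation.  Clinical lookup snaps to the
nearest lattice value per axis, with exact midpoints resolving toward the
lower value (configurable by passing an explicit lattice).  Queries beyond
the lattice by more than half a step fall back to the exact equation with
a warning, since the norms claim validity only for the sampled ranges; the
supraspan equations are nevertheless evaluated at any span 2–8, which is
precisely the extension the single-regression approach buys over
span-stratified legacy norms.

## Cutpoints

The impairment cutoff is the outer one-sided nonparametric tolerance limit
on the population 5th centile at 95% confidence: with X ~ Binomial(n, p),
outer_rank = max{r : P(X ≤ r−1) ≤ 1−confidence} and
inner_rank = min{r : P(X ≤ r) ≥ confidence}, from the exact binomial CDF.
This construction reproduces the published ranks (11, 24) at n = 340 and
needs n ≥ 59 at p = 0.05/95% (below that no valid outer rank exists and the
computation refuses).  Equivalent Scores partition the adjusted-score line:
ES0 at or below the outer-limit order statistic (ties included in ES0),
ES4 strictly above the sample median, ES1–ES3 splitting the ranks between
into three contiguous bands as equal as possible with remainders assigned
to the lower bands.  The interior split is one defensible reading of
"rank-based Equivalent Scores" and is isolated in a single function so an
alternative rule can be swapped in.  All boundaries are order statistics of
the sample — no interpolation is invented.  Percentiles default to the
Hazen convention 100·(rank − 0.5)/n with mean ranks for ties; Weibull and
ECDF conventions are available.

## Synthetic cohorts

`generate_healthy` emulates the published normative sample: n = 340 (by
default), ages 21–89 (mean 51.6, SD 19.4), education 4–25 (mean 13.1,
SD 4.6), sex 177 F : 163 M, and the published pairwise correlations among
age, education, CS, CSSL and CSSR (e.g. age–education −0.60, CS–CSSL 0.47,
CSSL–CSSR 0.61).  Dependence comes from a Gaussian copula.  Margins are:
truncated rounded normals for age and education; CS rounded and clipped to
2–8 (calibrated to mean 4.97, SD 1.03); CSSL clipped to [0, 29.16]; CSSR
censored at the 1.62 ceiling from a wider latent normal (latent mean 1.537,
SD 1.271) chosen so the censored variable reproduces the observed ceiling
fraction (47.4%) and mean (1.14) — its SD comes out near 0.60 rather than
the observed 0.54, the cost of using a single censored Gaussian.  Because
rounding, discretization and censoring attenuate Pearson correlations, the
latent correlation matrix is calibrated by a short fixed-point iteration
(six rounds on 20 000-draw calibration samples, PSD-projected each round)
so the *observed* correlations hit the targets; with n = 5000 the maximum
absolute error against the target matrix is about 0.02.

What the generator does **not** emulate: trial-level response processes
(only raw scores are simulated; session-level fixtures are hand-written),
any joint structure beyond pairwise correlations, age-conditional score
variances, and MMSE screening.  Passing tests on these cohorts shows the
pipeline machinery is correct under the published moments, not that the
synthetic cohorts are exchangeable with real participants.

In *equation mode* (`generating_equations` set) scores are produced as
`raw = mean − correction(x) + noise`, so that with zero noise the fitted
pipeline must invert the generator exactly — the basis of the
parameter-recovery tests (coefficients of the published CS equation are
recovered within their 95% CIs in well over 90% of seeded n = 2000
replicates at residual SD 0.9, the value implied by the published
R² = 0.24 and score SD 1.03).

`generate_impaired` draws each score from a clipped normal marginal and
rank-reorders CSSL against CS (an Iman–Conover-style permutation, leaving
marginals untouched) with a blending weight found by bisection until the
sample correlation is within ±0.03 of the target (default r = 0.22).  The
default score moments are a labelled synthetic fixture: the published
comparison drew its patient moments from an external clinical study, so a
real comparison must supply those moments.

## Norm comparison

"Impaired" under a system means adjusted score ≤ the system's cutoff
(conventionally its ES0/outer-tolerance boundary); the boundary case counts
as impaired, and the rule is a plain field of `NormativeSystem` so other
conventions are one assignment away.  Legacy systems are represented as
span-stratified cutoff tables with an applicable span range (4–6 for the
legacy supraspan norms); participants outside the range are excluded and
reported, mirroring how low- and high-span patients could not be scored
under the stratified norms.  Cohen's κ uses the standard marginal-expected
agreement; AUC is the rank-based (Mann–Whitney) statistic on the continuous
adjusted score, oriented so lower scores indicate impairment, with ties
credited one half.  Both are verified against brute-force pair counting and
an independent library implementation.  Ground truth in a simulated
comparison is user-supplied (all patients impaired, or any graded
definition) — the package computes metrics for whatever truth vector it is
given.

## Numerical and reproducibility notes

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical spec + seed reproduces tables and
  pipeline outputs byte-identically.
- Grid display rounding uses the shortest-decimal representation before
  rounding half-away, so values stored a hair below a midpoint (e.g. 1.005)
  still round as printed tables do.
- One transcribed grid cell (CSSR table, span 8, education 5, age 20→25
  column) is internally inconsistent in the source table (a repeated
  digit-level value) and is excluded from the reproduction fixtures; the
  remaining 1199 printed cells reproduce within ±0.01.
- Problem sizes in the test suite (n = 2000 recovery cohorts, 100 seeds,
  20 000 coverage replicates, 30-seed transform-recovery runs) were chosen
  so the full suite completes in a few seconds while keeping Monte-Carlo
  error an order of magnitude below every asserted margin.

## Known limitations

- The ES1–ES3 interior split and the percentile convention are documented
  choices; published interior cutoffs cannot be recomputed without the raw
  normative sample, so only their structural properties are asserted.
- The tolerance-rank construction needs n ≥ 59; smaller normative samples
  fail loudly rather than approximating.
- The impaired-cohort generator correlates only CS with CSSL (the published
  simulation constraint); CSSR is drawn independently.
- Sex is modelled as a 0/1 indicator with no effect in the default
  generator, matching the published finding that sex does not influence
  performance; cohorts with real sex effects would need a generator
  extension.
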