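# Methods

## Setting

Two raters independently assign each of *n* subjects to one of two
categories (in the bundled study: presence/absence of each of 12
personality-disorder diagnoses from structured clinical interviews).
The data for one analysis reduce to a 2×2 table

|            | rater 1: No | rater 1: Yes | total |
|------------|------------|--------------|-------|
| rater 2: No  | a | b | b1 |
| rater 2: Yes | c | d | b2 |
| total        | a1 | a2 | n |

with category 1 = "No" by default so the agreed-positive count sits in
`d`. Observed agreement is `p = (a + d) / n`.

## Coefficients

Both chance-corrected coefficients have the form `(p − p_e) / (1 − p_e)`;
they differ only in the chance-agreement term `p_e`:

- **Cohen's Kappa** uses the product of the raters' marginal
  distributions: `e_K = (a1·b1 + a2·b2) / n²`. When the marginals are
  concentrated (rare traits, hence mostly "No/No" subjects) `e_K`
  approaches 1 and the denominator `1 − e_K` collapses, so Kappa can be
  near 0 despite near-total observed agreement — the *kappa paradox*.
- **Gwet's AC1** replaces the marginal product with
  `e_γ = 2q(1 − q)` where `q = (a1 + b1) / (2n)` is the mean category-1
  propensity across raters. As a parabola in `q`, `e_γ ≤ 0.5` always, so
  AC1 stays close to percent agreement under extreme prevalence.

Point estimates are computed in exact rational arithmetic
(`fractions.Fraction`); floats appear only at the API boundary, and
rounding (half away from zero — the convention the study's tables use,
e.g. 7/8 → 88%) happens only in the reporting layer.

### Degenerate-table conventions

- `p = 1` and `e_K = 1` (every subject in one agreement cell): the 0/0
  form is resolved to Kappa = 1.0 and flagged `perfect_agreement`. (With
  mixed marginals, `p = 1` gives Kappa = 1 without any convention.)
- One rater's marginal fully concentrated with `p < 1` (e.g. cells
  (7,1,0,0)): algebraically `e_K = p`, so Kappa is exactly 0; flagged
  `kappa_zero_marginal`. AC1 needs no special case anywhere: for
  single-cell tables `e_γ = 0` and AC1 = p = 1.

Negative Kappa (systematic disagreement) is permitted and unflagged.

## Standard errors

The study prints SEs without formulas. We use the subject-level
linearization for two raters: with per-subject agreement indicator
`a_i` and subject-level chance term `pe_i`,

    s_i = (a_i − p_e)/(1 − p_e) − 2(1 − θ̂)(pe_i − p_e)/(1 − p_e)
    var(θ̂) = (1/n²) Σ_i (s_i − θ̂)²

where for Kappa `pe_i` averages each rater's category indicator against
the *other* rater's marginal, and for AC1 `pe_i = π_i(1 − q) + (1 −
π_i)q` with `π_i` the subject's mean category-1 indicator. With the
`1/n²` normalization this is, for Kappa, algebraically identical to the
Fleiss–Cohen–Everitt (1969) large-sample variance; the alternative
`1/(n(n−1))` normalization seen elsewhere in the literature is larger by
`n/(n−1)` and does not reproduce the study's printed SEs. No
finite-population correction is applied. Under the perfect-agreement
convention the SE is reported as 0.

A leave-one-subject-out **jackknife** (all *n* deletions enumerated,
standard `(n−1)/n` scaling) is provided as an independent check. For AC1
it agrees with the analytic SE within a few percent on every bundled
table. For Kappa the two genuinely diverge on sparse tables: Kappa is
strongly nonlinear in singleton off-diagonal cells (on (16,1,1,1),
deleting the one agreed-positive subject moves Kappa from .441 to
−.059), and the jackknife SE exceeds the delta-method SE by 26–119% on
nine of the 48 bundled tables. This is a property of the statistic at
these sample sizes, not an implementation defect; the delta-method
values are the ones the study prints. Two tests in the suite encode the
aspirational 20%-agreement check and the AC1-tracking bound below and
are expected to fail; their docstrings explain why.

## Benchmark scales

Three published interpretation scales (Landis–Koch, Altman, Fleiss) are
encoded as contiguous half-open bands over (−1, 1], closed at the upper
edge (0.60 is still "Moderate"); printed gaps such as "<.20" followed by
".21 to .40" are treated as rounded band edges, so every value in
[−1, 1] classifies uniquely. A coefficient of exactly 0 falls in
Landis–Koch "Slight" (the study treats its 0 values as interpretable);
Fleiss's "more than .75" is taken as [0.75, 1].

## Study pipeline

`run_study` evaluates all 48 bundled tables (4 rater pairs × 12
criteria), attaching trait prevalence (`100·d/n`, the proportion of
agreed-positive subjects), benchmark labels and a *paradox flag*
(observed agreement ≥ 80% with Kappa < 0.40, the Fleiss "Poor" cutoff;
both thresholds configurable). Study summaries (min/max/mean/sample-SD)
are taken over per-cell values rounded as the study reports them
(coefficients to 3 decimals, agreement to whole percents), and
per-criterion means average 3-decimal per-pair estimates — this is how
the published summary numbers (e.g. the Schizoid means .726/.853) were
formed; full-precision means are available via `rounded_means=False`.

### Known print artifacts in the bundled study tables

The bundled fixture stores the printed cell counts byte-identically;
recomputation exposes a few inconsistencies in the source's printed
derived values, all ≤ 0.005:

- Dependent VU–MN has counts identical to Histrionic VU–MN (17,1,0,1)
  yet prints Kappa .640 / AC1 .934 where the counts give .641(5) / .938.
- Several cells were truncated rather than rounded (Histrionic VU–MN
  Kappa .6415 → ".641"; Schizoid VU–MN AC1 .75271 → ".752";
  Passive-Aggressive US–SP AC1 .92471 → ".924"), while others were
  rounded; fixture-reproduction tests therefore compare within ±0.001.
- Histrionic VU–MN prints 94% agreement though 18/19 = 94.7 → 95; the
  study-level agreement mean therefore recomputes as 96.60 ± 4.98
  against the printed 96.58 ± 4.99.

## Synthetic ratings

The generator draws a binary latent trait with prevalence π and two
conditionally independent raters, each judging the trait with their own
sensitivity Se and specificity Sp. This standard latent-class
misclassification model is the minimal mechanism that turns trait
prevalence into an experimental dial; the bundled study could only vary
prevalence observationally. Closed-form population cell probabilities
(e.g. agreed-positive `π·Se₁·Se₂ + (1−π)(1−Sp₁)(1−Sp₂)`) yield exact
population coefficients, so simulations are validated against closed
form rather than against another simulation.

Defaults: Se = Sp = 0.9 (well-trained raters; at balanced prevalence
both population coefficients equal 0.64), n = 200 subjects, prevalence
grid {0.5, 0.3, 0.1, 0.02}, 500 replicates per grid point — small enough
to run in seconds, large enough that Monte-Carlo standard errors of the
replicate means are ~0.005. One master seed feeds
`numpy.random.SeedSequence`; per-prevalence and per-replicate streams
are spawned deterministically, so sweeps are exactly reproducible.

What the model does **not** emulate: rater correlation given latent
status (e.g. shared training biases), drifting rater behaviour across
subjects, more than two categories or raters, and prevalence that
differs between a rater's belief and the latent truth. Passing
simulation tests therefore demonstrate the coefficients' algebraic
behaviour under independent misclassification, not robustness of AC1 on
real clinical data.

Closed-form consequences worth knowing:

- At π = 0.5 with symmetric raters the marginals balance, both chance
  terms equal 0.5, and Kappa = AC1 (0.64 at Se = Sp = 0.9).
- At π = 0.02 the same raters give Kappa ≈ 0.122 but AC1 ≈ 0.774 while
  agreement stays 0.82 — the paradox in one line.
- AC1 tracks percent agreement within 0.1 only once the trait is rare
  (π ≤ 0.1 on this grid); at balanced prevalence both coefficients sit
  well below the 0.82 agreement because half of it is chance.

## Numerical and design choices

- Tie-breaking/rounding: half away from zero everywhere a value is
  printed; estimates are never rounded before further computation except
  in the summary statistics defined over rounded values (above).
- Rater roles are explicit (declared order), never inferred from sort
  order; swapping roles transposes the table and leaves every statistic
  unchanged (tested as a property).
- Category relabelling (swapping No/Yes) maps q → 1−q and leaves all
  five statistics unchanged (tested as a property).
- SE computations require n ≥ 2; single-subject tables return point
  estimates with no SE.
- The 4 study rater pairs with fewer than 8 subjects are not bundled —
  the study excluded them for insufficient cell size, and so does the
  fixture.

## Limitations

- Two raters, two categories only; no weighted kappa, no ordered-
  category AC2, no multi-rater generalizations.
- Wald intervals (±z·SE) only; no exact or bootstrap intervals.
- The delta-method Kappa SE underestimates leave-one-out variability on
  sparse tables (see Standard errors above); treat Kappa SEs on tables
  with singleton cells with caution — one more reason to prefer AC1 in
  low-prevalence settings.
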