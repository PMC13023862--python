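# Methods

## Scope and data flow

The package implements the full analysis chain for an implicit face–trait
(extraversion) IAT in developmental prosopagnosia: simulation of trial-level
sessions → D-score computation with trial- and participant-level exclusions
→ normative summarization → single-case (Crawford–Garthwaite) and
group-level (frequentist + Bayes factor) inference → screening-battery
scoring. Two small reference fixtures ship with the package: the combined
control norms (M = 0.082, SD = 0.405, N = 180) and the 36 published DP case
D-scores. Everything else is generated programmatically.

## Session simulator

The simulator emulates the standard seven-block IAT design: practice blocks
1, 2 and 5 (20 trials each; single-category face or word sorting), congruent
test blocks 3 (20) and 4 (40), incongruent test blocks 6 (20) and 7 (40).
Counterbalancing swaps presentation order (blocks 5, 2, 6, 7 first for the
incongruent-first arm) but never the pairing labels attached to block
numbers; scoring reads the pairing labels, so both arms score identically.

Latency model: lognormal, `exp(N(log m, sigma^2))` with block median m.
Reaction-time distributions are right-skewed and strictly positive; the
lognormal is the simplest standard choice with those properties. The
congruency effect delta lowers the congruent-block median by delta
milliseconds (an additive shift on the log-location), keeping the parameter
interpretable in ms. Error trials (probability `error_rate`) keep the base
draw as the first-keypress latency and add a fixed correction time
(`error_correction_extra_ms`) to reach the final correct response —
modelling a paradigm in which a wrong response must be corrected before the
next trial. Fast anticipatory responses (probability `fast_responder_rate`)
replace the draw with a uniform 100–299 ms latency, guaranteeing they fall
under the 300 ms screening rule.

Defaults (the simulated study conditions, chosen once):

| parameter | default | rationale |
|---|---|---|
| `base_latency_ms` | 800 | typical median two-choice categorization RT |
| `latency_sigma` | 0.25 | gives a realistic ~200 ms latency SD at 800 ms |
| `congruency_effect_ms` | 16 | calibrated so the 180-participant cohort mean D ≈ 0.082, the published control mean |
| `error_rate` | 0.05 | typical IAT error rate |
| `error_correction_extra_ms` | 400 | plausible re-orient + second keypress time |
| `fast_responder_rate` | 0 | contamination is opt-in for exclusion tests |
| `n_participants` | 180 | the normative cohort size |
| `congruent_first_fraction` | 0.5 | counterbalanced design |

Per-participant RNG streams are seeded as `seed + participant_index`, so
cohorts are reproducible and single sessions re-generable in isolation.

What the simulator does *not* emulate: between-participant heterogeneity in
association strength (all simulated participants share one delta), so the
simulated between-subject D spread (≈ 0.19) is narrower than the published
control SD (0.405), which folds in real individual differences; no
stimulus-level variability, fatigue, or block-order practice effects; no
latency floor other than the lognormal's natural one. Passing tests
therefore demonstrate correctness of the scoring and inference machinery
under a faithful *design*, not distributional realism of every moment of
real RT data.

## D-score

Both variants follow the improved scoring algorithm over the four test
blocks: remove latencies > 10,000 ms (strict); flag the participant when
more than 10% (strict) of the remaining analysis-block trials are faster
than 300 ms (strict); average each block; difference the incongruent and
congruent block means within each pair; divide by one pooled SD per pair;
average the two quotients. Sign convention: positive D = faster under the
congruent pairing, derived from the pairing labels, so relabelling
congruent↔incongruent negates D exactly (a tested invariant, alongside
shift- and scale-invariance).

Decisions the algorithm's terse published form leaves open, fixed here and
tested:

- **Pooled SD** is the n−1 sample SD over *all* retained trials of the block
  pair, with error trials contributing their variant-specific value (the
  replaced mean+600 value in the reference variant; the full corrected
  latency in the error-penalty variant).
- **"Correct latencies"** in the reference variant's block means are the
  first-keypress latencies of first-response-correct trials.
- **Sequencing**: slow-trial removal precedes the fast-fraction computation,
  whose denominator is the post-removal analysis-trial count.
- **Degenerate data**: a zero pooled SD or a block with fewer than 2 usable
  trials raises instead of producing infinities.

An independent straight-line transcription of the twelve scoring steps
(stdlib only) serves as the oracle in the test suite, alongside a fully
hand-computed two-level example.

## Single-case inference

`t = (x − M)/(S·√((N+1)/N))`, df = N − 1, with the percentile rank as the
Student-t CDF of t (point estimate of abnormality; no credible/confidence
limits on the percentile). One-tailed p is taken in the direction of the
observed deviation; the two-tailed p doubles it. Deficit screening counts
cases with t < 0 and one-tailed p < α (default 0.05). The published
single-case table's t column is internally inconsistent with its own norms
for most rows; only its row-4 values (and the zero-deficit count) are
treated as reproduction targets, which the implementation meets to within
printed-rounding tolerance (t 1.980 vs printed 1.981; percentile 97.5 vs
97.6).

## Group inference

One-sample t, CI and Spearman correlation are delegated to scipy; Cohen's d
uses the identity d = mean/sd = t/√n (asserted to 1e−12 on simulated
samples). The JZS Bayes factor integrand is authored here via the
inverse-gamma(1/2, 1/2) mixture representation of the Cauchy(0, r) prior,
integrated by adaptive quadrature on the log-transformed mixing axis
(the integrand is heavy-tailed in g, well-behaved in log g); relative
integration error above 1e−6 raises with diagnostics. Default prior scale
r = √2/2, the common "medium" default of Bayes-factor software; the source
analysis does not state its r, and at t = 2.635, n = 36 this default
reproduces the published BF₁₀ = 3.51 to three significant figures. Two
independent cross-checks run in the test suite: a 200,000-point trapezoid
grid oracle (agreement to 4 significant digits) and pingouin's
implementation (agreement to 1e−6 relative). The sequential Bayes factor
recomputes BF₁₀ on every prefix of length 2..n in presentation order; its
final element equals the full-sample value by construction.

The published per-case D column is inconsistent with the published group
summary (its mean is ≈ 0.045, not 0.156), so group statistics computed from
the case column are not expected to match the printed group results; the
group driver reports both the case-column computation and the
summary-statistic reconstructions (d = t/√n = 0.439, 95% CI upper limit
0.274, BF₁₀ = 3.51) and the discrepancy is deliberate, not an error.

## Screening battery

- **PI20**: 20 five-point Likert items, reverse items mapped v → 6 − v
  (default reverse positions 3, 8, 11, 15, 19); bands mild 65–74, moderate
  75–84, severe 85–100, "none" below 65. The honest attainable range is
  [20, 100] (the floor 40 sometimes quoted assumes reverse items answered at
  the agree extreme); the property test enumerates per-item extremes.
- **Face-sorting deviation score**: sum over faces of absolute positional
  displacement; 0 perfect, per-trial maximum 18 (full reversal of 6,
  verified by exhaustive enumeration of all 720 arrangements), task maximum
  144 over 8 upright trials.
- **Famous-faces test**: percent correct over `total − unknown` items;
  all-unknown is rejected (undefined denominator).
- **AQ exclusion**: score ≥ 32 excludes (the inclusive reading; the retained
  cohort's observed maximum of 31 and the 51 − 15 = 36 arithmetic both
  require it).
- **Diagnostic rule**: a task is impaired beyond 2 control SDs in the
  deficit direction — *below* mean − 2·SD for face memory and famous faces,
  *above* mean + 2·SD for the sorting task (higher = worse; the generic
  "2 SD below" criterion is mirrored for inverted scales); DP requires ≥ 2
  impaired tasks of 3. Plain z-distances against the control mean are used
  here, as the rule is stated; no single-case t correction is applied at the
  screening stage.

## Problem sizes and numerical choices

Monte-Carlo tests use 500 sessions per condition for null calibration and
effect-monotonicity, 1,000 replicates for CI coverage and 2,000 for type-I
calibration — sizes at which the binomial bands asserted (95 ± 2%,
5 ± 1.5%) have comfortable power while the suite stays fast. Trial files
round-trip floats exactly (repr-precision text). All RNGs are
`numpy.random.default_rng` with explicitly threaded integer seeds.

## Known limitations

- The simulator's single shared delta understates between-subject D
  variance (see above); calibrations target the cohort *mean* D only.
- Sequential Bayes factors are O(n) quadratures; fine for n ≤ a few hundred.
- The screening module scores and classifies but ships no control norms for
  the battery tasks (none are published in the source material); callers
  supply their own `NormativeSample` per task.
- Spearman p-values use the t-approximation, adequate for n ≈ 36; no exact
  permutation option.
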