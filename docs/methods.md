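# Methods

## Preferred temperature range (PTR)

The PTR of a population is estimated as central quantiles of
gradient-selected body temperatures, by default the interquartile range
(q_low = 0.25, q_high = 0.75) of all pooled hourly measures.  Two
choices here were genuinely open:

* **Pooling unit.** The quantiles can run over pooled hourly measures
  (default; with 24 lizards × 6 measures that is 144 values) or over
  per-individual means (`by_individual=True`, 24 values).  Hourly
  pooling is the default because the set-point range is a property of
  the temperatures animals select, not of individual averages; both
  modes are exposed so either convention can be matched against a given
  dataset.
* **Quantile convention.** Linear interpolation between order statistics
  (`numpy.quantile` `method="linear"`), the most common default across
  statistical environments; the `method` parameter switches conventions
  since published ranges rarely state one.

A temperature exactly on a PTR bound is *within* the range (deviation
zero).  Degenerate inputs (all values equal) give a zero-width PTR with
a log warning rather than an error.

The sex-pooling check compares per-individual mean selected temperatures
(one value per lizard) between males and females with a one-way ANOVA,
falling back to a Mann–Whitney U test when Shapiro normality or Levene
homogeneity fails at the assumption alpha (0.05).  Two identical samples
are reported with p = 1 by convention (no evidence of a difference, and
the underlying statistics are undefined under total ties).  `pooled` is
`p >= alpha`.

## Thermoregulation indices and bootstrap

d̄_b and d̄_e are arithmetic means of absolute deviations of T_b and T_e
from the PTR; E = 1 − d̄_b/d̄_e.  E is *not* clamped to [0, 1]: negative
values (body temperatures deviating more than the habitat) are
meaningful, and d̄_e = 0 raises an explicit "thermally ideal habitat"
error rather than returning infinity.

The bootstrap resamples the T_b and the T_e samples **independently**,
each with replacement at its original size, holding the PTR fixed, and
recomputes the three indices per iteration (default n_iter = 100, the
convention of the classic implementations; stability properties are
additionally tested at 10 000).  Reported summaries are the
pseudo-distribution mean, its standard deviation (the "±" value), and a
percentile CI at `ci_level` (default 95%); a normal-theory CI
(mean ± z·sd) is available via `ci_method="normal"` since legacy tools
differ here.  Iterations whose resampled d̄_e is zero leave E undefined;
they are excluded from the E pseudo-distribution and counted.  All
randomness flows from one `numpy` Generator seed, so equal seeds give
bit-identical results; resampling is chunked internally, with a chunking
rule that cannot affect the random stream.

Operative temperatures feeding d̄_e default to the daily activity window
08:00–18:00 (half-open, record hour in [8, 18)); loggers run around the
clock, and whether night records belong in "the habitat the animal
experiences" is a study-level decision, so the window is a parameter
(`filter_window`, `activity_window` in the pipeline config).

## Habitat profiling

Suitability profiles count T_e records below / within / above a PTR per
microhabitat and overall.  Percentages are kept unrounded internally and
rounded to 1 decimal only in tables; raw counts are retained, so the
rounded rows may sum to 100 ± 0.2 while counts always sum exactly.

Multi-group T_e comparison uses the tie-corrected Kruskal–Wallis H
(scipy) over the microhabitat × sun × orientation categories actually
present in the data, never a hard-coded list; categories with fewer than
2 records are dropped with a warning.  All-pairs post-hoc comparisons
use the Nemenyi test, implemented here directly (chi-square variant for
tied data by default, studentized-range variant optional) because no
maintained Python implementation was available as a dependency; the
formulas are documented in `posthoc.py` and pinned by a hand-computed
oracle test.  Letter displays use the insert-and-absorb algorithm;
groups sharing a letter are statistically indistinguishable at alpha.

The four-way thermal grouping (cold / mild / warm / very-warm) is a
formalisation of a narrative classification, driven by per-hour-block
medians (configurable to means) of daytime T_e per category, evaluated
against the specialist's (colder, narrower) and the generalist's PTRs,
in precedence order: *very_warm* — every block above both ranges;
*mild* — at least one block within the specialist range (such sites
offer the cold-adapted species its set-points at some hour, and the
generalist at warmer hours); *warm* — at least one block above the
specialist range but within the generalist's, never reaching the
specialist's; *cold* — every block below both.  A category matching no
rule (possible with oddly shaped diel curves) falls back to the position
of its overall daytime median; categories with no daytime records are
`unclassified`.  Because the two PTRs may not overlap, a literal "within
both ranges simultaneously" mild rule would be unsatisfiable; the
one-range-at-some-hour reading is the package's design choice.  Which
species is "specialist" is decided by PTR width, not by label order.

## Selection versus availability

Continuous variables (air/substrate temperature, refuge distance, perch
height) are compared across species A / species B / availability with
the same Kruskal–Wallis + Nemenyi machinery; missing values are excluded
per variable with logged counts (real capture datasets are incomplete in
exactly this way, which is why per-variable n differs).

Frequency selection uses Fisher's exact test for 2×2 tables.  For 2×k
(k > 2) the conditional exact p is estimated by Monte-Carlo: tables with
the observed margins are sampled with the Patefield algorithm
(`scipy.stats.random_table`) and p is the share whose conditional
(multivariate hypergeometric) probability does not exceed the observed
one, computed in the log domain with a 1e-9 tie tolerance and the
add-one rule (observed table included), 20 000 samples and a recorded
seed by default.  A full-enumeration oracle on small tables pins the
estimator in the tests.

Species contrasts are thin, reproducibility-oriented wrappers over the
named scipy tests (Mann–Whitney U, one-way ANOVA F, Levene W).  Levene
is mean-centred by default — the classic test matching the name — with
the median-centred Brown–Forsythe variant behind a flag.  P-values are
held exact internally; any "< 0.0001"-style truncation is display-only.

## Synthetic studies

The generator mimics the structure of a montane two-species study so the
pipeline's statistical behaviour can be verified against known ground
truth:

* **Operative temperatures** follow, per category,
  `T_e(t) = diel_mean + amplitude·(cos(2π(t − 12 − phase)/24) − 1)` +
  Normal(0, noise_sd) — the curve peaks at `diel_mean` at (phase-shifted)
  solar noon and falls off by up to 2·amplitude — sampled every 5
  minutes over the activity window (full-day mode optional) and rounded
  to 0.1 °C, the precision of the field thermometers.  The default
  landscape has 16 categories spanning ~20–46 °C noon temperatures,
  chosen once to mirror a slate-rock mountain site (shaded rock and soil
  cold; under-rock and filtered-sun sites mild; full-sun rock warm;
  full-sun grass/litter/soil very warm).
* **Selected temperatures** are iid Normal(mean, sd) per measure,
  balanced across sexes, six hourly measures per lizard at distinct
  hours.  The two default species use 28.8 ± 0.47 °C and 32.3 ± 2.11 °C
  with 24 individuals each, matching the scale of the study this package
  is calibrated against.  No within-individual correlation or circadian
  drift is modelled, so the generator under-disperses the hourly pool
  relative to real trials: recovered synthetic PTRs are narrower than
  published ones, and tests assert against the Normal quartiles
  μ ± 0.674σ, not against published ranges.
* **Body temperatures** come from a one-parameter behavioural model:
  pick a microhabitat by preference weights (uniform over all T_e
  records when no weights are given — the thermoconformer null), draw a
  T_e there, then pull it a fraction k toward the PTR
  (`T_b = T_e + k·(clamp(T_e, PTR) − T_e)`).  k = 0 reproduces the
  habitat's temperature distribution (E ≈ 0), k = 1 puts every T_b
  inside the PTR (E = 1 exactly).  This linear pull is a testing device
  that makes E identifiable and monotone in k — not a biological claim
  about behaviour.  Default capture counts are 79 and 72.
* **Availability points** echo random T_e readings with uniform (or
  configured) microhabitat draws and folded-normal heights/refuge
  distances with a longer tail than at capture points.

Every generator is a pure function of (spec, seed); the study-level
generator derives independent child seeds (kept below 2³¹) from one
`SeedSequence`.  What passing synthetic tests show is that the
*estimators* behave correctly under a known mechanism — they do not
validate the behavioural model against real lizards.

## Test-suite problem sizes

Simulation-based tests use one logging day of the default landscape
(1 920 records), 100-seed replicate loops for null-rate and
parameter-recovery checks, bootstrap sizes of 100–1 000 (10 000 for the
convergence property), and ~100 capture samples; these sizes give
stable Monte-Carlo margins while keeping the full suite in a few
seconds.  Checks that recompute published values from the original raw
measurement files activate only when those files are supplied under
`data/` (see `tests/test_acceptance.py`); the files are not
redistributable with the package.

## Known limitations

* The Nemenyi chi-square variant is asymptotic; with very small groups
  (n ≲ 5 per group) it is conservative, and the letter display inherits
  that.
* The Monte-Carlo exact frequency test has the usual ±O(1/√n_mc)
  p-value noise; raise `n_mc` for borderline calls.
* The thermoregulator model ignores costs, inertia and time budgets;
  E values from synthetic data should be read as estimator checks only.
* CSV ingestion assumes one record per row in the documented long
  formats; wide or multi-sheet exports must be reshaped (or mapped via
  the per-file column maps) first.
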