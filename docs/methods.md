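# Methods

`equiwag` implements a welfare-indicator aggregation pipeline for working
equid populations: a questionnaire schema with controlled vocabularies, a
per-individual scoring rule, a worst-case cumulative population grading
rule, driver and class-description analyses, and a seeded synthetic
population generator used to validate all of the above.

## Individual scoring

Each of the five welfare categories (nutrition, health, behaviour, housing,
working) carries four main indicator questions.  A response maps to a
welfare level — good, medium or bad — through the per-question level map in
`src/equiwag/data/wag_schema.yaml`; levels map to points (good = 25,
medium = 12.5, bad = 1, configurable through `ScoreConfig`), and the
category score is the sum over the four questions, so complete scores lie
in [4, 100].

Two main questions (duration of fibre availability; age the animal started
working) are routinely unanswerable during a rapid kiln-side assessment and
have designated alternates (presence of a clean water point when housed;
access to shade during work breaks).  When a main question is unanswered
and its alternate is answered, the alternate is scored in its place and the
substitution is recorded on the `CategoryScore`.  When neither is answered
the category is *incomplete*: the individual is excluded from that
category's population aggregation (with a count in the result) rather than
imputed — substitution is documented behaviour, imputation is not.

**Multi-select questions** (feed types, skin alterations, illness signs,
fear signs, harmful practices) are scored *worst-of*: the individual's level
is the worst level among its selected responses.  This is the conservative
choice for a protective welfare instrument — an additional clinical finding
can never improve the assessment — and it makes the level monotone under
adding responses (property-tested).  `ScoreConfig.multiselect_rule` offers
`best` and `modal` for sensitivity analyses; `modal` breaks ties toward the
worse level.

## Grades and population aggregation

Scores bin into ten letters, J (worst) to A (best), on contiguous width-10
intervals half-open on the left: J covers scores up to 10, I (10, 20], …,
A (90, 100].  Only the two extreme bins are fixed by the instrument's
published description; the contiguous width-10 interior is the only
partition consistent with them and is the package default (`GradeScale` is
configurable).

The population grade for a category accumulates the bin percentages of its
complete individual scores from the worst letter upward and assigns the
first letter at which the cumulative share reaches the threshold (default
15%).  The comparison is done on integer counts with exact rational
arithmetic (`100·cum_count ≥ threshold·n`), so a population with exactly
15% in the worst bin grades worst regardless of floating-point
representation; the threshold-edge behaviour is tested at both 15% and
14.999%.

The stratified grade matrix reports this grade per category for the whole
population and for every district, sex, species, age-category and work-type
stratum.  Strata with fewer than `min_stratum_n` records (default 5) are
reported as excluded rather than graded; very small groups — foals in the
emulated survey — lack the data for a stable grade.  Report percentages are
rounded to one decimal (round-half-even) for display only; grades are never
computed from rounded values.  Individuals are unweighted: no kiln- or
handler-level clustering weights are applied.

Driver reports rank a category's four (effective) questions by the
percentage of individuals at the bad level, then at medium, ties keeping
schema order.

## Class description (handler attitude)

For each value of a single-select class variable and each response of every
other question, the class-conditional proportion is compared with the
global proportion.  Under independence the overlap count is central
hypergeometric; the statistic is the standard-normal quantile of the
one-sided mid-p, signed by the direction of the effect (computed in integer
arithmetic, so the sign always matches the sign of class% − global%), and
the default p-value is the doubled one-sided mid-p capped at 1
(`method="exact"` gives the doubled conventional tails instead).  Mid-p was
chosen as the default because the plain exact tail is structurally
conservative at the class sizes that occur here — two attitude classes
contain only a handful of handlers — while mid-p has close-to-nominal
rejection rates on average.  Responses selected by nobody (or everybody)
admit no comparison and are not tested.  Raw p-values are reported by
default, matching the descriptive reporting style of such analyses; a
Benjamini–Hochberg flag is available.  Records missing the class variable
are excluded from that analysis's totals; multi-select responses are tested
as individual presence/absence indicators.

**Calibration caveat (measured, not assumed).**  With n = 2,448 records and
class labels simulated independently of all responses, the retained
fraction of tests at α = 0.05 is ≈ 3% under the survey's attitude marginal
and ≈ 4.4% even with balanced classes, not 5%: many survey responses are
rare (global counts of 2–10), and on so coarse a hypergeometric lattice the
smallest attainable p-value often exceeds α, so no exact-family test can
reject.  The test is conservative, never anti-conservative.  The
calibration suite asserts the nominal 5% band and therefore fails by
design, documenting this property honestly; reaching 5% would require a
normal-approximation test, which would misbehave in exactly the small
classes this analysis cares about.

**Mirror symmetry of attributions.**  When the class variable is dominated
by two values, enrichment of a response in the minority class and depletion
of the same response in the majority class are two views of one
association, with near-identical |statistic|; which of the two entries
leads an absolute-value ranking is sampling noise.  Planted-effect recovery
is therefore judged on the top *positively associated* entry (the planted
dependence boosts a response), and reports list both signed entries so the
reader sees the association from both sides.

## Synthetic populations

The generator produces populations with *exact* configured demography
(stratum counts, kiln and handler layouts are deterministic; only responses
are random).  `study_mimic_config()` encodes the emulated brick-kiln
survey: 2,448 equids — 55 donkeys, 1,365 horses, 1,028 mules — across 41
kilns (24 in Dhading, 17 in Lalitpur) worked by 126 handlers (58 and 68
respectively), with per-species response marginals matching the published
summary tables (single-select columns renormalised where rounding keeps
them from summing to 100).

Choices where the source material is silent or inconsistent:

* **District totals** are not published; equids are allocated to districts
  proportionally to kiln counts.
* **Kiln sizes**: the published size range ([8, 64]) is inconsistent with
  its own mean given the total and kiln count, so sizes come from an
  equal-share largest-remainder split of the district total (all ≈ 60,
  inside the range); per-kiln sizes are not individually published.
* **Sex / age / work mixes** are published only graphically; the defaults
  (geldings 60% > stallions 31% > females 9%; young adults 45% the modal
  age; pack 72%) respect the reported orderings.  Foals are set to ≈0.2%
  so that, as in the original analysis, they fall below the minimum
  stratum size and are excluded for lack of data.
* **Multi-select sampling**: the exclusive "no findings" response is drawn
  first with its configured probability; other responses are independent
  Bernoulli draws at conditional probability p/(1 − p_exclusive); empty
  sets are repaired by drawing one response from the renormalised
  non-exclusive vector.  Printed multi-select columns do not sum to a
  common denominator, so their marginals cannot all be reproduced exactly;
  `implied_marginals` gives the closed-form marginal the sampler does
  produce and `marginal_check` flags empirical deviations beyond three
  binomial standard errors of it.
* **Independence across questions**: only marginals are published, so
  responses are independent across questions by default.  *Dependence
  hooks* override one response's probability inside one class of a
  single-select question (e.g. boost a fear sign among equids of
  cautious/fearful handlers), providing a non-null regime in which planted
  effects are recoverable by the class-description analysis (recovered as
  the top-ranked entry in ≥95% of replicates in the acceptance suite).

Seeding is counter-based — stratum *i*, question *j* draw from
`default_rng([seed, i, j])` — giving byte-identical output per seed and
stream independence across strata (resizing one stratum leaves all others'
draws unchanged).

What passing tests on these populations show: the scoring, aggregation and
testing machinery is correct under known marginals and exact demography.
What they do not show: anything about the survey's real joint response
structure, kiln-level clustering, or handler effects beyond those planted —
the original raw records are not publicly deposited, so stratum-level
grades of the real survey are not reproducible and are not asserted.

## Problem sizes and determinism

The validation suite uses the full 2,448-record mimic population where the
analysis itself is under test, 1,000-population oracle sweeps for the
aggregation rule, exhaustive enumeration of all hypergeometric tables up to
n_total = 25, 1,000 label-permutation replicates for calibration and 200
generator replicates for planted-effect recovery.  All randomness flows
from explicit seeds; pipeline bundles contain no timestamps and hash
identically across reruns at a fixed seed and configuration.
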