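# equiwag

Welfare-indicator scoring and population grading for working equids.

Rapid welfare assessments of working donkeys, horses and mules — in brick
kilns, markets and agricultural settings — collect questionnaire responses
per animal: body condition, water access, skin alterations, signs of fear,
housing and working conditions, and the handler's behaviour toward the
animal.  `equiwag` turns such records into decision-ready summaries for
welfare scientists and NGO programme teams:

* **Individual scoring** — each response maps to a welfare level
  (good / medium / bad) and to points (25 / 12.5 / 1); a category score is
  the sum over a category's four indicator questions, so scores lie in
  [4, 100] across five categories: nutrition, health, behaviour, housing,
  working.  Documented alternate questions stand in for unanswerable mains;
  multi-select findings are scored worst-of.
* **Population grading** — scores bin into letters J (worst, ≤10) … A
  (best, 90–100].  A population's grade is the first letter, accumulating
  from J upward, at which the cumulative share of animals reaches 15%:

  grade = min { g : Σ_{g' ≤ g} pct(g') ≥ 15% },

  a deliberately protective, worst-case cumulative rule — 15% of animals in
  grade J makes the population grade J no matter how well the rest score.
* **Stratified reporting** — grades per district, sex, species, age
  category and work type; per-category rankings of the questions driving
  poor welfare; response percentage tables.
* **Class description** — for each handler-attitude class, responses whose
  class-conditional proportion differs from the global proportion, via an
  exact hypergeometric (mid-p) two-proportion test with a signed
  normal-scale statistic.
* **Synthetic populations** — a seeded generator with exact demography and
  configurable per-stratum marginals, including a study-mimic configuration
  (2,448 equids, 41 Nepalese brick kilns, 126 handlers) used to validate
  the whole pipeline; dependence hooks plant class effects to test recovery.

## Worked example

```python
import equiwag as ew

cfg = ew.study_mimic_config()                      # survey-like demography + marginals
rs = ew.generate_population(ew.synth.with_seed(cfg, 1))
gm = ew.grade_matrix(rs)                           # letter grades per stratum
print(gm.frame.loc[[("overall", "Overall"), ("species", "donkey")]])
```

```
                  nutrition health behaviour housing working
indicator stratum
overall   Overall         G      D         C       D       G
species   donkey          F      E         D       G       F
```

The overall nutrition grade G (scores 30–40) means at least 15% of animals
accumulate in grade G or worse for nutrition.  Why is visible in the driver
ranking:

```python
print(ew.driver_report(rs, "nutrition").frame.round(1))
```

```
                      n_answered  pct_bad  pct_medium  pct_good
question_id
diet                        2448     29.6        24.4      46.0
body_condition              2448      6.0        50.2      43.8
water_access_working        2448      0.8        95.7      3.5
water_point_housed          2448      0.3        97.7      2.0
```

Nearly every animal has only limited access to clean water while working
(95.7% medium) and while housed (97.7% medium), capping the attainable
nutrition score; poor-quality feed items add the bad-level mass.  The same
analysis from the shell:

```sh
equiwag run --seed 1 --outdir run/     # simulate + score + grade + describe
equiwag simulate --seed 1 --output records.csv
equiwag validate --input records.csv
equiwag aggregate --input records.csv --output grades.csv
```

`equiwag run` writes a deterministic bundle: validated records, individual
scores, the stratified grade matrix (CSV + Markdown), driver reports,
response tables, a handler-attitude class-description report and a
manifest with the seed and config hash.

See `docs/methods.md` for the model, its assumptions, the synthetic-data
design and known limitations.

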