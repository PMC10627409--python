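# Methods

This note documents the models and procedures implemented in `phenomap`, the
defaults that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Phecode maps and the label grammar

A phecode map is a many-to-many relation between ICD diagnosis codes (in one
of three vocabularies: ICD-9-CM, ICD-10-CM, or WHO ICD-10) and phecodes.  The
current dialect uses labels of the form `<AA>_<DDD>` or `<AA>_<DDD>.<d{1..3}>`:
a two-letter category prefix, an underscore, a three-digit root, and up to
three decimal digits.  The hierarchy is purely lexical — the parent of a code
is obtained by dropping one suffix digit — so `CV_416.221` sits under
`CV_416.22` under `CV_416.2` under `CV_416`, and a label's depth equals its
suffix length.  The legacy v1.2 dialect uses bare numeric strings with at most
two decimals; these are stored opaquely (leading zeros preserved, no grammar
beyond digits), because legacy releases contain quirks such as phecode `008`
that a numeric type would corrupt.

ICD codes are normalized before any matching: uppercased, dots and whitespace
stripped.  Matching is exact-after-normalization only; an unmapped code is
reported, never silently truncated to a prefix match, because a silent
fallback would change phenotype definitions invisibly.

Validation is structural and report-based (findings, not exceptions):
hierarchy closure (every child's truncation parent must exist; orphans are
reported, not auto-repaired, keeping the released map authoritative),
prefix/category consistency against the category registry, duplicate mapping
triples, ICD-10-only consistency (the flag implies a `*`-terminated
description and no ICD-9 mapping), and absence of exclude ranges in the
current dialect, which removed them by design.

The category registry defaults to 18 ordered (prefix, name) pairs.  Six
prefixes carry their conventional meanings (CV cardiovascular, ID infectious,
RE respiratory, GI gastrointestinal, EM endocrine/metabolic, GE genetic); the
remaining twelve names follow common phecode category naming and are a
package default, not an authoritative list — the registry is configurable
from a two-column file for use with a real release.

Multi-mapping statistics: an ICD code counts as multi-mapped within a
vocabulary when it maps to more than one distinct phecode.  Leaf statistics
(a leaf is an entry with no child present in the map) accept a configurable
exclusion list for high-level combination phecodes, defaulting to empty,
which is appropriate for synthetic maps.

The crosswalk between v1.2 and the current release is partial by design:
`translate` returns all counterparts in sorted order, and the empty tuple is
the explicit no-counterpart marker.

## Phenome construction

The counting unit is **distinct dates per (person, phecode)**, not raw event
rows: each event fans out to every directly mapped phecode and (with rollup)
every truncation ancestor, the expanded contributions are deduplicated to one
per (person, phecode, date), and the count is the number of surviving dates.
Same-day duplicate billing therefore never manufactures evidence, and the
parent count is always ≥ any child count.

Status assignment: count ≥ `min_code_count` (default 2) ⇒ case; count 0 ⇒
control; 0 < count < threshold ⇒ neither, excluded from both arms — the
standard minimum-code-count convention.  The person universe is the event
table plus an optional roster, so true zero-count controls are representable.

v1.2 exclude ranges demote controls: for a phecode with range `410-414.99`,
any control with a nonzero count on a phecode inside the closed numeric
interval becomes neither.  The count trigger defaults to any nonzero count
(configurable via `min_count`), cases are never touched, and with a
current-dialect map the operation is the identity (such maps define no
ranges; supplying one with ranges raises).  Membership is a numeric interval
test on the v1.2 code values, matching how the ranges are printed.

Crosswalking a count table moves counts to each counterpart phecode; where
several source phecodes land on one target the target takes the **maximum**
of the source counts, not the sum, because the sources typically describe the
same underlying clinical events and summing would double-count them.  Codes
without a counterpart go to a dropped-codes report.

No date-window, age or utilization filtering is applied; such cohort
restrictions belong upstream of this package.

## Association scan

Each phecode is tested by maximum-likelihood logistic regression of
case/control status on the predictor plus covariates, with per-phecode
test-wise deletion of "neither" persons.  The fit is iteratively reweighted
least squares (IRLS, the Newton iteration for the canonical logit link), with
convergence declared when the largest coefficient step falls below 1e-8 and a
cap of 25 iterations.  (Quasi-)separation manifests as diverging estimates
whose steps never shrink below tolerance, so it surfaces through the
`converged=False` flag; no Firth correction is applied in this version.
P-values are two-sided Wald.  The statistical core is deliberately
dependency-light and is cross-checked against `statsmodels.Logit` in the test
suite; degenerate designs (single-class outcome, rank deficiency, constant
predictor after deletion) are skipped with an explicit reason.

The case floor defaults to 100 cases — a conventional working filter for
PheWAS, configurable down to 1 — and skipped phecodes are always emitted with
their reason, so tested + skipped equals the phenome size.  Multiple testing
uses the Bonferroni bound α/m by default; Benjamini–Hochberg is available as
an exploratory alternative.  The Manhattan-style plot table groups phecodes
contiguously by category in registry order and attaches the Bonferroni
threshold over the tested set.

## Synthetic data

`simulate_map` grows a map from a seeded RNG: categories from the registry,
globally unique three-digit roots, children with probability `child_prob`
(1–3 of them), grandchildren with `grandchild_prob`.  Every phecode receives
1 + Poisson(mean−1) synthetic ICD-10-like codes (letter + three digits) and,
unless flagged ICD-10-only, ICD-9-like codes (four digits).  Multi-mapping
promotes exactly round(rate·n) codes per vocabulary to a second phecode
(never an ICD-9 code onto an ICD-10-only phecode), so the realized rate
matches the target to within 1/(2n).  Generated maps always pass validation
with an empty report — the generator–validator contract is itself under test.

`simulate_cohort` implements the generative model: genotype
g ~ Binomial(2, MAF); per person and leaf phecode, affection with probability
expit(logit(prevalence) + β·g), where β is the planted log-odds-ratio (zero
off the planted leaves).  Affected persons emit codes drawn uniformly from
the leaf's mapped ICDs on D distinct dates, D ~ 1 + Poisson(mean_dates − 1)
(dates are drawn uniformly over the observation window and redrawn on
collision, so distinctness holds exactly); with the default mean_dates = 3, a
fraction e⁻² ≈ 13.5% of affected persons have D = 1 and fall below the
default minimum code count — a computable miss rate used by the test
expectations.  Background noise adds Poisson(background_rate) events per
person drawn uniformly from the whole map.  Effects are planted at leaves
only: ancestors inherit signal solely through rollup, which isolates exactly
the mechanism under test.

What the generator does **not** emulate: realistic ICD code frequencies,
comorbidity correlation between phenotypes, care-utilization patterns, or
informative missingness.  Passing tests therefore demonstrate correctness of
the mapping/rollup/thresholding/testing machinery and calibration under the
stated generative model, not robustness to the dependence structure of real
EHR data.

## Study conditions used by the tests and the acceptance script

- Rollup oracle: 100 random fixtures, each ≤ 50 phecodes and 150 persons,
  20% multi-mapping, background rate 1 — compared for exact equality against
  an independent string-truncation expand/dedup/count oracle.
- Type-I calibration: a flat 500-phecode map, 5,000 persons, prevalence 0.05,
  no planted effects; the empirical fraction of tests with p < 0.05 is
  required to lie within 3 binomial standard errors of 0.05.
- Effect recovery: 20 replicates of a ~30-phecode hierarchical map with 10%
  multi-mapping and background rate 1, one leaf planted at log-OR 0.7
  (MAF 0.3, prevalence 0.05, n = 5,000).  The mean estimate across replicates
  is required to fall within 3 SEM of 0.7 and the mean odds ratio in
  [1.7, 2.4].  The mean is the right summary here: a single replicate's
  sampling SE on the log-OR is ≈ 0.09 at these settings, while the
  20-replicate mean has SEM ≈ 0.02.  Mild attenuation (≈ 0.01–0.03) relative
  to the planted affection-model β is expected, because background noise and
  sub-threshold affected persons produce small amounts of outcome
  misclassification; the acceptance band accommodates this by construction.

## Known limitations

- No Firth or exact logistic fallback for separated or near-separated fits;
  they are flagged and should be treated as untested phenotypes.
- Exclude-range semantics follow the printed interval convention; ranges that
  are not parseable as numeric intervals are ignored for membership.
- The v1.2 dialect's hierarchy is inferred from decimal truncation, which is
  the release convention but is not re-validated against any external source.
- Crosswalked counts approximate the counterpart phenome; where the two
  releases group ICDs differently, re-mapping the raw events through the
  other map is the exact route and is preferred when events are available.
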