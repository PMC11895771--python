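# Methods

This note documents the models, conventions and numerical choices behind
`jemkit`, and what the synthetic-data tests do and do not demonstrate about
real data.

## The matrix model

A job exposure matrix (JEM) cell is `(occupation code, gender, exposure) →
prevalence`, where prevalence is the percentage of workers within the
occupation reporting the exposure. Matrices are gender-specific throughout:
cells exist per gender independently and are never pooled, because men and
women in the same occupational code often perform different tasks. Records
with a missing gender are rejected at load time, with a count reported.

Occupation codes are strings, never integers: 4-digit ISCO-style codes can
carry leading zeros (armed forces are major group 0), and integer parsing
silently corrupts them.

### Banding and dichotomization

Prevalence is banded into five ordinal categories, `0 = 0–5%`, `1 = 6–24%`,
`2 = 25–49%`, `3 = 50–74%`, `4 = 75–100%`. The band edges are printed as
integer percents; continuous prevalences are **rounded half-up to an
integer percent before banding**, making the printed bands a total
partition of [0, 100] (so 5.4% → band 0, 5.5% → band 1). Half-up rather
than banker's rounding was chosen because it is the convention of the
surrounding epidemiologic literature and gives a single deterministic edge.

For agreement and validity analyses the bands collapse to binary:
*exposed* iff category ≥ `exposed_cut`, default 2, i.e. at least 25% of
workers exposed. The cut is configurable but every default in the package
uses 2.

## Construction from surveys

`build_jem` computes each cell's prevalence as `100 × (# exposed) /
(# respondents with an answer)`; rows missing an answer for one exposure
are dropped for that exposure's cell only (no imputation). The
`asymptomatic_only` option removes symptomatic respondents from both the
numerator and the denominator, reflecting the concern that workers with
musculoskeletal pain over-report physical exposures.

Cells with fewer than `min_n` respondents (default 10) are kept but flagged
`reliable = False`: small occupations carry estimation bias, but excluding
them would silently shrink matrix coverage; flagging leaves the decision to
the analyst. Records are equally weighted — national surveys use designs
and weights that are not portable across sources — though a weight column
is accepted by the file format.

## Transcoding

A crosswalk maps codes of one occupational classification to another, with
optional nonnegative weights normalized to sum to 1 per source code.
Transcoding rules:

* one-to-one: prevalence copied;
* one-to-many (split): prevalence replicated to every target; weights only
  apportion the bookkeeping of contributing respondent counts
  (`n_target = round(n_source × normalized weight)`);
* many-to-one (merge): target prevalence is the weighted mean of source
  prevalences with mass `m = base × normalized split weight`, where `base`
  is the workforce size if `size_weights` are supplied, else the source
  cell's respondent count, else 1. Using the mass (size × flow share) makes
  transcoding via a chained crosswalk equal to transcoding twice in
  sequence, up to respondent-count rounding — a property the tests assert
  on a 10-code fixture.

Categories are always recomputed from the transcoded prevalence, never
averaged directly: ordinal codes are lossy summaries of proportions and
averaging them has no population interpretation. Every transcoded cell
carries the list of contributing source codes in its provenance field.

Source codes absent from the crosswalk drop their cells and are reported in
an unmapped-codes summary (crosswalks between national systems are known to
be incomplete; failing hard would make partial crosswalks unusable).
`chain` composes two crosswalks by multiplying then renormalizing weights;
paths through an intermediate code missing from the second crosswalk are
recorded in `dropped_paths`.

For assigning a *population* to the target system (`recode_population`),
individual-level recoding must be single-valued, so split codes follow the
highest-weight target (ties broken lexicographically) and unmapped
individuals are dropped with a count.

## Harmonization

Cell universe = union of keys across the input matrices. A cell where all
sources are present and agree is adopted as-is and produces no ledger
entry; every other cell — any disagreement, or any source missing —
produces exactly one JSON-lines ledger entry recording the per-source
categories and respondent counts, the rule applied, the outcome and a note.
Occupations absent from a source are treated as *absent*, not as category
0: absence is missing information, not evidence of no exposure.

The reference workflow resolves disagreements by an expert panel, which no
algorithm can reproduce; the default rule is therefore `flag`, which
exports every non-unanimous cell to a review worksheet and excludes it from
the harmonized matrix until reviewed. Three automated stand-ins are
provided for unattended runs and labelled as stand-ins in the ledger:

* `majority` — modal category among present sources; modal ties flagged;
* `weighted_median` — respondent-count-weighted **lower** median
  (deterministic and conservative toward lower exposure on even splits);
* `available_consensus` — unanimity among the present sources only.

A harmonized cell carries a prevalence (the respondent-weighted mean of the
source prevalences) only when that mean re-bands to the resolved category;
otherwise the cell is category-only. This preserves the invariant
`category = categorize(prevalence)` and makes harmonizing identical
matrices exactly idempotent. Staged harmonization (`staged_harmonize`)
feeds each stage's result into the next and tags ledger entries with stage
labels; staged and one-shot runs may legitimately differ, and the ledger
makes any difference auditable rather than asserting equality.

## Validation statistics

* **Cohen's kappa**: `(p_o − p_e)/(1 − p_e)` with `p_e` from marginal
  products, computed directly (the explicit formula is needed to handle the
  degenerate `p_e = 1` case — both vectors constant and equal — which is
  reported as undefined rather than returned as a number). The test suite
  cross-checks against scikit-learn's implementation and a brute-force
  oracle.
* **AUC**: pairwise concordance probability with ties counted ½, via
  scikit-learn's rank-based implementation; verified against O(n²)
  enumeration. Scores may be ordinal matrix categories or binary
  assignments — the choice is an analysis option (`score_scale`) and is
  labelled in the output, and both orientations (A scored against B's
  labels and vice versa) are reported since neither matrix is a gold
  standard.
* **Interpretation bands**: the printed scales (kappa: poor < 0.20, fair
  0.21–0.40, moderate 0.41–0.60, good 0.61–0.80, excellent 0.81–1; AUC:
  failed 0.50–0.59, poor 0.60–0.69, fair 0.70–0.79, good 0.80–0.89,
  excellent 0.90–1) leave the two-decimal gaps unaddressed; values are
  rounded half-up to 2 decimals and banded with half-open intervals at
  0.205/0.405/0.605/0.805 (kappa) and 0.595/0.695/0.795/0.895 (AUC), which
  reproduces every published labelling.
* **Odds ratios**: maximum-likelihood logistic regression (statsmodels,
  Newton-Raphson, relative log-likelihood tolerance 1e-8, at most 50
  iterations) of outcome on intercept + binary exposure + age. Age enters
  as a continuous linear term by default (categorical bands are available
  via `age_bands`). The OR is the exponentiated exposure coefficient with a
  Wald 95% CI exponentiated from the log scale — standard epidemiologic
  reporting; profile-likelihood intervals are out of scope. Separation or
  non-convergence yields a flagged result with NaN estimates, never a
  silent number. All reports are gender-stratified; empty or degenerate
  strata appear as flagged rows, never dropped.

Working age defaults to 25–60 years at cohort load.

## Synthetic data

Generators are pure functions of `(config, seed)`; a master seed derives
independent sub-streams for profiles, survey, cohort and crosswalk via
`SeedSequence((seed, stream))`, so each stage regenerates independently.

* **Profiles**: 50 occupations per gender by default, 4-digit codes (one
  major-group-0 code exercises leading zeros). Each occupation is
  white-collar (prevalences ~ Uniform(0, 0.12)) or manual
  (~ Uniform(0.03, 0.98)) with equal probability; the two-component mixture
  populates all five bands at the default size. Workforce shares are
  Dirichlet(1) per gender.
* **Heterogeneity**: an individual in an occupation with planted prevalence
  `p` is exposed with probability `(1 − h)·E + h·p`, where `E` indicates
  whether the occupation dichotomizes as exposed. `h = 1` (default) is the
  plain Bernoulli(p) self-report model; `h = 0` makes occupations
  homogeneous, so group-level assignment incurs no misclassification —
  the regime in which planted odds ratios must be recovered exactly.
  Intermediate h produces Berkson-type error and attenuation.
* **Survey**: `survey_n_per_cell` respondents per occupation–gender cell
  (default 200); a symptomatic flag with baseline prevalence 0.15 and
  log-odds +0.5 for exposed workers exercises the asymptomatic filter.
* **Cohort**: default 20 000 members, gender-balanced, occupation sampled
  by workforce share, age uniform on 25–60. Outcomes follow
  `logit P = β₀ + Σ log(OR)·X + β_age·(age − 40)` with baseline prevalence
  0.20 at age 40 and `β_age = 0.02`/year; the default planted effect is a
  heavy-lifting → low-back-pain OR of 1.6, within the range typically
  reported for physical workload and musculoskeletal pain.
* **Crosswalk pair**: a second coding system made by merging 20% of codes
  pairwise and splitting 10% in two (half weights), with the planted
  structure returned for assertions.

What the generator does *not* emulate: realistic occupational size
distributions and code hierarchies, survey design effects and weights,
wording differences between national exposure items, correlated exposures
within workers, or panel-style qualitative judgement. Passing tests
therefore demonstrate the correctness of the arithmetic, the resolution
rules, the statistics and the misclassification behaviour — not that any
particular real pair of national matrices would agree well.

## Problem sizes in the test suite

The statistical end-to-end checks run the full pipeline at cohort
n = 100 000 for point-estimate recovery (|estimate − 1.6| ≤ 0.1 with
h = 0), 100 replicates at n = 20 000 for Wald-CI coverage (≥ 93/100), and
20 seeds at n = 100 000 for the attenuation direction (estimate strictly
between 1 and the planted OR with h = 1). These sizes give Monte-Carlo
standard errors comfortably below the asserted margins while keeping the
whole suite under half a minute on one CPU.

## Known limitations

* Automated resolution rules are explicit stand-ins for expert judgement;
  the `flag` default exists precisely because consensus is not computable.
* Merge aggregation uses weighted means of prevalences; when only
  categories are available, merges fail loudly rather than average ordinal
  codes.
* No survey-design variance adjustment, no multilevel models, and no
  multiple-testing correction (the validity analyses report each stratum
  separately, as is conventional).
* Respondent-count bookkeeping across splits rounds to integers; chained
  versus sequential transcoding can differ in the last decimal of the
  stored n (prevalences are unaffected).
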