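# Methods

## Data model

A survey table is tidy: one row per (survey, rater, specimen, term) tag.
Survey 1 terms are free text; Survey 2 terms are ZP CURIEs. Duplicated
(rater, specimen, term) rows are collapsed with a logged warning, and only
raters present in both surveys enter the analysis. Character handling is
UTF-8 throughout; terms are stored raw at the I/O layer and normalized only
inside harmonization.

## Harmonization

`normalize_term` case-folds, trims, collapses internal whitespace and strips
trailing sentence punctuation; it is idempotent, and lexicon keys are stored
in normalized form. Mapping is exact-match lookup after normalization —
deliberately no fuzzy or embedding matching, because the mapping being
modelled was a human curation step and a fuzzy matcher would fabricate
curation decisions. Strings absent from the lexicon become the sentinel
`UNMAPPED`, are carried through row-conserving (|annotated| = |input|), and
are emitted in a curation-queue TSV.

The trait hierarchy is fixed at two levels: every granular CURIE has exactly
one general parent and generals are self-parented. Deeper ZP ancestry is out
of scope. Special status categories are modelled as pseudo-traits: `normal`
and `hatched` have no CURIE and map to themselves; `dead` carries its CURIE
(`ZP:0000306`) and behaves as an ordinary general trait. `normal` and `dead`
participate in concordance (raters genuinely disagree about whether a larva
is normal or dead); `hatched` participates in summaries but sits outside the
48-term catalog, whose composition (21 general + 27 granular) follows the
published per-trait child counts. Granular CURIEs not printed in the source
tables are shipped as flagged `ZP:UNSPEC_*` placeholders so that per-trait
child counts are preserved; their labels are filled in where the granular
trait is named in prose.

## Heterogeneity metrics

Per general trait: `terms_per_tag = unique_terms / total_tags` (2 decimals)
and `terms_per_trait = unique_terms / (1 + granular_children)` (integer).
Both are rounded half-up **on the exact integer ratio** via `Decimal`; a
float quotient would misround exact halves (7/40 = 0.175 must report 0.18).
Classification uses the unrounded ratio: > 0.5 heterogeneous, < 0.15
homogeneous, boundary values intermediate. Uniqueness of verbatim strings is
counted on normalized text by default (a `raw_uniques` switch restores
case-sensitive counting, since the original counting convention is not
documented). Tags of granular children count toward the general trait's
totals; a granular-level summary is also available.

## Concordance

The presence tensor is binary over (rater, specimen, trait) per survey.
The majority call requires strictly more than half of raters; exact ties
(possible with an even rater panel) resolve to "absent" and are logged — a
conservative, deterministic choice. The scoring universe defaults to
(specimen, trait) pairs tagged by at least one rater in at least one survey
(`universe="observed"`); scoring all catalog pairs is available but inflates
concordance through universal mutual absence.

`fisher_exact_2x2` sums hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed table's.
Because every table in the support shares the denominator C(n, c1), the
comparison is done on integer numerators — exact, with no floating-point
tie ambiguity. A zero margin returns p = 1.0 by convention. Raw p-values are
reported with an optional Benjamini–Hochberg column (statsmodels); the
primary outputs quote unadjusted p-values.

The across-rater dispersion quoted next to survey-level mean concordance is
the sample SD of per-rater means, not the SD of the pooled 0/1 cells.

## Repeatability

ICC(1) by one-way random-effects ANOVA on the 0/1 observations, one
grouping factor at a time (specimen, trait, rater): with mean squares MSB,
MSW and effective group size k0 = (N − Σn²ᵢ/N)/(g − 1) for unbalanced
groups, σ²_b = max(0, (MSB − MSW)/k0), σ²_w = MSW, ICC = σ²_b/(σ²_b + σ²_w).
The moment estimator is truncated at zero, so ICC ∈ [0, 1]; constant data
yields ICC 0 with a warning. An original-scale ANOVA estimator was chosen
over a logit-link GLMM because it is deterministic, closed-form and exactly
testable; a GLMM backend is a possible extension, and numerical equality
with mixed-model ICCs is not claimed. The default response is the binary
concordance cell (presence is available as an alternative), so ICC values
from other response conventions are not directly comparable.

Confidence intervals are percentile bootstrap over groups resampled with
replacement, seeded, B ≥ 100 enforced. Constant or unestimable resamples
carry no ICC information and are dropped rather than scored zero; if all
resamples degenerate, the point estimate is returned as both bounds.

## Synthetic rater model

The generator emulates the study conditions of a two-survey exercise:
defaults of 18 raters × 24 specimens and the packaged 48-term catalog.

- **Truth**: specimen s shows trait t with probability
  expit(logit(πₜ) + bₛ), bₛ ~ N(0, σ²_specimen). Default prevalences are
  spread evenly over [0.05, 0.5] across the catalog — deterministic, and
  matching the real situation where some malformations are common and some
  rare. σ_specimen defaults to 0.5 (some larvae visibly worse than others).
- **Detection**: rater r detects a true trait with probability
  expit(logit(sens) + aᵣ + bₛ), aᵣ ~ N(0, σ²_rater), and false-alarms at
  1 − specificity. Defaults sens = 0.85, spec = 0.98, σ_rater = 0.5 — an
  attentive but imperfect panel; sensitivity and specificity accept
  per-rater vectors. Each survey is an independent annotation pass over the
  same truth.
- **Survey 1 reporting**: with probability `p_general` (default 0.3) the
  rater reports at the general level; the verbatim string is drawn from the
  rater's *idiolect* — a per-rater favorite subset (default size 3) of the
  trait's synonym pool, sampled once per rater — so terminology
  heterogeneity arises between raters, as between laboratories, not within
  one rater's output. Synonym pools are generated deterministically from
  trait labels with geometrically decaying weights.
- **Survey 2 reporting**: the trait's CURIE, with a small `choice_error`
  (default 0.05) probability of substituting the general parent — modelling
  raters who could not find their precise term in the provided list.

By construction every Survey-1 string is a lexicon key (zero UNMAPPED), and
the logit-additive random effects give tunable ground-truth ICC for
recovery tests. The generator does **not** model image content, chemical
exposure, dose–response, rater learning between surveys, or correlated
trait co-occurrence; passing tests therefore validate the statistical
pipeline, not biological realism of any particular survey.

## Problem sizes and numerical choices

The test suite and acceptance script use: exhaustive Fisher validation over
all 46,376 tables with N ≤ 30 against an independent reference; ICC recovery
at 200 groups × 20 observations × 20 replicates per generative value
(ICC ∈ {0, 0.3, 0.6}), with beta-binomial group probabilities Beta(a, a),
a = (1/ρ − 1)/2, whose binary-scale intraclass correlation is exactly ρ;
bootstrap CIs at B = 200 in tests and B = 1000 by default. Simulated
surveys in tests use 4–18 raters and 6–24 specimens. These sizes make the
default runs complete in well under a minute while keeping Monte-Carlo
error far inside the asserted tolerances.

## Known limitations

- The two-level hierarchy cannot express deeper ZP structure; terms mapped
  at intermediate depth must be curated to one of the two levels.
- Exact-match mapping means spelling variants absent from the lexicon land
  in the curation queue; coverage is only as good as the lexicon.
- The ANOVA ICC on binary data is a linear-model approximation; its values
  are attenuation-prone at extreme prevalence relative to latent-scale
  (GLMM) repeatability estimates.
- Fisher tests on per-unit 2×2 tables treat cells as independent; cells
  from the same specimen are not, so p-values are descriptive flags rather
  than strict error-rate guarantees — one reason raw p-values are reported
  with BH adjustment only as an optional column.
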