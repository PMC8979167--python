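# phenoconcord

Does giving raters a controlled phenotype vocabulary make their annotations
more consistent than free text? `phenoconcord` is a pipeline for answering
that question in multi-rater malformation-annotation exercises, such as
zebrafish (*Danio rerio*) larval toxicology screens where each participating
laboratory describes the same images in its own vocabulary ("C-tail",
"bent tail", "abnormal tail curvature" for one and the same endpoint).

It is built for a two-survey design: in Survey 1 raters annotate specimens
with free text; in Survey 2 the same raters annotate the same specimens from
a fixed list of Zebrafish Phenotype Ontology (ZP) terms, identified by
CURIEs such as `ZP:0001129` (*abnormal tail*). The package provides:

- **Term harmonization** — normalization of verbatim strings, exact-match
  mapping to granular ZP CURIEs through a curated lexicon, and roll-up to
  general traits through a two-level hierarchy (e.g. *abnormally curved
  tail* → *abnormal tail*). Unmappable strings are surfaced in a curation
  queue, never guessed at or dropped.
- **Heterogeneity metrics** — per trait *g* with `U_g` unique verbatim
  strings, `T_g` total tags and `C_g` granular children:
  `terms per tag = U_g / T_g` (> 0.5 heterogeneous, < 0.15 homogeneous) and
  `terms per trait = U_g / (1 + C_g)`.
- **Majority-vote concordance** — a rater's annotation of trait *t* on
  specimen *s* is concordant when its 0/1 presence equals the strict
  majority call over raters; means are grouped by rater, specimen or trait,
  and between-survey change per unit is tested with a two-sided Fisher
  exact test on `[[concordant₁, discordant₁], [concordant₂, discordant₂]]`
  (implemented in exact integer arithmetic).
- **Repeatability** — one-way random-effects intraclass correlation
  ICC(1) = σ²_between / (σ²_between + σ²_within) of the binary concordance
  data with specimen, trait or rater as the grouping factor, with seeded
  group-bootstrap confidence intervals.
- **A synthetic rater simulator** — per-specimen true trait sets,
  per-rater sensitivity/specificity with logit-scale rater and specimen
  random effects, per-rater synonym idiolects and a general-vs-granular
  reporting preference, so the whole pipeline is testable end to end with
  known ground truth.

## Worked example

```python
import phenoconcord as pc

sim = pc.generate(pc.SimConfig(seed=8))  # 18 raters x 24 specimens, 48-term catalog
res = pc.run_analysis(sim.survey1, sim.survey2, sim.lexicon, sim.hierarchy)

for level in ("general", "granular"):
    m1 = res.mean_by[(level, "S1", "rater")]
    m2 = res.mean_by[(level, "S2", "rater")]
    print(f"{level:8s} rater mean concordance: "
          f"{100*m1.table['mean'].mean():.1f}% +/- {100*m1.sd_across_groups:.1f}% (S1) -> "
          f"{100*m2.table['mean'].mean():.1f}% +/- {100*m2.sd_across_groups:.1f}% (S2)")

change = res.change[("general", "rater_trait")]
sig = change[change["p_value"] < 0.05]
print(f"significant per-(rater, trait) concordance changes: {len(sig)} of {len(change)}")
```

prints

```
general  rater mean concordance: 91.3% +/- 3.5% (S1) -> 91.3% +/- 2.7% (S2)
granular rater mean concordance: 81.8% +/- 2.0% (S1) -> 89.5% +/- 2.4% (S2)
significant per-(rater, trait) concordance changes: 0 of 378
```

Read: at the general trait level the free-text survey was already quite
concordant and the controlled vocabulary mainly tightened the across-rater
spread (±3.5% → ±2.7%); at the granular level — where free-text phrasing
must be interpreted before it can be compared — the controlled vocabulary
raised mean concordance by almost 8 points. No single (rater, trait) unit
changed significantly over only 24 specimens, which is why survey-level
summaries, not per-cell stars, carry the message.

The same analyses are available from the shell:

```sh
phenoconcord simulate --seed 8 --out-dir sim/
phenoconcord map        --survey1 sim/survey1.tsv --survey2 sim/survey2.tsv \
                        --lexicon sim/lexicon.tsv --hierarchy sim/hierarchy.tsv
phenoconcord summarize  ... # trait_summary.tsv: the per-trait heterogeneity table
phenoconcord concordance ...# cells, grouped means, change tests (TSV)
phenoconcord icc        ... # 2 granularities x 3 factors x 2 surveys ICC table
```

All inputs and outputs are plain TSV; survey tables are tidy
(`rater  specimen  term`, one row per tag). The package ships the published
worked-example lexicon for the *abnormal tail* trait (32 verbatim strings →
4 CURIEs), the 48-term two-level trait catalog (21 general + 27 granular),
and the published per-trait count table used to validate the heterogeneity
metrics.

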