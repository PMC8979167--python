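"""Terminology-heterogeneity metrics per general trait.

Two normalized counts summarize how consistently a trait was described:

* terms per tag — unique verbatim strings divided by total annotations of
  the trait (and its granular children). Near 1 means nearly every mention
  used a different string; near 0 means raters converged on shared wording.
* terms per trait — unique verbatim strings divided by the number of trait
  categories involved (the general trait plus its granular children).

A trait with terms-per-tag above 0.5 is classed heterogeneous, below 0.15
homogeneous, otherwise intermediate. Reported values use half-up rounding on
the exact integer ratio (so 7/40 = 0.175 prints as 0.18), matching the
convention of the published summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .harmonize import UNMAPPED, TraitHierarchy

HETEROGENEOUS = "heterogeneous"
INTERMEDIATE = "intermediate"
HOMOGENEOUS = "homogeneous"


class UndefinedMetricError(ValueError):
    """A ratio's denominator is zero or an argument is out of range."""


def _half_up(numerator: int, denominator: int, places: str) -> Decimal:
    # exact rational division, then decimal half-up: float quotients would
    # misround exact halves like 7/40.
    return (Decimal(numerator) / Decimal(denominator)).quantize(
        Decimal(places), rounding=ROUND_HALF_UP
    )


def terms_per_tag(unique_terms: int, total_tags: int) -> float:
    """unique_terms / total_tags, half-up to 2 decimals."""
    if total_tags < 1 or unique_terms < 1:
        raise UndefinedMetricError(
            f"need unique_terms >= 1 and total_tags >= 1, got "
            f"({unique_terms}, {total_tags})"
        )
    return float(_half_up(unique_terms, total_tags, "0.01"))


def terms_per_trait(unique_terms: int, child_traits: int) -> int:
    """unique_terms / (general + children), half-up to an integer."""
    if unique_terms < 1 or child_traits < 0:
        raise UndefinedMetricError(
            f"need unique_terms >= 1 and child_traits >= 0, got "
            f"({unique_terms}, {child_traits})"
        )
    return int(_half_up(unique_terms, 1 + child_traits, "1"))


def classify_heterogeneity(tpt: float) -> str:
    """>0.5 heterogeneous, <0.15 homogeneous, boundaries intermediate."""
    if not 0 < tpt <= 1:
        raise UndefinedMetricError(f"terms-per-tag must be in (0, 1], got {tpt}")
    if tpt > 0.5:
        return HETEROGENEOUS
    if tpt < 0.15:
        return HOMOGENEOUS
    return INTERMEDIATE


@dataclass(frozen=True)
class TraitSummary:
    """One per-trait row of a survey heterogeneity summary."""

    trait: str
    label: str
    total_tags: int
    unique_terms: int
    child_traits: int
    n_specimens: int
    terms_per_tag: float
    terms_per_trait: int
    het_class: str


def summarize_survey(
    harmonized: pd.DataFrame,
    hierarchy: TraitHierarchy,
    *,
    level: str = "general",
    raw_uniques: bool = False,
) -> pd.DataFrame:
    """Per-trait tag/term/specimen counts and heterogeneity metrics.

    Counts run over all raters and specimens of one harmonized survey table.
    At the default general level a tag of a granular child counts toward its
    general parent, and ``child_traits`` is the number of distinct granular
    children observed. Uniqueness of verbatim strings is counted on
    normalized text unless ``raw_uniques`` is set. UNMAPPED records are
    excluded (they belong to no trait).

    Parameters
    ----------
    level
        ``"general"`` or ``"granular"`` — which trait column to group on.
    """
    if level not in ("general", "granular"):
        raise ValueError(f"level must be 'general' or 'granular', got {level!r}")
    df = harmonized[harmonized["granular"] != UNMAPPED]
    term_col = "term" if raw_uniques else "normalized"
    rows = []
    for trait, grp in df.groupby(level, sort=True):
        observed_children = {
            g for g in grp["granular"] if g != trait
        } if level == "general" else set()
        uniq = grp[term_col].nunique()
        tpt = terms_per_tag(uniq, len(grp))
        # classify on the exact ratio: the 2-dp report value can round to 0.00
        raw_ratio = uniq / len(grp)
        rows.append(
            TraitSummary(
                trait=trait,
                label=hierarchy.labels.get(trait, ""),
                total_tags=len(grp),
                unique_terms=uniq,
                child_traits=len(observed_children),
                n_specimens=grp["specimen"].nunique(),
                terms_per_tag=tpt,
                terms_per_trait=terms_per_trait(uniq, len(observed_children)),
                het_class=classify_heterogeneity(raw_ratio),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def recompute_printed_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute terms-per-tag/-per-trait from a published count table.

    Input columns: ``total_tags``, ``unique_terms``, ``child_traits`` (blank
    allowed, meaning the metric was not printed). Returns the input plus
    ``tpt_recomputed`` and ``tptrait_recomputed`` columns as strings formatted
    at printed precision, empty where the source cell is blank.
    """
    out = counts.copy()
    tpt, tptrait = [], []
    for row in counts.itertuples(index=False):
        total = int(row.total_tags)
        uniq = int(row.unique_terms)
        tpt.append(f"{terms_per_tag(uniq, total):.2f}")
        if str(row.child_traits).strip() == "" or str(row.terms_per_trait).strip() == "":
            tptrait.append("")
        else:
            tptrait.append(str(terms_per_trait(uniq, int(row.child_traits))))
    out["tpt_recomputed"] = tpt
    out["tptrait_recomputed"] = tptrait
    return out
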