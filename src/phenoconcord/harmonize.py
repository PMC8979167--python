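"""Free-text normalization, lexicon mapping, and general/granular roll-up.

Raters describe the same malformation with many different strings ("C-tail",
"bent tail", "abnormal tail curvature"). A curated lexicon maps each
normalized verbatim string to the most specific ontology term available
(granular CURIE), and a two-level hierarchy rolls every granular term up to
its general parent ("abnormally curved tail" -> "abnormal tail"). Lookups are
exact-match after normalization only; anything not in the lexicon is surfaced
as UNMAPPED in a curation queue rather than guessed at or dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import SurveyTable, ValidationError, is_curie

logger = logging.getLogger(__name__)

#: Sentinel for a verbatim string absent from the lexicon. A value, not an error.
UNMAPPED = "UNMAPPED"

_WS_RE = re.compile(r"\s+")
_TRAILING_PUNCT_RE = re.compile(r"[.!?;:,]+$")


def normalize_term(text: str) -> str:
    """Case-fold, trim, collapse internal whitespace, strip trailing punctuation.

    Idempotent; empty input yields empty output. Internal punctuation such as
    hyphens is preserved ("C-tail" -> "c-tail").
    """
    text = _WS_RE.sub(" ", text.strip()).casefold()
    return _TRAILING_PUNCT_RE.sub("", text).strip()


@dataclass
class TraitHierarchy:
    """Two-level granular -> general trait map.

    General terms are self-parented; special status categories (``normal``,
    ``hatched``) are CURIE-less pseudo-traits that also map to themselves.
    """

    parent: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)
    #: CURIE-less pseudo-traits carried through all statistics.
    specials: frozenset[str] = frozenset({"normal", "hatched"})
    #: status categories outside the trait catalog proper (e.g. "hatched").
    non_catalog: frozenset[str] = frozenset({"hatched"})

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if par not in self.parent:
                raise ValidationError(f"general parent {par!r} of {child!r} not listed")
            if self.parent[par] != par:
                raise ValidationError(
                    f"{par!r} is a parent but not self-parented (depth must be <= 1)"
                )

    @property
    def generals(self) -> set[str]:
        return {t for t, p in self.parent.items() if t == p}

    @property
    def granulars(self) -> set[str]:
        return {t for t, p in self.parent.items() if t != p}

    @property
    def catalog_generals(self) -> set[str]:
        return self.generals - self.non_catalog

    @property
    def catalog_granulars(self) -> set[str]:
        return self.granulars - self.non_catalog

    def children(self, general: str) -> set[str]:
        """Granular children of a general trait (excluding itself)."""
        return {t for t, p in self.parent.items() if p == general and t != general}

    def __contains__(self, curie: str) -> bool:
        return curie in self.parent

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitHierarchy":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        parent = dict(zip(df["granular_curie"], df["general_curie"]))
        labels = dict(zip(df["granular_curie"], df.get("label", "")))
        non_catalog = frozenset(
            df.loc[df.get("provenance", "") == "special", "granular_curie"]
        )
        specials = non_catalog | frozenset(
            t for t in parent if not is_curie(t)
        )
        return cls(parent=parent, labels=labels, specials=specials,
                   non_catalog=non_catalog)


@dataclass
class TermLexicon:
    """Normalized verbatim string -> granular (or general) CURIE map."""

    entries: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k in self.entries if normalize_term(k) != k]
        if bad:
            raise ValidationError(f"lexicon keys not normalized: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, hierarchy: TraitHierarchy) -> None:
        missing = sorted(set(self.entries.values()) - set(hierarchy.parent))
        if missing:
            raise ValidationError(f"lexicon CURIEs absent from hierarchy: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermLexicon":
        """Load a ``verbatim<TAB>curie<TAB>provenance`` file.

        Raw verbatim strings are normalized on load; rows that collapse to
        the same key must agree on the target CURIE.
        """
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        entries: dict[str, str] = {}
        provenance: dict[str, str] = {}
        for row in df.itertuples(index=False):
            key = normalize_term(row.verbatim)
            if key in entries and entries[key] != row.curie:
                raise ValidationError(
                    f"conflicting lexicon targets for {key!r}: "
                    f"{entries[key]} vs {row.curie}"
                )
            entries[key] = row.curie
            provenance[key] = getattr(row, "provenance", "")
        return cls(entries=entries, provenance=provenance)

    def collapsed_to_general(self, hierarchy: TraitHierarchy) -> "TermLexicon":
        """A copy whose targets are rolled up to general terms."""
        return TermLexicon(
            entries={k: generalize(v, hierarchy) for k, v in self.entries.items()},
            provenance=dict(self.provenance),
        )


def map_verbatim(text: str, lexicon: TermLexicon) -> str:
    """Exact lookup of the normalized string; returns UNMAPPED when absent."""
    return lexicon.entries.get(normalize_term(text), UNMAPPED)


def generalize(curie: str, hierarchy: TraitHierarchy) -> str:
    """General parent of a granular term; general terms return themselves.

    Raises
    ------
    KeyError
        for a CURIE the hierarchy does not know.
    """
    try:
        return hierarchy.parent[curie]
    except KeyError:
        raise KeyError(f"CURIE {curie!r} not in trait hierarchy") from None


def harmonize_table(
    table: SurveyTable,
    lexicon: TermLexicon,
    hierarchy: TraitHierarchy,
) -> pd.DataFrame:
    """Annotate every record with granular and general trait columns.

    Survey-1 verbatim strings go through the lexicon (UNMAPPED preserved);
    Survey-2 CURIEs are validated against the hierarchy and pass through.
    Row count is conserved: unmappable records stay, flagged UNMAPPED.

    Returns the table's frame with added columns ``normalized``, ``granular``
    and ``general``.
    """
    df = table.df.copy()
    df["normalized"] = df["term"].map(normalize_term)
    if table.survey_id == "S1":
        df["granular"] = df["normalized"].map(
            lambda t: lexicon.entries.get(t, UNMAPPED)
        )
    else:
        unknown = sorted(
            set(df["term"]) - set(hierarchy.parent)
        )
        if unknown:
            raise ValidationError(
                f"Survey-2 CURIEs absent from trait hierarchy: {unknown}"
            )
        df["granular"] = df["term"]
    df["general"] = [
        g if g == UNMAPPED else generalize(g, hierarchy) for g in df["granular"]
    ]
    n_unmapped = int((df["granular"] == UNMAPPED).sum())
    if n_unmapped:
        logger.warning(
            "survey %s: %d records unmapped (kept, flagged UNMAPPED)",
            table.survey_id, n_unmapped,
        )
    return df


def curation_queue(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Distinct unmapped strings with usage counts, for human curation."""
    un = harmonized[harmonized["granular"] == UNMAPPED]
    out = (
        un.groupby("normalized")
        .agg(n_uses=("term", "size"), example=("term", "first"))
        .reset_index()
        .sort_values("n_uses", ascending=False)
    )
    return out.reset_index(drop=True)


def _data_path(name: str):
    return resources.files("phenoconcord.data").joinpath(name)


def load_packaged_lexicon() -> TermLexicon:
    """The lexicon shipped with the package (published tail rows + specials)."""
    with resources.as_file(_data_path("lexicon.tsv")) as p:
        return TermLexicon.from_tsv(p)


def load_packaged_hierarchy() -> TraitHierarchy:
    """The packaged 48-term trait catalog (21 general + 27 granular)."""
    with resources.as_file(_data_path("hierarchy.tsv")) as p:
        return TraitHierarchy.from_tsv(p)


def load_survey1_trait_counts() -> pd.DataFrame:
    """The published Survey-1 per-trait count table (counts + printed metrics)."""
    with resources.as_file(_data_path("survey1_trait_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
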