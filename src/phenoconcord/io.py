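"""Reading, validation and writing of long-format survey annotation tables.

A survey table is tidy: one row per (survey, rater, specimen, term) tag.
Survey 1 terms are free-text endpoint phrases as raters typed them; Survey 2
terms are ontology identifiers in CURIE form (e.g. ``ZP:0001129``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SURVEY_IDS = ("S1", "S2")

#: CURIE syntax: alphanumeric prefix, colon, non-blank local identifier.
CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:\S+$")

#: Special status categories recorded without a malformation CURIE.
SPECIAL_TERMS = frozenset({"normal", "dead", "hatched"})

REQUIRED_COLUMNS = ("rater", "specimen", "term")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table violates a content rule (e.g. malformed CURIE)."""


def is_curie(term: str) -> bool:
    return bool(CURIE_RE.match(term))


@dataclass(frozen=True)
class AnnotationRecord:
    """One rater's one tag on one specimen in one survey."""

    survey_id: str
    rater_id: str
    specimen_id: str
    verbatim: str = ""
    curie: str = ""
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.survey_id not in SURVEY_IDS:
            raise ValidationError(f"unknown survey_id {self.survey_id!r}")
        if bool(self.verbatim) == bool(self.curie):
            raise ValidationError(
                "exactly one of verbatim/curie must be non-empty "
                f"(got verbatim={self.verbatim!r}, curie={self.curie!r})"
            )
        if self.curie and not is_curie(self.curie):
            raise ValidationError(f"malformed CURIE {self.curie!r}")

    @property
    def term(self) -> str:
        return self.curie or self.verbatim


@dataclass
class SurveyTable:
    """A validated, de-duplicated collection of annotation records.

    ``df`` holds columns ``survey``, ``rater``, ``specimen``, ``term`` with
    one row per distinct tag. Duplicated (rater, specimen, term) rows are
    collapsed at construction with a logged warning.
    """

    survey_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.survey_id not in SURVEY_IDS:
            raise ValidationError(f"unknown survey_id {self.survey_id!r}")
        df = self.df.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        df["survey"] = self.survey_id
        df = df[["survey", "rater", "specimen", "term"]].astype(str)
        n_before = len(df)
        df = df.drop_duplicates(subset=["rater", "specimen", "term"])
        n_dup = n_before - len(df)
        if n_dup:
            logger.warning(
                "survey %s: collapsed %d duplicated (rater, specimen, term) rows",
                self.survey_id, n_dup,
            )
        self.df = df.reset_index(drop=True)

    @property
    def records(self) -> list[AnnotationRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            if self.survey_id == "S1":
                out.append(AnnotationRecord("S1", row.rater, row.specimen, verbatim=row.term))
            else:
                out.append(AnnotationRecord("S2", row.rater, row.specimen, curie=row.term))
        return out

    @property
    def raters(self) -> set[str]:
        return set(self.df["rater"])

    @property
    def specimens(self) -> set[str]:
        return set(self.df["specimen"])

    def __len__(self) -> int:
        return len(self.df)

    def restrict_to_raters(self, raters: set[str]) -> "SurveyTable":
        """Return a new table containing only the given raters' records."""
        sub = self.df[self.df["rater"].isin(raters)].reset_index(drop=True)
        return SurveyTable(self.survey_id, sub)


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)


def read_survey(
    path: str | Path,
    survey_id: str,
    *,
    split_cells: bool = False,
) -> SurveyTable:
    """Read a long-format annotation table (TSV default, CSV by extension).

    Blank terms are dropped with the count logged. With ``split_cells``,
    multi-term cells are split on semicolons and commas (off by default:
    Survey-1 free text may legitimately contain commas inside one phrase).

    Raises
    ------
    SchemaError
        if a required column (rater, specimen, term) is absent.
    ValidationError
        if a Survey-2 file contains a term that is not CURIE-shaped.
    """
    df = _read_frame(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if "survey" in df.columns:
        foreign = df[(df["survey"] != "") & (df["survey"] != survey_id)]
        if len(foreign):
            logger.warning(
                "%s: dropping %d rows from other surveys", path, len(foreign)
            )
            df = df[(df["survey"] == "") | (df["survey"] == survey_id)]
    df = df[list(REQUIRED_COLUMNS)].copy()
    df["term"] = df["term"].str.strip()
    if split_cells:
        df = df.assign(term=df["term"].str.split(r"[;,]")).explode("term")
        df["term"] = df["term"].str.strip()
        logger.info("%s: multi-term cells split on ;/,", path)
    n_blank = int((df["term"] == "").sum())
    if n_blank:
        logger.warning("%s: dropped %d blank-term rows", path, n_blank)
        df = df[df["term"] != ""]
    if survey_id == "S2":
        bad = df[~df["term"].map(is_curie) & ~df["term"].isin(SPECIAL_TERMS)]
        if len(bad):
            rows = ", ".join(
                f"(rater={r.rater}, specimen={r.specimen}, term={r.term!r})"
                for r in bad.head(20).itertuples(index=False)
            )
            raise ValidationError(
                f"{path}: {len(bad)} Survey-2 terms are not CURIEs: {rows}"
            )
    return SurveyTable(survey_id, df.reset_index(drop=True))


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey table as TSV (or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.df.to_csv(path, sep=sep, index=False)


def paired_raters(s1: SurveyTable, s2: SurveyTable) -> set[str]:
    """Raters that took both surveys; only these enter the analysis.

    Raises
    ------
    ValidationError
        if no rater appears in both tables.
    """
    common = s1.raters & s2.raters
    if not common:
        raise ValidationError("no rater appears in both surveys")
    return common
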