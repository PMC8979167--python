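"""End-to-end wiring of the analysis stages for a pair of surveys."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import concordance as conc
from .harmonize import TermLexicon, TraitHierarchy, harmonize_table
from .io import SurveyTable, paired_raters
from .repeatability import icc_table


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one survey pair."""

    harmonized: dict[str, pd.DataFrame]
    cells: dict[tuple[str, str], pd.DataFrame]  # (level, survey) -> cells
    mean_by: dict[tuple[str, str, str], conc.MeanConcordance]
    change: dict[tuple[str, str], pd.DataFrame]  # (level, unit) -> table
    icc: pd.DataFrame = field(default=None)


def run_analysis(
    s1: SurveyTable,
    s2: SurveyTable,
    lexicon: TermLexicon,
    hierarchy: TraitHierarchy,
    *,
    levels: tuple[str, ...] = ("general", "granular"),
    change_unit: str = "rater_trait",
    universe: str = "observed",
    with_icc: bool = True,
) -> AnalysisResult:
    """Harmonize, score concordance at each trait level, test change, and
    estimate repeatability, restricted to raters who took both surveys.

    ``universe`` is ``"observed"`` (score only (specimen, trait) pairs tagged
    by someone in some survey) or ``"all"`` (score every pair).
    """
    raters = sorted(paired_raters(s1, s2))
    s1 = s1.restrict_to_raters(set(raters))
    s2 = s2.restrict_to_raters(set(raters))
    h1 = harmonize_table(s1, lexicon, hierarchy)
    h2 = harmonize_table(s2, lexicon, hierarchy)

    from .harmonize import UNMAPPED

    cells: dict[tuple[str, str], pd.DataFrame] = {}
    mean_by = {}
    change = {}
    for level in levels:
        mapped = pd.concat([h1, h2])
        mapped = mapped[mapped[level] != UNMAPPED]
        specimens = sorted(mapped["specimen"].unique())
        traits = sorted(mapped[level].unique())
        m1 = conc.presence_matrix(
            h1, level, raters=raters, specimens=specimens, traits=traits
        )
        m2 = conc.presence_matrix(
            h2, level, raters=raters, specimens=specimens, traits=traits
        )
        mask = conc.observed_universe(m1, m2) if universe == "observed" else None
        c1 = conc.concordance_cells(m1, mask)
        c2 = conc.concordance_cells(m2, mask)
        cells[(level, "S1")] = c1
        cells[(level, "S2")] = c2
        for survey, cc in (("S1", c1), ("S2", c2)):
            for grouping in conc.MEAN_GROUPINGS:
                mean_by[(level, survey, grouping)] = conc.mean_concordance(cc, grouping)
        change[(level, change_unit)] = conc.concordance_change(c1, c2, change_unit)

    icc = icc_table(cells) if with_icc else None
    return AnalysisResult(
        harmonized={"S1": h1, "S2": h2},
        cells=cells,
        mean_by=mean_by,
        change=change,
        icc=icc,
    )
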