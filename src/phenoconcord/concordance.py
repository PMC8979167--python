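"""Majority-vote concordance and between-survey concordance change.

For every (specimen, trait, survey) cell, the majority call is 1 when
strictly more than half of the raters tagged that trait on that specimen. A
rater's annotation is concordant when it equals the majority call — note
that *not* tagging an un-majority trait is itself a concordant act, which is
why the universe of (specimen, trait) columns matters: by default it is
restricted to pairs tagged by at least one rater in at least one survey, so
concordance is not inflated by universal mutual absence of never-used terms.

Between-survey change per unit (rater x trait by default) is the count of
concordant cells in Survey 2 minus Survey 1, with a two-sided Fisher exact
test on the 2x2 table [[concordant_1, discordant_1], [concordant_2,
discordant_2]].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MEAN_GROUPINGS = ("rater", "specimen", "trait")
CHANGE_UNITS = ("rater_trait", "rater", "trait")


@dataclass
class PresenceMatrix:
    """Binary rater x specimen x trait presence tensor for one survey."""

    survey_id: str
    trait_level: str
    raters: list[str]
    specimens: list[str]
    traits: list[str]
    values: np.ndarray = field(repr=False)  # (R, S, T) uint8

    def __post_init__(self) -> None:
        expected = (len(self.raters), len(self.specimens), len(self.traits))
        if self.values.shape != expected:
            raise ValueError(f"shape {self.values.shape} != axes {expected}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence cells must be 0/1")

    def cell(self, rater: str, specimen: str, trait: str) -> int:
        return int(
            self.values[
                self.raters.index(rater),
                self.specimens.index(specimen),
                self.traits.index(trait),
            ]
        )


def presence_matrix(
    harmonized: pd.DataFrame,
    level: str = "general",
    *,
    raters: list[str] | None = None,
    specimens: list[str] | None = None,
    traits: list[str] | None = None,
) -> PresenceMatrix:
    """Build the binary presence tensor from a harmonized survey table.

    Axis orders may be supplied explicitly so that the two surveys share
    axes; otherwise they are the sorted distinct values observed. UNMAPPED
    records are excluded.
    """
    from .harmonize import UNMAPPED

    df = harmonized[harmonized[level] != UNMAPPED]
    if not len(df):
        raise ValueError("empty harmonized table")
    raters = sorted(df["rater"].unique()) if raters is None else list(raters)
    specimens = sorted(df["specimen"].unique()) if specimens is None else list(specimens)
    traits = sorted(df[level].unique()) if traits is None else list(traits)
    r_ix = {r: i for i, r in enumerate(raters)}
    s_ix = {s: i for i, s in enumerate(specimens)}
    t_ix = {t: i for i, t in enumerate(traits)}
    values = np.zeros((len(raters), len(specimens), len(traits)), dtype=np.uint8)
    for row in df.itertuples(index=False):
        tr = getattr(row, level)
        if row.rater in r_ix and row.specimen in s_ix and tr in t_ix:
            values[r_ix[row.rater], s_ix[row.specimen], t_ix[tr]] = 1
    survey = df["survey"].iloc[0]
    return PresenceMatrix(survey, level, raters, specimens, traits, values)


def observed_universe(*matrices: PresenceMatrix) -> np.ndarray:
    """Boolean (S, T) mask of columns tagged by >=1 rater in >=1 survey."""
    masks = [m.values.any(axis=0) for m in matrices]
    out = masks[0]
    for m in masks[1:]:
        out = out | m
    return out


def majority_call(
    matrix: PresenceMatrix, specimen: str, trait: str
) -> int:
    """1 iff strictly more than half of raters tagged the cell; ties -> 0."""
    if len(matrix.raters) < 2:
        raise ValueError("majority needs >= 2 raters")
    col = matrix.values[:, matrix.specimens.index(specimen), matrix.traits.index(trait)]
    k, n = int(col.sum()), len(col)
    if 2 * k == n and k > 0:
        logger.info(
            "majority tie (%d/%d) at specimen=%s trait=%s: resolved to absent",
            k, n, specimen, trait,
        )
    return int(2 * k > n)


def concordance_cells(
    matrix: PresenceMatrix,
    universe: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binary agreement of each rater with the majority, per (specimen, trait).

    ``universe`` is an optional boolean (S, T) mask restricting which columns
    are scored (typically :func:`observed_universe` over both surveys).
    Returns one row per (rater, specimen, trait) with a 0/1 ``concordant``
    column. Majority ties resolve to absent and are counted in the log.
    """
    v = matrix.values
    n_raters = v.shape[0]
    if n_raters < 2:
        raise ValueError("concordance needs >= 2 raters")
    k = v.sum(axis=0)  # (S, T) positive counts
    maj = (2 * k > n_raters).astype(np.uint8)
    n_ties = int(((2 * k == n_raters) & (k > 0)).sum())
    if n_ties:
        logger.info(
            "survey %s: %d (specimen, trait) majority ties resolved to absent",
            matrix.survey_id, n_ties,
        )
    conc = (v == maj[None, :, :]).astype(np.uint8)
    if universe is None:
        universe = np.ones(k.shape, dtype=bool)
    s_idx, t_idx = np.nonzero(universe)
    rows = []
    for r_i, rater in enumerate(matrix.raters):
        rows.append(
            pd.DataFrame(
                {
                    "rater": rater,
                    "specimen": np.asarray(matrix.specimens)[s_idx],
                    "trait": np.asarray(matrix.traits)[t_idx],
                    "survey": matrix.survey_id,
                    "concordant": conc[r_i, s_idx, t_idx],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class MeanConcordance:
    """Per-group mean concordance with its across-group dispersion."""

    group_by: str
    table: pd.DataFrame  # columns: group, mean, n
    pooled_mean: float
    sd_across_groups: float


def mean_concordance(cells: pd.DataFrame, group_by: str) -> MeanConcordance:
    """Group means of the binary concordance cells.

    ``sd_across_groups`` is the sample standard deviation of the per-group
    means (the scale on which survey-level rater spread is quoted); the
    pooled mean is the grand mean over all cells.
    """
    if group_by not in MEAN_GROUPINGS:
        raise ValueError(f"group_by must be one of {MEAN_GROUPINGS}, got {group_by!r}")
    if not len(cells):
        raise ValueError("no concordance cells")
    tab = (
        cells.groupby(group_by)["concordant"]
        .agg(mean="mean", n="size")
        .reset_index()
        .rename(columns={group_by: "group"})
    )
    sd = float(tab["mean"].std(ddof=1)) if len(tab) > 1 else 0.0
    return MeanConcordance(
        group_by=group_by,
        table=tab,
        pooled_mean=float(cells["concordant"].mean()),
        sd_across_groups=sd,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities (margins fixed) of all tables at most
    as probable as the observed one. Computed in exact integer arithmetic:
    every table in the support shares the denominator C(n, c1), so the
    comparison "p(x) <= p(observed)" reduces to comparing integer
    numerators, with no floating-point tie ambiguity. A zero margin yields
    p = 1.0 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        x != int(x) for x in (a, b, c, d)
    ):
        raise ValueError(f"table entries must be nonnegative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    acc = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            acc += num
    return min(1.0, acc / total)


def concordance_change(
    cells_s1: pd.DataFrame,
    cells_s2: pd.DataFrame,
    unit: str = "rater_trait",
    *,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Per-unit change in concordant-cell counts between surveys.

    ``delta`` is Survey-2 concordant count minus Survey-1; with one trait per
    unit it ranges over +/- the number of specimens. The p-value is the
    two-sided Fisher exact test of the concordant/discordant 2x2 table; a
    Benjamini-Hochberg ``q_value`` column is appended unless disabled.
    """
    if unit not in CHANGE_UNITS:
        raise ValueError(f"unit must be one of {CHANGE_UNITS}, got {unit!r}")
    keys = ["rater", "trait"] if unit == "rater_trait" else [unit]
    for frame_name, s1_vals, s2_vals in (
        ("raters", set(cells_s1["rater"]), set(cells_s2["rater"])),
        ("specimens", set(cells_s1["specimen"]), set(cells_s2["specimen"])),
        ("traits", set(cells_s1["trait"]), set(cells_s2["trait"])),
    ):
        if s1_vals != s2_vals:
            raise ValueError(f"survey {frame_name} axes differ: cannot compare")
    g1 = cells_s1.groupby(keys)["concordant"].agg(["sum", "size"])
    g2 = cells_s2.groupby(keys)["concordant"].agg(["sum", "size"])
    joined = g1.join(g2, how="outer", lsuffix="_s1", rsuffix="_s2").fillna(0)
    rows = []
    for key, row in joined.iterrows():
        c1, n1 = int(row["sum_s1"]), int(row["size_s1"])
        c2, n2 = int(row["sum_s2"]), int(row["size_s2"])
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n_concordant_s1=c1,
            n_total_s1=n1,
            n_concordant_s2=c2,
            n_total_s2=n2,
            delta=c2 - c1,
            mean_s1=c1 / n1 if n1 else np.nan,
            mean_s2=c2 / n2 if n2 else np.nan,
            p_value=fisher_exact_2x2([[c1, n1 - c1], [c2, n2 - c2]]),
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def concordance_vs_heterogeneity(
    trait_means: pd.DataFrame, summary: pd.DataFrame
) -> dict[str, float]:
    """Correlate per-trait mean concordance with its heterogeneity drivers.

    ``trait_means`` is the table of a trait-grouped :func:`mean_concordance`;
    ``summary`` a trait summary with ``unique_terms`` and ``n_specimens``.
    Returns Pearson correlations of mean concordance against the number of
    unique terms and the number of specimens showing the trait.
    """
    merged = trait_means.merge(summary, left_on="group", right_on="trait")
    if len(merged) < 3:
        raise ValueError("need >= 3 traits in common to correlate")
    return {
        "r_concordance_unique_terms": pearson_r(merged["mean"], merged["unique_terms"]),
        "r_concordance_n_specimens": pearson_r(merged["mean"], merged["n_specimens"]),
    }
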