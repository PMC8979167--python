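"""Repeatability (intraclass correlation) of binary annotation data.

How much of the variance in agreement is explained by which larva was being
annotated, which endpoint, or which rater? Each grouping factor is assessed
separately with the one-way random-effects ANOVA estimator ICC(1) applied
directly to the 0/1 observations: with between- and within-group mean
squares MSB and MSW and effective group size k0,

    var_between = max(0, (MSB - MSW) / k0),   var_within = MSW,
    ICC = var_between / (var_between + var_within).

For unbalanced groups k0 = (N - sum(n_i^2)/N) / (g - 1). Negative
moment estimates of the between-group variance are truncated at zero, so
the ICC lies in [0, 1]. Confidence intervals come from a seeded percentile
bootstrap that resamples whole groups with replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPING_FACTORS = ("specimen", "trait", "rater")


@dataclass
class ICCEstimate:
    survey_id: str
    grouping_factor: str
    var_between: float
    var_within: float
    icc: float
    n_groups: int
    n_obs: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def _anova_components(values: np.ndarray, codes: np.ndarray):
    """(var_between, var_within, n_groups, n_obs) for one-way layout."""
    n_obs = len(values)
    group_sums = np.bincount(codes, weights=values)
    group_ns = np.bincount(codes)
    g = len(group_ns)
    grand = values.mean()
    group_means = group_sums / group_ns
    ssb = float((group_ns * (group_means - grand) ** 2).sum())
    ssw = float(((values - group_means[codes]) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (n_obs - g) if n_obs > g else 0.0
    k0 = (n_obs - (group_ns**2).sum() / n_obs) / (g - 1)
    var_between = max(0.0, (msb - msw) / k0)
    return var_between, msw, g, n_obs


def icc_anova(
    values,
    groups,
    *,
    survey_id: str = "",
    grouping_factor: str = "",
) -> ICCEstimate:
    """One-way random-effects ICC(1) point estimate.

    Parameters
    ----------
    values
        Numeric (typically 0/1) observations.
    groups
        Group label per observation.

    Raises
    ------
    ValueError
        with fewer than two groups, or no group holding >= 2 observations.
    """
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    if values.shape != codes.shape or values.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-d")
    if len(np.unique(codes)) < 2:
        raise ValueError("ICC needs >= 2 groups")
    if np.bincount(codes).max() < 2:
        raise ValueError("ICC needs >= 2 observations in at least one group")
    if np.ptp(values) == 0:
        warnings.warn("constant data: ICC set to 0", stacklevel=2)
        vb, vw, g, n = 0.0, 0.0, len(np.unique(codes)), len(values)
    else:
        vb, vw, g, n = _anova_components(values, codes)
    denom = vb + vw
    return ICCEstimate(
        survey_id=survey_id,
        grouping_factor=grouping_factor,
        var_between=vb,
        var_within=vw,
        icc=vb / denom if denom > 0 else 0.0,
        n_groups=g,
        n_obs=n,
    )


def icc_bootstrap_ci(
    values,
    groups,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ICC(1), resampling groups with replacement.

    Deterministic for a fixed seed. Requires ``n_boot >= 100``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    g = len(uniques)
    by_group = [values[codes == i] for i in range(g)]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, g, size=g)
        vals = np.concatenate([by_group[i] for i in pick])
        labels = np.repeat(np.arange(g), [len(by_group[i]) for i in pick])
        if np.ptp(vals) == 0 or np.bincount(labels).max() < 2:
            # a constant (or unestimable) resample carries no ICC information
            reps[b] = np.nan
            continue
        vb, vw, _, _ = _anova_components(vals, labels)
        reps[b] = vb / (vb + vw) if vb + vw > 0 else 0.0
    reps = reps[~np.isnan(reps)]
    if not len(reps):
        point = icc_anova(values, groups).icc
        return point, point
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def icc_table(
    cells_by_level: dict[tuple[str, str], pd.DataFrame],
    *,
    response: str = "concordant",
    ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ICC estimates for every granularity x grouping factor x survey cell.

    ``cells_by_level`` maps (granularity, survey_id) -> concordance-cell (or
    presence) frame with ``specimen``, ``trait``, ``rater`` columns and the
    binary ``response`` column. With two granularities and two surveys the
    output has the full 2 x 3 x 2 = 12 rows.
    """
    rows = []
    for (granularity, survey_id), cells in sorted(cells_by_level.items()):
        for factor in GROUPING_FACTORS:
            est = icc_anova(
                cells[response].to_numpy(),
                cells[factor].to_numpy(),
                survey_id=survey_id,
                grouping_factor=factor,
            )
            if ci:
                est.ci_low, est.ci_high = icc_bootstrap_ci(
                    cells[response].to_numpy(),
                    cells[factor].to_numpy(),
                    n_boot=n_boot,
                    seed=seed,
                )
            rows.append(
                {
                    "granularity": granularity,
                    "factor": factor,
                    "survey": survey_id,
                    "icc": est.icc,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "var_between": est.var_between,
                    "var_within": est.var_within,
                    "n_groups": est.n_groups,
                    "n_obs": est.n_obs,
                }
            )
    return pd.DataFrame(rows)
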