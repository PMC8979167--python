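"""Generative model of multi-rater phenotype annotation surveys.

The simulator emulates the structure of a two-survey annotation exercise:
a panel of raters (default 18) each examines the same specimens (default 24
larvae) twice. Each specimen carries a latent set of true traits drawn from
per-trait prevalences with a specimen-level random effect on the logit
scale. Each rater detects a true trait with a sensitivity shifted by a
rater-level logit random effect, and false-alarms on absent traits at
1 - specificity. In the free-text pass (Survey 1) the rater reports a
verbatim string drawn from a personal "idiolect" — a per-rater favorite
subset of the trait's synonym list — at either the granular or the general
level; in the controlled-vocabulary pass (Survey 2) the rater reports the
trait's CURIE, occasionally substituting the general parent for a granular
term (modelling an incomplete term list).

Because every synonym the simulator can emit is also written into the
emitted lexicon, harmonizing Survey 1 through that lexicon always yields
zero UNMAPPED records; heterogeneity then arises from between-rater
vocabulary differences, and the logit random effects give tunable
ground-truth repeatability for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .harmonize import TermLexicon, TraitHierarchy, normalize_term
from .io import SurveyTable


class SimConfigError(ValueError):
    """A simulation parameter is out of range."""


@dataclass(frozen=True)
class TraitSpec:
    """One annotatable trait: its CURIE, parent, and verbatim synonym pool."""

    curie: str
    label: str
    general: str  # == curie for general-level traits
    synonyms: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.synonyms) != len(self.weights) or not self.synonyms:
            raise SimConfigError(f"{self.curie}: synonyms/weights mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) < 0:
            raise SimConfigError(f"{self.curie}: weights must be a distribution")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-survey exercise.

    Defaults mirror the annotation exercise being emulated: 18 raters, 24
    specimens, and a 48-term two-level trait catalog. Probabilities are
    base rates before the logit-scale rater/specimen random effects.
    """

    n_raters: int = 18
    n_specimens: int = 24
    catalog: tuple[TraitSpec, ...] = ()
    prevalence: float | dict[str, float] | None = None
    #: scalar base rate, or one value per rater
    sensitivity: float | tuple[float, ...] = 0.85
    specificity: float | tuple[float, ...] = 0.98
    p_general: float = 0.3
    choice_error: float = 0.05
    rater_effect_sd: float = 0.5
    specimen_effect_sd: float = 0.5
    idiolect_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "p_general", "choice_error"):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if isinstance(v, tuple) and len(v) != self.n_raters:
                raise SimConfigError(f"per-rater {name} needs {self.n_raters} values")
            if any(not 0 <= x <= 1 for x in vals):
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_raters < 2 or self.n_specimens < 1:
            raise SimConfigError("need >= 2 raters and >= 1 specimen")
        if self.rater_effect_sd < 0 or self.specimen_effect_sd < 0:
            raise SimConfigError("random-effect SDs must be >= 0")
        if isinstance(self.prevalence, (int, float)) and not 0 <= self.prevalence <= 1:
            raise SimConfigError("prevalence must be in [0, 1]")
        if not self.catalog:
            object.__setattr__(self, "catalog", default_catalog())

    def trait_prevalence(self) -> dict[str, float]:
        """Per-trait true-presence base rates.

        A scalar applies uniformly; ``None`` spreads prevalences evenly over
        [0.05, 0.5] across the catalog so that, as in real screens, some
        malformations are common and some rare.
        """
        traits = [t.curie for t in self.catalog]
        if isinstance(self.prevalence, dict):
            missing = set(traits) - set(self.prevalence)
            if missing:
                raise SimConfigError(f"prevalence missing traits: {sorted(missing)}")
            return {t: float(self.prevalence[t]) for t in traits}
        if self.prevalence is None:
            k = max(len(traits) - 1, 1)
            return {
                t: 0.05 + 0.45 * i / k for i, t in enumerate(traits)
            }
        return {t: float(self.prevalence) for t in traits}


def _synonym_pool(label: str, used: set[str]) -> list[str]:
    """Deterministic plausible lab-vocabulary variants of a trait label."""
    words = label.split()
    core = " ".join(w for w in words if w not in ("abnormal", "abnormally"))
    candidates = [
        label,
        f"{core} malformation",
        f"malformed {core}",
        f"{core} defect",
        f"{core.capitalize()} abnormality",
        "".join(w[0] for w in core.split()).upper() + "-" + words[-1][:3].upper(),
    ]
    out = []
    for cand in candidates:
        key = normalize_term(cand)
        if key and key not in used:
            used.add(key)
            out.append(cand)
    return out


def default_catalog(hierarchy: TraitHierarchy | None = None) -> tuple[TraitSpec, ...]:
    """Trait catalog derived from the packaged two-level hierarchy.

    Every catalog trait (general and granular alike — raters do tag at both
    levels) gets a synonym pool built from its label, with geometrically
    decaying synonym weights so some phrasings dominate.
    """
    from .harmonize import load_packaged_hierarchy

    h = hierarchy or load_packaged_hierarchy()
    used: set[str] = set()
    specs = []
    for curie in sorted(h.parent):
        if curie in h.non_catalog:
            continue
        syns = _synonym_pool(h.labels.get(curie, curie), used)
        if not syns:  # label fully collided; fall back to the identifier
            syns = [curie]
        w = 0.6 ** np.arange(len(syns))
        w = w / w.sum()
        specs.append(
            TraitSpec(
                curie=curie,
                label=h.labels.get(curie, curie),
                general=h.parent[curie],
                synonyms=tuple(syns),
                weights=tuple(float(x) for x in w),
            )
        )
    return tuple(specs)


@dataclass
class SimOutput:
    """Ground truth plus the two simulated survey tables and their catalog."""

    config: SimConfig
    truth: pd.DataFrame = field(repr=False)  # specimens x traits, 0/1
    survey1: SurveyTable = field(repr=False)
    survey2: SurveyTable = field(repr=False)
    lexicon: TermLexicon = field(repr=False)
    hierarchy: TraitHierarchy = field(repr=False)
    #: detection tensors (survey, rater, specimen, trait) for recovery checks
    detections: np.ndarray = field(repr=False, default=None)
    rater_effects: np.ndarray = field(repr=False, default=None)
    specimen_effects: np.ndarray = field(repr=False, default=None)


def generate(config: SimConfig) -> SimOutput:
    """Run the generative model; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    traits = list(config.catalog)
    trait_ids = [t.curie for t in traits]
    specimens = [f"larva{i + 1:02d}" for i in range(config.n_specimens)]
    raters = [f"rater{i + 1:02d}" for i in range(config.n_raters)]
    prev = config.trait_prevalence()

    rater_eff = rng.normal(0.0, config.rater_effect_sd, size=config.n_raters)
    spec_eff = rng.normal(0.0, config.specimen_effect_sd, size=config.n_specimens)

    # latent truth: logit-additive specimen effect on per-trait prevalence
    base = logit(np.clip([prev[t] for t in trait_ids], 1e-6, 1 - 1e-6))
    p_true = expit(base[None, :] + spec_eff[:, None])  # (S, T)
    truth = (rng.random(p_true.shape) < p_true).astype(np.uint8)

    # per-rater idiolects: favorite synonym subset per trait, fixed across images
    idiolects: list[list[np.ndarray]] = []
    for _ in raters:
        per_trait = []
        for t in traits:
            k = min(config.idiolect_size, len(t.synonyms))
            pick = rng.choice(len(t.synonyms), size=k, replace=False, p=t.weights)
            per_trait.append(pick)
        idiolects.append(per_trait)

    sens = np.broadcast_to(
        np.asarray(config.sensitivity, dtype=float), (config.n_raters,)
    )
    spec = np.broadcast_to(
        np.asarray(config.specificity, dtype=float), (config.n_raters,)
    )
    sens_logit = logit(np.clip(sens, 1e-6, 1 - 1e-6))
    t_index = {t.curie: i for i, t in enumerate(traits)}
    det = np.zeros((2, config.n_raters, config.n_specimens, len(traits)), np.uint8)
    general_of = {t.curie: t.general for t in traits}
    spec_by_id = {t.curie: t for t in traits}

    rows1, rows2 = [], []
    for pass_ix in range(2):
        for r_i, rater in enumerate(raters):
            p_hit = expit(sens_logit[r_i] + rater_eff[r_i] + spec_eff)  # (S,)
            if sens[r_i] == 1.0:  # exact perfect-detection limit
                p_hit = np.ones_like(p_hit)
            for s_i, specimen in enumerate(specimens):
                u = rng.random(len(traits))
                detected = np.where(
                    truth[s_i].astype(bool),
                    u < p_hit[s_i],
                    u < 1 - spec[r_i],
                )
                det[pass_ix, r_i, s_i] = detected
                for t_i in np.nonzero(detected)[0]:
                    t = traits[t_i]
                    if pass_ix == 0:
                        report = t
                        if (
                            t.general != t.curie
                            and t.general in spec_by_id
                            and rng.random() < config.p_general
                        ):
                            report = spec_by_id[t.general]
                        pool = idiolects[r_i][t_index[report.curie]]
                        syn = report.synonyms[pool[rng.integers(len(pool))]]
                        rows1.append((rater, specimen, syn))
                    else:
                        curie = t.curie
                        if t.general != t.curie and rng.random() < config.choice_error:
                            curie = t.general
                        rows2.append((rater, specimen, curie))

    s1 = SurveyTable(
        "S1", pd.DataFrame(rows1, columns=["rater", "specimen", "term"])
    )
    s2 = SurveyTable(
        "S2", pd.DataFrame(rows2, columns=["rater", "specimen", "term"])
    )

    parent = dict(general_of)
    for gen in set(general_of.values()):
        parent.setdefault(gen, gen)
    hierarchy = TraitHierarchy(
        parent=parent,
        labels={t.curie: t.label for t in traits},
        specials=frozenset(),
        non_catalog=frozenset(),
    )
    entries = {}
    for t in traits:
        for syn in t.synonyms:
            entries[normalize_term(syn)] = t.curie
    lexicon = TermLexicon(entries=entries)

    return SimOutput(
        config=config,
        truth=pd.DataFrame(truth, index=specimens, columns=trait_ids),
        survey1=s1,
        survey2=s2,
        lexicon=lexicon,
        hierarchy=hierarchy,
        detections=det,
        rater_effects=rater_eff,
        specimen_effects=spec_eff,
    )


def perfect_rater_config(**overrides) -> SimConfig:
    """Error-free limit: every rater detects exactly the truth, one fixed
    synonym per trait, granular reporting only."""
    base = dict(
        sensitivity=1.0,
        specificity=1.0,
        p_general=0.0,
        choice_error=0.0,
        rater_effect_sd=0.0,
        idiolect_size=1,
    )
    base.update(overrides)
    return SimConfig(**base)


def recover_parameters(sim: SimOutput, *, prevalence_tol=0.05, error_tol=0.05):
    """Compare realized rates in a simulation against their configured values.

    Returns a frame with one row per check (overall prevalence, per-rater
    sensitivity and specificity, both survey passes pooled) giving the
    configured value, the realized value, the tolerance used and a pass
    flag. Tolerances are on absolute probability scale.
    """
    cfg = sim.config
    truth = sim.truth.to_numpy().astype(bool)  # (S, T)
    prev_cfg = float(np.mean(list(cfg.trait_prevalence().values())))
    rows = [
        {
            "quantity": "mean_prevalence",
            "configured": prev_cfg,
            "realized": float(truth.mean()),
            "tol": prevalence_tol,
        }
    ]
    det = sim.detections  # (2, R, S, T)
    hits = det[:, :, truth]  # (2, R, n_true)
    fas = det[:, :, ~truth]
    rows.append(
        {
            "quantity": "mean_sensitivity",
            # configured sensitivity is the base rate; random effects are
            # centred so the panel mean should land near it
            "configured": float(np.mean(cfg.sensitivity)),
            "realized": float(hits.mean()),
            "tol": error_tol,
        }
    )
    rows.append(
        {
            "quantity": "mean_specificity",
            "configured": float(np.mean(cfg.specificity)),
            "realized": float(1 - fas.mean()),
            "tol": error_tol,
        }
    )
    out = pd.DataFrame(rows)
    out["passed"] = (out["configured"] - out["realized"]).abs() <= out["tol"]
    return out


def write_sim(sim: SimOutput, out_dir) -> None:
    """Write truth/survey/lexicon/hierarchy TSVs for a simulation run."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.truth.rename_axis("specimen").to_csv(out / "truth.tsv", sep="\t")
    sim.survey1.df.to_csv(out / "survey1.tsv", sep="\t", index=False)
    sim.survey2.df.to_csv(out / "survey2.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "verbatim": list(sim.lexicon.entries),
            "curie": list(sim.lexicon.entries.values()),
            "provenance": "simulated",
        }
    ).to_csv(out / "lexicon.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "granular_curie": list(sim.hierarchy.parent),
            "general_curie": list(sim.hierarchy.parent.values()),
            "label": [sim.hierarchy.labels.get(c, "") for c in sim.hierarchy.parent],
            "provenance": "simulated",
        }
    ).to_csv(out / "hierarchy.tsv", sep="\t", index=False)
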