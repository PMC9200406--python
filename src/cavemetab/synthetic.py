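"""Synthetic metabolome generator emulating the cavefish study design.

Generates peak tables with the statistical structure the pipeline assumes
— not real chemistry. The emulated design: 3 populations x 3 tissues x 3
feeding states x 6 replicates; roughly 174 identified primary metabolites
and 483 identified lipid-like features (plus some unidentified peaks so
mTIC normalization is exercised). Intensities are multiplicative: on the
log10 scale each cell is

    feature baseline + tissue offset + planted effects
    + nuisance loading x per-sample nuisance score + N(0, noise_sd),

exponentiated to base 10, with a zero-inflation step that blanks whole
(feature, population x tissue) cells to mimic absent metabolites, and a
per-sample multiplicative mTIC jitter. Planted effects are expressed in
z-units (multiples of noise_sd on the log scale) and recorded in a
ground-truth object for recovery scoring. Everything is reproducible from
(config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_logistic import FeatureTestResult
from .data_model import (
    FeedingState,
    PeakTable,
    Population,
    SampleMeta,
    Tissue,
    parse_feeding_state,
    parse_population,
    parse_tissue,
)
from .preprocess import BROAD_CATEGORIES

LIPID_CLASSES = ("TG", "PC", "PE", "FFA", "Cer", "SM")

SCOPE_POPULATIONS = {
    "shared_cave": (Population.PACHON, Population.TINAJA),
    "pachon_only": (Population.PACHON,),
    "tinaja_only": (Population.TINAJA,),
    "surface_only": (Population.SURFACE,),
}


@dataclass(frozen=True)
class PlantedEffect:
    """One planted group difference, in z-units of the residual noise.

    axis="feeding_state": the shift applies to the scope populations'
    samples in the listed feeding states (a feeding-state response).
    axis="population_baseline": the shift applies to every sample of the
    scope populations (a constitutive population difference).
    """

    feature_ids: tuple[str, ...]
    scope: str
    axis: str
    magnitude: float
    states: tuple[FeedingState, ...] = ()

    def __post_init__(self) -> None:
        if self.scope not in SCOPE_POPULATIONS:
            raise ValueError(f"unknown scope: {self.scope!r}")
        if self.axis not in {"feeding_state", "population_baseline"}:
            raise ValueError(f"unknown axis: {self.axis!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.axis == "feeding_state" and not self.states:
            raise ValueError("feeding_state effects need affected states")


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the study conditions."""

    n_reps: int = 6
    populations: tuple[Population, ...] = tuple(Population)
    tissues: tuple[Tissue, ...] = tuple(Tissue)
    states: tuple[FeedingState, ...] = tuple(FeedingState)
    n_primary: int = 174
    n_lipid: int = 483
    n_unidentified: int = 50
    seed: int = 0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.8
    tissue_sd: float = 0.4
    noise_sd: float = 0.25
    effects: tuple[PlantedEffect, ...] | None = None  # None -> default suite
    nuisance_loading_sd: float = 0.3
    nuisance_score_sd: float = 1.0
    zero_rate: float = 0.02
    mtic_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        self.populations = tuple(parse_population(p) if not isinstance(p, Population) else p
                                 for p in self.populations)
        self.tissues = tuple(parse_tissue(t) if not isinstance(t, Tissue) else t
                             for t in self.tissues)
        self.states = tuple(parse_feeding_state(s) if not isinstance(s, FeedingState) else s
                            for s in self.states)
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population level")
        if self.n_reps < 3:
            raise ValueError("n_reps must be >= 3")
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must be in [0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_primary + self.n_lipid + self.n_unidentified


def feature_names(config: SimConfig) -> tuple[list[str], np.ndarray, list[str]]:
    """Deterministic feature ids, identified flags and category labels."""
    ids, cats = [], []
    for i in range(config.n_primary):
        ids.append(f"met_{i + 1:04d}")
        cats.append(BROAD_CATEGORIES[i % len(BROAD_CATEGORIES)])
    for i in range(config.n_lipid):
        ids.append(f"lip_{i + 1:04d}")
        cats.append(LIPID_CLASSES[i % len(LIPID_CLASSES)])
    for i in range(config.n_unidentified):
        ids.append(f"unk_{i + 1:04d}")
        cats.append("unknown")
    identified = np.array(
        [True] * (config.n_primary + config.n_lipid) + [False] * config.n_unidentified
    )
    return ids, identified, cats


def default_effects(config: SimConfig) -> tuple[PlantedEffect, ...]:
    """A planted-effect suite spanning comfortably detectable (2.0 z) to
    marginal (0.5 z) at six replicates per cell, over disjoint feature
    blocks: shared-cave and single-cave fasting responses plus a
    constitutive cave baseline shift."""
    ids, _, _ = feature_names(config)
    blocks = [ids[i:i + 5] for i in range(0, 50, 5)]
    fasted = (FeedingState.FASTED30,)
    specs = [
        ("shared_cave", "feeding_state", 2.0, fasted),
        ("shared_cave", "feeding_state", 1.0, fasted),
        ("shared_cave", "feeding_state", 0.5, fasted),
        ("pachon_only", "feeding_state", 2.0, fasted),
        ("pachon_only", "feeding_state", 1.0, fasted),
        ("tinaja_only", "feeding_state", 1.0, fasted),
        ("surface_only", "feeding_state", 1.0, fasted),
        ("shared_cave", "population_baseline", 2.0, ()),
        ("shared_cave", "population_baseline", 0.5, ()),
        ("pachon_only", "population_baseline", 1.0, ()),
    ]
    return tuple(
        PlantedEffect(feature_ids=tuple(block), scope=scope, axis=axis,
                      magnitude=mag, states=states)
        for block, (scope, axis, mag, states) in zip(blocks, specs)
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, kept for recovery scoring."""

    effects: tuple[PlantedEffect, ...]
    nuisance_scores: pd.Series  # per sample
    nuisance_loadings: pd.Series  # per feature
    config: SimConfig
    seed: int

    def affected_features(self, scope: str | None = None, axis: str | None = None) -> set[str]:
        out: set[str] = set()
        for e in self.effects:
            if scope is not None and e.scope != scope:
                continue
            if axis is not None and e.axis != axis:
                continue
            out.update(e.feature_ids)
        return out

    @property
    def null_features(self) -> set[str]:
        all_ids = set(self.nuisance_loadings.index)
        return all_ids - self.affected_features()


def simulate(
    config: SimConfig, seed: int | None = None
) -> tuple[PeakTable, list[SampleMeta], SyntheticTruth]:
    """Draw one synthetic dataset; ``seed`` overrides ``config.seed``."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ids, identified, cats = feature_names(config)
    n_feat = config.n_features

    meta: list[SampleMeta] = []
    for pop, tissue, state in itertools.product(
        config.populations, config.tissues, config.states
    ):
        for rep in range(1, config.n_reps + 1):
            meta.append(SampleMeta(
                sample_id=f"{pop.value}_{tissue.value}_{state.value}_r{rep}",
                population=pop, tissue=tissue, feeding_state=state, replicate=rep,
            ))
    n_samp = len(meta)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_feat)
    tissue_offsets = {
        t: rng.normal(0.0, config.tissue_sd, n_feat) for t in config.tissues
    }
    loadings = rng.normal(0.0, config.nuisance_loading_sd, n_feat)
    scores = rng.normal(0.0, config.nuisance_score_sd, n_samp)

    effects = default_effects(config) if config.effects is None else tuple(config.effects)
    known = set(ids)
    for e in effects:
        unknown = set(e.feature_ids) - known
        if unknown:
            raise ValueError(f"planted effect names unknown features: {sorted(unknown)[:3]}")

    fid_index = {f: i for i, f in enumerate(ids)}
    logx = np.empty((n_feat, n_samp))
    for j, m in enumerate(meta):
        col = baseline + tissue_offsets[m.tissue] + loadings * scores[j]
        logx[:, j] = col
    for e in effects:
        rows = np.array([fid_index[f] for f in e.feature_ids], dtype=int)
        delta = e.magnitude * config.noise_sd
        for j, m in enumerate(meta):
            if m.population not in SCOPE_POPULATIONS[e.scope]:
                continue
            if e.axis == "feeding_state" and m.feeding_state not in e.states:
                continue
            logx[rows, j] += delta
    logx += rng.normal(0.0, config.noise_sd, (n_feat, n_samp))

    intensities = 10.0 ** logx

    # zero-inflation: blank whole (feature, population x tissue) cells
    if config.zero_rate > 0:
        cells = list(itertools.product(config.populations, config.tissues))
        blank = rng.random((n_feat, len(cells))) < config.zero_rate
        col_cells = np.array(
            [cells.index((m.population, m.tissue)) for m in meta], dtype=int
        )
        intensities[blank[:, col_cells]] = 0.0

    # per-sample multiplicative mTIC jitter
    jitter = 10.0 ** rng.normal(0.0, config.mtic_jitter_sd, n_samp)
    intensities *= jitter[np.newaxis, :]

    table = PeakTable(
        feature_ids=ids,
        sample_ids=[m.sample_id for m in meta],
        intensities=intensities,
        identified=identified,
        category=cats,
    )
    truth = SyntheticTruth(
        effects=effects,
        nuisance_scores=pd.Series(scores, index=table.sample_ids, name="nuisance_score"),
        nuisance_loadings=pd.Series(loadings, index=ids, name="nuisance_loading"),
        config=replace(config, effects=effects, seed=seed),
        seed=seed,
    )
    return table, meta, truth


def recovery_report(
    truth: SyntheticTruth,
    results: Sequence[FeatureTestResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score the pipeline's flags against the planted truth.

    One row per planted (scope, axis) group with its sensitivity, one
    "null" row with the false-positive rate, and one "overall" row with
    precision (NA when nothing was flagged). Features never tested (or
    whose test errored) count as not flagged.
    """
    universe = set(truth.nuisance_loadings.index)
    tested = {r.feature_id for r in results}
    stray = tested - universe
    if stray:
        raise ValueError(f"results reference features outside the simulation: {sorted(stray)[:3]}")
    flagged = {r.feature_id for r in results if r.fit is not None and r.p_value <= alpha}

    rows = []
    groups: dict[tuple[str, str], set[str]] = {}
    for e in truth.effects:
        groups.setdefault((e.scope, e.axis), set()).update(e.feature_ids)
    for (scope, axis), feats in sorted(groups.items()):
        feats_tested = feats & tested
        hit = len(feats_tested & flagged)
        rows.append({
            "scope": scope, "axis": axis, "n_features": len(feats_tested),
            "sensitivity": hit / len(feats_tested) if feats_tested else np.nan,
            "false_positive_rate": np.nan,
            "precision": np.nan,
        })
    null = truth.null_features & tested
    fp = len(null & flagged)
    rows.append({
        "scope": "null", "axis": "none", "n_features": len(null),
        "sensitivity": np.nan,
        "false_positive_rate": fp / len(null) if null else np.nan,
        "precision": np.nan,
    })
    tp = len(truth.affected_features() & flagged)
    rows.append({
        "scope": "overall", "axis": "all", "n_features": len(tested),
        "sensitivity": np.nan, "false_positive_rate": np.nan,
        "precision": tp / len(flagged) if flagged else np.nan,
    })
    return pd.DataFrame(rows)
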