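"""Parallel-adaptation contrast: shared cave feeding-state responses.

The two cave populations (Pachon, Tinaja) derive independently from
surface stock, so a metabolite whose feeding-state response moved the same
way in both caves — but not at the surface — is a candidate for parallel
metabolic adaptation. The test statistic is built per feature from the
linear combination

    x = (P + T)/2 - S,

where P, T and S are the feature's z-scored intensities (z computed within
each population over that population's samples for one feeding-state pair,
typically 6 + 6). Replicates are paired across populations by sorted
replicate id — fish are not biologically paired, and any pairing is
exchangeable under the null — giving a pseudo-sample vector of length 12
whose elements keep their feeding-state labels. A Bayesian logistic
regression of label on x then scores each feature; the construction is
symmetric in P and T and selective for responses shared by both caves,
since a single-cave shift enters x at half weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_logistic import FeatureTestResult, PriorConfig, bayes_logistic_fit
from .data_model import (
    ComparisonAxis,
    FeedingState,
    PeakTable,
    Population,
    SampleMeta,
    STATE_ORDER,
    Tissue,
)
from .opls import OPLS
from .preprocess import ZMatrix, log_z_transform

logger = logging.getLogger(__name__)


@dataclass
class ContrastSet:
    """Per-feature contrast pseudo-samples for one tissue and state pair.

    ``values`` is features x pseudo-samples; ``labels`` are +1 for the
    higher-ranked feeding state (more fasted) and -1 for the lower.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    tissue: Tissue
    state_pair: tuple[FeedingState, FeedingState]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.feature_ids), self.labels.size):
            raise ValueError("contrast matrix shape mismatch")
        if not ((self.labels == 1).any() and (self.labels == -1).any()):
            raise ValueError("both feeding-state classes must be present")


def _population_columns(
    Z: ZMatrix, meta_by_id: dict[str, SampleMeta], state_pair: tuple[FeedingState, FeedingState]
) -> tuple[np.ndarray, np.ndarray]:
    """Column order for one population: per state, samples sorted by
    replicate id. Returns (column indices, +/-1 labels)."""
    cols, labels = [], []
    for state, lab in zip(state_pair, (1.0, -1.0)):
        members = [
            (meta_by_id[s].replicate, i)
            for i, s in enumerate(Z.sample_ids)
            if meta_by_id[s].feeding_state == state
        ]
        members.sort()
        cols.extend(i for _, i in members)
        labels.extend([lab] * len(members))
    return np.array(cols, dtype=int), np.array(labels)


def build_contrast(
    Z_P: ZMatrix,
    Z_T: ZMatrix,
    Z_S: ZMatrix,
    meta: Sequence[SampleMeta],
    tissue: Tissue,
    state_pair: tuple[FeedingState, FeedingState],
    pairing: str = "sorted",
) -> ContrastSet:
    """Combine per-population z-matrices into x = (P+T)/2 - S.

    Each input z-matrix covers one population's samples for the state pair
    (z computed within that population). Features must agree across the
    three matrices; per state, the three populations must have equal
    replicate counts (no imputation) and are paired by sorted replicate id.
    """
    if pairing != "sorted":
        raise ValueError(f"unknown pairing rule: {pairing!r}")
    if not (Z_P.feature_ids == Z_T.feature_ids == Z_S.feature_ids):
        raise ValueError("population z-matrices disagree on features")
    meta_by_id = {m.sample_id: m for m in meta}
    cols_p, lab_p = _population_columns(Z_P, meta_by_id, state_pair)
    cols_t, lab_t = _population_columns(Z_T, meta_by_id, state_pair)
    cols_s, lab_s = _population_columns(Z_S, meta_by_id, state_pair)
    if not (lab_p.size == lab_t.size == lab_s.size) or not (
        np.array_equal(lab_p, lab_t) and np.array_equal(lab_p, lab_s)
    ):
        raise ValueError("unbalanced populations: per-state replicate counts differ")
    x = (Z_P.values[:, cols_p] + Z_T.values[:, cols_t]) / 2.0 - Z_S.values[:, cols_s]
    return ContrastSet(
        values=x, labels=lab_p, feature_ids=list(Z_P.feature_ids),
        tissue=tissue, state_pair=state_pair,
    )


def build_contrasts_from_table(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    tissue: Tissue,
    state_pair: tuple[FeedingState, FeedingState],
    pairing: str = "sorted",
) -> ContrastSet:
    """Convenience path from a (normalized) peak table: restrict to the
    tissue and state pair, z-score within each population, and combine.

    Only features usable in all three populations (some positive signal,
    so not dropped by the transform) enter the contrast.
    """
    z_by_pop: dict[Population, ZMatrix] = {}
    for pop in Population:
        ids = sorted(
            m.sample_id
            for m in meta
            if m.tissue == tissue and m.population == pop and m.feeding_state in state_pair
        )
        if not ids:
            raise ValueError(f"no samples for population {pop.value} in {tissue.value}")
        z_by_pop[pop] = log_z_transform(table, sample_ids=ids)
    common = set(z_by_pop[Population.PACHON].feature_ids)
    for z in z_by_pop.values():
        common &= set(z.feature_ids)
    order = [f for f in table.feature_ids if f in common]

    def restrict(z: ZMatrix) -> ZMatrix:
        pos = {f: i for i, f in enumerate(z.feature_ids)}
        rows = np.array([pos[f] for f in order], dtype=int)
        return ZMatrix(
            values=z.values[rows, :], feature_ids=order, sample_ids=z.sample_ids,
            constant_mask=z.constant_mask[rows], dropped_features=z.dropped_features,
        )

    return build_contrast(
        restrict(z_by_pop[Population.PACHON]),
        restrict(z_by_pop[Population.TINAJA]),
        restrict(z_by_pop[Population.SURFACE]),
        meta, tissue, state_pair, pairing=pairing,
    )


def contrast_test(
    contrasts: ContrastSet,
    n_orth: int = 1,
    prior: PriorConfig | None = None,
    alpha: float = 0.05,
) -> list[FeatureTestResult]:
    """O-PLS-filter the contrast matrix against the feeding-state labels,
    then fit one Bayesian logistic regression per feature.

    Direction "up" means the metabolite is increased in the cave
    populations in the more-fasted state (relative to surface).
    """
    prior = prior or PriorConfig()
    X = contrasts.values.T  # pseudo-samples x features
    y_pm = contrasts.labels
    y01 = (y_pm + 1) / 2.0
    if n_orth > 0 and X.shape[1] > 0:
        X = OPLS(n_orth=n_orth).fit(X, y_pm).X_filtered_
    cid = f"{contrasts.tissue.value}|contrast:{contrasts.state_pair[0].value}_vs_{contrasts.state_pair[1].value}"
    results: list[FeatureTestResult] = []
    for f, fid in enumerate(contrasts.feature_ids):
        try:
            fit = bayes_logistic_fit(X[:, f], y01, prior)
            results.append(FeatureTestResult(
                feature_id=fid, comparison_id=cid, fit=fit,
                direction="up" if fit.slope > 0 else "down", significant_at=alpha,
            ))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.info("contrast feature %s failed: %s", fid, exc)
            results.append(FeatureTestResult(
                feature_id=fid, comparison_id=cid, fit=None,
                direction="none", significant_at=alpha, error=str(exc),
            ))
    return results


def state_pairs() -> list[tuple[FeedingState, FeedingState]]:
    """The three feeding-state pairs, higher-ranked (more fasted) first."""
    out = []
    for i in range(len(STATE_ORDER)):
        for j in range(i + 1, len(STATE_ORDER)):
            out.append((STATE_ORDER[i], STATE_ORDER[j]))
    return out


def top_k_table(results: Sequence[FeatureTestResult], k: int = 20) -> pd.DataFrame:
    """The k most significant features regardless of direction.

    Sorted by p ascending, ties broken by |slope| descending then
    feature_id lexicographic, so the table is deterministic across runs.
    Rows carry -log10(p) and the direction for heatmap rendering.
    """
    ok = [r for r in results if r.fit is not None and np.isfinite(r.p_value)]
    ok.sort(key=lambda r: (r.p_value, -abs(r.slope), r.feature_id))
    rows = [
        {
            "feature_id": r.feature_id,
            "comparison_id": r.comparison_id,
            "p_value": r.p_value,
            "slope": r.slope,
            "direction": r.direction,
            "neg_log10_p": -np.log10(max(r.p_value, np.finfo(float).tiny)),
            "stars": r.stars,
        }
        for r in ok[:k]
    ]
    return pd.DataFrame(rows)
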