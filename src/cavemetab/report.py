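"""Pipeline orchestration, PCA score computation and output tables.

`run_pipeline` wires the stages end to end: (simulate or load) -> mTIC
normalize -> enumerate binary comparisons -> per-category O-PLS + PLS/DQ2
permutation classification -> per-feature Bayesian logistic tests ->
parallel-adaptation contrast tests -> ranked top-k tables, writing TSVs
plus a machine-readable JSON summary. Re-running with the same config and
seed reproduces identical tables (timestamps are excluded from the
summary), which is the pipeline's reproducibility contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .bayes_logistic import FeatureTestResult, PriorConfig, run_feature_tests
from .contrast import build_contrasts_from_table, contrast_test, state_pairs, top_k_table
from .data_model import (
    ComparisonAxis,
    PeakTable,
    Population,
    SampleMeta,
    Tissue,
    build_comparisons,
    check_join,
    read_peak_table,
    read_sample_meta,
)
from .pls_dq2 import permutation_significance
from .preprocess import (
    BROAD_CATEGORIES,
    ZMatrix,
    log_z_transform,
    mtic_normalize,
    significance_stars,
)
from .synthetic import SimConfig, simulate

logger = logging.getLogger(__name__)


def pca_scores(Z: ZMatrix | np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA sample scores and explained-variance fractions of a z-matrix.

    SVD-based on the feature-centred samples x features matrix. The sign
    of each component is fixed so its largest-|loading| element is
    positive. If the matrix rank is below ``n_components`` the available
    components are returned with a warning.
    """
    X = Z.X if isinstance(Z, ZMatrix) else np.asarray(Z, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D samples x features matrix")
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tot = (s**2).sum()
    if tot == 0:
        raise ValueError("matrix has no variation")
    rank = int((s > s[0] * 1e-12).sum())
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("rank %d < requested %d components; returning %d", rank, n_components, k)
    # sign convention: largest-|loading| element of each component positive
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * s[:k]
    explained = s[:k] ** 2 / tot
    return scores, explained


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; serializable to/from YAML."""

    simulation: SimConfig | None = None
    peak_table_path: str | None = None
    sample_meta_path: str | None = None
    out_dir: str | None = None
    mtic_grouping: str = "population_x_tissue"
    n_orth: int = 1
    n_perm: int = 200
    seed: int = 0
    alpha: float = 0.05
    top_k: int = 20
    bh_fdr: bool = False
    prior: PriorConfig = field(default_factory=PriorConfig)
    classify_categories: tuple[str, ...] = tuple(BROAD_CATEGORIES)


@dataclass
class PipelineRun:
    config: PipelineConfig
    input_digests: dict[str, str]
    n_comparisons: int
    classification: pd.DataFrame
    feature_tests: pd.DataFrame
    contrast_tables: dict[str, pd.DataFrame]
    summary: dict[str, Any]
    out_dir: Path | None


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _feature_results_frame(results: Sequence[FeatureTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "feature_id": r.feature_id,
            "comparison_id": r.comparison_id,
            "slope": r.slope,
            "se": r.fit.slope_se if r.fit else np.nan,
            "z": r.fit.z_stat if r.fit else np.nan,
            "p_value": r.p_value,
            "direction": r.direction,
            "separation": r.fit.separation_detected if r.fit else False,
            "significant": r.significant,
            "stars": r.stars,
            "error": r.error or "",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the full analysis; see module docstring for the stages."""
    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        table, meta, truth = simulate(config.simulation)
    elif config.peak_table_path and config.sample_meta_path:
        for p in (config.peak_table_path, config.sample_meta_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"[inputs] missing input path: {p}")
        table = read_peak_table(config.peak_table_path)
        meta = read_sample_meta(config.sample_meta_path)
        truth = None
    else:
        raise ValueError("[inputs] config needs a simulation spec or both input paths")
    check_join(table, meta)
    digests = {
        "intensities": _digest(table.intensities),
        "sample_ids": hashlib.sha256("|".join(table.sample_ids).encode()).hexdigest()[:16],
    }

    # ---- normalize --------------------------------------------------------
    try:
        norm = mtic_normalize(table, meta, grouping=config.mtic_grouping)
    except ValueError as exc:
        raise RuntimeError(f"[normalize] {exc}") from exc

    # ---- comparisons ------------------------------------------------------
    comparisons = build_comparisons(meta)
    logger.info("enumerated %d comparisons", len(comparisons))

    seed_seq = np.random.SeedSequence(config.seed)
    children = iter(seed_seq.spawn(len(comparisons) * max(1, len(config.classify_categories))))

    # ---- per-category DQ2 classification ---------------------------------
    cls_rows = []
    for comp in comparisons:
        for cat in config.classify_categories:
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            try:
                z = log_z_transform(norm, comparison=comp, category_subset=cat)
            except ValueError as exc:
                logger.info("classify %s/%s skipped: %s", comp.comparison_id, cat, exc)
                continue
            if len(z.feature_ids) < 2:
                continue
            res = permutation_significance(
                z.X, comp.labels, n_perm=config.n_perm, seed=child_seed,
                n_orth=config.n_orth,
            )
            cls_rows.append({
                "comparison_id": comp.comparison_id,
                "axis": comp.axis.value,
                "category": cat,
                "n_features": len(z.feature_ids),
                "q2": res.q2, "dq2": res.dq2,
                "perm_mean": res.perm_mean, "perm_sd": res.perm_sd,
                "z": res.z, "p_value": res.p_value,
                "stars": significance_stars(res.p_value),
                "seed": child_seed,
            })
    classification = pd.DataFrame(cls_rows)

    # ---- per-feature tests ------------------------------------------------
    feat_results: list[FeatureTestResult] = []
    for comp in comparisons:
        try:
            z = log_z_transform(norm, comparison=comp)
        except ValueError as exc:
            logger.warning("feature tests for %s skipped: %s", comp.comparison_id, exc)
            continue
        feat_results.extend(run_feature_tests(
            z, comp, n_orth=config.n_orth, prior=config.prior,
            alpha=config.alpha, bh_fdr=config.bh_fdr,
        ))
    feature_tests = _feature_results_frame(feat_results)

    # ---- parallel-adaptation contrasts ------------------------------------
    tissues = sorted({m.tissue for m in meta}, key=[t for t in Tissue].index)
    have_all_pops = {m.population for m in meta} >= set(Population)
    contrast_tables: dict[str, pd.DataFrame] = {}
    if have_all_pops:
        for tissue in tissues:
            for pair in state_pairs():
                key = f"{tissue.value}|{pair[0].value}_vs_{pair[1].value}"
                try:
                    cs = build_contrasts_from_table(norm.normalized, meta, tissue, pair)
                except ValueError as exc:
                    logger.warning("contrast %s skipped: %s", key, exc)
                    continue
                results = contrast_test(cs, n_orth=config.n_orth,
                                        prior=config.prior, alpha=config.alpha)
                contrast_tables[key] = top_k_table(results, k=config.top_k)
    else:
        logger.warning("not all three populations present; contrast stage skipped")

    # ---- summary + outputs -------------------------------------------------
    summary = {
        "config": _config_dict(config),
        "input_digests": digests,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "n_comparisons": len(comparisons),
        "comparison_ids": [c.comparison_id for c in comparisons],
        "n_classification_rows": int(len(classification)),
        "n_feature_tests": int(len(feature_tests)),
        "n_significant_feature_tests": int(feature_tests["significant"].sum())
        if len(feature_tests) else 0,
        "contrast_tables": {k: len(v) for k, v in contrast_tables.items()},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        classification.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
        feature_tests.to_csv(out_dir / "feature_tests.tsv", sep="\t", index=False)
        for key, df in contrast_tables.items():
            fname = "contrast_" + key.replace("|", "_") + ".tsv"
            df.to_csv(out_dir / fname, sep="\t", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineRun(
        config=config, input_digests=digests, n_comparisons=len(comparisons),
        classification=classification, feature_tests=feature_tests,
        contrast_tables=contrast_tables, summary=summary, out_dir=out_dir,
    )


def _config_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if hasattr(obj, "value"):
            return obj.value
        return obj

    return enc(config)
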