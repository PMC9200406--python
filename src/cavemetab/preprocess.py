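"""Normalization, transformation and univariate-routing steps.

mTIC normalization rescales every sample so that the summed peak height of
its *identified* metabolites equals the average of that sum over the
sample's normalization group (by default population x tissue): for
metabolite i in sample j,

    y_ij = (x_ij / mTIC_j) * mTIC_bar,

where mTIC_j excludes unidentified peaks (column bleed, contaminants) but
the resulting per-sample scale factor is applied to every feature.

Downstream modelling operates on log10 intensities z-scored per feature
within the samples of a single binary comparison, so each feature enters
the multivariate and per-feature models dimensionless and centred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .data_model import ComparisonDesign, PeakTable, SampleMeta

logger = logging.getLogger(__name__)

CATEGORY_CARBOHYDRATES = "Carbohydrates / CCM"
CATEGORY_AMINO_ACIDS = "Amino acids"
CATEGORY_FATTY_ACIDS = "Fatty acids"
CATEGORY_NUCLEOTIDES = "Nucleotides"
CATEGORY_MISC = "Miscellaneous / secondary"

BROAD_CATEGORIES = (
    CATEGORY_CARBOHYDRATES,
    CATEGORY_AMINO_ACIDS,
    CATEGORY_FATTY_ACIDS,
    CATEGORY_NUCLEOTIDES,
    CATEGORY_MISC,
)

#: Default HMDB-style term -> broad-category mapping. Terms are matched
#: case-insensitively on the feature's subclass first, falling back to its
#: superclass; anything unmapped lands in the miscellaneous/secondary bin.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "monosaccharides": CATEGORY_CARBOHYDRATES,
    "disaccharides": CATEGORY_CARBOHYDRATES,
    "sugar acids": CATEGORY_CARBOHYDRATES,
    "sugar alcohols": CATEGORY_CARBOHYDRATES,
    "carbohydrate phosphates": CATEGORY_CARBOHYDRATES,
    "carbohydrates and carbohydrate conjugates": CATEGORY_CARBOHYDRATES,
    "tca acids": CATEGORY_CARBOHYDRATES,
    "tricarboxylic acids and derivatives": CATEGORY_CARBOHYDRATES,
    "organic dicarboxylic acids": CATEGORY_CARBOHYDRATES,
    "amino acids, peptides, and analogues": CATEGORY_AMINO_ACIDS,
    "amino acids and derivatives": CATEGORY_AMINO_ACIDS,
    "organonitrogen compounds": CATEGORY_AMINO_ACIDS,
    "fatty acids and conjugates": CATEGORY_FATTY_ACIDS,
    "fatty acid esters": CATEGORY_FATTY_ACIDS,
    "fatty alcohols": CATEGORY_FATTY_ACIDS,
    "lineolic acids and derivatives": CATEGORY_FATTY_ACIDS,
    "purines and purine derivatives": CATEGORY_NUCLEOTIDES,
    "pyrimidines and pyrimidine derivatives": CATEGORY_NUCLEOTIDES,
    "nucleosides, nucleotides, and analogues": CATEGORY_NUCLEOTIDES,
    "purine nucleosides": CATEGORY_NUCLEOTIDES,
    "pyrimidine nucleosides": CATEGORY_NUCLEOTIDES,
}


@dataclass
class NormalizationResult:
    """mTIC-normalized peak table plus the per-sample sums and group references."""

    normalized: PeakTable
    mtic_per_sample: pd.Series
    mtic_reference: pd.Series  # indexed by sample id: the group mean applied


@dataclass
class ZMatrix:
    """Per-feature z-scores of log10 intensities over one sample group.

    ``constant_mask`` flags features that were constant within the group
    (their rows are all-zero by convention). Features with no positive
    intensity in the group are dropped before transformation.
    """

    values: np.ndarray  # features x samples
    feature_ids: list[str]
    sample_ids: list[str]
    constant_mask: np.ndarray
    dropped_features: list[str]
    log_base: float = 10.0
    zero_rule: str = "half-min"
    grouping: str = "comparison"

    @property
    def X(self) -> np.ndarray:
        """Samples x features orientation used by the multivariate models."""
        return self.values.T


def mtic_normalize(
    table: PeakTable,
    meta: Sequence[SampleMeta] | None = None,
    grouping: str = "population_x_tissue",
) -> NormalizationResult:
    """Normalize each sample to its group's average identified-peak sum.

    grouping="population_x_tissue" averages mTIC over samples sharing
    population and tissue (all feeding states pooled); "global" uses one
    reference over all samples.
    """
    if grouping not in {"population_x_tissue", "global"}:
        raise ValueError(f"unknown mTIC grouping: {grouping!r}")
    ident = table.identified
    if not ident.any():
        raise ValueError("no identified features: mTIC undefined")
    mtic = table.intensities[ident, :].sum(axis=0)
    zero = np.flatnonzero(mtic == 0)
    if zero.size:
        raise ValueError(
            f"zero mTIC (no identified signal) in sample(s) "
            f"{[table.sample_ids[i] for i in zero[:5]]}"
        )
    mtic_s = pd.Series(mtic, index=table.sample_ids, name="mTIC")

    if grouping == "global":
        group_of = {s: "all" for s in table.sample_ids}
    else:
        if meta is None:
            raise ValueError("population_x_tissue grouping requires sample metadata")
        group_of = {
            m.sample_id: f"{m.population.value}|{m.tissue.value}" for m in meta
        }
        missing = [s for s in table.sample_ids if s not in group_of]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
    groups = pd.Series([group_of[s] for s in table.sample_ids], index=table.sample_ids)
    ref = mtic_s.groupby(groups).transform("mean")
    factors = (ref / mtic_s).values
    normalized = PeakTable(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        intensities=table.intensities * factors[np.newaxis, :],
        identified=table.identified.copy(),
        category=list(table.category),
    )
    return NormalizationResult(
        normalized=normalized, mtic_per_sample=mtic_s, mtic_reference=ref.rename("mTIC_ref")
    )


def log_z_transform(
    table: PeakTable | NormalizationResult,
    comparison: ComparisonDesign | None = None,
    category_subset: str | Iterable[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ZMatrix:
    """Restrict, log10-transform and z-score a peak table per feature.

    Zeros are replaced by half the smallest positive intensity of that
    feature within the selected samples; features with no positive value
    are dropped with a warning; features constant after the log transform
    are flagged and set to all-zero. z-scores use the sample SD (ddof=1).
    """
    if isinstance(table, NormalizationResult):
        table = table.normalized
    if comparison is not None and sample_ids is not None:
        raise ValueError("give either a comparison or explicit sample_ids, not both")
    if comparison is not None:
        sample_ids = comparison.sample_ids
    if sample_ids is None:
        sample_ids = list(table.sample_ids)
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 samples for a stable z-score")
    sub = table.subset_samples(sample_ids)
    if category_subset is not None:
        wanted = {category_subset} if isinstance(category_subset, str) else set(category_subset)
        mask = np.array([c in wanted for c in sub.category])
        sub = sub.subset_features(mask)

    x = sub.intensities.astype(float)
    pos_any = (x > 0).any(axis=1)
    dropped = [f for f, keep in zip(sub.feature_ids, pos_any) if not keep]
    if dropped:
        logger.warning("dropping %d all-zero feature(s) in group, e.g. %s",
                       len(dropped), dropped[:3])
    x = x[pos_any, :]
    kept_ids = [f for f, keep in zip(sub.feature_ids, pos_any) if keep]

    # half-minimum replacement, per feature within the group
    with np.errstate(invalid="ignore"):
        min_pos = np.where(x > 0, x, np.inf).min(axis=1)
    x = np.where(x == 0, (min_pos / 2.0)[:, np.newaxis], x)
    logx = np.log10(x)

    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=1, keepdims=True)
    # relative tolerance so round-off from exactly-cancelling scale factors
    # does not masquerade as biological variance
    constant = (sd[:, 0] <= 1e-9 * (1.0 + np.abs(mean[:, 0]))) | ~np.isfinite(sd[:, 0])
    if constant.any():
        logger.warning("%d feature(s) constant within group, z set to 0", int(constant.sum()))
    safe_sd = np.where(constant[:, np.newaxis], 1.0, sd)
    z = (logx - mean) / safe_sd
    z[constant, :] = 0.0
    return ZMatrix(
        values=z,
        feature_ids=kept_ids,
        sample_ids=list(sample_ids),
        constant_mask=constant,
        dropped_features=dropped,
    )


def categorize_features(
    annotations: pd.DataFrame,
    mapping: Mapping[str, str] | None = None,
) -> pd.Series:
    """Assign each feature one of the five broad metabolite categories.

    ``annotations`` needs a ``feature_id`` column plus ``subclass`` and/or
    ``superclass`` columns (HMDB-style terms). The subclass is tried first;
    if absent or unmapped, the superclass; anything still unmapped falls
    back to the miscellaneous/secondary category with a warning.
    """
    if mapping is None:
        mapping = DEFAULT_CATEGORY_MAP
    lookup = {str(k).strip().lower(): v for k, v in mapping.items()}
    bad = sorted(set(lookup.values()) - set(BROAD_CATEGORIES))
    if bad:
        raise ValueError(f"mapping targets outside the five broad categories: {bad}")
    if "feature_id" not in annotations.columns:
        raise ValueError("annotations need a feature_id column")

    out = {}
    n_fallback = 0
    for row in annotations.itertuples(index=False):
        cat = None
        for col in ("subclass", "superclass"):
            term = getattr(row, col, None)
            if term is not None and pd.notna(term) and str(term).strip():
                cat = lookup.get(str(term).strip().lower())
                if cat is not None:
                    break
        if cat is None:
            cat = CATEGORY_MISC
            n_fallback += 1
        out[str(row.feature_id)] = cat
    if n_fallback:
        logger.warning("%d feature(s) without a category mapping -> %s",
                       n_fallback, CATEGORY_MISC)
    return pd.Series(out, name="category")


@dataclass(frozen=True)
class FishBiometrics:
    """Body-condition metrics for one fish over a feeding regimen.

    Fulton's condition factor K = (mass / length^3) x 100 with mass in g and
    standard length in cm. The percentage changes divide by the *final*
    value (dWt% = (m_f - m_i)/m_f x 100 and likewise for dK%), which is the
    printed convention of the source protocol; pass denominator="initial"
    for the conventional baseline-relative change.
    """

    mass_initial_g: float
    mass_final_g: float
    length_initial_cm: float
    length_final_cm: float
    delta_wt_pct: float
    k_initial: float
    k_final: float
    delta_k_pct: float


def k_factor(mass_g: float, length_cm: float) -> float:
    if not (mass_g > 0 and length_cm > 0):
        raise ValueError("mass and length must be positive")
    return mass_g / length_cm**3 * 100.0


def biometrics(
    mass_initial_g: float,
    mass_final_g: float,
    length_initial_cm: float,
    length_final_cm: float,
    denominator: str = "final",
) -> FishBiometrics:
    for name, v in (("mass_initial_g", mass_initial_g), ("mass_final_g", mass_final_g),
                    ("length_initial_cm", length_initial_cm), ("length_final_cm", length_final_cm)):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    if denominator not in {"final", "initial"}:
        raise ValueError("denominator must be 'final' or 'initial'")
    k_i = k_factor(mass_initial_g, length_initial_cm)
    k_f = k_factor(mass_final_g, length_final_cm)
    wt_den = mass_final_g if denominator == "final" else mass_initial_g
    k_den = k_f if denominator == "final" else k_i
    return FishBiometrics(
        mass_initial_g=mass_initial_g,
        mass_final_g=mass_final_g,
        length_initial_cm=length_initial_cm,
        length_final_cm=length_final_cm,
        delta_wt_pct=(mass_final_g - mass_initial_g) / wt_den * 100.0,
        k_initial=k_i,
        k_final=k_f,
        delta_k_pct=(k_f - k_i) / k_den * 100.0,
    )


def significance_stars(p: float) -> str:
    """Star-coding: ns p>0.05, * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparisonReport:
    route: str  # "anova_tukey" or "kruskal_dunn"
    normality_passes: dict[str, bool]
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adj, stars


def _normality_battery(residuals: np.ndarray, alpha: float) -> dict[str, bool]:
    """Four normality tests on pooled residuals; each passes at its alpha.

    Kolmogorov-Smirnov is the Lilliefors form (mean/SD estimated from the
    data); Anderson-Darling passes when its statistic is below the critical
    value closest to the requested level.
    """
    res: dict[str, bool] = {}
    res["dagostino_pearson"] = stats.normaltest(residuals).pvalue > alpha
    res["shapiro_wilk"] = stats.shapiro(residuals).pvalue > alpha
    res["kolmogorov_smirnov"] = lilliefors(residuals, dist="norm")[1] > alpha
    ad = stats.anderson(residuals, dist="norm", method="interpolate")
    res["anderson_darling"] = float(ad.pvalue) > alpha
    return res


def _dunn_posthoc(groups: Sequence[np.ndarray], names: Sequence[str]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z-tests with tie correction and Bonferroni
    adjustment over all pairwise comparisons."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [gr.mean() for gr in group_ranks]
    sizes = [g.size for g in groups]
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            rows.append({"group_a": names[i], "group_b": names[j], "stat": z,
                         "p_adj": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def group_compare_router(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparisonReport:
    """Route a multi-group comparison through ANOVA/Tukey or Kruskal-Wallis/Dunn.

    Pooled within-group residuals are screened with four normality tests at
    ``alpha``; data passing at least three go through one-way ANOVA with
    Tukey's HSD, anything failing more than one test goes through
    Kruskal-Wallis with Dunn's (Bonferroni-adjusted) post-hoc.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 3 for a in arrays):
        raise ValueError("every group needs at least 3 values")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]

    residuals = np.concatenate([a - a.mean() for a in arrays])
    passes = _normality_battery(residuals, alpha)
    if sum(passes.values()) >= 3:
        stat, p = stats.f_oneway(*arrays)
        tk = stats.tukey_hsd(*arrays)
        rows = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                padj = float(tk.pvalue[i, j])
                rows.append({"group_a": names[i], "group_b": names[j],
                             "stat": float(tk.statistic[i, j]),
                             "p_adj": padj, "stars": significance_stars(padj)})
        return GroupComparisonReport(
            route="anova_tukey", normality_passes=passes,
            omnibus_stat=float(stat), omnibus_p=float(p), pairwise=pd.DataFrame(rows),
        )
    stat, p = stats.kruskal(*arrays)
    return GroupComparisonReport(
        route="kruskal_dunn", normality_passes=passes,
        omnibus_stat=float(stat), omnibus_p=float(p),
        pairwise=_dunn_posthoc(arrays, names),
    )
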