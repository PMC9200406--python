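"""Domain types and delimited-text IO for peak tables and sample metadata.

The pipeline operates on processed peak-height tables (features x samples,
non-negative instrument units) together with a per-sample factor table
describing the experimental design: population (Surface river fish vs. the
Pachon and Tinaja cave populations), tissue (liver, muscle, brain) and
feeding state (refed, 4-day fasted, 30-day fasted), with six biological
replicates per design cell. Absent metabolites are encoded as a peak
intensity of exactly zero; NaN is rejected so that missingness decisions
stay explicit and upstream.
"""

from __future__ import annotations

import itertools
import logging
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_ID_COLUMN = "feature_id"
RESERVED_COLUMNS = (FEATURE_ID_COLUMN, "identified", "category")


class Population(str, Enum):
    SURFACE = "Surface"
    PACHON = "Pachon"
    TINAJA = "Tinaja"


class Tissue(str, Enum):
    LIVER = "liver"
    MUSCLE = "muscle"
    BRAIN = "brain"


class FeedingState(str, Enum):
    REFED = "Refed"
    FASTED4 = "Fasted4"
    FASTED30 = "Fasted30"


#: Fixed factor-level ranking used when assigning +/-1 class labels to a
#: pairwise comparison: the higher-ranked level is group_pos (label +1), so
#: reported coefficient signs are reproducible across runs.
POPULATION_ORDER = (Population.PACHON, Population.TINAJA, Population.SURFACE)
STATE_ORDER = (FeedingState.FASTED30, FeedingState.FASTED4, FeedingState.REFED)

_STATE_ALIASES = {
    "refed": FeedingState.REFED,
    "fasted4": FeedingState.FASTED4,
    "4-day fasted": FeedingState.FASTED4,
    "fasted_4": FeedingState.FASTED4,
    "fasted30": FeedingState.FASTED30,
    "30-day fasted": FeedingState.FASTED30,
    "fasted_30": FeedingState.FASTED30,
}


def _strip_accents(text: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", text) if not unicodedata.combining(c)
    )


def parse_population(value: str) -> Population:
    key = _strip_accents(str(value)).strip().lower()
    for pop in Population:
        if key == pop.value.lower():
            return pop
    raise ValueError(f"unknown population: {value!r}")


def parse_tissue(value: str) -> Tissue:
    key = str(value).strip().lower()
    for tissue in Tissue:
        if key == tissue.value.lower():
            return tissue
    raise ValueError(f"unknown tissue: {value!r}")


def parse_feeding_state(value: str) -> FeedingState:
    key = str(value).strip().lower()
    if key in _STATE_ALIASES:
        return _STATE_ALIASES[key]
    for state in FeedingState:
        if key == state.value.lower():
            return state
    raise ValueError(f"unknown feeding state: {value!r}")


@dataclass
class PeakTable:
    """Features x samples matrix of non-negative peak heights.

    ``identified`` marks features with a confirmed compound annotation;
    only identified features contribute to the mTIC normalization sum.
    ``category`` carries the broad metabolite category or lipid class label
    ("unknown" when unannotated).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    identified: np.ndarray
    category: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.identified = np.asarray(self.identified, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_feat, n_samp = len(self.feature_ids), len(self.sample_ids)
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature id")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample id")
        if self.intensities.shape != (n_feat, n_samp):
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"({n_feat} features, {n_samp} samples)"
            )
        if np.isnan(self.intensities).any():
            raise ValueError("NaN intensities forbidden; encode absence as 0")
        if (self.intensities < 0).any():
            raise ValueError("negative intensity")
        if self.identified.shape != (n_feat,):
            raise ValueError("identified flag length mismatch")
        if len(self.category) != n_feat:
            raise ValueError("category length mismatch")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id not in peak table: {exc.args[0]!r}") from exc

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        idx = self.sample_index(sample_ids)
        return PeakTable(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            intensities=self.intensities[:, idx].copy(),
            identified=self.identified.copy(),
            category=list(self.category),
        )

    def subset_features(self, mask_or_ids) -> "PeakTable":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in mask_or_ids], dtype=int)
        return PeakTable(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            intensities=self.intensities[idx, :].copy(),
            identified=self.identified[idx].copy(),
            category=[self.category[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, index=pd.Index(self.feature_ids, name=FEATURE_ID_COLUMN),
            columns=self.sample_ids,
        )
        df.insert(0, "category", self.category)
        df.insert(0, "identified", self.identified)
        return df.reset_index()


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample design factors plus optional biometrics."""

    sample_id: str
    population: Population
    tissue: Tissue
    feeding_state: FeedingState
    replicate: int
    mass_g: float | None = None
    length_cm: float | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        for name in ("mass_g", "length_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when given")

    @property
    def cell(self) -> tuple[Population, Tissue, FeedingState, int]:
        return (self.population, self.tissue, self.feeding_state, self.replicate)


class ComparisonAxis(str, Enum):
    POPULATION_WITHIN_STATE = "population_within_state"
    STATE_WITHIN_POPULATION = "state_within_population"
    PARALLEL_CONTRAST = "parallel_contrast"


@dataclass
class ComparisonDesign:
    """A binary contrast within one tissue: group_pos labelled +1, group_neg -1."""

    comparison_id: str
    tissue: Tissue
    group_pos: list[str]
    group_neg: list[str]
    axis: ComparisonAxis

    def __post_init__(self) -> None:
        if not self.group_pos or not self.group_neg:
            raise ValueError("both comparison groups must be non-empty")
        if set(self.group_pos) & set(self.group_neg):
            raise ValueError("comparison groups overlap")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_pos) + list(self.group_neg)

    @property
    def labels(self) -> np.ndarray:
        """+/-1 label per sample, aligned with :attr:`sample_ids`."""
        return np.concatenate(
            [np.ones(len(self.group_pos)), -np.ones(len(self.group_neg))]
        )


def validate_meta(meta: Sequence[SampleMeta]) -> None:
    cells = [m.cell for m in meta]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate design cell (population, tissue, state, replicate)")
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample id in metadata")


def check_join(table: PeakTable, meta: Sequence[SampleMeta]) -> None:
    """Every metadata sample must map to exactly one peak-table column and vice versa."""
    meta_ids = {m.sample_id for m in meta}
    table_ids = set(table.sample_ids)
    if meta_ids != table_ids:
        missing = sorted(meta_ids ^ table_ids)[:5]
        raise ValueError(f"sample ids of metadata and peak table differ, e.g. {missing}")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_peak_table(path: str | Path, delimiter: str | None = None) -> PeakTable:
    """Read a delimited peak table: feature_id column, optional identified /
    category columns, then one numeric column per sample.

    Unparseable numeric cells raise rather than being coerced to zero.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    cols = list(df.columns)
    if len(set(cols)) != len(cols) or any(c.endswith(".1") and c[:-2] in cols for c in cols):
        raise ValueError("duplicate sample id in header")
    if FEATURE_ID_COLUMN not in cols:
        raise ValueError(f"peak table must have a {FEATURE_ID_COLUMN!r} column")
    sample_cols = [c for c in cols if c not in RESERVED_COLUMNS]
    feature_ids = df[FEATURE_ID_COLUMN].astype(str).tolist()
    raw = df[sample_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"unparseable numeric cell {raw.iat[r, c]!r} "
            f"(feature {feature_ids[r]!r}, sample {sample_cols[c]!r})"
        )
    if numeric.isna().any().any():
        raise ValueError("NaN intensities forbidden; encode absence as 0")
    if "identified" in df.columns:
        identified = df["identified"].astype(str).str.strip().str.lower().isin(
            {"true", "1", "yes", "t"}
        ).values
    else:
        identified = np.ones(len(feature_ids), dtype=bool)
    if "category" in df.columns:
        category = df["category"].fillna("unknown").astype(str).tolist()
    else:
        category = ["unknown"] * len(feature_ids)
    return PeakTable(
        feature_ids=feature_ids,
        sample_ids=sample_cols,
        intensities=numeric.values.astype(float),
        identified=identified,
        category=category,
    )


def write_peak_table(table: PeakTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


META_COLUMNS = ("sample_id", "population", "tissue", "feeding_state", "replicate")


def read_sample_meta(path: str | Path, delimiter: str | None = None) -> list[SampleMeta]:
    """Read the sample-metadata table; factor levels validated case-insensitively."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = []
    for row in df.itertuples(index=False):
        meta.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                population=parse_population(row.population),
                tissue=parse_tissue(row.tissue),
                feeding_state=parse_feeding_state(row.feeding_state),
                replicate=int(row.replicate),
                mass_g=float(row.mass_g) if "mass_g" in df.columns and pd.notna(row.mass_g) else None,
                length_cm=float(row.length_cm) if "length_cm" in df.columns and pd.notna(row.length_cm) else None,
            )
        )
    validate_meta(meta)
    return meta


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    rows = [
        {
            "sample_id": m.sample_id,
            "population": m.population.value,
            "tissue": m.tissue.value,
            "feeding_state": m.feeding_state.value,
            "replicate": m.replicate,
            "mass_g": m.mass_g,
            "length_cm": m.length_cm,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def _pair_id(a: Enum, b: Enum) -> str:
    return f"{a.value}_vs_{b.value}"


def build_comparisons(meta: Sequence[SampleMeta]) -> list[ComparisonDesign]:
    """Enumerate all pairwise binary comparisons the analysis runs.

    Per tissue: every population pair within each feeding state
    (population_within_state) and every feeding-state pair within each
    population (state_within_population). group_pos holds the
    higher-ranked level of the fixed orders Pachon > Tinaja > Surface and
    Fasted30 > Fasted4 > Refed. Tissues lacking a pair are skipped with a
    log record.
    """
    validate_meta(meta)
    designs: list[ComparisonDesign] = []
    by_cell: dict[tuple, list[str]] = {}
    for m in meta:
        by_cell.setdefault((m.tissue, m.population, m.feeding_state), []).append(m.sample_id)
    for ids in by_cell.values():
        ids.sort()
    tissues = sorted({m.tissue for m in meta}, key=[t for t in Tissue].index)

    for tissue in tissues:
        states_present = [s for s in STATE_ORDER
                          if any((tissue, p, s) in by_cell for p in Population)]
        pops_present = [p for p in POPULATION_ORDER
                        if any((tissue, p, s) in by_cell for s in FeedingState)]
        # population pairs within each feeding state
        for state in states_present:
            pops = [p for p in POPULATION_ORDER if (tissue, p, state) in by_cell]
            if len(pops) < 2:
                logger.info("tissue %s state %s: <2 populations, skipped", tissue.value, state.value)
            for hi, lo in itertools.combinations(pops, 2):
                designs.append(ComparisonDesign(
                    comparison_id=f"{tissue.value}|pop:{_pair_id(hi, lo)}|state:{state.value}",
                    tissue=tissue,
                    group_pos=by_cell[(tissue, hi, state)],
                    group_neg=by_cell[(tissue, lo, state)],
                    axis=ComparisonAxis.POPULATION_WITHIN_STATE,
                ))
        # feeding-state pairs within each population
        for pop in pops_present:
            states = [s for s in STATE_ORDER if (tissue, pop, s) in by_cell]
            if len(states) < 2:
                logger.info("tissue %s population %s: <2 states, skipped", tissue.value, pop.value)
            for hi, lo in itertools.combinations(states, 2):
                designs.append(ComparisonDesign(
                    comparison_id=f"{tissue.value}|state:{_pair_id(hi, lo)}|pop:{pop.value}",
                    tissue=tissue,
                    group_pos=by_cell[(tissue, pop, hi)],
                    group_neg=by_cell[(tissue, pop, lo)],
                    axis=ComparisonAxis.STATE_WITHIN_POPULATION,
                ))
    return designs
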