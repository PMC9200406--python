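import numpy as np
import pytest

from cavemetab import (
    FeedingState,
    PeakTable,
    SimConfig,
    build_comparisons,
    mtic_normalize,
    simulate,
)


@pytest.fixture
def toy_table() -> PeakTable:
    """Two identified features + one unidentified, two samples.

    Identified sums: A = 2+3 = 5, B = 4+6 = 10, so the global mTIC
    reference is 7.5 and the scale factors are 1.5 and 0.75.
    """
    return PeakTable(
        feature_ids=["m1", "m2", "u1"],
        sample_ids=["A", "B"],
        intensities=np.array([[2.0, 4.0], [3.0, 6.0], [10.0, 20.0]]),
        identified=np.array([True, True, False]),
        category=["Amino acids", "Nucleotides", "unknown"],
    )


@pytest.fixture(scope="session")
def null_dataset():
    """One tissue, two populations x two states x 6 reps, no planted effects."""
    cfg = SimConfig(
        n_primary=40, n_lipid=0, n_unidentified=5,
        tissues=("liver",), states=("Refed", "Fasted30"),
        populations=("Surface", "Pachon"), effects=(), zero_rate=0.0, seed=77,
    )
    table, meta, truth = simulate(cfg)
    return table, meta, truth


@pytest.fixture(scope="session")
def null_comparison(null_dataset):
    table, meta, _ = null_dataset
    norm = mtic_normalize(table, meta)
    comps = build_comparisons(meta)
    state_comps = [c for c in comps if "|state:Fasted30_vs_Refed|" in c.comparison_id]
    return norm, state_comps[0]
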