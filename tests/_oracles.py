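"""Independent oracles used by the tests: brute-force enumeration and
grid-search optimisation kept deliberately separate from the package's own
algorithms."""

import itertools

import numpy as np


def grid_posterior_mode(
    x: np.ndarray,
    y: np.ndarray,
    scale_intercept: float = 10.0,
    scale_slope: float = 2.5,
    n_zoom: int = 40,
) -> tuple[float, float]:
    """2-D zooming grid search of the exact Cauchy-prior log-posterior on
    the standardized covariate scale (centred, SD 0.5)."""
    xs = (x - x.mean()) / (2.0 * x.std(ddof=1))

    def log_post(a: float, b: float) -> float:
        eta = a + b * xs
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return (ll - np.log1p((a / scale_intercept) ** 2)
                - np.log1p((b / scale_slope) ** 2))

    a0, b0, w = 0.0, 0.0, 8.0
    for _ in range(n_zoom):
        aa = np.linspace(a0 - w, a0 + w, 41)
        bb = np.linspace(b0 - w, b0 + w, 41)
        vals = np.array([[log_post(a, b) for b in bb] for a in aa])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        a0, b0, w = float(aa[i]), float(bb[j]), w * 0.35
    return a0, b0


def brute_force_comparison_count(meta) -> int:
    """Count pairwise comparisons by direct enumeration over observed cells."""
    cells = {(m.tissue, m.population, m.feeding_state) for m in meta}
    count = 0
    tissues = {t for t, _, _ in cells}
    for tissue in tissues:
        pops = {p for t, p, _ in cells if t == tissue}
        states = {s for t, _, s in cells if t == tissue}
        for state in states:
            present = [p for p in pops if (tissue, p, state) in cells]
            count += len(list(itertools.combinations(present, 2)))
        for pop in pops:
            present = [s for s in states if (tissue, pop, s) in cells]
            count += len(list(itertools.combinations(present, 2)))
    return count
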