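"""mTIC normalization, log/z transform, categorization, biometrics, routing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cavemetab import (
    PeakTable,
    biometrics,
    build_comparisons,
    categorize_features,
    group_compare_router,
    k_factor,
    log_z_transform,
    mtic_normalize,
    significance_stars,
)
from cavemetab.data_model import ComparisonAxis, ComparisonDesign, Tissue
from cavemetab.preprocess import (
    CATEGORY_CARBOHYDRATES,
    CATEGORY_MISC,
    CATEGORY_NUCLEOTIDES,
)


class TestMticNormalize:
    def test_toy_samples_rescaled_to_group_mean(self, toy_table):
        res = mtic_normalize(toy_table, grouping="global")
        # mTIC_A=5, mTIC_B=10, reference 7.5 -> factors 1.5 and 0.75
        np.testing.assert_allclose(res.mtic_per_sample.values, [5.0, 10.0])
        np.testing.assert_allclose(res.mtic_reference.values, [7.5, 7.5])
        np.testing.assert_allclose(
            res.normalized.intensities[:2], [[3.0, 3.0], [4.5, 4.5]]
        )
        # unidentified features are scaled by the same per-sample factor
        np.testing.assert_allclose(res.normalized.intensities[2], [15.0, 15.0])

    def test_equal_mtic_is_identity(self):
        t = PeakTable(["f1", "f2"], ["A", "B"], np.array([[1.0, 2.0], [3.0, 2.0]]),
                      np.array([True, True]), ["unknown"] * 2)
        res = mtic_normalize(t, grouping="global")
        np.testing.assert_allclose(res.normalized.intensities, t.intensities)

    def test_zero_mtic_sample_rejected(self):
        t = PeakTable(["f1", "u1"], ["A", "B"], np.array([[1.0, 0.0], [3.0, 2.0]]),
                      np.array([True, False]), ["unknown"] * 2)
        with pytest.raises(ValueError, match="zero mTIC"):
            mtic_normalize(t, grouping="global")

    def test_identified_sums_conserved_per_group(self, null_dataset):
        table, meta, _ = null_dataset
        res = mtic_normalize(table, meta, grouping="population_x_tissue")
        sums = res.normalized.intensities[res.normalized.identified].sum(axis=0)
        np.testing.assert_allclose(sums, res.mtic_reference.values, rtol=1e-9)

    def test_sample_scale_factors_cancel_up_to_group_reference(self, toy_table):
        # rescaling sample columns changes only the group's mTIC reference,
        # a single common factor: the normalized table is proportional
        res1 = mtic_normalize(toy_table, grouping="global")
        scaled = PeakTable(
            toy_table.feature_ids, toy_table.sample_ids,
            toy_table.intensities * np.array([3.0, 0.2]),
            toy_table.identified, toy_table.category,
        )
        res2 = mtic_normalize(scaled, grouping="global")
        ratio = res2.normalized.intensities / res1.normalized.intensities
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-12)
        # and the within-sample profile (which downstream log/z uses) is intact
        np.testing.assert_allclose(
            res2.normalized.intensities / res2.normalized.intensities.sum(axis=0),
            res1.normalized.intensities / res1.normalized.intensities.sum(axis=0),
            rtol=1e-12,
        )


def _one_feature_comparison(values, n_pos=2):
    ids = [f"s{i}" for i in range(len(values))]
    table = PeakTable(["f"], ids, np.array([values], dtype=float),
                      np.array([True]), ["unknown"])
    comp = ComparisonDesign("c", Tissue.LIVER, ids[:n_pos], ids[n_pos:],
                            ComparisonAxis.STATE_WITHIN_POPULATION)
    return table, comp


class TestLogZTransform:
    def test_powers_of_ten_z_scores(self):
        table, comp = _one_feature_comparison([1, 10, 100, 1000])
        z = log_z_transform(table, comp)
        np.testing.assert_allclose(
            z.values[0], [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-6
        )
        assert not z.constant_mask[0]

    def test_constant_feature_flagged_and_zeroed(self):
        table, comp = _one_feature_comparison([5, 5, 5, 5])
        z = log_z_transform(table, comp)
        assert z.constant_mask[0]
        np.testing.assert_array_equal(z.values[0], 0.0)

    def test_zero_replaced_by_half_minimum_positive(self):
        table, comp = _one_feature_comparison([0, 10, 100, 1000])
        z = log_z_transform(table, comp)
        # zero -> 5 before log10: same z-row as [5, 10, 100, 1000]
        ref_table, _ = _one_feature_comparison([5, 10, 100, 1000])
        ref = log_z_transform(ref_table, comp)
        np.testing.assert_allclose(z.values, ref.values)

    def test_all_zero_feature_dropped(self):
        ids = ["s0", "s1", "s2", "s3"]
        table = PeakTable(["dead", "ok"], ids,
                          np.array([[0, 0, 0, 0], [1, 2, 3, 4.0]]),
                          np.array([True, True]), ["unknown"] * 2)
        comp = ComparisonDesign("c", Tissue.LIVER, ids[:2], ids[2:],
                                ComparisonAxis.STATE_WITHIN_POPULATION)
        z = log_z_transform(table, comp)
        assert z.feature_ids == ["ok"]
        assert z.dropped_features == ["dead"]

    def test_rows_have_zero_mean_unit_sd(self, null_comparison):
        norm, comp = null_comparison
        z = log_z_transform(norm, comparison=comp)
        live = ~z.constant_mask
        np.testing.assert_allclose(z.values[live].mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values[live].std(axis=1, ddof=1), 1.0, rtol=1e-9)

    def test_z_invariant_to_positive_feature_scaling(self):
        table, comp = _one_feature_comparison([2, 9, 40, 700])
        z1 = log_z_transform(table, comp)
        table2, _ = _one_feature_comparison([2 * 13.7, 9 * 13.7, 40 * 13.7, 700 * 13.7])
        z2 = log_z_transform(table2, comp)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_too_few_samples_rejected(self):
        table, comp = _one_feature_comparison([1, 10], n_pos=1)
        with pytest.raises(ValueError, match="at least 3"):
            log_z_transform(table, comp)


class TestCategorizeFeatures:
    def test_subclass_superclass_and_fallback(self):
        ann = pd.DataFrame({
            "feature_id": ["glc", "amp", "odd"],
            "subclass": ["monosaccharides", None, "foo"],
            "superclass": [None, "Nucleosides, nucleotides, and analogues", "bar"],
        })
        cats = categorize_features(ann)
        assert cats["glc"] == CATEGORY_CARBOHYDRATES
        assert cats["amp"] == CATEGORY_NUCLEOTIDES
        assert cats["odd"] == CATEGORY_MISC

    def test_mapping_outside_five_categories_rejected(self):
        ann = pd.DataFrame({"feature_id": ["x"], "subclass": ["foo"]})
        with pytest.raises(ValueError, match="outside the five broad categories"):
            categorize_features(ann, mapping={"foo": "Lipids"})


class TestBiometrics:
    def test_worked_values(self):
        assert k_factor(1.0, 1.0) == 100.0
        assert k_factor(2.0, 2.0) == 25.0
        b = biometrics(10.0, 8.0, 2.0, 2.0)
        assert b.delta_wt_pct == -25.0  # denominator is the FINAL mass

    def test_initial_denominator_option(self):
        b = biometrics(10.0, 8.0, 2.0, 2.0, denominator="initial")
        assert b.delta_wt_pct == -20.0

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError):
            biometrics(0.0, 8.0, 2.0, 2.0)

    @settings(derandomize=True, max_examples=50)
    @given(m=st.floats(0.1, 100), x=st.floats(0.5, 30), c=st.floats(0.1, 10))
    def test_k_factor_homogeneity(self, m, x, c):
        # K(c*m, c^(1/3)*x) = K(m, x)
        assert k_factor(c * m, c ** (1 / 3) * x) == pytest.approx(k_factor(m, x), rel=1e-9)


class TestGroupCompareRouter:
    def test_normal_samples_route_to_anova_ns(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        rep = group_compare_router(groups)
        assert rep.route == "anova_tukey"
        assert sum(rep.normality_passes.values()) >= 3
        assert rep.omnibus_p > 0.05
        assert set(rep.pairwise["stars"]) == {"ns"}

    def test_heavy_tailed_routes_to_kruskal(self):
        rng = np.random.default_rng(7)
        groups = [rng.standard_cauchy(50) for _ in range(3)]
        rep = group_compare_router(groups)
        assert rep.route == "kruskal_dunn"
        assert sum(rep.normality_passes.values()) < 3

    def test_identical_groups_all_ns(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = group_compare_router([g, g, g])
        assert (rep.pairwise["stars"] == "ns").all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(3, 1, 30)]
        rep = group_compare_router(groups, names=["a", "b", "c"])
        sig = rep.pairwise[rep.pairwise["stars"] != "ns"]
        assert set(sig["group_b"]) == {"c"}

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            group_compare_router([[1.0, 2.0], [1.0, 2.0, 3.0]])


@pytest.mark.parametrize("p,stars", [
    (0.2, "ns"), (0.05, "*"), (0.01, "**"), (0.0005, "***"), (1e-5, "****"),
])
def test_significance_stars(p, stars):
    assert significance_stars(p) == stars
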