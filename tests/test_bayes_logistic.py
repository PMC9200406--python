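"""Bayesian logistic fits: oracle agreement, separation, calibration."""

import numpy as np
import pytest
import statsmodels.api as sm

from cavemetab import (
    BayesianLogisticRegression,
    PriorConfig,
    bayes_logistic_fit,
    class_level_tests,
    log_z_transform,
    run_feature_tests,
    saturation_class,
)
from cavemetab.data_model import ComparisonAxis, ComparisonDesign, Tissue
from cavemetab.preprocess import ZMatrix

from _oracles import grid_posterior_mode


def _toy_datasets():
    """Fixed toy problems, including completely separated ones."""
    rng = np.random.default_rng(2024)
    data = []
    # five completely separated configurations
    for gap in (0.5, 1.0, 2.0):
        x = np.array([-2.0, -1.5, -1.0, gap, gap + 1, gap + 2])
        data.append(("sep", x, np.array([0.0, 0, 0, 1, 1, 1])))
    data.append(("sep", np.array([1.0, 2, 3, 4, 5, 6]), np.array([0.0, 0, 0, 1, 1, 1])))
    data.append(("sep", np.array([3.0, 2, 1, -1, -2, -3]), np.array([0.0, 0, 0, 1, 1, 1])))
    # overlapping configurations
    for seed in range(6):
        r = np.random.default_rng(seed)
        x = r.normal(size=10)
        y = (r.random(10) > 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        data.append(("mix", x, y))
    data.append(("mix", np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 0, 1])))
    return data


class TestBayesLogisticFit:
    @pytest.mark.parametrize("kind,x,y", _toy_datasets())
    def test_mode_matches_grid_search_oracle(self, kind, x, y):
        est = BayesianLogisticRegression().fit(x, y)
        a, b = grid_posterior_mode(x, y)
        assert abs(est.intercept_std_ - a) < 1e-3
        assert abs(est.coef_std_[0] - b) < 1e-3
        if kind == "sep":
            assert est.separation_detected_
            assert np.isfinite(est.coef_[0])

    def test_separated_slope_finite_and_positive(self):
        fit = bayes_logistic_fit(np.array([-1.0, -1, -1, 1, 1, 1]),
                                 np.array([0.0, 0, 0, 1, 1, 1]))
        assert fit.separation_detected
        assert np.isfinite(fit.slope)
        assert fit.slope > 0

    def test_independent_covariate_gives_large_p(self):
        fit = bayes_logistic_fit(np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 0, 1]))
        assert abs(fit.z_stat) < 1.0
        assert fit.p_value > 0.5

    def test_label_flip_negates_slope_keeps_p(self):
        x = np.array([0.3, -1.2, 0.8, 1.9, -0.5, 0.1])
        y = np.array([0.0, 0, 1, 1, 0, 1])
        a = bayes_logistic_fit(x, y)
        b = bayes_logistic_fit(x, 1 - y)
        assert a.slope == pytest.approx(-b.slope, rel=1e-6)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_covariate_scaling_contract(self):
        x = np.array([0.3, -1.2, 0.8, 1.9, -0.5, 0.1])
        y = np.array([0.0, 0, 1, 1, 0, 1])
        a = bayes_logistic_fit(x, y)
        b = bayes_logistic_fit(7.0 * x, y)
        assert b.slope == pytest.approx(a.slope / 7.0, rel=1e-8)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-8)

    def test_wide_prior_converges_to_mle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        wide = PriorConfig(scale_slope=1e7, scale_intercept=1e7, df=np.inf)
        fit = bayes_logistic_fit(x, y, prior=wide)
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.slope == pytest.approx(mle.params[1], abs=1e-4)
        assert fit.intercept == pytest.approx(mle.params[0], abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            bayes_logistic_fit(np.ones(6), np.array([0.0, 0, 0, 1, 1, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bayes_logistic_fit(np.arange(4.0), np.zeros(4))


def _zmatrix(values, sample_ids, feature_ids):
    values = np.asarray(values, dtype=float)
    return ZMatrix(values=values, feature_ids=list(feature_ids),
                   sample_ids=list(sample_ids),
                   constant_mask=np.zeros(values.shape[0], dtype=bool),
                   dropped_features=[])


def _comparison(sample_ids, n_pos):
    return ComparisonDesign("cmp", Tissue.LIVER, list(sample_ids[:n_pos]),
                            list(sample_ids[n_pos:]),
                            ComparisonAxis.POPULATION_WITHIN_STATE)


class TestRunFeatureTests:
    def test_planted_feature_ranks_near_top(self):
        # a 2-SD effect among 50 null features should dominate the ranking;
        # asserted over 10 seeds since a single 6v6 draw is noisy
        n, n_null = 12, 50
        y = np.array([1.0] * 6 + [0.0] * 6)
        samples = [f"s{i}" for i in range(n)]
        ids = ["planted"] + [f"null{i}" for i in range(n_null)]
        ranks, directions = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            planted = np.where(y == 1, 2.0, 0.0) + rng.normal(0, 1, n)
            Z = np.vstack([planted, rng.normal(0, 1, (n_null, n))])
            Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
            res = run_feature_tests(_zmatrix(Z, samples, ids), _comparison(samples, 6))
            order = sorted(res, key=lambda r: r.p_value)
            ranks.append([r.feature_id for r in order].index("planted") + 1)
            directions.append(next(r for r in res if r.feature_id == "planted").direction)
        assert np.median(ranks) <= 3
        assert sum(r <= 3 for r in ranks) >= 6
        assert all(d == "up" for d in directions)

    def test_null_type_one_error_not_anticonservative(self):
        rng = np.random.default_rng(29)
        n_feat = 400
        samples = [f"s{i}" for i in range(12)]
        Z = rng.normal(size=(n_feat, 12))
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
        ids = [f"f{i}" for i in range(n_feat)]
        res = run_feature_tests(_zmatrix(Z, samples, ids), _comparison(samples, 6))
        rate = np.mean([r.p_value <= 0.05 for r in res])
        # upper edge of the 95% binomial band around 0.05 for 400 draws
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_feat)

    def test_empty_feature_set_gives_empty_results(self):
        samples = [f"s{i}" for i in range(12)]
        res = run_feature_tests(
            _zmatrix(np.empty((0, 12)), samples, []), _comparison(samples, 6)
        )
        assert res == []

    def test_bh_fdr_flag_increases_p(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(12)]
        Z = rng.normal(size=(30, 12))
        ids = [f"f{i}" for i in range(30)]
        raw = run_feature_tests(_zmatrix(Z, samples, ids), _comparison(samples, 6))
        adj = run_feature_tests(_zmatrix(Z, samples, ids), _comparison(samples, 6),
                                bh_fdr=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-12


class TestClassLevelTests:
    def test_coherent_class_beats_median_member(self):
        rng = np.random.default_rng(41)
        n, m = 12, 8
        y = np.array([1.0] * 6 + [0.0] * 6)
        shift = np.where(y == 1, 1.5, 0.0)
        Z = shift + rng.normal(0, 1, (m, n))
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
        ids = [f"lip{i}" for i in range(m)]
        samples = [f"s{i}" for i in range(n)]
        zm = _zmatrix(Z, samples, ids)
        comp = _comparison(samples, 6)
        members = run_feature_tests(zm, comp, n_orth=0)
        (cls_res,) = class_level_tests(zm, comp, {f: "TG" for f in ids})
        member_ps = sorted(r.p_value for r in members)
        assert cls_res.p_value < np.median(member_ps)

    def test_noise_class_not_significant(self):
        rng = np.random.default_rng(43)
        samples = [f"s{i}" for i in range(12)]
        Z = rng.normal(size=(6, 12))
        ids = [f"lip{i}" for i in range(6)]
        (res,) = class_level_tests(_zmatrix(Z, samples, ids),
                                   _comparison(samples, 6), {f: "PC" for f in ids})
        assert not res.significant

    def test_singleton_class_skipped(self):
        samples = [f"s{i}" for i in range(12)]
        Z = np.random.default_rng(1).normal(size=(2, 12))
        res = class_level_tests(_zmatrix(Z, samples, ["a", "b"]),
                                _comparison(samples, 6), {"a": "TG", "b": "SM"})
        assert res == []


@pytest.mark.parametrize("bonds,expected", [(0, "SFA"), (1, "MUFA"), (2, "PUFA"), (5, "PUFA")])
def test_saturation_class(bonds, expected):
    assert saturation_class(bonds) == expected
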