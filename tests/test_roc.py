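import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from metacad import roc


def binormal_sample(rng, a, b, n_pos, n_neg):
    """Scores drawn from the latent binormal model: neg ~ N(0,1), pos ~ N(a/b, 1/b)."""
    return roc.RatingData(rng.normal(a / b, 1.0 / b, n_pos), rng.normal(0.0, 1.0, n_neg))


class TestEmpiricalAuc:
    def test_pair_counting_example(self):
        data = roc.RatingData([3, 5], [1, 2, 4])
        assert roc.empirical_auc(data) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert roc.empirical_auc(roc.RatingData([5, 6], [1, 2])) == 1.0

    def test_all_ties(self):
        assert roc.empirical_auc(roc.RatingData([2, 2], [2, 2, 2])) == 0.5

    def test_direction_flips(self):
        data = roc.RatingData([1, 2], [5, 6], direction="lower_is_positive")
        assert roc.empirical_auc(data) == 1.0

    def test_empty_class_raises(self):
        with pytest.raises(roc.InsufficientDataError):
            roc.empirical_auc(roc.RatingData([], [1.0]))

    @given(st.sampled_from(["affine", "cube", "exp"]), st.integers(0, 10**6))
    def test_monotone_transform_invariance(self, transform, seed):
        r = np.random.default_rng(seed)
        pos, neg = r.normal(1, 1, 20), r.normal(0, 1, 30)
        f = {"affine": lambda x: 2 * x + 1, "cube": lambda x: x**3, "exp": np.exp}[transform]
        a0 = roc.empirical_auc(roc.RatingData(pos, neg))
        a1 = roc.empirical_auc(roc.RatingData(f(pos), f(neg)))
        assert a0 == pytest.approx(a1)


class TestCategorize:
    def test_quantile_bins_nonempty(self):
        data = roc.RatingData(np.arange(1, 6, dtype=float), np.arange(6, 11, dtype=float))
        table = roc.categorize_scores(data, 5)
        totals = table.neg_counts + table.pos_counts
        assert (totals > 0).all()
        assert table.neg_counts.sum() == 5 and table.pos_counts.sum() == 5

    def test_constant_scores_collapse_with_warning(self):
        data = roc.RatingData(np.ones(5), np.ones(5))
        with pytest.warns(UserWarning):
            table = roc.categorize_scores(data, 5)
        assert len(table.neg_counts) == 1

    def test_counts_match_brute_force_binning(self, rng):
        pos, neg = rng.normal(1, 1, 60), rng.normal(0, 1, 80)
        table = roc.categorize_scores(roc.RatingData(pos, neg), 8)
        edges = table.edges
        for scores, counts in ((neg, table.neg_counts), (pos, table.pos_counts)):
            brute = np.zeros(len(edges) + 1, int)
            for x in scores:
                brute[sum(e < x for e in edges)] += 1
            assert np.array_equal(brute, counts)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            roc.categorize_scores(roc.RatingData([1.0], [0.0]), 2)


class TestClosedForm:
    def test_zero_intercept_is_chance(self):
        assert roc.auc_closed_form(0.0, 2.7) == 0.5

    def test_known_values(self):
        assert roc.auc_closed_form(1.0, 1.0) == pytest.approx(0.7602, abs=1e-4)
        assert roc.auc_closed_form(np.sqrt(2), 1.0) == pytest.approx(0.8413, abs=1e-4)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            roc.auc_closed_form(1.0, 0.0)


class TestFitBinormal:
    def test_recovers_closed_form_auc(self):
        r = np.random.default_rng(42)
        fit = roc.fit_binormal(binormal_sample(r, 1.5, 1.0, 5000, 5000))
        assert fit.auc == pytest.approx(norm.cdf(1.5 / np.sqrt(2)), abs=0.02)
        assert fit.converged

    def test_null_case(self):
        r = np.random.default_rng(7)
        data = roc.RatingData(r.normal(0, 1, 2000), r.normal(0, 1, 2000))
        assert 0.45 <= roc.fit_binormal(data).auc <= 0.55

    def test_equal_variance_recovers_intercept(self):
        r = np.random.default_rng(3)
        a_true = 1.2
        fit = roc.fit_binormal(binormal_sample(r, a_true, 1.0, 5000, 5000), fix_b=True)
        assert fit.b == 1.0
        assert fit.a == pytest.approx(a_true, abs=0.1)

    def test_class_swap_symmetry(self):
        r = np.random.default_rng(11)
        data = binormal_sample(r, 1.0, 1.0, 300, 300)
        fwd = roc.fit_binormal(data).auc
        rev = roc.fit_binormal(roc.RatingData(data.neg_scores, data.pos_scores)).auc
        assert fwd + rev == pytest.approx(1.0, abs=0.01)

    def test_affine_transform_stability(self):
        r = np.random.default_rng(13)
        data = binormal_sample(r, 1.0, 0.8, 250, 250)
        shifted = roc.RatingData(3.0 * data.pos_scores - 7.0, 3.0 * data.neg_scores - 7.0)
        assert roc.fit_binormal(data).auc == pytest.approx(
            roc.fit_binormal(shifted).auc, abs=0.02
        )

    def test_se_shrinks_with_sample_size(self):
        r = np.random.default_rng(5)
        big = binormal_sample(r, 1.0, 1.0, 4000, 4000)
        small = roc.RatingData(big.pos_scores[:2000], big.neg_scores[:2000])
        ratio = roc.fit_binormal(small).se_auc / roc.fit_binormal(big).se_auc
        assert ratio == pytest.approx(np.sqrt(2), rel=0.25)

    def test_perfect_separation_flagged_not_crashed(self):
        data = roc.RatingData(np.arange(10, 20.0), np.arange(0, 10.0))
        fit = roc.fit_binormal(data)
        assert fit.degenerate
        # the 0.25 continuity correction pulls a perfect separation down
        # from 1.0 to a finite, still-high estimate
        assert fit.auc > 0.85

    def test_insufficient_data(self):
        with pytest.raises(roc.InsufficientDataError):
            roc.fit_binormal(roc.RatingData([1, 2, 3], [0, 1, 2, 3, 4]))


class TestScreening:
    def test_floor_and_ordering(self):
        fits = {
            "f1": roc.ROCFit(1, 1, 0.90, 0.02, 10, True, 0.0),
            "f2": roc.ROCFit(0.1, 1, 0.52, 0.04, 10, True, 0.0),
            "f3": roc.ROCFit(0.5, 1, 0.64, 0.03, 10, True, 0.0),
        }
        assert roc.screen_features(fits, floor=0.55) == ["f1", "f3"]

    def test_nothing_retained_warns(self):
        fits = {"f": roc.ROCFit(0, 1, 0.50, 0.04, 10, True, 0.0)}
        with pytest.warns(UserWarning):
            assert roc.screen_features(fits, floor=0.55) == []


def jackknife_cov(pos_i, neg_i, pos_j, neg_j):
    """Leave-one-image-out covariance of two paired empirical AUCs."""
    def auc(p, n):
        return roc.empirical_auc(roc.RatingData(p, n))

    reps = []
    m, n = len(pos_i), len(neg_i)
    for k in range(m):
        keep = np.arange(m) != k
        reps.append((auc(pos_i[keep], neg_i), auc(pos_j[keep], neg_j)))
    for k in range(n):
        keep = np.arange(n) != k
        reps.append((auc(pos_i, neg_i[keep]), auc(pos_j, neg_j[keep])))
    reps = np.array(reps)
    nn = len(reps)
    dev = reps - reps.mean(axis=0)
    return (nn - 1) / nn * (dev[:, 0] * dev[:, 1]).sum()


class TestPairedComparison:
    def _paired(self, seed=0, rho=0.6, d1=1.0, d2=1.0, m=67, n=133):
        r = np.random.default_rng(seed)
        cov = [[1, rho], [rho, 1]]
        pos = r.multivariate_normal([d1, d2], cov, m)
        neg = r.multivariate_normal([0, 0], cov, n)
        return (
            roc.RatingData(pos[:, 0], neg[:, 0]),
            roc.RatingData(pos[:, 1], neg[:, 1]),
        )

    def test_self_comparison_is_null(self):
        di, _ = self._paired()
        res = roc.compare_auc_paired(di, di)
        assert res.delta_auc == 0.0
        assert res.p_value == 1.0

    def test_covariance_matches_jackknife(self):
        di, dj = self._paired(seed=1, m=100, n=100)
        res = roc.compare_auc_paired(di, dj)
        jk = jackknife_cov(di.pos_scores, di.neg_scores, dj.pos_scores, dj.neg_scores)
        assert res.covariance == pytest.approx(jk, rel=0.10)

    def test_power_on_separated_aucs(self):
        # independent features with true AUCs ~0.90 vs ~0.60 at the study's
        # sample size: the paired test should nearly always reject
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            di = roc.RatingData(r.normal(1.81, 1, 67), r.normal(0, 1, 133))
            dj = roc.RatingData(r.normal(0.36, 1, 67), r.normal(0, 1, 133))
            if roc.compare_auc_paired(di, dj).p_value < 0.01:
                hits += 1
        assert hits >= 95

    def test_z_sign_matches_delta(self):
        di, dj = self._paired(seed=2, d1=1.5, d2=0.5)
        res = roc.compare_auc_paired(di, dj)
        assert res.delta_auc > 0 and res.z > 0

    def test_bootstrap_agrees_roughly_with_delong(self):
        di, dj = self._paired(seed=3)
        de = roc.compare_auc_paired(di, dj, method="delong")
        bo = roc.compare_auc_paired(di, dj, method="bootstrap", n_boot=400, seed=0)
        assert bo.delta_auc == de.delta_auc
        assert np.sign(bo.z) == np.sign(de.z)

    def test_misaligned_scores_rejected(self):
        with pytest.raises(ValueError):
            roc.compare_auc_paired(
                roc.RatingData([1, 2], [0, 1]), roc.RatingData([1, 2, 3], [0, 1])
            )


class TestCorrelation:
    def test_identity_and_negation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -x})
        corr = roc.feature_correlation(df)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 4, 5, 4]})
        r = roc.feature_correlation(df).loc["x", "y"]
        assert r == pytest.approx(3.5 / np.sqrt(5 * 4.75), abs=1e-4)  # 0.7182
        assert r == pytest.approx(np.corrcoef(df["x"], df["y"])[0, 1])

    def test_zero_variance_is_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        corr = roc.feature_correlation(df)
        assert np.isnan(corr.loc["x", "c"])
        assert corr.loc["x", "x"] == 1.0

    def test_positive_semidefinite(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        corr = roc.feature_correlation(df)
        assert np.linalg.eigvalsh(corr.to_numpy()).min() >= -1e-8

    def test_requires_three_complete_rows(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [2.0, 3.0]})
        with pytest.raises(roc.InsufficientDataError):
            roc.feature_correlation(df)


class TestChooseDirection:
    def test_oriented_features(self):
        labels = np.array([1, 0] * 50)
        scores = np.where(labels == 1, 5.0, 1.0) + np.arange(100) * 1e-3
        assert roc.choose_direction(scores, labels) == "higher_is_positive"
        assert roc.choose_direction(-scores, labels) == "lower_is_positive"
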