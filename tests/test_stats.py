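import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from exsmallrna.simulate import CohortConfig, simulate_cohort_counts
from exsmallrna.stats import (
    CountMatrix,
    cv_analysis,
    detection_summary,
    median_ratio_size_factors,
    normalize_counts,
    pca_mirna,
    rpm_normalize,
    saturation_curve,
    subsampled_saturation,
    wilcoxon_rank_sum,
)


def permutation_wilcoxon_oracle(x, y):
    """Exhaustive relabelling of the raw observations (independent route)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    mu = n1 * (len(pooled) + 1) / 2
    t_obs = ranks[:n1].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= abs(t_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestRPM:
    def test_basic(self):
        assert rpm_normalize(5, 1_000_000) == pytest.approx(5.0)
        assert rpm_normalize(0, 10) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)

    def test_vector_sums_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(0, 100, size=20))
        rpm = rpm_normalize(counts, int(counts.sum()))
        assert rpm.sum() == pytest.approx(1e6)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(median_ratio_size_factors(m), 1.0)

    def test_doubled_sample_closed_form(self):
        # two samples, second exactly 2x the first: factors (1/sqrt2, sqrt2)
        m = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = median_ratio_size_factors(m)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_single_sample_unit_factor(self):
        m = pd.DataFrame({"only": [3, 1, 4]})
        assert median_ratio_size_factors(m).tolist() == [1.0]

    def test_zero_features_excluded_from_median(self):
        m = pd.DataFrame({"a": [10, 0, 10], "b": [10, 50, 10]})
        sf = median_ratio_size_factors(m)  # row with the zero is ignored
        assert np.allclose(sf, 1.0)

    def test_no_all_positive_feature_rejected(self):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="no feature"):
            median_ratio_size_factors(m)

    def test_recovers_scaling_constants_up_to_global_factor(self):
        rng = np.random.default_rng(7)
        base = rng.integers(50, 500, size=(40, 1)).astype(float)
        scales = np.array([0.5, 1.0, 2.0, 4.0, 0.25, 1.5])
        m = pd.DataFrame(base * scales)  # noiseless per-sample scaling
        sf = median_ratio_size_factors(m)
        ratio = sf.to_numpy() / scales
        assert np.allclose(ratio, ratio[0], atol=1e-9)


class TestDetection:
    def test_strict_threshold_and_grid(self):
        m = pd.DataFrame({"s1": [11, 10], "s2": [11, 10], "s3": [9, 10]})
        ds = detection_summary(m, thresholds=(10,))
        # feature 1: >10 in 2/3 samples -> detected at fractions <= 60%
        assert ds.loc["at_least_1", ">10"] == 1
        assert ds.loc["60%", ">10"] == 1
        assert ds.loc["70%", ">10"] == 0
        # a count of exactly 10 is never ">10"
        assert ds[">10"].max() == 1

    def test_detected_everywhere(self):
        m = pd.DataFrame({"s1": [100], "s2": [100]})
        ds = detection_summary(m)
        assert ds.loc["100%", ">10"] == 1
        assert ds.loc["100%", ">50"] == 1

    def test_monotone_along_grid_and_thresholds(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 200, size=(50, 10)))
        ds = detection_summary(m)
        for col in ds.columns:
            assert (np.diff(ds[col].to_numpy()) <= 0).all()
        assert (ds[">50"] <= ds[">10"]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detection_summary(pd.DataFrame())


class TestSaturation:
    def test_single_bin_median(self):
        m = pd.DataFrame({"s1": [20, 5], "s2": [60, 5], "s3": [200, 5]})
        depth = pd.Series({"s1": 1.2e6, "s2": 1.5e6, "s3": 1.9e6})
        curve = saturation_curve(m, depth)
        assert list(curve.index) == [1]
        assert curve.loc[1, 10] == 1.0  # median of (1, 1, 1)

    def test_even_bin_median_is_midpoint(self):
        m = pd.DataFrame({"s1": [20, 20, 0, 0], "s2": [20, 20, 20, 20]})
        depth = pd.Series({"s1": 5.0e5, "s2": 8.0e5})
        curve = saturation_curve(m, depth, thresholds=(10,))
        assert curve.loc[0, 10] == 3.0  # midpoint of (2, 4)

    def test_subsampling_monotone_in_expectation(self):
        rng = np.random.default_rng(5)
        counts = pd.Series(rng.integers(0, 2000, size=300))
        curve = subsampled_saturation(counts, [1000, 10_000, 100_000], seed=9)
        for thr in (1, 10, 50):
            assert (np.diff(curve[thr].to_numpy()) >= 0).all()


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(loc=rng.normal(), size=n2)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            permutation_wilcoxon_oracle(x, y)
        )

    def test_exact_with_ties_matches_enumeration(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 4.0, 5.0, 5.0]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(permutation_wilcoxon_oracle(x, y))

    def test_asymptotic_close_to_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(0.8, size=25)
        ours = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1, 1, 1] * 10, [1, 1, 1] * 10) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCV:
    def _cohort(self, seed=21, intra=0.05, inter=0.5):
        cfg = CohortConfig(6, 6, "urine", inter, intra, 100_000, seed)
        matrix, sheet = simulate_cohort_counts(cfg, n_mirna=120)
        return matrix, sheet.set_index("sample_id")["subject_id"]

    def test_constant_feature_cv_zero(self):
        m = pd.DataFrame(
            {f"s{i}": [100, 60 + i] for i in range(6)},
            index=["const", "var"],
        )
        subj = pd.Series({f"s{i}": f"p{i % 2}" for i in range(6)})
        report = cv_analysis(m, subj, size_factors=pd.Series(1.0, index=m.columns),
                             min_count=10, min_fraction=0.5, min_samples_per_subject=3)
        assert report.per_mirna.loc["const", "cv"] == 0.0

    def test_hand_computed_cv(self):
        # normalized counts {1,2,3}: mean 2, sample sd 1 -> CV 0.5
        m = pd.DataFrame(
            {"a": [1], "b": [2], "c": [3], "d": [4], "e": [4], "f": [4]},
            index=["m1"],
        )
        subj = pd.Series({"a": "p1", "b": "p1", "c": "p1",
                          "d": "p2", "e": "p2", "f": "p2"})
        report = cv_analysis(m, subj, size_factors=pd.Series(1.0, index=m.columns),
                             min_count=0, min_fraction=0.0, min_samples_per_subject=3)
        assert report.subject_cvs["p1"].loc["m1"] == pytest.approx(0.5)
        assert report.subject_cvs["p2"].loc["m1"] == 0.0

    def test_cv_scale_invariance(self):
        matrix, subj = self._cohort()
        sf = pd.Series(1.0, index=matrix.columns)
        r1 = cv_analysis(matrix, subj, size_factors=sf)
        r2 = cv_analysis(matrix * 7, subj, size_factors=sf * 1.0)
        assert np.allclose(
            r1.per_mirna["cv"].dropna(), r2.per_mirna["cv"].dropna()
        )

    def test_intra_below_inter_with_strong_subject_effects(self):
        matrix, subj = self._cohort(seed=33)
        report = cv_analysis(matrix, subj)
        for subject, p in report.wilcoxon_p.items():
            assert p < 0.05
            assert report.subject_cvs[subject].median() < report.inter_cv.median()

    def test_no_qualifying_subject_rejected(self):
        matrix, subj = self._cohort()
        with pytest.raises(ValueError, match="no subject"):
            cv_analysis(matrix, subj, min_samples_per_subject=99)

    def test_inter_random_choice_seeded(self):
        matrix, subj = self._cohort()
        r1 = cv_analysis(matrix, subj, inter_choice="random", seed=5)
        r2 = cv_analysis(matrix, subj, inter_choice="random", seed=5)
        assert r1.inter_samples == r2.inter_samples


class TestPCA:
    def _two_cluster_matrix(self, seed=11):
        rng = np.random.default_rng(seed)
        base_a = rng.integers(100, 1000, size=40)
        base_b = base_a * rng.uniform(0.1, 10, size=40)
        cols = {}
        for i in range(5):
            cols[f"A{i}"] = rng.poisson(base_a)
            cols[f"B{i}"] = rng.poisson(base_b)
        return pd.DataFrame(cols)

    def test_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        m = self._two_cluster_matrix()
        res = pca_mirna(m)
        labels = [c[0] for c in m.columns]
        score = silhouette_score(res.scores[["PC1"]], labels)
        assert score > 0

    def test_duplicated_samples_identical_scores(self):
        m = self._two_cluster_matrix()
        m2 = m.copy()
        m2["A0_dup"] = m["A0"]
        res = pca_mirna(m2)
        assert np.allclose(res.scores.loc["A0"], res.scores.loc["A0_dup"])

    def test_variance_fractions_valid(self):
        res = pca_mirna(self._two_cluster_matrix(), n_components=4)
        var = res.variance_explained.to_numpy()
        assert var.sum() <= 1.0 + 1e-9
        assert (np.diff(var) <= 1e-12).all()
        assert ((var >= 0) & (var <= 1)).all()

    def test_sign_convention_largest_loading_positive(self):
        res = pca_mirna(self._two_cluster_matrix())
        for pc in res.loadings.columns:
            col = res.loadings[pc]
            assert col.loc[col.abs().idxmax()] > 0

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [2, 3]})
        with pytest.raises(ValueError, match="3 samples"):
            pca_mirna(m)


class TestCountMatrix:
    def test_validation(self):
        counts = pd.DataFrame({"s1": [1, 2]})
        meta = pd.DataFrame({"fluid": ["plasma"]}, index=["s1"])
        CountMatrix(counts, meta)  # ok
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(counts - 5, meta)
        with pytest.raises(ValueError, match="metadata"):
            CountMatrix(pd.DataFrame({"s2": [1]}), meta)
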