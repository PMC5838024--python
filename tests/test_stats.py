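"""Normalization, alpha diversity, Bray-Curtis, ordination, and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from ambin.errors import ArgumentError
from ambin.stats import (
    alpha_diversity, bray_curtis, cap, diversity_report, fisher_alpha,
    group_ttest, pcoa, permanova, size_factors_median_of_ratios,
)


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        matrix = pd.DataFrame([[10, 10], [5, 5], [3, 3]], columns=["a", "b"])
        assert np.allclose(size_factors_median_of_ratios(matrix), 1.0)

    def test_doubled_sample_hand_computation(self):
        """5-OTU fixture with B = 2A elementwise: ratio of factors is 2 and
        each factor matches the direct median-of-ratios computation."""
        a = np.array([10.0, 20.0, 5.0, 8.0, 100.0])
        matrix = pd.DataFrame({"A": a, "B": 2 * a})
        factors = size_factors_median_of_ratios(matrix)
        geomean = np.sqrt(a * 2 * a)
        expected_a = np.median(a / geomean)
        assert factors["B"] / factors["A"] == pytest.approx(2.0)
        assert factors["A"] == pytest.approx(expected_a)

    def test_single_sample_factor_one(self):
        matrix = pd.DataFrame({"only": [4, 9, 16]})
        assert size_factors_median_of_ratios(matrix)["only"] == pytest.approx(1.0)

    def test_scale_equivariance(self):
        """Scaling one sample's counts by c multiplies its factor relative
        to every other sample by c (the per-OTU geometric means absorb a
        common c**(1/n), so only ratios of factors are equivariant)."""
        rng = np.random.default_rng(8)
        matrix = pd.DataFrame(rng.poisson(50, size=(40, 6)) + 1,
                              columns=list("abcdef"))
        base = size_factors_median_of_ratios(matrix)
        scaled = matrix.copy()
        scaled["c"] = scaled["c"] * 3
        factors = size_factors_median_of_ratios(scaled)
        assert (factors["c"] / factors["a"]) / (base["c"] / base["a"]) == \
            pytest.approx(3.0, rel=1e-6)

    def test_fallback_without_all_positive_row(self, caplog):
        matrix = pd.DataFrame([[10, 0], [0, 10]], columns=["a", "b"])
        factors = size_factors_median_of_ratios(matrix)
        assert (factors > 0).all()


class TestAlphaDiversity:
    def test_uniform_community_closed_forms(self):
        out = alpha_diversity([5] * 8)
        assert out["shannon"] == pytest.approx(np.log(8))
        assert out["inv_simpson"] == pytest.approx(8.0)
        assert out["simpson"] == pytest.approx(1 - 1 / 8)
        assert out["observed"] == 8

    def test_chao1_equals_observed_without_rare_counts(self):
        out = alpha_diversity([5, 7, 9, 3])
        assert out["chao1"] == out["observed"] == 4

    def test_chao1_singleton_doubleton_formula(self):
        out = alpha_diversity([1, 1, 1, 2, 5])
        assert out["chao1"] == pytest.approx(5 + 3 * 2 / (2 * 2))

    def test_fisher_alpha_matches_bisection_oracle(self):
        alpha = fisher_alpha(10, 100)
        lo, hi = 1e-9, 1e6  # independent bisection on S = a ln(1 + N/a)
        for _ in range(200):
            mid = (lo + hi) / 2
            if mid * np.log(1 + 100 / mid) < 10:
                lo = mid
            else:
                hi = mid
        assert alpha == pytest.approx((lo + hi) / 2, abs=1e-8)
        assert alpha * np.log(1 + 100 / alpha) == pytest.approx(10, abs=1e-8)

    def test_inverse_relation_and_skbio_cross_check(self):
        counts = [13, 2, 8, 1, 1, 40]
        out = alpha_diversity(counts)
        assert out["inv_simpson"] == pytest.approx(1 / (1 - out["simpson"]))
        assert out["shannon"] == pytest.approx(
            skbio_alpha.shannon(counts, base=np.e))
        assert out["chao1"] == pytest.approx(skbio_alpha.chao1(counts))
        assert out["fisher_alpha"] == pytest.approx(
            skbio_alpha.fisher_alpha(counts), rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ArgumentError):
            alpha_diversity([0, 0, 0])

    def test_report_shape(self):
        matrix = pd.DataFrame([[3, 1], [2, 6], [9, 0]], columns=["a", "b"])
        report = diversity_report(matrix)
        assert list(report.index) == ["a", "b"]
        assert report.shape == (2, 6)


class TestGroupTtest:
    GROUPS = {"a1": "A", "a2": "A", "a3": "A",
              "b1": "B", "b2": "B", "b3": "B"}

    def test_identical_groups_t_zero_p_one(self):
        values = pd.Series({"a1": 1.0, "a2": 2.0, "a3": 3.0,
                            "b1": 1.0, "b2": 2.0, "b3": 3.0})
        row = group_ttest(values, self.GROUPS).iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_zero_variance_separated_groups_flagged(self):
        values = pd.Series({"a1": 0.0, "a2": 0.0, "a3": 0.0,
                            "b1": 1.0, "b2": 1.0, "b3": 1.0})
        row = group_ttest(values, self.GROUPS).iloc[0]
        assert row["degenerate"] and row["p"] == 0.0
        assert np.isinf(row["t"])

    def test_too_small_group_rejected(self):
        with pytest.raises(ArgumentError):
            group_ttest(pd.Series({"a1": 1.0, "b1": 2.0, "b2": 3.0}),
                        {"a1": "A", "b1": "B", "b2": "B"})

    def test_null_calibration(self):
        """Equal-mean normal groups: rejection at 0.05 stays within the
        binomial confidence band over 1000 replicates."""
        rng = np.random.default_rng(17)
        groups = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        rejections = 0
        reps = 1000
        for _ in range(reps):
            values = pd.Series(rng.normal(size=8), index=list(groups))
            rejections += group_ttest(values, groups).iloc[0]["p"] < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        matrix = pd.DataFrame({"a": [1, 2, 0], "b": [1, 2, 0], "c": [0, 0, 5]})
        d = bray_curtis(matrix)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == 1.0

    def test_hand_evaluated_formula(self):
        matrix = pd.DataFrame({"a": [1, 1, 0], "b": [0, 1, 1]})
        assert bray_curtis(matrix)["a", "b"] == pytest.approx(0.5)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(4)
        matrix = pd.DataFrame(rng.poisson(5, size=(20, 6)) + 1)
        d = bray_curtis(matrix)
        assert np.all(d.data >= 0) and np.all(d.data <= 1)
        assert np.allclose(d.data, d.data.T)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ArgumentError):
            bray_curtis(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


class TestPcoa:
    def test_euclidean_reconstruction(self):
        """PCoA of Euclidean distances of known 2-D points reproduces the
        inter-point distances to 1e-8."""
        points = np.array([[0, 0], [3, 0], [0, 4], [5, 5], [1, 2]], float)
        d = DistanceMatrix(squareform(pdist(points)),
                           ids=[f"p{i}" for i in range(5)])
        coords = pcoa(d).coordinates.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, d.data, atol=1e-8)

    def test_collinear_points_single_positive_eigenvalue(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                           ids=list("abc"))
        result = pcoa(d)
        assert result.coordinates.shape[1] == 1

    def test_eigenvalue_sum_bounded_by_trace(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(8, 3))
        d = DistanceMatrix(squareform(pdist(points)),
                           ids=[f"p{i}" for i in range(8)])
        result = pcoa(d)
        gower = -0.5 * (np.eye(8) - 1 / 8) @ (d.data ** 2) @ (np.eye(8) - 1 / 8)
        assert result.eigenvalues[result.eigenvalues > 0].sum() <= \
            np.trace(gower) + 1e-9

    def test_matches_skbio(self):
        rng = np.random.default_rng(15)
        points = rng.normal(size=(10, 4))
        d = DistanceMatrix(squareform(pdist(points)),
                           ids=[f"p{i}" for i in range(10)])
        mine = pcoa(d)
        theirs = skbio_pcoa(d)
        n_pos = mine.coordinates.shape[1]
        assert np.allclose(
            np.sort(mine.eigenvalues[:n_pos]),
            np.sort(theirs.eigvals.to_numpy()[:n_pos]), atol=1e-8,
        )


class TestCap:
    GROUPS5 = {f"s{i}": ["A", "B", "C", "D", "E"][i % 5] for i in range(20)}

    def test_at_most_groups_minus_one_axes(self):
        rng = np.random.default_rng(19)
        matrix = pd.DataFrame(rng.poisson(20, size=(30, 20)) + 1,
                              columns=[f"s{i}" for i in range(20)])
        result = cap(bray_curtis(matrix), self.GROUPS5)
        assert result.coordinates.shape[1] <= 4

    def test_separated_clusters_fraction_near_one(self):
        """Tight, widely separated group clusters: the constrained inertia
        fraction approaches 1 and matches a direct between/within
        decomposition of the PCoA scores."""
        rng = np.random.default_rng(20)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        points = np.vstack([c + rng.normal(0, 0.01, (5, 2)) for c in centers])
        ids = [f"s{i}" for i in range(20)]
        groups = {f"s{i}": f"G{i // 5}" for i in range(20)}
        d = DistanceMatrix(squareform(pdist(points)), ids=ids)
        result = cap(d, groups)
        assert result.constrained_fraction > 0.999
        y = pcoa(d).coordinates.to_numpy()
        labels = np.array([groups[s] for s in ids])
        between = sum(
            (labels == g).sum() * (y[labels == g].mean(axis=0) ** 2).sum()
            for g in np.unique(labels)
        )  # scores are column-centered, so between-inertia is over group means
        assert result.constrained_fraction == pytest.approx(
            between / (y ** 2).sum(), abs=1e-9)

    def test_permuted_labels_reduce_constrained_fraction(self):
        rng = np.random.default_rng(21)
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5]], float)
        points = np.vstack([c + rng.normal(0, 0.3, (5, 2)) for c in centers])
        ids = [f"s{i}" for i in range(20)]
        groups = {f"s{i}": f"G{i // 5}" for i in range(20)}
        d = DistanceMatrix(squareform(pdist(points)), ids=ids)
        structured = cap(d, groups).constrained_fraction
        worse = 0
        for _ in range(20):
            perm = rng.permutation(20)
            shuffled = {ids[i]: groups[ids[perm[i]]] for i in range(20)}
            worse += cap(d, shuffled).constrained_fraction < structured
        assert worse >= 18

    def test_single_group_rejected(self):
        d = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["a", "b"])
        with pytest.raises(ArgumentError):
            cap(d, {"a": "G", "b": "G"})


class TestPermanova:
    def test_equidistant_null(self):
        n = 9
        d = DistanceMatrix(np.ones((n, n)) - np.eye(n),
                           ids=[f"s{i}" for i in range(n)])
        groups = {f"s{i}": f"G{i % 3}" for i in range(n)}
        f, p = permanova(d, groups, n_perm=499, seed=1)
        assert np.isfinite(f)
        assert p > 0.9

    def test_two_clusters_attain_minimal_p(self):
        rng = np.random.default_rng(22)
        points = np.vstack([rng.normal(0, 0.05, (10, 3)),
                            rng.normal(8, 0.05, (10, 3))])
        d = DistanceMatrix(squareform(pdist(points)),
                           ids=[f"s{i}" for i in range(20)])
        groups = {f"s{i}": "A" if i < 10 else "B" for i in range(20)}
        _, p = permanova(d, groups, n_perm=999, seed=2)
        assert p == pytest.approx(1 / 1000)

    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(23)
        points = rng.normal(size=(12, 3))
        ids = [f"s{i}" for i in range(12)]
        d = DistanceMatrix(squareform(pdist(points)), ids=ids)
        groups = {s: f"G{i % 3}" for i, s in enumerate(ids)}
        f, _ = permanova(d, groups, n_perm=9, seed=0)
        theirs = skbio_permanova(d, [groups[s] for s in ids], permutations=9)
        assert f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_null_p_values_roughly_uniform(self):
        """Labels independent of distances: KS distance of the p-value
        sample from uniform stays small over 500 datasets."""
        from scipy import stats as sps

        rng = np.random.default_rng(24)
        groups = {f"s{i}": ["A", "B", "C", "D"][i % 4] for i in range(16)}
        pvals = []
        for k in range(500):
            matrix = pd.DataFrame(rng.poisson(50, size=(30, 16)) + 1,
                                  columns=[f"s{i}" for i in range(16)])
            _, p = permanova(bray_curtis(matrix), groups, n_perm=99,
                             seed=5000 + k)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.08

    def test_invalid_permutation_count(self):
        d = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["a", "b"])
        with pytest.raises(ArgumentError):
            permanova(d, {"a": "A", "b": "B"}, n_perm=0)
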