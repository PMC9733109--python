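"""Ordination, dissimilarity, and permutation tests on distance matrices.

scikit-bio serves as the independent cross-check for ANOSIM / Mantel /
PERMANOVA statistics; small instances are also checked against exhaustive
label enumeration.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

import skbio
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from competab import stats


def _dm(points: np.ndarray, metric: str = "euclidean") -> stats.DistanceMatrix:
    return stats.DistanceMatrix(
        range(len(points)), squareform(pdist(points, metric=metric))
    )


class TestPCACounts:
    def test_loadings_orthonormal_and_variance_sums_to_one(self, rng):
        X = rng.integers(0, 50, size=(8, 5)).astype(float)
        res = stats.pca_counts(X, min_total_fraction=0.0)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(res.loadings.shape[1]), atol=1e-10
        )
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_first_axis_separates_constructed_clusters(self, rng):
        a = rng.poisson([40, 5, 5, 40], size=(6, 4))
        b = rng.poisson([5, 40, 40, 5], size=(6, 4))
        res = stats.pca_counts(np.vstack([a, b]), min_total_fraction=0.0)
        from sklearn.metrics import silhouette_score

        labels = [0] * 6 + [1] * 6
        assert silhouette_score(res.scores[:, :1], labels) > 0

    def test_identical_rows_have_no_variance(self):
        X = np.tile([10.0, 20.0, 5.0], (4, 1))
        res = stats.pca_counts(X, min_total_fraction=0.0)
        assert res.variance_explained.sum() == pytest.approx(0.0, abs=1e-12)

    def test_rare_behavior_columns_dropped(self):
        X = np.array([[50.0, 2.0, 48.0]] * 3)  # middle column is 2% of events
        res = stats.pca_counts(X, min_total_fraction=0.05)
        assert len(res.variables) == 2

    def test_too_few_columns_rejected(self):
        X = np.array([[99.0, 1.0]] * 3)
        with pytest.raises(ValueError):
            stats.pca_counts(X, min_total_fraction=0.05)


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        dm = stats.bray_curtis([[3, 0, 2], [3, 0, 2], [0, 5, 0]])
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(1.0)

    def test_hand_formula_small_matrix(self):
        X = np.array([[1.0, 2, 0, 4], [2.0, 1, 3, 0], [0.0, 0, 1, 1]])
        dm = stats.bray_curtis(X)
        for i, j in itertools.combinations(range(3), 2):
            expected = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
            assert dm.values[i, j] == pytest.approx(expected)

    def test_bounds_and_zero_rows(self, rng):
        X = rng.integers(0, 20, size=(6, 4)) + 1
        dm = stats.bray_curtis(X)
        assert ((dm.values >= 0) & (dm.values <= 1)).all()
        with pytest.raises(ValueError):
            stats.bray_curtis([[0, 0], [1, 2]])


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        pts = np.vstack([np.zeros((3, 2)), np.ones((4, 2)) * 10])
        r = stats.anosim(_dm(pts), ["a"] * 3 + ["b"] * 4, n_perm=99, seed=1)
        assert r.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        pts[:5] += 1.0
        dm = _dm(pts)
        groups = ["a"] * 5 + ["b"] * 5
        ours = stats.anosim(dm, groups, n_perm=99, seed=2)
        theirs = skbio_anosim(
            skbio.DistanceMatrix(dm.values), grouping=groups, permutations=9
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-12)
        assert -1.0 <= ours.statistic <= 1.0

    def test_p_matches_exhaustive_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = _dm(pts)
        codes = np.array([0, 0, 0, 1, 1, 1])
        ours = stats.anosim(dm, codes, n_perm=4999, seed=3)
        ranks = rankdata(dm.condensed())
        i, j = np.triu_indices(6, 1)

        def r_stat(c):
            within = c[i] == c[j]
            return (ranks[~within].mean() - ranks[within].mean()) / 7.5

        exhaustive = np.mean(
            [
                r_stat(np.array(p)) >= ours.statistic - 1e-12
                for p in itertools.permutations(codes)
            ]
        )
        assert ours.p_value == pytest.approx(exhaustive, abs=0.03)

    def test_reproducible_given_seed(self, rng):
        pts = rng.normal(size=(8, 2))
        dm = _dm(pts)
        g = ["a"] * 4 + ["b"] * 4
        assert (
            stats.anosim(dm, g, n_perm=199, seed=7).p_value
            == stats.anosim(dm, g, n_perm=199, seed=7).p_value
        )

    def test_singleton_group_rejected(self, rng):
        dm = _dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            stats.anosim(dm, ["a", "a", "a", "a", "b"], n_perm=9, seed=1)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = _dm(rng.normal(size=(6, 2)))
        r = stats.mantel(dm, dm, n_perm=99, seed=1)
        assert r.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        a, b = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
        ours = stats.mantel(_dm(a), _dm(b), n_perm=99, seed=2)
        theirs_r, _, _ = skbio_mantel(
            skbio.DistanceMatrix(_dm(a).values),
            skbio.DistanceMatrix(_dm(b).values),
            method="pearson",
            permutations=9,
        )
        assert ours.statistic == pytest.approx(theirs_r, rel=1e-10)

    def test_p_matches_exhaustive_enumeration(self, rng):
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        dma, dmb = _dm(a), _dm(b)
        ours = stats.mantel(dma, dmb, n_perm=9999, seed=3)
        iu = np.triu_indices(5, 1)
        v1 = dma.values[iu]

        def corr(m):
            v2 = m[iu]
            return np.corrcoef(v1, v2)[0, 1]

        exhaustive = np.mean(
            [
                corr(dmb.values[np.ix_(p, p)]) >= ours.statistic - 1e-12
                for p in itertools.permutations(range(5))
            ]
        )
        assert ours.p_value == pytest.approx(exhaustive, abs=0.03)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.mantel(_dm(rng.normal(size=(5, 2))), _dm(rng.normal(size=(6, 2))))


class TestPermanova:
    def test_single_factor_matches_direct_decomposition(self, rng):
        resp = pd.DataFrame(np.abs(rng.normal(size=(12, 3))))
        pred = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        res = stats.permanova(resp, pred, n_perm=99, seed=4)[0]
        # direct within/between decomposition on the same distance matrix
        Y = np.log1p(resp.to_numpy())
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        D = squareform(pdist(Y))
        n = 12
        ss_tot = (D[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_w = 0.0
        for grp in ("a", "b"):
            idx = np.where(pred["g"] == grp)[0]
            sub = D[np.ix_(idx, idx)]
            ss_w += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        f_direct = (ss_tot - ss_w) / (ss_w / (n - 2))
        assert res.statistic == pytest.approx(f_direct, rel=1e-10)

    def test_single_factor_matches_skbio(self, rng):
        resp = pd.DataFrame(np.abs(rng.normal(size=(10, 4))))
        pred = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        res = stats.permanova(resp, pred, n_perm=99, seed=5)[0]
        Y = np.log1p(resp.to_numpy())
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(squareform(pdist(Y))),
            grouping=pred["g"].tolist(),
            permutations=9,
        )
        assert res.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_pseudo_f_monotone_in_separation(self, rng):
        base = np.abs(rng.normal(size=(12, 3)))
        pred = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        fs = []
        for shift in (0.0, 2.0, 6.0):
            resp = base.copy()
            resp[6:] += shift
            fs.append(stats.permanova(resp, pred, n_perm=19, seed=1)[0].statistic)
        assert fs[0] < fs[1] < fs[2]

    def test_sequential_terms_and_rank_deficiency(self, rng):
        resp = np.abs(rng.normal(size=(12, 3)))
        pred = pd.DataFrame(
            {
                "g": ["a"] * 6 + ["b"] * 6,
                "dup": ["a"] * 6 + ["b"] * 6,  # perfectly collinear with g
                "w": rng.normal(size=12),
            }
        )
        with pytest.warns(UserWarning, match="rank deficient"):
            res = stats.permanova(resp, pred, n_perm=19, seed=2)
        assert [r.extra["term"] for r in res] == ["g", "w"]

    def test_missing_values_rejected(self, rng):
        resp = np.abs(rng.normal(size=(6, 2)))
        resp[0, 0] = np.nan
        with pytest.raises(ValueError):
            stats.permanova(resp, pd.DataFrame({"g": list("aaabbb")}), n_perm=9)


class TestPermutationEstimator:
    def test_p_value_lower_bound_is_one_over_nperm_plus_one(self, rng):
        pts = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 100])
        r = stats.anosim(_dm(pts), ["a"] * 4 + ["b"] * 4, n_perm=199, seed=1)
        assert r.p_value >= 1 / 200
        assert r.n_perm == 199 and r.seed == 1
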