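"""Hierarchical clustering, cut selection, consolidation, and transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from regencomp import reference
from regencomp.cluster import (
    ClusterAssignment,
    ClusteringParams,
    bin_zscores,
    build_foldchange_matrix,
    classify_focal_clusters,
    coarse_classify_comparator,
    consolidate_clusters,
    cut_dendrogram,
    euclidean_distance,
    hierarchical_cluster,
    select_cut_height,
    zscore_transform,
)
from regencomp.expr import CONTRASTS, DEGTable

COLS = list(CONTRASTS)


def _deg_table(values, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(len(values))]
    return DEGTable(
        log2fc=pd.DataFrame(values, index=genes, columns=COLS),
        p_value=pd.DataFrame(0.01, index=genes, columns=COLS),
    )


class TestFoldchangeMatrix:
    def test_single_deg_gives_1x6(self):
        deg = _deg_table([[1, 2, 3, 4, 5, 6]])
        mat = build_foldchange_matrix(deg, deg.log2fc.index)
        assert mat.shape == (1, 6)
        assert np.allclose(mat.to_numpy(), [[1, 2, 3, 4, 5, 6]])

    def test_values_identical_to_table(self):
        rng = np.random.default_rng(0)
        deg = _deg_table(rng.normal(size=(10, 6)))
        union = deg.log2fc.index[[1, 3, 5]]
        mat = build_foldchange_matrix(deg, union)
        assert mat.equals(deg.log2fc.loc[union])

    def test_empty_union_rejected(self):
        deg = _deg_table([[0] * 6])
        with pytest.raises(ValueError):
            build_foldchange_matrix(deg, deg.log2fc.index[:0])


class TestEuclideanDistance:
    def test_three_four_five(self):
        d = euclidean_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(50, 6))
        assert np.allclose(
            euclidean_distance(rows), reference.pairwise_distances_loop(rows),
            atol=1e-12,
        )

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.array([[0.0, np.nan]]))


class TestLinkage:
    def test_three_equidistant_points_average(self):
        # equilateral triangle, side 1
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        Z = hierarchical_cluster(euclidean_distance(pts), "average")
        assert np.allclose(Z[:, 2], 1.0)

    def test_ward_one_dimensional_merge_order(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        Z = hierarchical_cluster(euclidean_distance(pts), "ward2")
        # first merge joins 0 and 1 at their Euclidean distance
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        # second merge height reflects the variance increase of {0,1}+{10}
        oracle = reference.greedy_linkage(pts, "ward2")
        assert Z[1, 2] == pytest.approx(oracle[1][2])

    @pytest.mark.parametrize("method", ["ward2", "average"])
    def test_merge_sequence_matches_greedy_oracle(self, method):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            pts = rng.normal(size=(n, 3))
            Z = hierarchical_cluster(euclidean_distance(pts), method)
            oracle = reference.greedy_linkage(pts, method)
            scipy_merges = _merge_sets(Z)
            for (oa, ob, oh), (sa, sb, sh) in zip(oracle, scipy_merges):
                assert {oa, ob} == {sa, sb}
                assert oh == pytest.approx(sh, rel=1e-8)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((1, 1)), "average")


def _merge_sets(Z):
    """scipy linkage rows -> (cluster_a, cluster_b, height) frozensets."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, h, _) in enumerate(Z):
        ca, cb = members[int(a)], members[int(b)]
        out.append((ca, cb, float(h)))
        members[n + i] = ca | cb
    return out


class TestCutSelection:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        Z = hierarchical_cluster(euclidean_distance(pts), "average")
        h = select_cut_height(Z, plateau_window=2.0)
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        assert len(set(labels)) == 2

    def test_tiny_window_returns_smallest_grid_height(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        Z = hierarchical_cluster(euclidean_distance(pts), "average")
        h = select_cut_height(Z, plateau_window=1e-12)
        assert h == pytest.approx(float(np.min(Z[:, 2])))

    def test_count_constant_across_window(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 3))
        Z = hierarchical_cluster(euclidean_distance(pts), "ward2")
        window = 0.1 * (Z[:, 2].max() - Z[:, 2].min())
        h = select_cut_height(Z, plateau_window=window)
        heights = Z[:, 2]
        assert not ((heights > h) & (heights <= h + window)).any()


class TestCutDendrogram:
    def _random(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        pts = pd.DataFrame(rng.normal(size=(n, 4)),
                           index=[f"g{i}" for i in range(n)])
        Z = hierarchical_cluster(euclidean_distance(pts), "average")
        return pts, Z

    def test_zero_height_gives_singletons(self):
        pts, Z = self._random()
        assert cut_dendrogram(Z, 0.0, pts).labels.nunique() == len(pts)

    def test_max_height_gives_one_cluster(self):
        pts, Z = self._random()
        assert cut_dendrogram(Z, float(Z[:, 2].max()), pts).labels.nunique() == 1

    def test_matches_scipy_cut_tree(self):
        pts, Z = self._random()
        h = float(np.median(Z[:, 2]))
        ours = cut_dendrogram(Z, h, pts).labels
        ref = hierarchy.fcluster(Z, t=h, criterion="distance")
        # same partition up to relabeling
        assert pd.crosstab(ours, ref).astype(bool).sum(axis=0).eq(1).all()


class TestConsolidation:
    def _assignment(self, centers, per=10, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for i, c in enumerate(centers):
            rows.append(np.asarray(c) + rng.normal(0, noise, (per, len(c))))
            labels += [i + 1] * per
        data = pd.DataFrame(np.vstack(rows),
                            index=[f"g{i}" for i in range(per * len(centers))])
        return ClusterAssignment(labels=pd.Series(labels, index=data.index), data=data)

    def test_identical_centroids_merge(self):
        a = self._assignment([[1, 2, 3, 1, 2, 3], [1, 2, 3, 1, 2, 3]])
        assert consolidate_clusters(a, 0.9).labels.nunique() == 1

    def test_anticorrelated_never_merge(self):
        a = self._assignment([[1, 1, 1, -1, -1, -1], [-1, -1, -1, 1, 1, 1]])
        assert consolidate_clusters(a, 0.9).labels.nunique() == 2

    def test_eight_clusters_with_duplicates_consolidate_to_five(self):
        # five base patterns, three of them duplicated with a small offset
        base = [
            [2, 1, 0, 2, 1, 0],
            [-2, -1, 0, -2, -1, 0],
            [1.5, 1.5, 1.5, -1.5, -1.5, -1.5],
            [-1.5, -1.5, -1.5, 1.5, 1.5, 1.5],
            [0, 0, 2, 0, 0, 2],
        ]
        dup = [list(1.1 * np.asarray(base[i])) for i in range(3)]
        a = self._assignment(base + dup, noise=0.05)
        assert consolidate_clusters(a, 0.9).labels.nunique() == 5


class TestFocalClassification:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((2, 1, 0, 2, 1, 0), "I"),
            ((-2, -1, 0, -2, -1, 0), "II"),
            ((1.5, 1.5, 1.5, -1.5, -1.5, -1.5), "III"),
            ((-1.5, -1.5, -1.5, 1.5, 1.5, 1.5), "IV"),
            ((0, 0, 1.5, 0, 0, 1.5), "V"),
            ((0.1, 0, 0, 0.1, 0, 0), "other"),
        ],
    )
    def test_rule_application(self, centroid, expected):
        data = pd.DataFrame([centroid, centroid],
                            index=["a", "b"], columns=COLS)
        a = ClusterAssignment(labels=pd.Series([1, 1], index=data.index), data=data)
        assert classify_focal_clusters(a)[1] == expected


class TestZscore:
    def test_constant_row_is_zero(self):
        table = pd.DataFrame([[1, 1, 1, 1]], index=["g"])
        with pytest.warns(UserWarning):
            z = zscore_transform(table)
        assert (z.to_numpy() == 0).all()

    def test_two_point_z(self):
        # counts chosen so log2(x+1) = (0, 2)
        table = pd.DataFrame([[0, 3]], index=["g"])
        z = zscore_transform(table)
        assert np.allclose(z.to_numpy(), [[-1.0, 1.0]])

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.exponential(50, size=(40, 6)))
        z = zscore_transform(table)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-10)


class TestBins:
    def test_equal_thirds(self):
        z = pd.DataFrame([[0.0, 0.5, 1.0]])
        assert bin_zscores(z).to_numpy().tolist() == [[0, 1, 2]]

    def test_extremes_hit_outer_bins(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(30, 5)))
        bins = bin_zscores(z)
        arr = z.to_numpy()
        b = bins.to_numpy()
        assert (b[np.arange(30), arr.argmin(axis=1)] == 0).all()
        assert (b[np.arange(30), arr.argmax(axis=1)] == 2).all()

    def test_constant_row_is_all_ones(self):
        z = pd.DataFrame([[0.3, 0.3, 0.3]])
        assert (bin_zscores(z).to_numpy() == 1).all()


class TestCoarseComparator:
    def _table(self, kind, n=30, seed=0):
        rng = np.random.default_rng(seed)
        shapes = {
            "down": np.array([2.0, 1.2, 0.5, 0.0]),
            "up": np.array([0.0, 0.5, 1.2, 2.0]),
            "flat": np.zeros(4),
        }
        rows = shapes[kind] + rng.normal(0, 0.05, size=(n, 4))
        return pd.DataFrame(rows, index=[f"{kind}{i}" for i in range(n)])

    def test_planted_direction_labels(self):
        table = pd.concat([self._table("down"), self._table("up"),
                           self._table("flat")])
        assign = coarse_classify_comparator(table, "ward2", 3)
        labels = assign.labels.map(assign.classes)
        assert set(labels[labels.index.str.startswith("down")]) == {"up_early"}
        assert set(labels[labels.index.str.startswith("up")]) == {"down_early"}
        assert set(labels[labels.index.str.startswith("flat")]) == {"other"}

    def test_k_larger_than_table_rejected(self):
        with pytest.raises(ValueError):
            coarse_classify_comparator(self._table("flat", n=2), "average", 3)


def test_permutation_invariance_of_memberships():
    """Row shuffling leaves the recovered gene sets unchanged."""
    rng = np.random.default_rng(5)
    centers = np.array([[0, 0, 0, 0], [4, 4, 4, 4], [-4, 0, 4, 0]])
    rows = np.repeat(centers, 15, axis=0) + rng.normal(0, 0.2, (45, 4))
    data = pd.DataFrame(rows, index=[f"g{i}" for i in range(45)])
    perm = rng.permutation(45)
    shuffled = data.iloc[perm]

    def clusters(df):
        Z = hierarchical_cluster(euclidean_distance(df), "ward2")
        labels = hierarchy.fcluster(Z, t=3, criterion="maxclust")
        return {frozenset(df.index[labels == l]) for l in set(labels)}

    assert clusters(data) == clusters(shuffled)


def test_params_validation():
    with pytest.raises(ValueError):
        ClusteringParams(linkage="single")
    with pytest.raises(ValueError):
        ClusteringParams(plateau_window=-1.0)
    with pytest.raises(ValueError):
        ClusteringParams(consolidation_correlation=0.0)
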