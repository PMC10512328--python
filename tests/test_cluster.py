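"""Correlation distances, UPGMA/Ward linkage, inconsistency flat clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from ohnodiv.cluster import (
    build_stre_profiles,
    correlation_distance_matrix,
    flat_clusters_k,
    go_indicator_vectors,
    inconsistency,
    inconsistency_flat_clusters,
    to_newick,
    upgma,
    ward,
    ward_go_clusters,
)
from ohnodiv.orthology import OhnologPair
from oracles import brute_agglomerate, linkage_to_leafsets


class TestCorrelationDistance:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]] * 2)
        D = correlation_distance_matrix(df)
        assert D[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_two(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        D = correlation_distance_matrix(df)
        assert D[0, 1] == pytest.approx(2.0)

    def test_pairwise_complete_hand_computation(self):
        # both rows observed on 4 shared columns only
        x = [1.0, 2.0, np.nan, 4.0, 3.0, np.nan]
        y = [2.0, 1.0, 5.0, 3.0, 4.0, np.nan]
        df = pd.DataFrame([x, y])
        shared = [0, 1, 3, 4]
        r = np.corrcoef([x[i] for i in shared], [y[i] for i in shared])[0, 1]
        D = correlation_distance_matrix(df)
        assert D[0, 1] == pytest.approx(1 - r)

    def test_insufficient_overlap_neutral_distance(self):
        df = pd.DataFrame([[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 1.0, 2.0]])
        D = correlation_distance_matrix(df)
        assert D[0, 1] == 1.0

    def test_row_location_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 8)))
        D1 = correlation_distance_matrix(df)
        df2 = df.copy()
        df2.iloc[2] += 100.0
        D2 = correlation_distance_matrix(df2)
        assert np.allclose(D1, D2)


class TestUpgma:
    def test_three_leaf_hand_agglomeration(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_equal_distances_all_heights_equal(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        Z = upgma(D)
        assert np.allclose(Z[:, 2], 2.0)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma(D)

    def test_matches_brute_force_small_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(3, 9)
            M = rng.uniform(0.1, 2.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            Z = upgma(D)
            got = {(fs, round(h, 9)) for fs, h in linkage_to_leafsets(Z)}
            want = {(fs, round(h, 9)) for fs, h in brute_agglomerate(D, "average")}
            assert got == want

    def test_ultrametric_input_recovered_exactly(self):
        # two clades at height 1, joined at height 5
        D = np.array(
            [
                [0, 1, 5, 5],
                [1, 0, 5, 5],
                [5, 5, 0, 1],
                [5, 5, 1, 0],
            ],
            float,
        )
        Z = upgma(D)
        assert sorted(Z[:, 2]) == [1.0, 1.0, 5.0]


class TestWard:
    def test_matches_brute_force_lance_williams(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 4))
            Z = ward(X)
            D = squareform(pdist(X))
            got = {(fs, round(h, 8)) for fs, h in linkage_to_leafsets(Z)}
            want = {(fs, round(h, 8)) for fs, h in brute_agglomerate(D, "ward")}
            assert got == want

    def test_identical_vectors_merge_first_at_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        Z = ward(X)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}


class TestInconsistency:
    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            X = rng.normal(size=(n, 3))
            Z = hierarchy.linkage(pdist(X), method="average")
            mine = inconsistency(Z, depth=2, ddof=1)
            ref = hierarchy.inconsistent(Z, 2)[:, 3]
            assert np.allclose(mine, ref, atol=1e-10)

    def test_equal_heights_single_cluster(self):
        D = np.full((5, 5), 1.0)
        np.fill_diagonal(D, 0.0)
        Z = upgma(D)
        labels = inconsistency_flat_clusters(Z)
        assert len(set(labels)) == 1

    def test_two_tight_blobs_split_into_two(self):
        # leaves 0-2 pairwise 0.1 apart, 3-5 pairwise 0.1, blobs 10 apart
        D = np.full((6, 6), 10.0)
        for blob in ([0, 1, 2], [3, 4, 5]):
            for i in blob:
                for j in blob:
                    D[i, j] = 0.0 if i == j else 0.1
        Z = upgma(D)
        labels = inconsistency_flat_clusters(Z, t=1.1)
        assert len(set(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_labels_partition_leaves(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        Z = hierarchy.linkage(pdist(X), method="average")
        labels = inconsistency_flat_clusters(Z)
        assert len(labels) == 12
        assert set(labels) == set(range(1, len(set(labels)) + 1))

    def test_matches_scipy_fcluster(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            X = rng.normal(size=(n, 3))
            Z = hierarchy.linkage(pdist(X), method="average")
            mine = inconsistency_flat_clusters(Z, t=1.1)
            ref = hierarchy.fcluster(Z, t=1.1, criterion="inconsistent", depth=2)
            # same partition (label numbering may differ)
            mine_parts = {frozenset(np.flatnonzero(mine == l)) for l in set(mine)}
            ref_parts = {frozenset(np.flatnonzero(ref == l)) for l in set(ref)}
            assert mine_parts == ref_parts

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        D = squareform(pdist(X))
        Z = upgma(D)
        labels = inconsistency_flat_clusters(Z)
        perm = rng.permutation(10)
        Zp = upgma(D[np.ix_(perm, perm)])
        labels_p = inconsistency_flat_clusters(Zp)
        parts = {frozenset(perm[np.flatnonzero(labels_p == l)]) for l in set(labels_p)}
        orig = {frozenset(np.flatnonzero(labels == l)) for l in set(labels)}
        assert parts == orig


class TestStreProfiles:
    def _pairs(self):
        return [
            OhnologPair("P0", "a0", "b0", {"sp1": ("x0",), "sp2": ("y0", "y1")}),
            OhnologPair("P1", "a1", "b1", {"sp1": ("x1",)}),
            OhnologPair("P2", "a2", "b2", {}),
        ]

    def test_single_ortholog_cells_equal_counts(self):
        counts = {"sp1": {"x0": 2, "x1": 5}, "sp2": {"y0": 1, "y1": 3}}
        with pytest.warns(UserWarning, match="P2"):
            prof = build_stre_profiles(self._pairs(), counts, ["sp1", "sp2"])
        assert prof.loc["P0", "sp1"] == 2
        assert prof.loc["P1", "sp1"] == 5

    def test_duplicated_orthologs_averaged(self):
        counts = {"sp1": {"x0": 2, "x1": 5}, "sp2": {"y0": 1, "y1": 3}}
        with pytest.warns(UserWarning):
            prof = build_stre_profiles(self._pairs(), counts, ["sp1", "sp2"])
        assert prof.loc["P0", "sp2"] == 2.0

    def test_missing_ortholog_is_nan(self):
        counts = {"sp1": {"x0": 2, "x1": 5}, "sp2": {"y0": 1, "y1": 3}}
        with pytest.warns(UserWarning):
            prof = build_stre_profiles(self._pairs(), counts, ["sp1", "sp2"])
        assert np.isnan(prof.loc["P1", "sp2"])


class TestWardGoClusters:
    def test_metabolic_indicator_distance(self):
        pairs = [
            OhnologPair("P0", "a0", "b0"),
            OhnologPair("P1", "a1", "b1"),
            OhnologPair("P2", "a2", "b2"),
            OhnologPair("P3", "a3", "b3"),
        ]
        go = {g: {"T0"} for g in "a0 b0 a1 b1 a2 b2 a3 b3".split()}
        vec = go_indicator_vectors(pairs, go, ["T0"], {"P0", "P1"}, 4.0)
        X = vec.to_numpy()
        # same map status -> distance 0; across -> the indicator differs by 4
        assert np.linalg.norm(X[0] - X[1]) == 0.0
        assert np.linalg.norm(X[0] - X[2]) == pytest.approx(4.0)

    def test_map_pairs_cluster_together(self):
        pairs = [OhnologPair(f"P{i}", f"a{i}", f"b{i}") for i in range(6)]
        rng = np.random.default_rng(7)
        terms = [f"T{j}" for j in range(4)]
        go = {}
        for i in range(6):
            for m in (f"a{i}", f"b{i}"):
                go[m] = {t for t in terms if rng.random() < 0.5}
        Z, labels, vec = ward_go_clusters(pairs, go, terms, {"P0", "P1", "P2"})
        k2 = flat_clusters_k(Z, 2)
        assert len(set(k2[:3])) == 1 and len(set(k2[3:])) == 1


def test_newick_round_trip_heights():
    D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
    Z = upgma(D)
    nwk = to_newick(Z, ["A", "B", "C"])
    assert nwk.endswith(";") and "A" in nwk and "C" in nwk
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert {t.name for t in tree.get_terminals()} == {"A", "B", "C"}
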