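import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from codres.cluster import (
    ClusterConfig,
    cut_tree,
    distance_matrix,
    merge_tree_newick,
    select_representatives,
    soergel_distance,
    ward_cluster,
)
from codres.errors import CodresError, InvalidRecordError
from codres.fixtures import FixtureSpec, synth_fingerprints
from codres.model import Fingerprint

fp = lambda name, bits: Fingerprint(name, np.array(bits, dtype=np.uint8))

bitvectors = st.lists(st.integers(0, 1), min_size=4, max_size=32)


def partition(labels: dict) -> set:
    groups = {}
    for item, cid in labels.items():
        groups.setdefault(cid, set()).add(item)
    return {frozenset(g) for g in groups.values()}


class TestSoergel:
    def test_identical(self):
        assert soergel_distance(fp("a", [1, 1, 0, 0]), fp("b", [1, 1, 0, 0])) == 0.0

    def test_disjoint(self):
        assert soergel_distance(fp("a", [1, 0]), fp("b", [0, 1])) == 1.0

    def test_hand_enumeration(self):
        # intersection {bit0} = 1, union {bit0,bit1,bit2} = 3 -> 1 - 1/3
        d = soergel_distance(fp("a", [1, 1, 0, 0]), fp("b", [1, 0, 1, 0]))
        assert d == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(CodresError):
            soergel_distance(fp("a", [1, 0]), fp("b", [1, 0, 0]))

    def test_both_zero_defined_as_zero(self):
        a = np.zeros(4, dtype=np.uint8)
        assert soergel_distance(a, a) == 0.0

    @given(bitvectors, bitvectors, bitvectors)
    @settings(max_examples=300, deadline=None)
    def test_metric_axioms(self, a, b, c):
        n = max(len(a), len(b), len(c))
        a, b, c = (np.pad(np.array(v, dtype=np.uint8), (0, n - len(v))) for v in (a, b, c))
        dab = soergel_distance(a, b)
        dba = soergel_distance(b, a)
        assert dab == dba  # symmetry
        assert 0 <= dab <= 1
        # identity of indiscernibles (on bit sets)
        assert (dab == 0) == bool(np.array_equal(a, b) or (not a.any() and not b.any()))
        # triangle inequality
        assert soergel_distance(a, c) <= dab + soergel_distance(b, c) + 1e-12


class TestDistanceMatrix:
    def test_identical_pair(self):
        dm = distance_matrix([fp("a", [1, 0]), fp("b", [1, 0])])
        assert np.array_equal(dm, np.zeros((2, 2)))

    def test_mutually_disjoint(self):
        dm = distance_matrix([fp("a", [1, 0, 0]), fp("b", [0, 1, 0]), fp("c", [0, 0, 1])])
        assert np.array_equal(dm, 1 - np.eye(3))

    def test_matches_pairwise_calls(self, rng):
        fps = [fp(f"d{i}", rng.integers(0, 2, size=16)) for i in range(6)]
        dm = distance_matrix(fps)
        for i in range(6):
            for j in range(6):
                assert dm[i, j] == pytest.approx(
                    soergel_distance(fps[i], fps[j]) if i != j else 0.0
                )

    def test_too_few(self):
        with pytest.raises(CodresError):
            distance_matrix([fp("a", [1])])


class TestWardCluster:
    def planted_dm(self):
        # two well-separated groups: within ~0.1, between ~0.9
        dm = np.full((6, 6), 0.9)
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    dm[i, j] = 0.0 if i == j else 0.1
        return dm

    def test_planted_partition_recovered(self):
        a = ward_cluster(self.planted_dm(), ClusterConfig(cut_height=1.0))
        assert a.n_clusters == 2
        assert partition(a.labels) == {
            frozenset({"item0", "item1", "item2"}),
            frozenset({"item3", "item4", "item5"}),
        }

    def test_cut_above_root_single_cluster(self):
        dm = self.planted_dm()
        root = max(m[2] for m in ward_cluster(dm).merges)
        a = ward_cluster(dm, ClusterConfig(cut_height=root + 1))
        assert a.n_clusters == 1

    def test_merge_heights_non_decreasing(self, rng):
        pts = rng.random((8, 3))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        heights = [m[2] for m in ward_cluster(dm).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(15):
            pts = rng.random((6, 3))
            dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            mine = ward_cluster(dm)
            ref = linkage(squareform(dm, checks=False), method="ward")
            assert np.allclose([m[2] for m in mine.merges], ref[:, 2])
            for t in (0.3, 0.7, 1.2):
                a = ward_cluster(dm, ClusterConfig(cut_height=t))
                b = fcluster(ref, t, criterion="distance")
                ref_part = {}
                for i, cid in enumerate(b):
                    ref_part.setdefault(cid, set()).add(f"item{i}")
                assert partition(a.labels) == {frozenset(g) for g in ref_part.values()}

    def test_cluster_count_monotone_in_cut(self, rng):
        pts = rng.random((10, 2))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        counts = [
            ward_cluster(dm, ClusterConfig(cut_height=t)).n_clusters
            for t in (0.1, 0.3, 0.6, 1.0, 2.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_fixed_cluster_count(self):
        a = ward_cluster(self.planted_dm(), ClusterConfig(n_clusters=3))
        assert a.n_clusters == 3

    def test_validation(self):
        with pytest.raises(CodresError):
            ward_cluster(np.array([[0.0, 1.0], [0.9, 0.0]]))  # asymmetric
        with pytest.raises(CodresError):
            ward_cluster(np.zeros((1, 1)))
        with pytest.raises(InvalidRecordError):
            ClusterConfig(cut_height=0)
        with pytest.raises(InvalidRecordError):
            ClusterConfig(linkage="single")

    def test_ids_contiguous_from_one(self, rng):
        pts = rng.random((9, 2))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        a = ward_cluster(dm, ClusterConfig(cut_height=0.4))
        assert sorted(set(a.labels.values())) == list(range(1, a.n_clusters + 1))


class TestSyntheticRecovery:
    def test_zero_noise_within_cluster_distance_zero(self):
        fps, labels = synth_fingerprints(FixtureSpec(seed=5, n_drugs=9, n_clusters=3, noise=0.0))
        by_label = {}
        for f in fps:
            by_label.setdefault(labels[f.drug], []).append(f)
        for members in by_label.values():
            for x in members:
                for y in members:
                    assert soergel_distance(x, y) == 0.0

    def test_one_cluster(self):
        _, labels = synth_fingerprints(FixtureSpec(seed=5, n_drugs=6, n_clusters=1))
        assert set(labels.values()) == {1}

    def test_planted_recovery_default_cut(self):
        fps, labels = synth_fingerprints(FixtureSpec(seed=11, n_drugs=30, n_clusters=3))
        a = ward_cluster(distance_matrix(fps), drugs=[f.drug for f in fps])
        truth = {}
        for d, c in labels.items():
            truth.setdefault(c, set()).add(d)
        assert partition(a.labels) == {frozenset(g) for g in truth.values()}


class TestRepresentatives:
    def test_argmax(self):
        fps = [fp("a", [1, 1, 0, 0]), fp("b", [1, 1, 1, 0]), fp("c", [0, 0, 0, 1])]
        a = ward_cluster(distance_matrix(fps), ClusterConfig(n_clusters=2),
                         drugs=[f.drug for f in fps])
        reps = select_representatives(a, {"a": 0.7, "b": 0.5, "c": 0.6})
        assert [(drug, score) for _, drug, score in reps] == [("a", 0.7), ("c", 0.6)]

    def test_singleton_cluster(self):
        fps = [fp("a", [1, 0]), fp("b", [0, 1])]
        a = ward_cluster(distance_matrix(fps), ClusterConfig(n_clusters=2),
                         drugs=["a", "b"])
        reps = select_representatives(a, {"a": 0.2, "b": 0.9})
        assert {drug for _, drug, _ in reps} == {"a", "b"}

    def test_missing_ranking_errors(self):
        fps = [fp("a", [1, 0]), fp("b", [0, 1])]
        a = ward_cluster(distance_matrix(fps), drugs=["a", "b"])
        with pytest.raises(CodresError):
            select_representatives(a, {"a": 0.2})

    def test_permutation_invariant(self, rng):
        fps, _ = synth_fingerprints(FixtureSpec(seed=3, n_drugs=12, n_clusters=3))
        ranking = {f.drug: float(rng.random()) for f in fps}
        a1 = ward_cluster(distance_matrix(fps), drugs=[f.drug for f in fps])
        order = rng.permutation(len(fps))
        shuffled = [fps[i] for i in order]
        a2 = ward_cluster(distance_matrix(shuffled), drugs=[f.drug for f in shuffled])
        r1 = {(d, s) for _, d, s in select_representatives(a1, ranking)}
        r2 = {(d, s) for _, d, s in select_representatives(a2, ranking)}
        assert r1 == r2

    def test_planted_maxima_recovered(self, rng):
        fps, labels = synth_fingerprints(FixtureSpec(seed=21, n_drugs=15, n_clusters=3))
        ranking = {f.drug: float(rng.random()) for f in fps}
        best = {}
        for d, c in labels.items():
            if c not in best or ranking[d] > ranking[best[c]]:
                best[c] = d
        a = ward_cluster(distance_matrix(fps), drugs=[f.drug for f in fps])
        reps = {d for _, d, _ in select_representatives(a, ranking)}
        assert reps == set(best.values())


class TestNewick:
    def test_leaf_names_present_and_parses(self):
        fps = [fp("aa", [1, 1, 0]), fp("bb", [1, 0, 0]), fp("cc", [0, 0, 1])]
        a = ward_cluster(distance_matrix(fps), drugs=[f.drug for f in fps])
        text = merge_tree_newick(a)
        assert text.endswith(";") and "aa" in text and "cc" in text
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(text), "newick")
        assert {t.name for t in tree.get_terminals()} == {"aa", "bb", "cc"}
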