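import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepforge.partition import (
    Cluster,
    DatasetSplit,
    PartitionError,
    ccpart,
    cluster_diversity,
    connected_components,
    interdependence,
    random_partition,
    stratified_kfold,
)
from pepforge.peptide_io import Peptide, PeptideDataset


def _clustered_graph(sizes, labels_by_cluster=None):
    """Graph of disjoint cliques; returns (graph, labels)."""
    g = nx.Graph()
    labels = {}
    for ci, size in enumerate(sizes):
        nodes = [f"c{ci}n{j}" for j in range(size)]
        g.add_nodes_from(nodes)
        for a in nodes:
            for b in nodes:
                if a < b:
                    g.add_edge(a, b, identity=0.9)
        lab = labels_by_cluster[ci] if labels_by_cluster else ci % 2
        for n in nodes:
            labels[n] = lab
    return g, labels


class TestConnectedComponents:
    def test_chain_plus_isolate(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_node("d")
        comps = connected_components(g)
        assert sorted(c.members for c in comps) == [
            frozenset({"a", "b", "c"}), frozenset({"d"})
        ][::-1] or {c.members for c in comps} == {
            frozenset({"a", "b", "c"}), frozenset({"d"})
        }

    def test_empty_edges_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(7))
        assert [c.size for c in connected_components(g)] == [1] * 7

    def test_complete_graph_single_cluster(self):
        g = nx.complete_graph(5)
        assert [c.size for c in connected_components(g)] == [5]


class TestCCPart:
    def test_twenty_equal_clusters_give_exact_twenty_percent(self):
        g, labels = _clustered_graph([5] * 20)
        split = ccpart(g, labels, test_fraction=0.2, tie_seed=0)
        assert len(split.test_ids) == 20
        assert split.metadata["n_test_clusters"] == 4

    def test_singletons_take_two_of_ten(self):
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(10))
        labels = {f"n{i}": i % 2 for i in range(10)}
        split = ccpart(g, labels, test_fraction=0.2, tie_seed=3)
        assert len(split.test_ids) == 2

    def test_smallest_clusters_moved_first(self):
        g, labels = _clustered_graph([1, 1, 8], labels_by_cluster=[0, 1, 0])
        # make the size-8 cluster mixed-label so train keeps both classes
        for j in range(4):
            labels[f"c2n{j}"] = 1
        split = ccpart(g, labels, test_fraction=0.2, tie_seed=0)
        assert split.test_ids == {"c0n0", "c1n0"}

    def test_giant_component_raises(self):
        g, labels = _clustered_graph([9, 1], labels_by_cluster=[0, 1])
        for j in range(4):
            labels[f"c0n{j}"] = 1
        with pytest.raises(PartitionError, match="no valid split"):
            ccpart(g, labels, test_fraction=0.5, tie_seed=0)

    def test_single_class_train_raises(self):
        g, labels = _clustered_graph([2, 8], labels_by_cluster=[1, 0])
        with pytest.raises(PartitionError, match="single class"):
            # test takes the 2-cluster (all label 1)... train all label 0
            ccpart(g, {k: 1 - v for k, v in labels.items()}, 0.2, tie_seed=0)

    def test_single_class_test_warns_in_metadata(self):
        g, labels = _clustered_graph([2, 4, 4], labels_by_cluster=[0, 1, 0])
        split = ccpart(g, labels, test_fraction=0.2, tie_seed=0)
        assert "warning" in split.metadata

    def test_no_cluster_straddles_boundary(self, family_dataset):
        from pepforge.similarity import build_similarity_graph

        ds, _ = family_dataset
        g = build_similarity_graph(ds)
        split = ccpart(g, ds.labels(), 0.2, tie_seed=1)
        for c in connected_components(g):
            assert not (c.members & split.train_ids and c.members & split.test_ids)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_zero_leakage_on_random_clustered_graphs(self, seed):
        """Interdependence after homology partitioning is exactly zero."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 8, size=rng.integers(4, 12)).tolist()
        g, labels = _clustered_graph(sizes)
        try:
            split = ccpart(g, labels, test_fraction=0.2, tie_seed=seed)
        except PartitionError:
            return  # infeasible configurations are allowed to refuse
        assert interdependence(split, g) == 0.0


class TestRandomPartition:
    def test_sizes_and_determinism(self):
        ds = PeptideDataset([Peptide(f"p{i}", "ACDEF") for i in range(10)])
        split = random_partition(ds, 0.2, seed=0)
        assert len(split.test_ids) == 2
        again = random_partition(ds, 0.2, seed=0)
        assert split.test_ids == again.test_ids

    def test_round_half_even(self):
        ds = PeptideDataset([Peptide(f"p{i}", "ACDEF") for i in range(3)])
        split = random_partition(ds, 0.5, seed=1)
        assert len(split.test_ids) == round(1.5) == 2


class TestStratifiedKFold:
    def test_balanced_folds(self):
        labels = {f"p{i}": int(i < 50) for i in range(100)}
        folds = stratified_kfold(set(labels), labels, k=10, seed=0)
        assert len(folds) == 10
        for fold in folds.values():
            assert sum(labels[i] for i in fold) == 5 and len(fold) == 10

    def test_k1_single_fold(self):
        labels = {"a": 1, "b": 0}
        assert stratified_kfold({"a", "b"}, labels, k=1) == {0: {"a", "b"}}

    def test_single_class_rejected(self):
        labels = {f"p{i}": 1 for i in range(10)}
        with pytest.raises(PartitionError):
            stratified_kfold(set(labels), labels, k=2)

    def test_k_exceeding_minority_rejected(self):
        labels = {f"p{i}": int(i < 3) for i in range(20)}
        with pytest.raises(PartitionError, match="minority"):
            stratified_kfold(set(labels), labels, k=5)


class TestDiagnostics:
    def test_interdependence_counts_cross_edges(self):
        g = nx.Graph([("a", "b")])
        split = DatasetSplit(train_ids={"a"}, test_ids={"b"})
        assert interdependence(split, g) == 1.0

    def test_no_cross_edges_zero(self):
        g = nx.Graph([("a", "c")])
        g.add_node("b")
        split = DatasetSplit(train_ids={"a", "c"}, test_ids={"b"})
        assert interdependence(split, g) == 0.0

    def test_cluster_diversity_ratio(self):
        clusters = [Cluster(frozenset({f"t{i}"})) for i in range(16)]
        clusters += [Cluster(frozenset({f"s{i}"})) for i in range(4)]
        split = DatasetSplit(
            train_ids={f"t{i}" for i in range(16)},
            test_ids={f"s{i}" for i in range(4)},
        )
        assert cluster_diversity(split, clusters) == 0.25

    def test_all_clusters_in_train_gives_zero(self):
        clusters = [Cluster(frozenset({"a"})), Cluster(frozenset({"b"}))]
        split = DatasetSplit(train_ids={"a", "b"}, test_ids=set())
        assert cluster_diversity(split, clusters) == 0.0


class TestSplitSerialization:
    def test_json_round_trip(self, tmp_path):
        split = DatasetSplit(
            train_ids={"a", "b", "c"},
            test_ids={"d"},
            folds={0: {"a", "b"}, 1: {"c"}},
            method="ccpart",
            params={"test_fraction": 0.25},
            metadata={"overshoot": 0},
        )
        path = tmp_path / "split.json"
        split.to_json(path)
        back = DatasetSplit.from_json(path)
        assert back.train_ids == split.train_ids
        assert back.test_ids == split.test_ids
        assert back.folds == split.folds
        assert back.method == split.method

    def test_overlapping_folds_rejected(self):
        with pytest.raises(PartitionError):
            DatasetSplit(
                train_ids={"a", "b"}, test_ids=set(),
                folds={0: {"a", "b"}, 1: {"b"}},
            )
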