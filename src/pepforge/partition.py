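"""Homology-aware train/test partitioning and leakage diagnostics.

Random splitting of sequence datasets lets homologous peptides land on both
sides of the train/test boundary, so the test score partly measures
memorisation of near-duplicates. The connected-components partitioner
(here ``ccpart``) removes that channel entirely: peptides are clustered as
the connected components of the similarity graph, and whole clusters are
moved into the test set — smallest first — until the test-size target is
reached. Because no similarity edge can cross a component boundary, the
resulting split has *zero* train/test interdependence by construction.

Moving the smallest clusters first also keeps the test set diverse: many
small, relatively unique clusters rather than a slice of one big family,
which emulates predicting genuinely novel sequences.

Cross-validation folds within the training set are random-stratified over
peptides (not homology-aware); this within-train leakage channel is
deliberate — folds guide hyperparameter selection only, while the held-out
test set carries the honest generalization estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .peptide_io import PeptideDataset


class PartitionError(ValueError):
    """Raised when no valid split exists for the requested parameters."""


@dataclass(frozen=True)
class Cluster:
    """A similarity cluster: a connected component of the graph."""

    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def min_id(self) -> str:
        return min(self.members)


@dataclass
class DatasetSplit:
    """Train/test membership plus CV fold assignments over train."""

    train_ids: set[str]
    test_ids: set[str]
    folds: dict[int, set[str]] = field(default_factory=dict)
    method: str = "unspecified"
    params: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise PartitionError("train and test sets overlap")
        if self.folds:
            pooled: set[str] = set()
            for fold in self.folds.values():
                if pooled & fold:
                    raise PartitionError("folds overlap")
                pooled |= fold
            if pooled != self.train_ids:
                raise PartitionError("folds do not partition the training set")

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.test_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": sorted(self.train_ids),
            "test": sorted(self.test_ids),
            "folds": {str(k): sorted(v) for k, v in self.folds.items()},
            "method": self.method,
            "params": self.params,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=set(payload["train"]),
            test_ids=set(payload["test"]),
            folds={int(k): set(v) for k, v in payload["folds"].items()},
            method=payload["method"],
            params=payload["params"],
            metadata=payload["metadata"],
        )


def connected_components(graph: nx.Graph) -> list[Cluster]:
    """Connected components of the similarity graph, largest last."""
    comps = [Cluster(frozenset(c)) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (c.size, c.min_id))


def ccpart(
    graph: nx.Graph,
    labels: dict[str, int],
    test_fraction: float = 0.2,
    tie_seed: int = 0,
) -> DatasetSplit:
    """Partition whole similarity clusters into train/test, smallest first.

    Clusters are moved into the test set in ascending size order (ties
    broken by a seeded shuffle, then lowest member id) until the test set
    first reaches ``test_fraction`` of all sequences. The test set may
    overshoot the target by at most the final cluster's size minus one; the
    overshoot is recorded in the split metadata. No edge ever crosses the
    boundary.
    """
    if not (0.0 < test_fraction < 1.0):
        raise PartitionError(f"test_fraction must be in (0,1), got {test_fraction}")
    clusters = connected_components(graph)
    n = graph.number_of_nodes()
    target = test_fraction * n
    rng = np.random.default_rng(tie_seed)
    priority = {c: rng.random() for c in clusters}
    order = sorted(clusters, key=lambda c: (c.size, priority[c], c.min_id))

    test_ids: set[str] = set()
    test_clusters = []
    for c in order:
        if len(test_ids) >= target:
            break
        test_ids |= c.members
        test_clusters.append(c)
    train_ids = set(graph.nodes) - test_ids

    if len(test_ids) > (1.0 - test_fraction) * n:
        raise PartitionError(
            f"no valid split: reaching a {test_fraction:.0%} test set required "
            f"moving {len(test_ids)}/{n} sequences (a dominant similarity "
            f"cluster covers most of the data at this threshold); lower the "
            f"identity threshold or revisit the dataset"
        )
    if not train_ids:
        raise PartitionError("no valid split: training set would be empty")

    metadata: dict = {
        "target_test_size": target,
        "overshoot": len(test_ids) - int(np.ceil(target)),
        "n_test_clusters": len(test_clusters),
        "n_clusters": len(clusters),
    }
    train_labels = {labels[i] for i in train_ids}
    if len(train_labels) < 2:
        raise PartitionError(
            "training set contains a single class after partitioning; "
            "supervised training is impossible"
        )
    if len({labels[i] for i in test_ids}) < 2:
        metadata["warning"] = (
            "test set contains a single class; evaluation will be degenerate"
        )
    return DatasetSplit(
        train_ids=train_ids,
        test_ids=test_ids,
        method="ccpart",
        params={"test_fraction": test_fraction, "tie_seed": tie_seed},
        metadata=metadata,
    )


def random_partition(
    dataset: PeptideDataset | list[str], test_fraction: float, seed: int
) -> DatasetSplit:
    """Uniform random split; |test| = round(n * fraction), round-half-even."""
    if not (0.0 < test_fraction < 1.0):
        raise PartitionError(f"test_fraction must be in (0,1), got {test_fraction}")
    ids = dataset.ids() if isinstance(dataset, PeptideDataset) else list(dataset)
    n_test = int(round(len(ids) * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test_ids = {ids[i] for i in perm[:n_test]}
    return DatasetSplit(
        train_ids=set(ids) - test_ids,
        test_ids=test_ids,
        method="random",
        params={"test_fraction": test_fraction, "seed": seed},
    )


def stratified_kfold(
    train_ids: set[str] | list[str],
    labels: dict[str, int],
    k: int = 10,
    seed: int = 0,
) -> dict[int, set[str]]:
    """Random stratified k-fold assignment over the training peptides.

    Per-fold class counts differ from perfect proportionality by at most
    one sample. ``k`` may not exceed the minority-class count.
    """
    ids = sorted(train_ids)
    y = np.array([labels[i] for i in ids])
    if k == 1:
        return {0: set(ids)}
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise PartitionError("stratified folds require both classes in train")
    if k > counts.min():
        raise PartitionError(
            f"k={k} exceeds the minority-class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[int, set[str]] = {}
    for fold_idx, (_, held) in enumerate(skf.split(np.zeros(len(ids)), y)):
        folds[fold_idx] = {ids[i] for i in held}
    return folds


def interdependence(split: DatasetSplit, graph: nx.Graph) -> float:
    """Fraction of training sequences with a similar sequence in test.

    This is the leakage statistic: the proportion of train peptides having
    at least one above-threshold identity edge into the test set. It is
    exactly 0 for any split produced by ``ccpart``.
    """
    if not split.train_ids:
        raise PartitionError("interdependence undefined for an empty training set")
    leaky = sum(
        1
        for t in split.train_ids
        if any(u in split.test_ids for u in graph.neighbors(t))
    )
    return leaky / len(split.train_ids)


def cluster_diversity(split: DatasetSplit, clusters: list[Cluster]) -> float:
    """(# clusters intersecting test) / (# clusters intersecting train).

    A diagnostic that homology partitioning left the test set diverse: a
    healthy split keeps this ratio near test_fraction / (1 - test_fraction).
    """
    n_train = sum(1 for c in clusters if c.members & split.train_ids)
    n_test = sum(1 for c in clusters if c.members & split.test_ids)
    if n_train == 0:
        raise PartitionError("no clusters intersect the training set")
    return n_test / n_train
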