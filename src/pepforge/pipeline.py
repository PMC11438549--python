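"""End-to-end model-builder and prediction pipelines.

``build`` chains the full development life-cycle: negative sampling from a
tagged database (unless negatives are supplied directly), similarity-graph
construction, homology-aware (or random) train/test partitioning,
stratified cross-validation folds, representation, per-algorithm
hyperparameter optimization, ensemble fitting, and held-out evaluation.
Every stage's parameters and seeds land in the bundle manifest so a build
can be reproduced bit-for-bit from the bundle plus the input data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import negdb, partition, represent, similarity, train as train_mod
from .evaluate import EvaluationReport, evaluate_split, render_report
from .peptide_io import PeptideDataset
from .similarity import IdentityParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a build needs; round-trips losslessly through JSON."""

    # data
    positives_path: str | None = None
    negatives_path: str | None = None
    db_path: str | None = None
    output_dir: str = "pepforge-run"
    excluded_tags: list[str] = field(default_factory=list)
    dedupe: bool = True
    # similarity
    identity_threshold: float = 0.30
    prefilter_kmer: int = 2
    # partition
    partition_method: str = "ccpart"  # or "random"
    test_fraction: float = 0.2
    k_folds: int = 10
    # representation
    backend: str = "onehot"
    # training
    algorithms: list[str] = field(default_factory=lambda: list(train_mod.DEFAULT_ALGORITHMS))
    n_trials: int = 100
    sampler: str = "gp"
    # seeds
    sampling_seed: int = 0
    partition_seed: int = 0
    fold_seed: int = 0
    optimizer_seed: int = 0

    def identity_params(self) -> IdentityParams:
        return IdentityParams(
            threshold=self.identity_threshold, prefilter_kmer=self.prefilter_kmer
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BuildResult:
    bundle_dir: Path
    report: EvaluationReport
    split: partition.DatasetSplit
    dataset: PeptideDataset
    ensemble: train_mod.EnsembleModel


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.monotonic()


def build_dataset(
    config: PipelineConfig, positives: PeptideDataset,
    negatives: PeptideDataset | None = None,
    db: negdb.BioactivePeptideDB | None = None,
) -> PeptideDataset:
    """Assemble the labeled binary dataset, sampling negatives if needed."""
    if config.dedupe:
        positives = positives.deduplicated()
    if negatives is None:
        if db is None:
            raise ValueError(
                "no negatives supplied and no database to sample them from"
            )
        hist = negdb.build_length_histogram(positives)
        policy = negdb.ExclusionPolicy(frozenset(config.excluded_tags))
        negatives = negdb.sample_negatives(
            db, hist, policy, seed=config.sampling_seed,
            forbidden_sequences=set(positives.sequences()),
        )
    return negdb.assemble_binary_dataset(positives, negatives)


def build(
    config: PipelineConfig,
    positives: PeptideDataset | None = None,
    negatives: PeptideDataset | None = None,
    db: negdb.BioactivePeptideDB | None = None,
    dataset: PeptideDataset | None = None,
) -> BuildResult:
    """Run the full model-builder pipeline and write the bundle + reports.

    Inputs may be passed in memory or read from the paths in ``config``.
    ``dataset`` short-circuits negative sampling when a pre-labeled binary
    dataset is supplied.
    """
    from .peptide_io import read_csv_dataset, read_fasta

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if positives is None:
            if config.positives_path is None:
                raise ValueError("config.positives_path is required")
            ppath = Path(config.positives_path)
            positives = (
                read_fasta(ppath) if ppath.suffix in (".fa", ".fasta", ".faa")
                else read_csv_dataset(ppath)
            )
        if negatives is None and config.negatives_path:
            npath = Path(config.negatives_path)
            negatives = (
                read_fasta(npath) if npath.suffix in (".fa", ".fasta", ".faa")
                else read_csv_dataset(npath)
            )
        if negatives is None and db is None:
            if config.db_path is None:
                raise ValueError(
                    "provide a negatives file or a tagged peptide database"
                )
            db = negdb.BioactivePeptideDB.from_csv(config.db_path)
        _stage("negative sampling")
        dataset = build_dataset(config, positives, negatives, db)

    labels = dataset.labels()

    _stage("similarity graph")
    params = config.identity_params()
    graph = similarity.build_similarity_graph(dataset, params)

    _stage("partition")
    if config.partition_method == "ccpart":
        split = partition.ccpart(
            graph, labels, test_fraction=config.test_fraction,
            tie_seed=config.partition_seed,
        )
    elif config.partition_method == "random":
        split = partition.random_partition(
            dataset, config.test_fraction, seed=config.partition_seed
        )
    else:
        raise ValueError(f"unknown partition method: {config.partition_method!r}")
    split.folds = partition.stratified_kfold(
        split.train_ids, labels, k=config.k_folds, seed=config.fold_seed
    )
    split.to_json(out / "split.json")

    _stage("representation")
    backend = represent.get_backend(config.backend)
    vectors = represent.embed_dataset(dataset, backend)
    train_vectors = {i: vectors[i] for i in sorted(split.train_ids)}
    test_vectors = {i: vectors[i] for i in sorted(split.test_ids)}

    _stage("hyperparameter optimization")
    space = train_mod.default_search_space(
        tuple(config.algorithms), n_trials=config.n_trials,
        seed=config.optimizer_seed, sampler=config.sampler,
    )
    best_configs: dict[str, dict] = {}
    cv_scores: dict[str, float] = {}
    with open(out / "hpo_trials.jsonl", "w") as trial_log:
        for algo in config.algorithms:
            result = train_mod.optimize_algorithm(
                train_vectors, labels, split.folds, algo, space
            )
            best_configs[algo] = result.best_params
            cv_scores[algo] = result.best_score
            for t in result.trace:
                trial_log.write(json.dumps({"algorithm": algo, **t}) + "\n")
            logger.info("%s best CV MCC: %.3f", algo, result.best_score)

    _stage("ensemble fit")
    ensemble = train_mod.fit_ensemble(
        train_vectors, labels, split.folds, best_configs,
        backend_name=backend.name, seed=config.optimizer_seed,
        cv_scores=cv_scores,
    )

    _stage("evaluation")
    test_labels = {i: labels[i] for i in split.test_ids}
    report = evaluate_split(
        ensemble, test_vectors, test_labels, graph=graph, split=split
    )

    _stage("bundle")
    bundle_dir = out / "model_bundle"
    train_mod.save_model(ensemble, bundle_dir)
    config.to_json(bundle_dir / "pipeline_config.json")
    render_report(report, out / "report.json", "json")
    render_report(report, out / "report.md", "markdown")
    return BuildResult(bundle_dir, report, split, dataset, ensemble)


def predict(
    bundle_dir: str | Path, peptides: PeptideDataset
) -> pd.DataFrame:
    """Score peptides with a saved bundle; rows sorted by descending score.

    The uncertainty column is the standard deviation of the 30 member
    scores — a dispersion measure, high when the members disagree.
    """
    ensemble = train_mod.load_model(bundle_dir)
    config_path = Path(bundle_dir) / "pipeline_config.json"
    backend_name = ensemble.backend_name
    if config_path.exists():
        backend_name = PipelineConfig.from_json(config_path).backend
    backend = represent.get_backend(backend_name)
    vectors = represent.embed_dataset(peptides, backend)
    scored = ensemble.predict_with_uncertainty(vectors)
    rows = [
        {"id": p.id, "sequence": p.sequence,
         "score": scored[p.id][0], "uncertainty": scored[p.id][1]}
        for p in peptides
    ]
    df = pd.DataFrame(rows, columns=["id", "sequence", "score", "uncertainty"])
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def diagnose(
    dataset: PeptideDataset,
    identity_params: IdentityParams = IdentityParams(),
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Leakage diagnostics: interdependence under random vs ccpart splits.

    One row per partitioning method with the interdependence percentage
    and the cluster-diversity ratio of the resulting split.
    """
    labels = dataset.labels()
    graph = similarity.build_similarity_graph(dataset, identity_params)
    clusters = partition.connected_components(graph)
    rows = []
    for method in ("random", "ccpart"):
        if method == "random":
            split = partition.random_partition(dataset, test_fraction, seed=seed)
        else:
            split = partition.ccpart(graph, labels, test_fraction, tie_seed=seed)
        rows.append({
            "method": method,
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
            "interdependence_pct": 100.0 * partition.interdependence(split, graph),
            "cluster_diversity": partition.cluster_diversity(split, clusters),
        })
    return pd.DataFrame(rows)
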