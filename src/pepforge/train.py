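"""Optimized ML ensemble: per-algorithm hyperparameter search + k-fold ensemble.

The training strategy has two stages:

1. **Hyperparameter optimization**, run separately for each learning
   algorithm (k-nearest neighbours, LightGBM, random forest by default).
   The objective for a candidate configuration is the mean Matthews
   correlation coefficient (MCC) over the cross-validation folds: for each
   fold the model is fitted on the remaining folds and scored on the held
   fold. The search is sequential and seeded; two samplers are provided —
   a Gaussian-process surrogate maximizing expected improvement after a
   random warm-up (the default), and plain seeded random search, which the
   surrogate degrades to gracefully and which keeps the trace/seed contract
   independent of surrogate internals.

2. **Ensembling**: each algorithm, at its best configuration, is fitted
   once per fold (training on all other folds), giving
   ``n_algorithms x k`` members — 30 with the default three algorithms and
   ten folds. The ensemble score for a peptide is the unweighted mean of
   all member positive-class probabilities, so it always lies between the
   smallest and largest member score.

Small peptide datasets are the design point: ensembling across folds
stabilizes the decision function where a single fit would be noisy.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.neighbors import KNeighborsClassifier
from scipy.stats import norm

from .evaluate import ConfusionCounts, mcc

BUNDLE_FORMAT_VERSION = 1

DEFAULT_ALGORITHMS = ("knn", "lightgbm", "rfc")


class TrainingError(RuntimeError):
    """Raised for degenerate folds, failed fits, or bundle mismatches."""


# ---------------------------------------------------------------------------
# search spaces


@dataclass(frozen=True)
class ParamSpec:
    """One hyperparameter domain: integer/float range or categorical choice."""

    kind: str  # "int" | "float" | "cat"
    low: float | None = None
    high: float | None = None
    log: bool = False
    choices: tuple = ()

    def sample(self, rng: np.random.Generator):
        if self.kind == "cat":
            return self.choices[rng.integers(len(self.choices))]
        if self.kind == "int":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def contains(self, value) -> bool:
        if self.kind == "cat":
            return value in self.choices
        return self.low <= value <= self.high

    def to_unit(self, value) -> float:
        """Map a value into [0,1] for the surrogate model."""
        if self.kind == "cat":
            return self.choices.index(value) / max(len(self.choices) - 1, 1)
        if self.log:
            return (math.log(value) - math.log(self.low)) / (
                math.log(self.high) - math.log(self.low)
            )
        return (value - self.low) / (self.high - self.low)


@dataclass
class SearchSpace:
    """Per-algorithm hyperparameter domains plus the trial budget and seed."""

    spaces: dict[str, dict[str, ParamSpec]]
    n_trials: int = 100
    seed: int = 0
    sampler: str = "gp"  # "gp" (surrogate after warm-up) or "random"

    @property
    def algorithms(self) -> tuple[str, ...]:
        return tuple(self.spaces)


def default_search_space(
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    n_trials: int = 100,
    seed: int = 0,
    sampler: str = "gp",
) -> SearchSpace:
    all_spaces = {
        "knn": {
            "n_neighbors": ParamSpec("int", 1, 30),
            "weights": ParamSpec("cat", choices=("uniform", "distance")),
        },
        "lightgbm": {
            "n_estimators": ParamSpec("int", 50, 500),
            "learning_rate": ParamSpec("float", 1e-3, 0.3, log=True),
            "num_leaves": ParamSpec("int", 8, 128),
            "min_child_samples": ParamSpec("int", 2, 50),
        },
        "rfc": {
            "n_estimators": ParamSpec("int", 50, 500),
            "max_depth": ParamSpec("int", 2, 32),
            "min_samples_leaf": ParamSpec("int", 1, 10),
        },
    }
    unknown = set(algorithms) - set(all_spaces)
    if unknown:
        raise TrainingError(f"unknown algorithms: {sorted(unknown)}")
    return SearchSpace(
        spaces={a: all_spaces[a] for a in algorithms},
        n_trials=n_trials,
        seed=seed,
        sampler=sampler,
    )


def make_estimator(algo: str, params: dict, seed: int = 0):
    """Instantiate a classifier for one algorithm/configuration pair."""
    if algo == "knn":
        return KNeighborsClassifier(n_jobs=1, **params)
    if algo == "lightgbm":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_col_wise=True, **params,
        )
    if algo == "rfc":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise TrainingError(f"unknown algorithm: {algo!r}")


# ---------------------------------------------------------------------------
# cross-validated objective


def _fold_arrays(
    vectors: dict[str, np.ndarray],
    labels: dict[str, int],
    folds: dict[int, set[str]],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Materialize (X_train, y_train, X_val, y_val) per fold, id-sorted."""
    out = []
    for fold_idx in sorted(folds):
        val_ids = sorted(folds[fold_idx])
        train_ids = sorted(
            pid for j, fold in folds.items() if j != fold_idx for pid in fold
        )
        y_tr = np.array([labels[i] for i in train_ids])
        y_va = np.array([labels[i] for i in val_ids])
        if len(set(y_tr)) < 2:
            raise TrainingError(
                f"fold {fold_idx}: training portion contains a single class"
            )
        out.append((
            np.stack([vectors[i] for i in train_ids]),
            y_tr,
            np.stack([vectors[i] for i in val_ids]),
            y_va,
        ))
    return out


def _predict_proba(model, X: np.ndarray) -> np.ndarray:
    # LightGBM's sklearn wrapper records auto-generated feature names at fit
    # time; scoring plain arrays then triggers a spurious name-check warning
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return model.predict_proba(X)


def _cv_mcc(fold_arrays, algo: str, params: dict, seed: int) -> float:
    scores = []
    for X_tr, y_tr, X_va, y_va in fold_arrays:
        model = make_estimator(algo, params, seed=seed)
        model.fit(X_tr, y_tr)
        proba = _predict_proba(model, X_va)[:, 1]
        pred = (proba > 0.5).astype(int)
        scores.append(mcc(ConfusionCounts.from_labels(y_va, pred)))
    return float(np.mean(scores))


@dataclass
class OptimizationResult:
    algorithm: str
    best_params: dict
    best_score: float
    trace: list[dict] = field(default_factory=list)


def optimize_algorithm(
    train_vectors: dict[str, np.ndarray],
    labels: dict[str, int],
    folds: dict[int, set[str]],
    algo: str,
    space: SearchSpace,
) -> OptimizationResult:
    """Search ``algo``'s hyperparameter domain for the best mean CV MCC.

    The trace records every (configuration, score) pair in evaluation
    order; the search is fully reproducible from ``space.seed``. Ties on
    the objective keep the earlier trial.
    """
    if len(folds) < 2:
        raise TrainingError("hyperparameter optimization requires >= 2 folds")
    params_spec = space.spaces[algo]
    rng = np.random.default_rng(space.seed + zlib.crc32(algo.encode()) % 10007)
    arrays = _fold_arrays(train_vectors, labels, folds)

    n_warmup = (
        space.n_trials if space.sampler == "random"
        else max(min(10, space.n_trials), space.n_trials // 4)
    )
    trials: list[dict] = []
    evaluated: list[tuple[dict, float]] = []

    def run_trial(params: dict) -> None:
        score = _cv_mcc(arrays, algo, params, seed=space.seed)
        trials.append({"params": dict(params), "score": score})
        evaluated.append((params, score))

    for _ in range(min(n_warmup, space.n_trials)):
        run_trial({name: ps.sample(rng) for name, ps in params_spec.items()})

    # sequential surrogate phase: fit a GP on unit-cube encodings, pick the
    # candidate maximizing expected improvement from a random pool
    names = sorted(params_spec)
    while len(trials) < space.n_trials:
        X = np.array(
            [[params_spec[n].to_unit(p[n]) for n in names] for p, _ in evaluated]
        )
        y = np.array([s for _, s in evaluated])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(X, y)
        pool = [
            {name: ps.sample(rng) for name, ps in params_spec.items()}
            for _ in range(128)
        ]
        Xp = np.array([[params_spec[n].to_unit(p[n]) for n in names] for p in pool])
        mu, sigma = gp.predict(Xp, return_std=True)
        best = y.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma == 0] = 0.0
        run_trial(pool[int(np.argmax(ei))])

    best_idx = int(np.argmax([t["score"] for t in trials]))
    return OptimizationResult(
        algorithm=algo,
        best_params=trials[best_idx]["params"],
        best_score=trials[best_idx]["score"],
        trace=trials,
    )


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleMember:
    algorithm: str
    params: dict
    fold: int
    model: object


@dataclass
class EnsembleModel:
    """``n_algorithms x k`` fitted members with averaged prediction."""

    members: list[EnsembleMember]
    backend_name: str
    dim: int
    train_ids: list[str]
    folds: dict[int, set[str]]
    best_configs: dict[str, dict]
    seed: int
    cv_scores: dict[str, float] = field(default_factory=dict)

    def member_scores(self, vectors: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
        """Positive-class probability from every member; rows = peptides."""
        ids = list(vectors)
        X = np.stack([vectors[i] for i in ids])
        if X.shape[1] != self.dim:
            raise TrainingError(
                f"feature dimension mismatch: ensemble expects e={self.dim}, "
                f"got {X.shape[1]}"
            )
        scores = np.stack(
            [_predict_proba(m.model, X)[:, 1] for m in self.members], axis=1
        )
        return ids, scores

    def predict(self, vectors: dict[str, np.ndarray]) -> dict[str, float]:
        """Unweighted mean of member probabilities, per peptide id."""
        ids, scores = self.member_scores(vectors)
        return dict(zip(ids, scores.mean(axis=1)))

    def predict_with_uncertainty(
        self, vectors: dict[str, np.ndarray]
    ) -> dict[str, tuple[float, float]]:
        """(mean, member-score standard deviation) per peptide id."""
        ids, scores = self.member_scores(vectors)
        return {
            i: (float(mu), float(sd))
            for i, mu, sd in zip(ids, scores.mean(axis=1), scores.std(axis=1))
        }


def fit_ensemble(
    train_vectors: dict[str, np.ndarray],
    labels: dict[str, int],
    folds: dict[int, set[str]],
    best_configs: dict[str, dict],
    backend_name: str = "unspecified",
    seed: int = 0,
    cv_scores: dict[str, float] | None = None,
) -> EnsembleModel:
    """Fit one member per (algorithm, fold): trained on all folds but its own."""
    arrays = _fold_arrays(train_vectors, labels, folds)
    members = []
    for algo, params in best_configs.items():
        for fold_idx, (X_tr, y_tr, _, _) in zip(sorted(folds), arrays):
            model = make_estimator(algo, params, seed=seed)
            try:
                model.fit(X_tr, y_tr)
            except Exception as e:  # no partial ensembles
                raise TrainingError(
                    f"fit failed for {algo} on fold {fold_idx}: {e}"
                ) from e
            members.append(EnsembleMember(algo, dict(params), fold_idx, model))
    dim = next(iter(train_vectors.values())).shape[0]
    return EnsembleModel(
        members=members,
        backend_name=backend_name,
        dim=dim,
        train_ids=sorted(train_vectors),
        folds={k: set(v) for k, v in folds.items()},
        best_configs={a: dict(p) for a, p in best_configs.items()},
        seed=seed,
        cv_scores=dict(cv_scores or {}),
    )


# ---------------------------------------------------------------------------
# model bundle persistence


def save_model(ensemble: EnsembleModel, bundle_dir: str | Path) -> Path:
    """Write a reproducibility bundle: manifest + one file per member."""
    bundle = Path(bundle_dir)
    (bundle / "members").mkdir(parents=True, exist_ok=True)
    member_files = []
    for i, m in enumerate(ensemble.members):
        fname = f"members/member_{i:03d}_{m.algorithm}_fold{m.fold}.joblib"
        joblib.dump(m.model, bundle / fname)
        member_files.append(
            {"file": fname, "algorithm": m.algorithm, "params": m.params,
             "fold": m.fold}
        )
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "backend": ensemble.backend_name,
        "dim": ensemble.dim,
        "seed": ensemble.seed,
        "train_ids": ensemble.train_ids,
        "folds": {str(k): sorted(v) for k, v in ensemble.folds.items()},
        "best_configs": ensemble.best_configs,
        "cv_scores": ensemble.cv_scores,
        "members": member_files,
    }
    (bundle / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def load_model(bundle_dir: str | Path) -> EnsembleModel:
    """Load a bundle; refuses version mismatches and incomplete bundles."""
    bundle = Path(bundle_dir)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise TrainingError(f"not a model bundle: {bundle} (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise TrainingError(
            f"bundle format version {version} does not match supported "
            f"version {BUNDLE_FORMAT_VERSION}; refusing best-effort load"
        )
    members = []
    for entry in manifest["members"]:
        path = bundle / entry["file"]
        if not path.exists():
            raise TrainingError(f"bundle incomplete: missing member {entry['file']}")
        members.append(
            EnsembleMember(
                entry["algorithm"], entry["params"], entry["fold"],
                joblib.load(path),
            )
        )
    return EnsembleModel(
        members=members,
        backend_name=manifest["backend"],
        dim=manifest["dim"],
        train_ids=manifest["train_ids"],
        folds={int(k): set(v) for k, v in manifest["folds"].items()},
        best_configs=manifest["best_configs"],
        seed=manifest["seed"],
        cv_scores=manifest.get("cv_scores", {}),
    )
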