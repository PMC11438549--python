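"""Peptide representations and physico-chemical descriptors.

Every representation backend maps a peptide to a per-residue matrix of
shape ``n x e`` (``n`` residues, ``e`` features per residue) and the
peptide-level vector is always the column-wise mean over residues,
``r = (1/n) * sum_i M_i``. Pooling by the mean makes the representation
length-invariant in dimension, so classifiers trained downstream accept
peptides of any length.

Two backends ship with the package:

* ``onehot`` — the naive baseline: each residue is a 20-dimensional unit
  vector, so the pooled vector is exactly the amino-acid composition.
* ``mock-plm`` — a deterministic stand-in for a protein language model
  used in tests and examples: each residue row is a pseudo-random
  32-dimensional vector keyed by a stable hash of the k-mer window around
  the residue, so the embedding is position- and context-sensitive like a
  real language model, reproducible, and requires no downloads. It is a
  synthetic construction for plumbing, not a trained model.

Real pretrained protein language models (ESM2, ProtBERT, ProtT5, ...) plug
in through the same :class:`EmbeddingBackend` interface: implement
``residue_matrix`` returning only residue rows (special tokens excluded),
register the backend, and everything downstream works unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import wasserstein_distance

from .peptide_io import AMINO_ACIDS, Peptide, PeptideDataset, validate_sequence

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _load_scales() -> dict:
    with resources.files("pepforge.data").joinpath("scales.json").open() as fh:
        return json.load(fh)


SCALES = _load_scales()


class BackendUnavailableError(RuntimeError):
    """Raised when a representation backend cannot be constructed."""


# ---------------------------------------------------------------------------
# matrices and pooling


def one_hot_matrix(p: Peptide | str) -> np.ndarray:
    """n x 20 one-hot residue matrix (rows sum to 1)."""
    seq = p.sequence if isinstance(p, Peptide) else p
    validate_sequence(seq)
    m = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        m[i, _AA_INDEX[aa]] = 1.0
    return m


def mean_pool(m: np.ndarray) -> np.ndarray:
    """Column-wise mean of a residue matrix; preserves the feature width."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("mean_pool requires a non-empty n x e matrix")
    return m.mean(axis=0)


class EmbeddingBackend:
    """Interface every representation backend implements.

    ``residue_matrix`` must return residue rows only — no special-token
    rows — so mean pooling averages over exactly the peptide's residues.
    """

    name: str = "abstract"
    dim: int = 0

    def residue_matrix(self, sequence: str) -> np.ndarray:
        raise NotImplementedError


class OneHotBackend(EmbeddingBackend):
    name = "onehot"
    dim = 20

    def residue_matrix(self, sequence: str) -> np.ndarray:
        return one_hot_matrix(sequence)


class MockPLMBackend(EmbeddingBackend):
    """Deterministic hash-of-k-mer residue embedder (synthetic).

    Row ``i`` is drawn from a generator seeded by a BLAKE2 hash of the
    k-mer window starting at residue ``i`` (clipped at the C-terminus)
    together with the backend seed, so identical sequences embed
    identically across processes while permuted sequences generally do not.
    """

    def __init__(self, dim: int = 32, k: int = 3, seed: int = 0):
        self.name = f"mock-plm-d{dim}k{k}s{seed}"
        self.dim = dim
        self.k = k
        self.seed = seed

    def residue_matrix(self, sequence: str) -> np.ndarray:
        validate_sequence(sequence)
        rows = np.empty((len(sequence), self.dim))
        for i in range(len(sequence)):
            window = sequence[i:i + self.k]
            digest = hashlib.blake2b(
                f"{self.seed}:{i % 7}:{window}".encode(), digest_size=4
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            rows[i] = rng.standard_normal(self.dim)
        return rows


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Resolve a backend by name.

    Known names: ``onehot``, ``mock-plm``. Names of real protein language
    models raise an actionable error pointing at the optional dependency
    rather than silently falling back to another representation.
    """
    if name == "onehot":
        return OneHotBackend()
    if name == "mock-plm" or name.startswith("mock-plm"):
        return MockPLMBackend(**kwargs)
    if name.lower().startswith(("esm", "prot")):
        raise BackendUnavailableError(
            f"backend {name!r} requires the optional protein-language-model "
            f"dependencies (install fair-esm or transformers and register an "
            f"adapter); no silent fallback is performed"
        )
    raise BackendUnavailableError(f"unknown representation backend: {name!r}")


class EmbeddingCache:
    """In-memory (optionally directory-backed) cache keyed by backend + sequence."""

    def __init__(self, directory: str | Path | None = None):
        self._mem: dict[tuple[str, str], np.ndarray] = {}
        self._dir = Path(directory) if directory else None
        if self._dir:
            self._dir.mkdir(parents=True, exist_ok=True)

    def _path(self, backend: str, sequence: str) -> Path:
        key = hashlib.blake2b(
            f"{backend}:{sequence}".encode(), digest_size=16
        ).hexdigest()
        return self._dir / f"{key}.npy"

    def get(self, backend: str, sequence: str) -> np.ndarray | None:
        key = (backend, sequence)
        if key in self._mem:
            return self._mem[key]
        if self._dir:
            path = self._path(backend, sequence)
            if path.exists():
                vec = np.load(path)
                self._mem[key] = vec
                return vec
        return None

    def put(self, backend: str, sequence: str, vec: np.ndarray) -> None:
        self._mem[(backend, sequence)] = vec
        if self._dir:
            np.save(self._path(backend, sequence), vec)


def embed(
    p: Peptide | str,
    backend: EmbeddingBackend,
    cache: EmbeddingCache | None = None,
) -> np.ndarray:
    """Mean-pooled fixed-length vector for one peptide."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if cache is not None:
        hit = cache.get(backend.name, seq)
        if hit is not None:
            return hit
    vec = mean_pool(backend.residue_matrix(seq))
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"backend {backend.name} produced non-finite values")
    if cache is not None:
        cache.put(backend.name, seq, vec)
    return vec


def embed_dataset(
    dataset: PeptideDataset,
    backend: EmbeddingBackend,
    cache: EmbeddingCache | None = None,
) -> dict[str, np.ndarray]:
    return {p.id: embed(p, backend, cache) for p in dataset}


# ---------------------------------------------------------------------------
# physico-chemical descriptors


@dataclass(frozen=True)
class PropertyProfile:
    """Classic peptide descriptors with their conventional scales.

    aliphatic_index: Ikai's index, 0–~390 (100 for poly-Ala).
    boman_index: mean per-residue interaction potential, kcal/mol.
    net_charge: Henderson–Hasselbalch net charge at the stated pH,
        including both termini.
    isoelectric_point: pH of zero net charge, in [0, 14].
    hydrophobic_moment: mean amphipathic moment at a 100 deg helical twist,
        Eisenberg consensus scale; >= 0.
    """

    aliphatic_index: float
    boman_index: float
    net_charge: float
    isoelectric_point: float
    hydrophobic_moment: float
    ph: float


def aliphatic_index(seq: str) -> float:
    """100*(x_Ala + 2.9*x_Val + 3.9*(x_Ile + x_Leu)), mole fractions."""
    n = len(seq)
    x = {aa: seq.count(aa) / n for aa in "AVIL"}
    return 100.0 * (x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"]))


def boman_index(seq: str) -> float:
    scale = SCALES["boman"]
    return sum(scale[aa] for aa in seq) / len(seq)


def net_charge(seq: str, ph: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge including N- and C-termini."""
    pka = SCALES["pka"]
    pos = [pka["n_terminus"]] + [
        pka["positive_side_chains"][aa]
        for aa in seq if aa in pka["positive_side_chains"]
    ]
    neg = [pka["c_terminus"]] + [
        pka["negative_side_chains"][aa]
        for aa in seq if aa in pka["negative_side_chains"]
    ]
    charge = sum(1.0 / (1.0 + 10 ** (ph - p)) for p in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (p - ph)) for p in neg)
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges; the
    result satisfies |net_charge(pI)| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) < 0:
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def hydrophobic_moment(seq: str, angle_deg: float = 100.0) -> float:
    """(1/n) * |sum_j H_j * exp(i*j*delta)| with delta = 100 deg (helix)."""
    scale = SCALES["hydrophobicity_eisenberg"]
    delta = np.deg2rad(angle_deg)
    j = np.arange(len(seq))
    h = np.array([scale[aa] for aa in seq])
    return float(np.abs(np.sum(h * np.exp(1j * j * delta))) / len(seq))


def property_profile(p: Peptide | str, ph: float = 7.0) -> PropertyProfile:
    """All shipped physico-chemical descriptors for one peptide."""
    seq = p.sequence if isinstance(p, Peptide) else p
    validate_sequence(seq)
    return PropertyProfile(
        aliphatic_index=aliphatic_index(seq),
        boman_index=boman_index(seq),
        net_charge=net_charge(seq, ph),
        isoelectric_point=isoelectric_point(seq),
        hydrophobic_moment=hydrophobic_moment(seq),
        ph=ph,
    )


_PROPERTY_FUNCS = {
    "length": len,
    "aliphatic_index": aliphatic_index,
    "boman_index": boman_index,
    "net_charge": net_charge,
    "isoelectric_point": isoelectric_point,
    "hydrophobic_moment": hydrophobic_moment,
}


def compare_distributions(
    a: PeptideDataset,
    b: PeptideDataset,
    property: str,
    n_bins: int = 20,
) -> dict:
    """Aligned histograms and Wasserstein-1 distance for one property.

    Returns a dict with the shared bin edges, per-dataset densities, the
    raw property values, and the Wasserstein-1 distance between the two
    empirical distributions. Emitted as data so callers can plot or report.
    """
    if property not in _PROPERTY_FUNCS:
        raise ValueError(
            f"unknown property {property!r}; choose from {sorted(_PROPERTY_FUNCS)}"
        )
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both datasets must be non-empty")
    f = _PROPERTY_FUNCS[property]
    va = np.array([float(f(p.sequence)) for p in a])
    vb = np.array([float(f(p.sequence)) for p in b])
    lo = min(va.min(), vb.min())
    hi = max(va.max(), vb.max())
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(va, bins=edges, density=True)
    hb, _ = np.histogram(vb, bins=edges, density=True)
    return {
        "property": property,
        "bin_edges": edges,
        "density_a": ha,
        "density_b": hb,
        "values_a": va,
        "values_b": vb,
        "wasserstein": float(wasserstein_distance(va, vb)),
    }
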