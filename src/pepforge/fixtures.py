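"""Synthetic peptide families, tagged databases, and label-signal injection.

Real peptide datasets come in families of homologous sequences (shared
evolutionary origin or a shared design motif). The generator emulates that
structure directly: each family grows from a random seed sequence, and
members are point-substituted copies at a controlled per-residue mutation
rate. With rate 0 a family is a set of identical copies; with modest rates
(~0.1) members stay well above any practical identity threshold while
families remain mutually dissimilar, so the true family map is recoverable
as the connected components of the similarity graph.

What the generator deliberately does *not* model: realistic amino-acid
composition biases, indel evolution (substitutions only by default), or
biophysically plausible motifs. It exists so that partitioning, sampling
and training can be exercised end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .negdb import BioactivePeptideDB
from .peptide_io import AMINO_ACIDS, Peptide, PeptideDataset


@dataclass(frozen=True)
class FamilySpec:
    """Controls for the homologous-family generator."""

    n_families: int = 20
    family_size_min: int = 10
    family_size_max: int = 10
    seed_length_min: int = 15
    seed_length_max: int = 30
    mutation_rate: float = 0.1
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (3 <= self.seed_length_min <= self.seed_length_max <= 50):
            raise ValueError("seed lengths must lie within the 3-50 peptide range")
        if self.family_size_min < 1 or self.family_size_min > self.family_size_max:
            raise ValueError("invalid family size range")


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float, indel_rate: float,
            alphabet: str) -> str:
    out = []
    for aa in seq:
        if indel_rate and rng.random() < indel_rate / 2 and len(seq) > 4:
            continue  # deletion
        if rng.random() < rate:
            choices = [c for c in alphabet if c != aa]
            aa = choices[rng.integers(len(choices))]
        out.append(aa)
        if indel_rate and rng.random() < indel_rate / 2 and len(seq) < 49:
            out.append(alphabet[rng.integers(len(alphabet))])  # insertion
    return "".join(out) if out else seq


def generate_families(
    spec: FamilySpec, alphabet: str = AMINO_ACIDS
) -> tuple[PeptideDataset, dict[str, int]]:
    """Generate homologous families; returns (dataset, id -> family index).

    Family ``f`` has members ``fam{f}_m{j}``; member 0 is the unmutated
    seed. Reproducible under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    peptides = []
    family_map: dict[str, int] = {}
    for f in range(spec.n_families):
        length = int(rng.integers(spec.seed_length_min, spec.seed_length_max + 1))
        seed_seq = _random_seq(rng, length, alphabet)
        size = int(rng.integers(spec.family_size_min, spec.family_size_max + 1))
        for j in range(size):
            seq = seed_seq if j == 0 else _mutate(
                rng, seed_seq, spec.mutation_rate, spec.indel_rate, alphabet
            )
            pid = f"fam{f}_m{j}"
            peptides.append(Peptide(pid, seq))
            family_map[pid] = f
    ds = PeptideDataset(peptides, name=f"families-{spec.n_families}x"
                        f"{spec.family_size_min}-{spec.family_size_max}")
    return ds, family_map


def label_families(
    dataset: PeptideDataset, family_map: dict[str, int], seed: int = 0
) -> PeptideDataset:
    """Assign binary labels at the family level, half the families positive.

    Whole families share a label so that homology partitioning cannot
    separate a peptide from its own class context.
    """
    rng = np.random.default_rng(seed)
    families = sorted(set(family_map.values()))
    perm = rng.permutation(len(families))
    positive = {families[i] for i in perm[: len(families) // 2]}
    labeled = [
        p.with_label(1 if family_map[p.id] in positive else 0) for p in dataset
    ]
    return PeptideDataset(labeled, name=dataset.name,
                          metadata=dict(dataset.metadata))


DEFAULT_TAG_VOCABULARY = (
    "antibacterial", "antiviral", "antifungal", "antiparasitic",
    "antioxidant", "anticancer", "antihypertensive", "immunomodulatory",
    "neuropeptide", "toxic",
)


def generate_tagged_db(
    n: int = 1000,
    tags: tuple[str, ...] = DEFAULT_TAG_VOCABULARY,
    length_min: int = 5,
    length_max: int = 50,
    seed: int = 0,
) -> BioactivePeptideDB:
    """Random tagged peptide database, dense across the length range.

    Lengths are uniform over [length_min, length_max]; each peptide gets
    1-3 distinct tags from the vocabulary. At n=1000 over a 5-50 range
    every 5-residue bin holds ~100 peptides, plenty for length-matched
    sampling tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    peptides = []
    for i in range(n):
        length = int(rng.integers(length_min, length_max + 1))
        seq = _random_seq(rng, length, AMINO_ACIDS)
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(tags), size=min(k, len(tags)), replace=False)
        peptides.append(
            Peptide(f"db{i}", seq, tags=frozenset(tags[j] for j in chosen))
        )
    return BioactivePeptideDB(peptides, name=f"synthetic-db-{n}")


def inject_label_signal(
    dataset: PeptideDataset,
    motif: str,
    fraction_pos_with_motif: float,
    seed: int = 0,
    scramble: bool = False,
    scatter: bool = False,
) -> PeptideDataset:
    """Embed a motif into a fraction of the positive peptides.

    The motif overwrites part of the sequence (lengths are preserved so
    length itself never becomes the label signal). Because the motif shifts
    amino-acid composition, even the mean-pooled one-hot representation can
    see it; the fraction controls how learnable the labels are.

    Placement modes control how much *sequence* homology the signal adds on
    top of the composition shift:

    * default — the motif overwrites one contiguous window, so all
      signal-carrying positives share an exact subsequence;
    * ``scramble`` — the motif letters are permuted per insertion (same
      composition, no shared exact subsequence);
    * ``scatter`` — the (optionally scrambled) letters overwrite random
      non-contiguous positions. Aligning two scattered insertions requires
      one gap per matched residue, which affine gap penalties price out, so
      the signal stays invisible to the similarity graph and the clusters
      keep reflecting family structure rather than the label. This is the
      right setting when the labeled dataset will be homology-partitioned.
    """
    if not (0.0 <= fraction_pos_with_motif <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    min_len = min((len(p) for p in dataset), default=0)
    if len(motif) >= min_len:
        raise ValueError(
            f"motif length {len(motif)} must be shorter than the shortest "
            f"sequence ({min_len})"
        )
    rng = np.random.default_rng(seed)
    pos_ids = [p.id for p in dataset if p.label == 1]
    n_signal = int(round(len(pos_ids) * fraction_pos_with_motif))
    perm = rng.permutation(len(pos_ids))
    chosen = {pos_ids[i] for i in perm[:n_signal]}
    out = []
    for p in dataset:
        if p.id in chosen:
            ins = motif
            if scramble:
                ins = "".join(motif[i] for i in rng.permutation(len(motif)))
            if scatter:
                positions = sorted(
                    int(i) for i in rng.choice(
                        len(p.sequence), size=len(motif), replace=False
                    )
                )
                chars = list(p.sequence)
                for pos, aa in zip(positions, ins):
                    chars[pos] = aa
                seq = "".join(chars)
            else:
                start = int(rng.integers(0, len(p.sequence) - len(motif) + 1))
                seq = p.sequence[:start] + ins + p.sequence[start + len(motif):]
            out.append(Peptide(p.id, seq, label=p.label, tags=p.tags,
                               description=p.description))
        else:
            out.append(p)
    return PeptideDataset(out, name=dataset.name, metadata=dict(dataset.metadata))
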