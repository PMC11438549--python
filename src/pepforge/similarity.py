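"""Pairwise sequence identity and similarity-graph construction.

Two peptides are considered similar when the fraction of identical aligned
residue pairs in their optimal local (Smith–Waterman) alignment, divided by
the length of the *longer* sequence, exceeds a threshold (30% by default).
Using the longer sequence as denominator makes short spurious alignments
between peptides of very different lengths count for little.

An exact k-mer prefilter limits alignment to pairs that share at least one
k-mer, the standard trick for avoiding the quadratic all-pairs alignment
cost. The default is k = 2: unlike k = 3, which measurably drops unrelated
pairs sitting just above the 30% identity threshold (their matches need
not include any three consecutive identical residues), no k = 2 miss has
been observed on randomized family datasets. The prefilter can be switched
off to recover the exhaustive computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .peptide_io import Peptide, PeptideDataset


@dataclass(frozen=True)
class IdentityParams:
    """Parameters of the pairwise-identity criterion.

    ``threshold`` is compared strictly (identity must *exceed* it).
    ``denominator`` is fixed to the longer sequence's length. Alignment is
    local with the named substitution matrix and affine gap penalties
    (``gap_open``/``gap_extend`` are positive costs).
    """

    threshold: float = 0.30
    denominator: str = "longest_sequence"
    prefilter_kmer: int = 2
    prefilter_min_shared: int = 1
    alignment_mode: str = "local"
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.prefilter_kmer < 1:
            raise ValueError("prefilter_kmer must be >= 1")
        if self.alignment_mode != "local":
            raise ValueError("only local alignment is supported")
        if self.denominator != "longest_sequence":
            raise ValueError("only the longest-sequence denominator is supported")


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner(mode="local")
    aln.substitution_matrix = substitution_matrices.load(matrix)
    aln.open_gap_score = -abs(gap_open)
    aln.extend_gap_score = -abs(gap_extend)
    return aln


def _match_count(aligner: Align.PairwiseAligner, a: str, b: str) -> int:
    """Identical aligned residue pairs in one optimal local alignment."""
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return 0
    matches = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    return matches


def pairwise_identity(
    a: Peptide | str, b: Peptide | str, params: IdentityParams = IdentityParams()
) -> float:
    """Local-alignment sequence identity in [0, 1].

    identity = (identical aligned residue pairs in the optimal local
    alignment) / max(len(a), len(b)).

    The pair is ordered canonically before aligning so the result is
    symmetric even when several co-optimal alignments exist.
    """
    sa = a.sequence if isinstance(a, Peptide) else a
    sb = b.sequence if isinstance(b, Peptide) else b
    if sa > sb:
        sa, sb = sb, sa
    aligner = _aligner(
        params.substitution_matrix, params.gap_open, params.gap_extend
    )
    matches = _match_count(aligner, sa, sb)
    return matches / max(len(sa), len(sb))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_prefilter(
    dataset: PeptideDataset, params: IdentityParams = IdentityParams()
) -> set[tuple[str, str]]:
    """Unordered id pairs sharing >= ``prefilter_min_shared`` exact k-mers.

    Any pair with no shared k-mer is dropped before alignment; every pair
    that does share one is retained, so the filter can only miss similar
    pairs that align without a single exact k-length word in common.
    """
    k = params.prefilter_kmer
    kmer_index: dict[str, list[str]] = {}
    for p in dataset:
        for km in _kmers(p.sequence, k):
            kmer_index.setdefault(km, []).append(p.id)
    shared: dict[tuple[str, str], int] = {}
    for ids in kmer_index.values():
        if len(ids) < 2:
            continue
        for x, y in itertools.combinations(sorted(ids), 2):
            shared[(x, y)] = shared.get((x, y), 0) + 1
    return {pair for pair, n in shared.items() if n >= params.prefilter_min_shared}


def build_similarity_graph(
    dataset: PeptideDataset,
    params: IdentityParams = IdentityParams(),
    prefilter: bool = True,
) -> nx.Graph:
    """Graph with one node per peptide and an edge where identity > threshold.

    Isolated peptides stay in the graph as singleton nodes. With
    ``prefilter`` disabled, all pairs are aligned exhaustively.
    """
    if len(dataset) == 0:
        raise ValueError("cannot build a similarity graph from an empty dataset")
    g = nx.Graph(threshold=params.threshold)
    g.add_nodes_from(dataset.ids())
    if prefilter:
        candidates = kmer_prefilter(dataset, params)
    else:
        candidates = {
            tuple(sorted((x, y)))
            for x, y in itertools.combinations(dataset.ids(), 2)
        }
    for x, y in sorted(candidates):
        ident = pairwise_identity(dataset[x], dataset[y], params)
        if ident > params.threshold:
            g.add_edge(x, y, identity=ident)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Export edges as TSV: id_a, id_b, identity."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity\n")
        for x, y, d in sorted(graph.edges(data=True)):
            fh.write(f"{x}\t{y}\t{d['identity']:.6f}\n")
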