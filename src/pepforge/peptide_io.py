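"""Peptide and dataset containers plus FASTA/CSV readers and writers.

Sequences are strings over the canonical 20-letter amino-acid alphabet.
Non-canonical residue codes (B, J, O, U, X, Z, gaps, digits) are rejected:
every downstream representation in this package assumes the 20-letter
alphabet, so ambiguous or non-standard codes cannot be encoded faithfully.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

#: Canonical amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PeptideIOError(ValueError):
    """Raised for malformed input files or invalid dataset contents."""


class SequenceValidationError(PeptideIOError):
    """Raised when a sequence contains non-canonical residues or is empty."""


def validate_sequence(seq: str, policy: str = "strict") -> str:
    """Validate ``seq`` against the canonical alphabet.

    Parameters
    ----------
    seq:
        Amino-acid sequence.
    policy:
        ``"strict"`` rejects any character outside the 20-letter uppercase
        alphabet. ``"coerce"`` first maps lowercase letters to uppercase,
        then applies the strict rule.

    Returns
    -------
    str
        The validated (possibly uppercased) sequence.

    Raises
    ------
    SequenceValidationError
        If the sequence is empty or contains non-canonical residues. The
        message lists each offending character with its 1-based position.
    """
    if policy not in ("strict", "coerce"):
        raise ValueError(f"unknown validation policy: {policy!r}")
    if policy == "coerce":
        seq = seq.upper()
    if not seq:
        raise SequenceValidationError("empty sequence")
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _AA_SET]
    if bad:
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
        raise SequenceValidationError(f"non-canonical residues: {detail}")
    return seq


@dataclass(frozen=True)
class Peptide:
    """A peptide: identifier, sequence, optional binary label and tag set."""

    id: str
    sequence: str
    label: Optional[int] = None
    tags: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise PeptideIOError(
                f"peptide {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )
        object.__setattr__(self, "tags", frozenset(self.tags))

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: int) -> "Peptide":
        return replace(self, label=label)


@dataclass
class PeptideDataset:
    """Ordered, id-unique collection of peptides.

    The dataset preserves input order and enforces unique ids. ``metadata``
    carries provenance (e.g. a sampling deficit report from negative
    sampling) and is never interpreted by the container itself.
    """

    peptides: list[Peptide] = field(default_factory=list)
    name: str = "dataset"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise PeptideIOError(f"duplicate peptide id: {p.id!r}")
            seen.add(p.id)
        self._by_id = {p.id: p for p in self.peptides}

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, pid: str) -> Peptide:
        return self._by_id[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_id

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def labels(self) -> dict[str, int]:
        """Mapping id -> label; raises if any peptide is unlabeled."""
        missing = [p.id for p in self.peptides if p.label is None]
        if missing:
            raise PeptideIOError(
                f"{len(missing)} peptides lack labels (e.g. {missing[0]!r})"
            )
        return {p.id: p.label for p in self.peptides}

    def subset(self, pids: Iterable[str], name: str | None = None) -> "PeptideDataset":
        keep = set(pids)
        return PeptideDataset(
            [p for p in self.peptides if p.id in keep],
            name=name or self.name,
            metadata=dict(self.metadata),
        )

    def deduplicated(self) -> "PeptideDataset":
        """Drop peptides whose sequence was already seen (first kept)."""
        seen: set[str] = set()
        kept = []
        for p in self.peptides:
            if p.sequence not in seen:
                seen.add(p.sequence)
                kept.append(p)
        meta = dict(self.metadata)
        meta["n_duplicates_removed"] = len(self.peptides) - len(kept)
        return PeptideDataset(kept, name=self.name, metadata=meta)


def read_fasta(path: str | Path, name: str | None = None) -> PeptideDataset:
    """Read a multi-record FASTA file into a :class:`PeptideDataset`.

    The header token up to the first whitespace becomes the id; the
    remainder is kept as the peptide description. Sequences are uppercased
    and validated against the canonical alphabet.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PeptideIOError(f"{path}: no FASTA records found")
    peptides = []
    for rec in records:
        try:
            seq = validate_sequence(str(rec.seq), policy="coerce")
        except SequenceValidationError as e:
            raise SequenceValidationError(f"{path}: record {rec.id!r}: {e}") from e
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        peptides.append(Peptide(id=rec.id, sequence=seq, description=desc))
    return PeptideDataset(peptides, name=name or path.stem)


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.description)
        for p in dataset
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_csv_dataset(
    path: str | Path,
    seq_col: str = "sequence",
    label_col: str | None = None,
    tag_col: str | None = None,
    id_col: str | None = None,
    tag_delimiter: str = ";",
    sep: str = ",",
    name: str | None = None,
) -> PeptideDataset:
    """Read a delimited table of peptides.

    Rows become peptides. Ids come from ``id_col`` when given, otherwise
    they are generated as ``row<i>``. Labels must be binary; tag cells are
    split on ``tag_delimiter`` and empty fragments dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in filter(None, (seq_col, label_col, tag_col, id_col)):
        if col not in df.columns:
            raise PeptideIOError(
                f"{path}: missing column {col!r} (have {list(df.columns)})"
            )
    peptides = []
    for i, row in df.iterrows():
        pid = row[id_col] if id_col else f"row{i}"
        seq = validate_sequence(row[seq_col], policy="coerce")
        label = None
        if label_col:
            raw = row[label_col].strip()
            if raw not in ("0", "1"):
                raise PeptideIOError(
                    f"{path}: row {i}: label must be 0 or 1, got {raw!r}"
                )
            label = int(raw)
        tags: frozenset[str] = frozenset()
        if tag_col:
            tags = frozenset(
                t.strip() for t in row[tag_col].split(tag_delimiter) if t.strip()
            )
        peptides.append(Peptide(id=str(pid), sequence=seq, label=label, tags=tags))
    return PeptideDataset(peptides, name=name or path.stem)


def write_csv_dataset(
    dataset: PeptideDataset,
    path: str | Path,
    tag_delimiter: str = ";",
    sep: str = ",",
) -> None:
    """Write a dataset as CSV (id, sequence, label, tags) round-trippably."""
    has_labels = any(p.label is not None for p in dataset)
    has_tags = any(p.tags for p in dataset)
    with open(path, "w", newline="") as fh:
        cols = ["id", "sequence"] + (["label"] if has_labels else []) + (
            ["tags"] if has_tags else []
        )
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(cols)
        for p in dataset:
            row = [p.id, p.sequence]
            if has_labels:
                row.append("" if p.label is None else str(p.label))
            if has_tags:
                row.append(tag_delimiter.join(sorted(p.tags)))
            writer.writerow(row)
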