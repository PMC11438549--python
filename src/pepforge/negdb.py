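"""Negative-control sampling from a bioactivity-tagged peptide database.

A binary bioactivity predictor needs presumed-inactive examples. Drawing
them from a database of peptides with *other* bioactivities — rather than
from random sequences or protein fragments — keeps the negative class close
to the positive class in its general properties, so the classifier cannot
lean on confounders that merely separate bioactive peptides from random
strings. Two controls enforce this:

* **tag exclusion** — any database peptide carrying a bioactivity that may
  overlap with the target activity is removed before sampling, to avoid
  false negatives;
* **length matching** — the positives' length histogram (bin width 5
  residues by default) is computed, and for each bin as many negatives are
  drawn uniformly without replacement from that length range as there are
  positives in it. A bin whose eligible pool runs short carries its deficit
  to the next bin in ascending length order; any residue left after the
  last bin is optionally back-filled from the nearest preceding bins and
  always reported in the result metadata, never hidden.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .peptide_io import Peptide, PeptideDataset, PeptideIOError, read_csv_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionPolicy:
    """Bioactivity tags that must not appear on sampled negatives."""

    excluded_tags: frozenset[str] = frozenset()

    @classmethod
    def from_json(cls, path: str | Path) -> "ExclusionPolicy":
        with open(path) as fh:
            tags = json.load(fh)
        if not isinstance(tags, list):
            raise PeptideIOError(f"{path}: expected a JSON list of tags")
        return cls(frozenset(tags))


@dataclass(frozen=True)
class LengthHistogram:
    """Contiguous half-open length bins ``[lower, upper)`` with counts.

    Bin edges are aligned to multiples of ``bin_width`` so that the binning
    is a pure function of the lengths, independent of their order.
    """

    bin_width: int
    bins: tuple[tuple[int, int, int], ...]  # (lower, upper, count)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.bins)

    def counts(self) -> dict[tuple[int, int], int]:
        return {(lo, hi): c for lo, hi, c in self.bins}


def build_length_histogram(
    positives: PeptideDataset, bin_width: int = 5
) -> LengthHistogram:
    """Bin the positives' sequence lengths into width-``bin_width`` bins.

    Bins run from the largest multiple of ``bin_width`` not exceeding the
    shortest sequence up to the bin containing the longest one; every
    peptide falls in exactly one half-open bin ``[lower, lower+bin_width)``.
    """
    if len(positives) == 0:
        raise ValueError("cannot build a length histogram from an empty dataset")
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    lengths = [len(p) for p in positives]
    lo = (min(lengths) // bin_width) * bin_width
    hi = (max(lengths) // bin_width + 1) * bin_width
    bins = []
    for start in range(lo, hi, bin_width):
        count = sum(1 for n in lengths if start <= n < start + bin_width)
        bins.append((start, start + bin_width, count))
    hist = LengthHistogram(bin_width=bin_width, bins=tuple(bins))
    assert hist.total == len(positives)
    return hist


class BioactivePeptideDB:
    """Tagged peptide collection queryable by length range and tags.

    Every peptide must carry at least one bioactivity tag; the tag and
    length indices are derived from the peptide list and rebuilt whenever
    a filtered copy is made.
    """

    def __init__(self, peptides: list[Peptide], name: str = "peptide-db"):
        for p in peptides:
            if not p.tags:
                raise PeptideIOError(
                    f"database peptide {p.id!r} has no bioactivity tags"
                )
        self.peptides = list(peptides)
        self.name = name
        self._by_id = {p.id: p for p in self.peptides}
        if len(self._by_id) != len(self.peptides):
            raise PeptideIOError("duplicate ids in database")
        self.tag_index: dict[str, set[str]] = {}
        self.length_index: dict[int, set[str]] = {}
        for p in self.peptides:
            for t in p.tags:
                self.tag_index.setdefault(t, set()).add(p.id)
            self.length_index.setdefault(len(p), set()).add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __getitem__(self, pid: str) -> Peptide:
        return self._by_id[pid]

    @property
    def tags(self) -> set[str]:
        return set(self.tag_index)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        seq_col: str = "sequence",
        tag_col: str = "tags",
        id_col: str | None = "id",
        sep: str = ",",
        tag_delimiter: str = ";",
    ) -> "BioactivePeptideDB":
        ds = read_csv_dataset(
            path, seq_col=seq_col, tag_col=tag_col, id_col=id_col,
            sep=sep, tag_delimiter=tag_delimiter,
        )
        return cls(list(ds), name=ds.name)

    def ids_in_length_range(self, lower: int, upper: int) -> list[str]:
        """Ids of peptides with ``lower <= length < upper``, in db order."""
        hit = set()
        for n in range(lower, upper):
            hit |= self.length_index.get(n, set())
        return [p.id for p in self.peptides if p.id in hit]


def apply_exclusions(
    db: BioactivePeptideDB, policy: ExclusionPolicy
) -> BioactivePeptideDB:
    """Remove every peptide carrying *any* excluded tag; rebuild indices.

    Tags in the policy that do not occur in the database are logged as a
    warning (they are harmless — often the target activity itself) but do
    not abort the run.
    """
    unknown = set(policy.excluded_tags) - db.tags
    if unknown:
        msg = f"exclusion tags not present in database: {sorted(unknown)}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    excl = frozenset(policy.excluded_tags)
    kept = [p for p in db.peptides if not (p.tags & excl)]
    return BioactivePeptideDB(kept, name=db.name)


def sample_negatives(
    db: BioactivePeptideDB,
    hist: LengthHistogram,
    policy: ExclusionPolicy,
    seed: int,
    forbidden_sequences: set[str] | frozenset[str] = frozenset(),
    backfill: bool = True,
) -> PeptideDataset:
    """Draw length-matched negatives from ``db`` under ``policy``.

    For each histogram bin, as many peptides as the bin's count are drawn
    uniformly without replacement from database peptides in that length
    range. Shortfalls spill over to the next bin (ascending length); a
    residual deficit after the last bin is back-filled from the nearest
    preceding bins when ``backfill`` is true. Peptides whose sequence
    appears in ``forbidden_sequences`` (normally the positives) are never
    drawn. The returned dataset's metadata records per-bin draws and any
    final deficit.
    """
    db = apply_exclusions(db, policy)
    if len(db) == 0:
        raise ValueError("database empty after applying exclusions")
    rng = np.random.default_rng(seed)
    drawn: list[str] = []
    drawn_set: set[str] = set()
    per_bin: dict[str, int] = {}

    def eligible(lo: int, hi: int) -> list[str]:
        return [
            pid for pid in db.ids_in_length_range(lo, hi)
            if pid not in drawn_set
            and db[pid].sequence not in forbidden_sequences
        ]

    def draw_from(lo: int, hi: int, want: int) -> int:
        pool = eligible(lo, hi)
        take = min(want, len(pool))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            for i in sorted(picked):
                drawn.append(pool[i])
                drawn_set.add(pool[i])
        per_bin[f"[{lo},{hi})"] = per_bin.get(f"[{lo},{hi})", 0) + take
        return take

    carry = 0
    for lo, hi, count in hist.bins:
        carry += count - draw_from(lo, hi, count + carry)

    # ascending spillover continues past the histogram's top edge into the
    # database's longer length bins
    if carry:
        top = hist.bins[-1][1]
        db_max = max((len(p) for p in db.peptides), default=top)
        lo = top
        while carry and lo <= db_max:
            carry -= draw_from(lo, lo + hist.bin_width, carry)
            lo += hist.bin_width

    if carry and backfill:
        # nearest preceding bins first: descending length over every bin with
        # remaining eligible peptides, down to length zero
        lo = hist.bins[-1][0]
        while carry and lo + hist.bin_width > 0:
            carry -= draw_from(max(lo, 0), lo + hist.bin_width, carry)
            lo -= hist.bin_width

    deficit = hist.total - len(drawn)
    if deficit:
        logger.warning(
            "negative sampling deficit: wanted %d, drew %d", hist.total, len(drawn)
        )
    negatives = [db[pid] for pid in drawn]
    return PeptideDataset(
        negatives,
        name="negatives",
        metadata={
            "requested": hist.total,
            "drawn": len(drawn),
            "deficit": deficit,
            "per_bin": per_bin,
            "seed": seed,
            "excluded_tags": sorted(policy.excluded_tags),
        },
    )


def assemble_binary_dataset(
    positives: PeptideDataset, negatives: PeptideDataset, name: str = "binary"
) -> PeptideDataset:
    """Combine positives (label 1) and negatives (label 0) into one dataset.

    Negative ids colliding with positive ids are prefixed ``neg_``. When the
    negative set is empty the result is flagged unusable for supervised
    training in its metadata.
    """
    pos_ids = set(positives.ids())
    out: list[Peptide] = [p.with_label(1) for p in positives]
    for p in negatives:
        pid = p.id if p.id not in pos_ids else f"neg_{p.id}"
        out.append(Peptide(pid, p.sequence, label=0, tags=p.tags,
                           description=p.description))
    meta = {
        "n_positives": len(positives),
        "n_negatives": len(negatives),
        "negative_sampling": dict(negatives.metadata),
        "supervised_usable": len(positives) > 0 and len(negatives) > 0,
    }
    return PeptideDataset(out, name=name, metadata=meta)
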