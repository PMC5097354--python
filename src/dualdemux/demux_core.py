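"""Index matching and sequence-read assignment for dual-indexed runs.

Index reads are matched to the expected index set by Hamming distance with a
mismatch budget (bcl2fastq's default is one mismatch per index); sequence
reads are assigned to the nearest expected amplicon reference by banded
Levenshtein distance (substitutions, insertions and deletions, unit cost),
with the band equal to the acceptance cutoff.  Both matchers distinguish
*no match* (``None``) from *ambiguous* (:data:`AMBIGUOUS`, two or more
candidates inside the acceptance radius); neither outcome counts as mapped.

An ``N`` base is treated as a mismatch against every base, including ``N``
(bcl2fastq's behaviour for N in its one-mismatch matching is not documented;
the conservative mismatch semantics is the default and a wildcard flag is
exposed).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .fastq_io import ReadRecord, ReadTriplet, mean_error_prob

__all__ = [
    "AMBIGUOUS",
    "Sample",
    "SampleSheet",
    "ReferenceSet",
    "TripletAssignment",
    "hamming",
    "match_index",
    "banded_edit_distance",
    "assign_sequence",
    "demultiplex",
    "validate_samplesheet",
    "load_samplesheet",
    "load_references",
    "write_samplesheet",
    "write_references",
]

logger = logging.getLogger(__name__)


class _Ambiguous:
    """Singleton marking a read that sits within the acceptance radius of
    two or more candidates and therefore cannot be assigned."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return "AMBIGUOUS"

    def __bool__(self) -> bool:
        return False


AMBIGUOUS = _Ambiguous()


@dataclass(frozen=True)
class Sample:
    """One multiplexed sample: its unique (i5, i7) index pair and the ids of
    its expected amplicon reference sequence(s)."""

    sample_id: str
    i5: str
    i7: str
    reference_ids: tuple[str, ...] = ()


class SampleSheet:
    """The multiplex design: samples with their dual-index pairs.

    Raises on duplicate (i5, i7) pairs or ragged index lengths.  Index sets
    whose minimum pairwise Hamming distance does not exceed twice the
    mismatch budget are legal but fragile; :func:`validate_samplesheet`
    reports them.
    """

    def __init__(self, samples: Sequence[Sample]):
        samples = list(samples)
        if not samples:
            raise ValueError("sample sheet has no samples")
        pairs = [(s.i5, s.i7) for s in samples]
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValueError(f"duplicate (i5, i7) pair in sample sheet: {dup}")
        if len({len(s.i5) for s in samples}) != 1:
            raise ValueError("i5 indices have inconsistent lengths")
        if len({len(s.i7) for s in samples}) != 1:
            raise ValueError("i7 indices have inconsistent lengths")
        self.samples = samples
        self.i5_length = len(samples[0].i5)
        self.i7_length = len(samples[0].i7)
        self.i5_set = sorted({s.i5 for s in samples})
        self.i7_set = sorted({s.i7 for s in samples})
        self._by_pair = {(s.i5, s.i7): s for s in samples}
        self._ref_owner: dict[str, str] = {}
        for s in samples:
            for rid in s.reference_ids:
                if rid in self._ref_owner and self._ref_owner[rid] != s.sample_id:
                    raise ValueError(f"reference {rid!r} claimed by two samples")
                self._ref_owner[rid] = s.sample_id

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample_for_pair(self, i5: str, i7: str) -> Sample | None:
        return self._by_pair.get((i5, i7))

    def sample_of_reference(self, ref_id: str) -> str | None:
        """sample_id owning a reference id, or None if unclaimed."""
        return self._ref_owner.get(ref_id)


class ReferenceSet:
    """Expected amplicon sequences keyed by reference id.

    ``min_pairwise_edit`` is the smallest Levenshtein distance between any
    two references; unambiguous assignment at cutoff ``max_edit`` needs it
    to exceed ``2 * max_edit`` (warned about by :meth:`check_separation`).
    """

    def __init__(self, references: Mapping[str, str]):
        if not references:
            raise ValueError("reference set is empty")
        self.references = dict(references)
        self.min_pairwise_edit = self._min_pairwise_edit()

    def _min_pairwise_edit(self) -> int | None:
        seqs = list(self.references.values())
        if len(seqs) < 2:
            return None
        best = None
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")[
                    "editDistance"
                ]
                best = d if best is None else min(best, d)
        return best

    def check_separation(self, max_edit: int) -> list[str]:
        warnings = []
        if self.min_pairwise_edit is not None and self.min_pairwise_edit <= 2 * max_edit:
            warnings.append(
                f"minimum pairwise reference edit distance "
                f"{self.min_pairwise_edit} <= 2*max_edit={2 * max_edit}; "
                "sequence assignment may be ambiguous"
            )
        return warnings

    def __len__(self) -> int:
        return len(self.references)

    def items(self):
        return self.references.items()


@dataclass(frozen=True)
class TripletAssignment:
    """Outcome of demultiplexing one triplet.

    Each matched field is the matched index sequence / reference id, ``None``
    (nothing within the acceptance radius) or :data:`AMBIGUOUS`.  The three
    fields are filled independently of each other.  The ``*_mean_p`` fields
    are the probability-domain mean error rates of the three read segments.
    """

    matched_i5: object
    matched_i7: object
    matched_ref: object
    seq_mean_p: float
    i5_mean_p: float
    i7_mean_p: float


def hamming(a: str, b: str) -> int:
    """Number of differing positions between equal-length strings.

    ``N`` differs from everything, including ``N``.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def match_index(
    observed: str,
    expected: Iterable[str],
    max_mismatch: int = 1,
    n_wildcard: bool = False,
):
    """Match an observed index read against the expected index set.

    Returns the unique expected index within Hamming distance
    ``max_mismatch`` of the observed bases, ``None`` if there is no such
    index, or :data:`AMBIGUOUS` if two or more qualify.  ``N`` in the
    observed read counts as a mismatch at that position unless
    ``n_wildcard`` is set, in which case it matches any base.
    """
    expected = list(expected)
    if not expected:
        raise ValueError("expected index set is empty")
    hits = []
    for exp in expected:
        if len(exp) != len(observed):
            raise ValueError(
                f"index length mismatch: observed {len(observed)} bp vs "
                f"expected {exp!r} ({len(exp)} bp)"
            )
        if n_wildcard:
            d = sum(1 for x, y in zip(observed, exp) if x != "N" and x != y)
        else:
            d = hamming(observed, exp)
        if d <= max_mismatch:
            hits.append(exp)
    if not hits:
        return None
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def banded_edit_distance(a: str, b: str, band: int) -> int | None:
    """Full-string (global) Levenshtein distance, or None if it exceeds ``band``.

    Unit costs for substitutions, insertions and deletions.  ``N`` is scored
    as a mismatch against every base, including ``N`` on the other side.
    """
    # map N to distinct private symbols so N never matches, not even N vs N
    if "N" in a:
        a = a.replace("N", "\x01")
    if "N" in b:
        b = b.replace("N", "\x02")
    res = edlib.align(a, b, mode="NW", task="distance", k=band)
    d = res["editDistance"]
    return None if d == -1 else d


def assign_sequence(read: ReadRecord | str, refs: ReferenceSet, max_edit: int = 4):
    """Assign a sequence read to the nearest expected reference.

    Full-string Levenshtein distance (band = ``max_edit``) to every
    reference; returns the unique nearest reference id with distance <=
    ``max_edit``, :data:`AMBIGUOUS` on a tie at the minimum, or ``None``
    when every reference is farther than ``max_edit``.
    """
    bases = read.bases if isinstance(read, ReadRecord) else read
    if not bases:
        raise ValueError("empty sequence read")
    best_d: int | None = None
    best_ids: list[str] = []
    for ref_id, ref_seq in refs.items():
        d = banded_edit_distance(bases, ref_seq, max_edit)
        if d is None:
            continue
        if best_d is None or d < best_d:
            best_d, best_ids = d, [ref_id]
        elif d == best_d:
            best_ids.append(ref_id)
    if best_d is None:
        return None
    if len(best_ids) > 1:
        return AMBIGUOUS
    return best_ids[0]


def demultiplex(
    triplet: ReadTriplet,
    sheet: SampleSheet,
    refs: ReferenceSet,
    max_mismatch: int = 1,
    max_edit: int = 4,
    n_wildcard: bool = False,
) -> TripletAssignment:
    """Match all three read segments of a triplet independently.

    No segment's outcome influences another's: the i5 read is matched against
    the full i5 set, the i7 read against the full i7 set, and the sequence
    read against the full reference set.  This is what lets misassigned reads
    surface as unexpected triplets instead of being forced onto a sample.
    """
    return TripletAssignment(
        matched_i5=match_index(triplet.i5.bases, sheet.i5_set, max_mismatch, n_wildcard),
        matched_i7=match_index(triplet.i7.bases, sheet.i7_set, max_mismatch, n_wildcard),
        matched_ref=assign_sequence(triplet.sequence, refs, max_edit),
        seq_mean_p=mean_error_prob(triplet.sequence),
        i5_mean_p=mean_error_prob(triplet.i5),
        i7_mean_p=mean_error_prob(triplet.i7),
    )


def _hamming_matrix(indices: Sequence[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=list(indices), columns=list(indices), dtype=int)
    for a in indices:
        for b in indices:
            mat.loc[a, b] = hamming(a, b) if a != b else 0
    return mat


def validate_samplesheet(
    sheet: SampleSheet, max_mismatch: int = 1
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Check index separation against the mismatch budget.

    Returns (warnings, i5 Hamming matrix, i7 Hamming matrix).  Any pair of
    distinct i5 (or i7) indices at Hamming distance <= 2*max_mismatch can
    collide under worst-case read errors and draws a warning.
    """
    warnings: list[str] = []
    i5_mat = _hamming_matrix(sheet.i5_set)
    i7_mat = _hamming_matrix(sheet.i7_set)
    for name, mat in (("i5", i5_mat), ("i7", i7_mat)):
        idx = list(mat.index)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                d = int(mat.iloc[i, j])
                if d <= 2 * max_mismatch:
                    warnings.append(
                        f"{name} indices {idx[i]} and {idx[j]} are at Hamming "
                        f"distance {d} <= 2*max_mismatch={2 * max_mismatch}"
                    )
    for w in warnings:
        logger.warning("%s", w)
    return warnings, i5_mat, i7_mat


# ---------------------------------------------------------------------------
# Sample-sheet / reference file formats (TSV + FASTA)

_SHEET_COLUMNS = ["sample_id", "i5", "i7", "reference_fasta_id"]


def load_samplesheet(path) -> SampleSheet:
    """Read a TSV/CSV sample sheet with columns sample_id, i5, i7,
    reference_fasta_id (the last may hold comma-separated ids)."""
    with open(path, newline="") as handle:
        sniff = handle.read(4096)
        handle.seek(0)
        delim = "\t" if "\t" in sniff.splitlines()[0] else ","
        reader = csv.DictReader(handle, delimiter=delim)
        missing = [c for c in _SHEET_COLUMNS[:3] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: sample sheet missing columns {missing}")
        samples = []
        for row in reader:
            refs = tuple(
                r.strip()
                for r in (row.get("reference_fasta_id") or "").split(",")
                if r.strip()
            )
            samples.append(
                Sample(
                    sample_id=row["sample_id"].strip(),
                    i5=row["i5"].strip().upper(),
                    i7=row["i7"].strip().upper(),
                    reference_ids=refs,
                )
            )
    return SampleSheet(samples)


def write_samplesheet(sheet: SampleSheet, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_SHEET_COLUMNS)
        for s in sheet:
            writer.writerow([s.sample_id, s.i5, s.i7, ",".join(s.reference_ids)])


def load_references(path) -> ReferenceSet:
    """Read expected amplicon sequences from a FASTA file."""
    refs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceSet(refs)


def write_references(refs: ReferenceSet, path) -> None:
    with open(path, "w") as handle:
        for ref_id, seq in refs.items():
            handle.write(f">{ref_id}\n{seq}\n")
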