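"""Synchronized FASTQ triplet I/O and Phred quality arithmetic.

A dual-indexed single-end Illumina run yields three reads per cluster: the
sequence read (R1) and the two index reads (i7 = I1, i5 = I2).  When
``bcl2fastq`` is run with ``--create-fastq-for-index-reads`` the three FASTQ
files carry the clusters in identical order, so the run can be streamed as a
sequence of triplets.

Quality encoding is fixed to Phred+33 (Sanger / Illumina 1.8+).  Other
offsets are rejected rather than auto-detected: every modern Illumina
deliverable is Phred+33 and a silently mis-detected offset would corrupt
every downstream error probability.

The Phred score Q of a base maps to its error probability p = 10^(-Q/10)
(Q20 = 1 %, Q26 = 0.25 % per-base error).  Averaging over a read is done in
the probability domain by default, matching filters that bound the *maximum
average error rate*; the Phred-equivalent of a mean probability is
-10*log10(mean p).
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "ReadTriplet",
    "FastqSyncError",
    "read_fastq",
    "read_triplets",
    "write_fastq",
    "q_to_error_prob",
    "error_prob_to_q",
    "mean_error_prob",
    "mean_quality",
    "cluster_id",
]

#: Phred+33 ASCII offset; fixed, never auto-detected.
PHRED_OFFSET = 33

#: Highest quality representable in Phred+33 with printable ASCII ('~').
MAX_PHRED = 93


class FastqSyncError(ValueError):
    """The three FASTQ streams of a run are out of step with each other."""


@dataclass(frozen=True)
class ReadRecord:
    """One read: identifier, bases over {A,C,G,T,N}, per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(
                    f"read {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadTriplet:
    """The three reads of one cluster: sequence read plus i5 and i7 index reads."""

    sequence: ReadRecord
    i5: ReadRecord
    i7: ReadRecord

    def __post_init__(self) -> None:
        ids = {cluster_id(r.read_id) for r in (self.sequence, self.i5, self.i7)}
        if len(ids) != 1:
            raise FastqSyncError(
                f"triplet mixes clusters: {sorted(ids)}"
            )


def cluster_id(read_id: str) -> str:
    """Cluster identity of a read id: token before the first whitespace,
    with a trailing ``/1`` or ``/2`` mate suffix stripped."""
    token = read_id.split()[0] if read_id.split() else read_id
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token


def _open_text(path, mode: str = "rt") -> IO[str]:
    # gzip accepted transparently by extension; everything else is plain text
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (optionally gzipped) as ReadRecord objects.

    Malformed records raise ``ValueError`` naming the file; Biopython's
    message carries the offending content.
    """
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield ReadRecord(
                    read_id=rec.description or rec.id,
                    bases=str(rec.seq).upper(),
                    quals=tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ: {exc}") from exc


_SENTINEL = object()


def read_triplets(r1_path, i7_path, i5_path) -> Iterator[ReadTriplet]:
    """Stream the three synchronized FASTQ files of a run as cluster triplets.

    Parameters are the paths of the sequence-read file (R1) and the i7 (I1)
    and i5 (I2) index-read files, in bcl2fastq's cluster order.  A cluster
    identifier mismatch or a length mismatch between files raises
    :class:`FastqSyncError` naming the offending record.
    """
    r1_it, i7_it, i5_it = read_fastq(r1_path), read_fastq(i7_path), read_fastq(i5_path)
    n = 0
    while True:
        seq = next(r1_it, _SENTINEL)
        i7 = next(i7_it, _SENTINEL)
        i5 = next(i5_it, _SENTINEL)
        if seq is _SENTINEL and i7 is _SENTINEL and i5 is _SENTINEL:
            return
        n += 1
        if _SENTINEL in (seq, i7, i5):
            short = [
                name
                for name, rec in (("R1", seq), ("I1/i7", i7), ("I2/i5", i5))
                if rec is _SENTINEL
            ]
            raise FastqSyncError(
                f"FASTQ files desynchronized: {', '.join(short)} ended before "
                f"record {n} of the other file(s)"
            )
        ids = {cluster_id(r.read_id) for r in (seq, i7, i5)}
        if len(ids) != 1:
            raise FastqSyncError(
                f"cluster id mismatch at record {n}: "
                f"R1={cluster_id(seq.read_id)!r} "
                f"i7={cluster_id(i7.read_id)!r} i5={cluster_id(i5.read_id)!r}"
            )
        yield ReadTriplet(sequence=seq, i5=i5, i7=i7)


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write records as 4-line FASTQ (Phred+33; gzip by ``.gz`` extension).

    Returns the number of records written.  Round-trips bit-exactly through
    :func:`read_fastq`.
    """
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            handle.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n


def q_to_error_prob(q: float) -> float:
    """Error probability of a Phred score: p = 10^(-Q/10).  Q must be >= 0."""
    if q < 0:
        raise ValueError(f"negative Phred score: {q}")
    return 10.0 ** (-q / 10.0)


def error_prob_to_q(p: float) -> float:
    """Phred-equivalent of an error probability: Q = -10*log10(p)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1]: {p}")
    return -10.0 * math.log10(p)


def mean_error_prob(record: ReadRecord | Sequence[int]) -> float:
    """Arithmetic mean of per-base error probabilities 10^(-Q/10).

    This is the probability-domain average used for filtering; it is
    invariant to base content and to permutation of the quality string.
    """
    quals = record.quals if isinstance(record, ReadRecord) else record
    if len(quals) == 0:
        raise ValueError("cannot average an empty quality string")
    q = np.asarray(quals, dtype=float)
    return float(np.mean(10.0 ** (-q / 10.0)))


def mean_quality(record: ReadRecord | Sequence[int]) -> float:
    """Plain arithmetic mean of Phred scores (Q-domain averaging).

    Exposed for sensitivity analysis against the default probability-domain
    average; the two differ because the Q->p map is convex.
    """
    quals = record.quals if isinstance(record, ReadRecord) else record
    if len(quals) == 0:
        raise ValueError("cannot average an empty quality string")
    return float(np.mean(quals))
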