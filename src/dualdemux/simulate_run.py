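"""Synthetic multiplexed-run generator with ground truth.

Emulates the statistical structure of a dual-indexed single-end Illumina
amplicon run: by default 14 samples, each with a unique 8-bp i5 and i7
index (pairwise Hamming distance >= 3 within each index set) and a unique
51-cycle amplicon sequence (pairwise edit distance >= 14), so that read
errors alone essentially never move a read between samples.

Misassignment events are injected per read, independent of index distance
(matching the empirical observation that cross-talk is not driven by index
similarity): an index misassignment swaps one index read for a uniformly
chosen other sample's index, a sequence misassignment swaps the sequence
read.  The quality-score coupling mirrors the empirical pattern: a
misassigned index read carries low quality in the swapped step only, while
a sequence misassignment carries low quality in all three steps.  Each read
segment draws a segment-level mean quality (Normal, sd ``q_sd``) around the
high or low regime, adds small per-base jitter, clamps to the Illumina RTA
binning extremes [2, 41], and then substitutes each base to a uniformly
chosen alternative with its own error probability 10^(-Q/10) — so quality
scores are calibrated by construction.

All randomness flows from a single seeded generator: identical
configurations produce byte-identical FASTQ output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demux_core import (
    ReferenceSet,
    Sample,
    SampleSheet,
    banded_edit_distance,
    hamming,
    write_references,
    write_samplesheet,
)
from .fastq_io import _open_text

__all__ = ["SimConfig", "SimOutput", "generate_design", "simulate", "run_simulation"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

LABEL_CORRECT = "CORRECT"
LABEL_I5 = "INDEX_MIS_I5"
LABEL_I7 = "INDEX_MIS_I7"
LABEL_SEQ = "SEQ_MIS"
_LABELS = (LABEL_CORRECT, LABEL_I5, LABEL_I7, LABEL_SEQ)


@dataclass
class SimConfig:
    """Run-simulation parameters.

    Defaults describe the emulated study design: 14 samples, 8-bp dual
    indices, 51-cycle reads, and injected misassignment probabilities of
    the order observed on a real lane (a few reads per thousand).  The
    quality regimes (means on the Phred scale) separate correct segments
    (~Q35) from misassigned ones (~Q15); sd 3 across segments with
    per-base jitter sd 2.
    """

    n_samples: int = 14
    index_length: int = 8
    read_length: int = 51
    reads_per_sample: int = 1000
    p_index_mis_i5: float = 0.0008
    p_index_mis_i7: float = 0.0008
    p_seq_mis: float = 0.0009
    q_high_mean: float = 35.0
    q_low_mean: float = 15.0
    q_sd: float = 3.0
    q_jitter_sd: float = 2.0
    substitution_errors: bool = True
    min_index_hamming: int = 3
    min_ref_edit: int = 14
    seed: int = 0
    gzip_output: bool = False

    def validate(self) -> None:
        probs = (self.p_index_mis_i5, self.p_index_mis_i7, self.p_seq_mis)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"misassignment probabilities outside [0,1]: {probs}")
        if sum(probs) >= 1.0:
            raise ValueError("misassignment probabilities must sum to < 1")
        if self.n_samples < 1 or self.index_length < 1 or self.read_length < 1:
            raise ValueError("n_samples, index_length, read_length must be >= 1")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if self.n_samples > 1 and self.p_seq_mis + max(
            self.p_index_mis_i5, self.p_index_mis_i7
        ) >= 1.0:
            raise ValueError("probabilities inconsistent")


@dataclass
class SimOutput:
    r1_path: Path
    i7_path: Path
    i5_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _random_separated_set(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_dist: int,
    metric: str,
    max_attempts: int,
) -> list[str]:
    """Rejection-sample n sequences pairwise separated by >= min_dist."""
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {n} sequences of length {length} with pairwise "
                f"{metric} distance >= {min_dist} after {max_attempts} attempts"
            )
        attempts += 1
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if metric == "hamming":
            ok = all(hamming(cand, prev) >= min_dist for prev in chosen)
        else:
            ok = all(
                (banded_edit_distance(cand, prev, min_dist - 1) is None)
                for prev in chosen
            )
        if ok:
            chosen.append(cand)
    return chosen


def generate_design(config: SimConfig) -> tuple[SampleSheet, ReferenceSet]:
    """Random multiplex design meeting the separation invariants.

    Deterministic given ``config.seed``.  Raises when the requested
    separation is unattainable (bounded rejection sampling; e.g. more
    samples than distinct indices of the given length can support).
    """
    config.validate()
    if config.n_samples > 4**config.index_length:
        raise RuntimeError(
            f"{config.n_samples} samples cannot have distinct "
            f"{config.index_length}-bp indices"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD5160]))
    attempts = max(10_000, 500 * config.n_samples)
    i5s = _random_separated_set(
        rng, config.n_samples, config.index_length, config.min_index_hamming,
        "hamming", attempts,
    )
    i7s = _random_separated_set(
        rng, config.n_samples, config.index_length, config.min_index_hamming,
        "hamming", attempts,
    )
    ref_seqs = _random_separated_set(
        rng, config.n_samples, config.read_length, config.min_ref_edit,
        "edit", attempts,
    )
    samples = []
    refs = {}
    for i in range(config.n_samples):
        sid = f"s{i + 1:02d}"
        rid = f"ref_{sid}"
        samples.append(Sample(sample_id=sid, i5=i5s[i], i7=i7s[i], reference_ids=(rid,)))
        refs[rid] = ref_seqs[i]
    return SampleSheet(samples), ReferenceSet(refs)


def _encode(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences as a (n, L) array of base codes 0..3."""
    lut = np.full(256, 255, dtype=np.uint8)
    for code, base in enumerate("ACGT"):
        lut[ord(base)] = code
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    return lut[arr]


def _segment(
    rng: np.random.Generator,
    source_codes: np.ndarray,
    low_mask: np.ndarray,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Qualities and (possibly substituted) bases for one read step.

    Returns (bases uint8 codes, quals int arrays), shape (n_reads, length).
    """
    n, length = source_codes.shape
    means = np.where(low_mask, config.q_low_mean, config.q_high_mean)
    seg_mean = rng.normal(means, config.q_sd)
    quals = seg_mean[:, None] + rng.normal(0.0, config.q_jitter_sd, size=(n, length))
    quals = np.clip(np.rint(quals), 2, 41).astype(np.int64)
    bases = source_codes.copy()
    if config.substitution_errors:
        p = 10.0 ** (-quals / 10.0)
        sub = rng.random(size=(n, length)) < p
        shift = rng.integers(1, 4, size=(n, length))
        bases[sub] = (bases[sub] + shift[sub]) % 4
    return bases, quals


def _write_fastq_matrix(path, read_ids, base_codes: np.ndarray, quals: np.ndarray):
    ascii_bases = _BASES[base_codes]
    ascii_quals = (quals + 33).astype(np.uint8)
    with _open_text(path, "wt") as handle:
        for i, rid in enumerate(read_ids):
            handle.write(
                f"@{rid}\n{ascii_bases[i].tobytes().decode()}\n+\n"
                f"{ascii_quals[i].tobytes().decode()}\n"
            )


def simulate(
    config: SimConfig,
    sheet: SampleSheet,
    refs: ReferenceSet,
    outdir,
) -> SimOutput:
    """Emit the three synchronized FASTQ files of a run plus ground truth.

    Per read: a label is drawn from the configured misassignment
    probabilities; the affected read step (if any) is swapped for a
    uniformly chosen other sample's segment and assigned the low-quality
    regime (all three steps for a sequence misassignment); every base is
    then substituted with its own Phred-derived probability.  Ground truth
    records, per read, the originating sample, the injected label and the
    donor sample of the swapped step.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_samples = len(sheet)
    n = n_samples * config.reads_per_sample
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD5]))

    origin = np.repeat(np.arange(n_samples), config.reads_per_sample)
    p_vec = [
        1.0 - (config.p_index_mis_i5 + config.p_index_mis_i7 + config.p_seq_mis),
        config.p_index_mis_i5,
        config.p_index_mis_i7,
        config.p_seq_mis,
    ]
    label_code = rng.choice(4, size=n, p=p_vec)
    if n_samples > 1:
        donor = (origin + rng.integers(1, n_samples, size=n)) % n_samples
    else:
        donor = origin.copy()
        label_code[:] = 0  # no other sample to swap with

    i5_src = np.where(label_code == 1, donor, origin)
    i7_src = np.where(label_code == 2, donor, origin)
    seq_src = np.where(label_code == 3, donor, origin)

    samples = list(sheet)
    i5_codes = _encode([s.i5 for s in samples])[i5_src]
    i7_codes = _encode([s.i7 for s in samples])[i7_src]
    ref_ids = [s.reference_ids[0] for s in samples]
    seq_codes = _encode([refs.references[r] for r in ref_ids])[seq_src]

    seq_low = label_code == 3
    i5_low = (label_code == 1) | seq_low
    i7_low = (label_code == 2) | seq_low

    seq_bases, seq_quals = _segment(rng, seq_codes, seq_low, config)
    i5_bases, i5_quals = _segment(rng, i5_codes, i5_low, config)
    i7_bases, i7_quals = _segment(rng, i7_codes, i7_low, config)

    read_ids = [f"sim-{config.seed}-{i:08d}" for i in range(n)]
    ext = ".fastq.gz" if config.gzip_output else ".fastq"
    r1_path = outdir / f"R1{ext}"
    i7_path = outdir / f"I1{ext}"  # bcl2fastq: I1 carries the i7 index read
    i5_path = outdir / f"I2{ext}"
    _write_fastq_matrix(r1_path, read_ids, seq_bases, seq_quals)
    _write_fastq_matrix(i7_path, read_ids, i7_bases, i7_quals)
    _write_fastq_matrix(i5_path, read_ids, i5_bases, i5_quals)

    sample_ids = np.array([s.sample_id for s in samples])
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "origin_sample": sample_ids[origin],
            "true_label": np.array(_LABELS)[label_code],
            "donor_sample": np.where(
                label_code == 0, "", sample_ids[donor]
            ),
        }
    )
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimOutput(
        r1_path=r1_path,
        i7_path=i7_path,
        i5_path=i5_path,
        truth_path=truth_path,
        truth=truth,
    )


def run_simulation(config: SimConfig, outdir) -> dict:
    """Generate a design, simulate the run, and write everything to ``outdir``.

    Returns a manifest dict of the paths written (also echoed to
    ``config.json`` alongside the configuration used).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet, refs = generate_design(config)
    sheet_path = outdir / "samplesheet.tsv"
    refs_path = outdir / "references.fasta"
    write_samplesheet(sheet, sheet_path)
    write_references(refs, refs_path)
    out = simulate(config, sheet, refs, outdir)
    manifest = {
        "config": asdict(config),
        "samplesheet": str(sheet_path),
        "references": str(refs_path),
        "r1": str(out.r1_path),
        "i7": str(out.i7_path),
        "i5": str(out.i5_path),
        "truth": str(out.truth_path),
    }
    with open(outdir / "config.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return manifest
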