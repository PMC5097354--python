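"""Cross-talk taxonomy, misassignment rates, negative controls and the
independent-substitution model.

A demultiplexed triplet either reproduces an expected (i5, i7, sequence)
combination or is an *unexpected triplet*.  Because every sample here has a
unique i5, a unique i7 and a unique amplicon sequence, an unexpected triplet
can be decomposed by which read step disagrees with the sample implied by
the other steps:

* ``SEQ_MIS`` — the (i5, i7) pair is an expected pair but the sequence read
  belongs to a different sample (sequence misassignment);
* ``INDEX_MIS_I5`` / ``INDEX_MIS_I7`` — the sequence read anchors the read
  to a sample and exactly one index read matches a different sample's index
  (index misassignment);
* ``MULTI_MIS`` — two or more read steps disagree (rare);
* ``CORRECT`` — all three steps agree;
* ``UNASSIGNED`` — some step matched nothing or matched ambiguously; such
  reads are excluded from all rate denominators ("mapped" reads).

With unique dual indexing, every (i5, i7) combination whose two components
each occur in the design but which is assigned to no sample is a built-in
negative control: the number of reads demultiplexed to it, epsilon, is a
direct estimate of misassignment that requires no knowledge of the sample
sequences.

The module also evaluates the null model in which misassignment is caused
purely by independent per-base substitutions of the index read, which
predicts rates decaying geometrically with the Hamming distance between
indices — the signature the observed data fail to show.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .demux_core import (
    AMBIGUOUS,
    ReferenceSet,
    SampleSheet,
    TripletAssignment,
    demultiplex,
    hamming,
)
from .fastq_io import ReadTriplet

__all__ = [
    "Classification",
    "NONE_SENTINEL",
    "AMBIGUOUS_SENTINEL",
    "Rates",
    "CrosstalkReport",
    "TheoreticalModel",
    "classify",
    "classify_run",
    "build_report",
    "compute_rates",
    "enumerate_control_pairs",
    "estimate_epsilon",
    "theoretical_misassignment_rate",
    "rate_vs_distance_table",
    "independent_misread_prob",
    "misread_tail_exact",
]


class Classification(str, Enum):
    """Mutually exclusive, exhaustive labels for one demultiplexed triplet."""

    CORRECT = "CORRECT"
    INDEX_MIS_I5 = "INDEX_MIS_I5"
    INDEX_MIS_I7 = "INDEX_MIS_I7"
    SEQ_MIS = "SEQ_MIS"
    MULTI_MIS = "MULTI_MIS"
    UNASSIGNED = "UNASSIGNED"


#: String stand-ins used in per-read outcome tables for segments that
#: matched nothing / matched ambiguously (kept distinct from any real
#: index sequence or reference id).
NONE_SENTINEL = "<none>"
AMBIGUOUS_SENTINEL = "<ambiguous>"


def _as_token(matched) -> str:
    if matched is None:
        return NONE_SENTINEL
    if matched is AMBIGUOUS:
        return AMBIGUOUS_SENTINEL
    return str(matched)


def classify(assignment: TripletAssignment, sheet: SampleSheet) -> Classification:
    """Place one triplet assignment in the error taxonomy.

    The sequence read is the truth anchor for index misassignments: it is
    unique per sample, so a read whose sequence maps to sample *t* but whose
    i5 read matches another sample's i5 is an i5 misassignment regardless of
    which index pair the read would demultiplex to.
    """
    i5, i7, ref = assignment.matched_i5, assignment.matched_i7, assignment.matched_ref
    if any(x is None or x is AMBIGUOUS for x in (i5, i7, ref)):
        return Classification.UNASSIGNED
    if i5 not in sheet.i5_set:
        raise ValueError(f"matched i5 {i5!r} not in sample sheet")
    if i7 not in sheet.i7_set:
        raise ValueError(f"matched i7 {i7!r} not in sample sheet")
    owner_id = sheet.sample_of_reference(ref)
    if owner_id is None:
        raise ValueError(f"matched reference {ref!r} not claimed by any sample")
    pair_sample = sheet.sample_for_pair(i5, i7)
    if pair_sample is not None:
        if pair_sample.sample_id == owner_id:
            return Classification.CORRECT
        return Classification.SEQ_MIS
    # unexpected index pair: anchor on the sequence read's sample
    anchor = next(s for s in sheet if s.sample_id == owner_id)
    i5_wrong = i5 != anchor.i5
    i7_wrong = i7 != anchor.i7
    if i5_wrong and i7_wrong:
        return Classification.MULTI_MIS
    if i5_wrong:
        return Classification.INDEX_MIS_I5
    return Classification.INDEX_MIS_I7


def classify_run(
    triplets: Iterable[ReadTriplet],
    sheet: SampleSheet,
    refs: ReferenceSet,
    max_mismatch: int = 1,
    max_edit: int = 4,
    n_wildcard: bool = False,
) -> pd.DataFrame:
    """Demultiplex and classify a stream of triplets.

    Returns one row per read with columns ``label, i5, i7, ref,
    seq_mean_p, i5_mean_p, i7_mean_p``; unmatched/ambiguous segments carry
    the sentinels :data:`NONE_SENTINEL` / :data:`AMBIGUOUS_SENTINEL`.  This
    single pass is the input shared by report building and threshold sweeps.
    """
    rows = []
    for trip in triplets:
        a = demultiplex(trip, sheet, refs, max_mismatch, max_edit, n_wildcard)
        rows.append(
            (
                classify(a, sheet).value,
                _as_token(a.matched_i5),
                _as_token(a.matched_i7),
                _as_token(a.matched_ref),
                a.seq_mean_p,
                a.i5_mean_p,
                a.i7_mean_p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["label", "i5", "i7", "ref", "seq_mean_p", "i5_mean_p", "i7_mean_p"],
    )


@dataclass
class Rates:
    """Pooled misassignment rates; a ``None`` rate had a zero denominator
    and is undefined (never silently reported as 0)."""

    seq_mis_rate: float | None
    index_mis_rate: float | None
    overall_incorrect_rate: float | None

    @property
    def undefined(self) -> set[str]:
        return {
            name
            for name in ("seq_mis_rate", "index_mis_rate", "overall_incorrect_rate")
            if getattr(self, name) is None
        }


def compute_rates(counts: Mapping) -> Rates:
    """Pooled rates from classification counts.

    * sequence misassignment rate: reads with an expected index pair that
      mapped to the wrong sequence, over all mapped reads with expected
      pairs (CORRECT + SEQ_MIS);
    * index misassignment rate: reads mapped to a known sequence whose
      triplet differs by a single i5 or i7 index, over all mapped reads;
    * overall incorrect rate: every misassigned read over all mapped reads.

    "Mapped" excludes UNASSIGNED.
    """
    c = {Classification(k): int(v) for k, v in counts.items()}
    correct = c.get(Classification.CORRECT, 0)
    seq = c.get(Classification.SEQ_MIS, 0)
    i5 = c.get(Classification.INDEX_MIS_I5, 0)
    i7 = c.get(Classification.INDEX_MIS_I7, 0)
    multi = c.get(Classification.MULTI_MIS, 0)
    mapped = correct + seq + i5 + i7 + multi
    pair_mapped = correct + seq
    return Rates(
        seq_mis_rate=seq / pair_mapped if pair_mapped else None,
        index_mis_rate=(i5 + i7) / mapped if mapped else None,
        overall_incorrect_rate=(seq + i5 + i7 + multi) / mapped if mapped else None,
    )


def enumerate_control_pairs(sheet: SampleSheet) -> list[tuple[str, str]]:
    """All (i5, i7) combinations whose components each occur in the design
    but which are assigned to no sample — the built-in negative controls.

    A fully unique dual-indexed design of n samples yields n*n - n controls.
    """
    return [
        (i5, i7)
        for i5 in sheet.i5_set
        for i7 in sheet.i7_set
        if sheet.sample_for_pair(i5, i7) is None
    ]


def estimate_epsilon(
    triplet_counts: Mapping[tuple[str, str, str], int],
    control_pairs: Sequence[tuple[str, str]],
) -> tuple[dict[tuple[str, str], int], int]:
    """Misassignment estimate per negative-control pair.

    epsilon(pair) is the number of reads whose matched (i5, i7) equals that
    unused pair, whatever their sequence read did.  Returns the per-pair map
    and its sum, the sweep's misassignment signal.
    """
    eps = {pair: 0 for pair in control_pairs}
    for (i5, i7, _ref), n in triplet_counts.items():
        if (i5, i7) in eps:
            eps[(i5, i7)] += int(n)
    return eps, sum(eps.values())


@dataclass
class CrosstalkReport:
    """Full accounting of one run's cross-talk.

    ``triplet_counts`` maps each observed (matched i5, matched i7, matched
    reference) combination — sentinels included — to its read count;
    ``label_counts`` always sums to ``total_reads``.
    """

    total_reads: int
    label_counts: dict[str, int]
    triplet_counts: dict[tuple[str, str, str], int]
    rates: Rates
    control_pairs: list[tuple[str, str]]
    control_estimates: dict[tuple[str, str], int]
    epsilon_sum: int
    per_sample: pd.DataFrame = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "label_counts": dict(self.label_counts),
            "rates": {
                "seq_mis_rate": self.rates.seq_mis_rate,
                "index_mis_rate": self.rates.index_mis_rate,
                "overall_incorrect_rate": self.rates.overall_incorrect_rate,
                "undefined": sorted(self.rates.undefined),
            },
            "n_control_pairs": len(self.control_pairs),
            "epsilon_sum": self.epsilon_sum,
            "control_estimates": [
                {"i5": i5, "i7": i7, "epsilon": eps}
                for (i5, i7), eps in sorted(self.control_estimates.items())
            ],
            "per_sample": self.per_sample.to_dict(orient="records"),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_json_dict(), handle, indent=2)

    def write_triplet_tsv(self, path) -> None:
        """One row per observed (i5, i7, ref) triplet with count and label."""
        rows = []
        for (i5, i7, ref), n in sorted(
            self.triplet_counts.items(), key=lambda kv: -kv[1]
        ):
            rows.append((i5, i7, ref, n))
        pd.DataFrame(rows, columns=["i5", "i7", "ref", "count"]).to_csv(
            path, sep="\t", index=False
        )


def _per_sample_table(outcomes: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-sample counts and rates; the pooled values stay the headline."""
    ref_owner = {rid: s.sample_id for s in sheet for rid in s.reference_ids}
    rows = []
    for s in sheet:
        on_pair = outcomes[(outcomes["i5"] == s.i5) & (outcomes["i7"] == s.i7)]
        pair_labels = Counter(on_pair["label"])
        anchored = outcomes[
            outcomes["ref"].map(lambda r: ref_owner.get(r)) == s.sample_id
        ]
        anchor_labels = Counter(anchored["label"])
        correct = pair_labels[Classification.CORRECT.value]
        seq_mis = pair_labels[Classification.SEQ_MIS.value]
        idx_mis = (
            anchor_labels[Classification.INDEX_MIS_I5.value]
            + anchor_labels[Classification.INDEX_MIS_I7.value]
        )
        mapped_anchor = sum(
            anchor_labels[l.value]
            for l in Classification
            if l is not Classification.UNASSIGNED
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "correct": correct,
                "seq_mis": seq_mis,
                "index_mis": idx_mis,
                "seq_mis_rate": seq_mis / (correct + seq_mis)
                if (correct + seq_mis)
                else np.nan,
                "index_mis_rate": idx_mis / mapped_anchor if mapped_anchor else np.nan,
            }
        )
    return pd.DataFrame(rows)


def build_report(outcomes: pd.DataFrame, sheet: SampleSheet) -> CrosstalkReport:
    """Aggregate per-read outcomes into a :class:`CrosstalkReport`."""
    label_counts = Counter(outcomes["label"])
    triplet_counts = (
        outcomes.groupby(["i5", "i7", "ref"], sort=False).size().to_dict()
        if len(outcomes)
        else {}
    )
    triplet_counts = {k: int(v) for k, v in triplet_counts.items()}
    control_pairs = enumerate_control_pairs(sheet)
    control_estimates, epsilon_sum = estimate_epsilon(triplet_counts, control_pairs)
    report = CrosstalkReport(
        total_reads=int(len(outcomes)),
        label_counts={l.value: int(label_counts.get(l.value, 0)) for l in Classification},
        triplet_counts=triplet_counts,
        rates=compute_rates(
            {l.value: label_counts.get(l.value, 0) for l in Classification}
        ),
        control_pairs=control_pairs,
        control_estimates=control_estimates,
        epsilon_sum=int(epsilon_sum),
        per_sample=_per_sample_table(outcomes, sheet),
    )
    assert sum(report.label_counts.values()) == report.total_reads
    return report


# ---------------------------------------------------------------------------
# Independent-substitution null model

@dataclass(frozen=True)
class TheoreticalModel:
    """Null model for index misassignment by misread bases alone.

    Each of the L index positions is substituted independently with
    probability ``p``, uniformly to one of the 3 alternative bases; the
    matcher accepts an index within ``k`` mismatches (uniquely, mirroring
    the demultiplexer's rule).
    """

    p: float
    L: int
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"substitution probability outside [0,1]: {self.p}")
        if self.L < 1:
            raise ValueError("index length must be >= 1")
        if self.k < 0:
            raise ValueError("mismatch budget must be >= 0")


def theoretical_misassignment_rate(
    model: TheoreticalModel, d: int, condition_on_true_reject: bool = True
) -> float:
    """Probability that an index transmitted as A is matched to a specific
    wrong index B at Hamming distance ``d``.

    Decompose the L positions into the d where A and B differ and the L-d
    where they agree.  A differing position is read as B's base with
    probability p/3 ("repaired"), stays A's base with probability 1-p, or
    becomes a third base with probability 2p/3.  An agreeing position is
    misread (away from both) with probability p.  Summing the multinomial
    terms whose resulting distance to B is <= k — and, by default, whose
    distance to A exceeds k, so A's own match cannot pre-empt B under the
    unique-within-k acceptance rule — gives the closed form.

    ``d = 0`` means B is A itself and the function returns the self-match
    probability P(at most k misreads).
    """
    p, L, k = model.p, model.L, model.k
    if not 0 <= d <= L:
        raise ValueError(f"Hamming distance {d} outside [0, {L}]")
    if d == 0:
        return float(sum(comb(L, e) * p**e * (1 - p) ** (L - e) for e in range(k + 1)))
    total = 0.0
    n_agree = L - d
    for j in range(d + 1):  # differing positions repaired to B's base
        for m in range(d - j + 1):  # differing positions left as A's base
            third = d - j - m  # differing positions turned into a third base
            for e in range(n_agree + 1):  # misread agreeing positions
                dist_b = (d - j) + e
                if dist_b > k:
                    continue
                dist_a = (d - m) + e
                if condition_on_true_reject and dist_a <= k:
                    continue
                total += (
                    comb(d, j)
                    * comb(d - j, m)
                    * (p / 3.0) ** j
                    * (1 - p) ** m
                    * (2.0 * p / 3.0) ** third
                    * comb(n_agree, e)
                    * p**e
                    * (1 - p) ** (n_agree - e)
                )
    return float(total)


def rate_vs_distance_table(
    model: TheoreticalModel, sheet: SampleSheet, observed: CrosstalkReport
) -> pd.DataFrame:
    """Observed vs model-predicted index-misassignment rate by Hamming distance.

    For every ordered (sample, wrong index) combination in the design —
    i5 and i7 alike — the observed rate is the fraction of that sample's
    mapped, sequence-anchored reads that carried the wrong index with the
    other index correct; rates are averaged within each Hamming distance.
    Under the independent-substitution null the column would decay
    geometrically with distance; distance-independent swaps make it flat.
    """
    ref_owner = {rid: s.sample_id for s in sheet for rid in s.reference_ids}
    # sequence-anchored mapped read count and per-wrong-index event counts
    mapped: Counter = Counter()
    events_i5: Counter = Counter()
    events_i7: Counter = Counter()
    for (i5, i7, ref), n in observed.triplet_counts.items():
        owner = ref_owner.get(ref)
        if owner is None or i5 not in sheet.i5_set or i7 not in sheet.i7_set:
            continue
        mapped[owner] += n
        s = next(x for x in sheet if x.sample_id == owner)
        if i7 == s.i7 and i5 != s.i5:
            events_i5[(owner, i5)] += n
        if i5 == s.i5 and i7 != s.i7:
            events_i7[(owner, i7)] += n
    per_distance: dict[int, list[float]] = {}
    for s in sheet:
        if not mapped[s.sample_id]:
            continue
        for wrong in sheet.i5_set:
            if wrong == s.i5:
                continue
            d = hamming(s.i5, wrong)
            rate = events_i5[(s.sample_id, wrong)] / mapped[s.sample_id]
            per_distance.setdefault(d, []).append(rate)
        for wrong in sheet.i7_set:
            if wrong == s.i7:
                continue
            d = hamming(s.i7, wrong)
            rate = events_i7[(s.sample_id, wrong)] / mapped[s.sample_id]
            per_distance.setdefault(d, []).append(rate)
    rows = [
        {
            "distance": d,
            "n_pairs": len(rates),
            "observed_rate": float(np.mean(rates)),
            "theoretical_rate": theoretical_misassignment_rate(model, d),
        }
        for d, rates in sorted(per_distance.items())
    ]
    return pd.DataFrame(rows, columns=["distance", "n_pairs", "observed_rate", "theoretical_rate"])


# ---------------------------------------------------------------------------
# Back-of-envelope misread probabilities

def independent_misread_prob(p: float, n_misreads: int) -> float:
    """Leading-order probability of ``n_misreads`` independent misreads: p**n.

    At p = 0.01 (Q20) three misreads give 1e-6 and six (both 8-bp indices
    crossing over) give 1e-12.  The combinatorial prefactor C(L, n) is
    dropped — this is the order-of-magnitude form, not the exact tail
    (see :func:`misread_tail_exact`).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0,1]")
    return p**n_misreads


def misread_tail_exact(length: int, p: float, min_misreads: int) -> float:
    """Exact binomial tail P(#misreads >= min_misreads) over ``length`` bases."""
    return float(binom.sf(min_misreads - 1, length, p))
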