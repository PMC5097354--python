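"""Quality filtering of triplets and threshold optimization.

Misassigned reads carry low quality scores in the read step that was
misassigned, so filtering on the *index* reads removes index misassignments
that sequence-read filtering cannot touch.  Three strategies are compared:
filter only the sequence read, only the two index reads, or all three.

Thresholds are expressed on the Phred-equivalent scale: a read segment
passes threshold Q when its mean error probability is at most 10^(-Q/10)
(boundary inclusive, so "average quality >= Q" passes).  The sweep
classifies the run once and re-applies every threshold to the stored
per-segment mean error probabilities, and tracks the negative-control
signal epsilon at each threshold so Q_thresh can be chosen without knowing
the sample sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crosstalk_stats import (
    Classification,
    classify_run,
    enumerate_control_pairs,
)
from .demux_core import ReferenceSet, SampleSheet
from .fastq_io import ReadTriplet, mean_error_prob, mean_quality, q_to_error_prob

__all__ = [
    "FilterStrategy",
    "SweepCurve",
    "passes_filter",
    "sweep",
    "sweep_outcomes",
    "choose_threshold",
    "plot_sweep",
    "DEFAULT_Q_GRID",
]

#: Default threshold grid: integer Phred 0..40.
DEFAULT_Q_GRID = tuple(range(0, 41))

_MIS_LABELS = [
    Classification.SEQ_MIS.value,
    Classification.INDEX_MIS_I5.value,
    Classification.INDEX_MIS_I7.value,
    Classification.MULTI_MIS.value,
]


class FilterStrategy(str, Enum):
    SEQUENCE_ONLY = "sequence"
    INDEX_ONLY = "index"
    ALL_READS = "all"

    @property
    def segments(self) -> tuple[str, ...]:
        if self is FilterStrategy.SEQUENCE_ONLY:
            return ("seq",)
        if self is FilterStrategy.INDEX_ONLY:
            return ("i5", "i7")
        return ("seq", "i5", "i7")


def passes_filter(
    triplet: ReadTriplet,
    strategy: FilterStrategy,
    q_thresh: float,
    q_domain: bool = False,
) -> bool:
    """True iff every read segment selected by the strategy meets Q >= q_thresh.

    INDEX_ONLY requires *both* i5 and i7 to pass; ALL_READS all three.  By
    default the comparison is in the probability domain (mean error
    probability <= 10^(-q_thresh/10)); ``q_domain=True`` instead compares
    the arithmetic mean of the Phred scores, for sensitivity analysis.
    """
    if q_thresh < 0:
        raise ValueError("q_thresh must be >= 0")
    segs = {
        "seq": triplet.sequence,
        "i5": triplet.i5,
        "i7": triplet.i7,
    }
    if q_domain:
        return all(mean_quality(segs[s]) >= q_thresh for s in strategy.segments)
    p_max = q_to_error_prob(q_thresh)
    return all(mean_error_prob(segs[s]) <= p_max for s in strategy.segments)


@dataclass
class SweepCurve:
    """Threshold-sweep result for one strategy.

    ``table`` has one row per threshold: reads retained (count and
    fraction), remaining reads per classification label, remaining
    misassigned total, and the negative-control signal ``epsilon_sum``.
    """

    strategy: FilterStrategy
    table: pd.DataFrame

    def row(self, q_thresh: float) -> pd.Series:
        match = self.table[self.table["q_thresh"] == q_thresh]
        if match.empty:
            raise KeyError(f"threshold {q_thresh} not in sweep grid")
        return match.iloc[0]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _segment_columns(strategy: FilterStrategy) -> list[str]:
    return [f"{s}_mean_p" for s in strategy.segments]


def sweep_outcomes(
    outcomes: pd.DataFrame,
    sheet: SampleSheet,
    strategy: FilterStrategy,
    thresholds: Sequence[float] = DEFAULT_Q_GRID,
) -> SweepCurve:
    """Apply every threshold to an already-classified run.

    ``outcomes`` is the per-read table from
    :func:`~dualdemux.crosstalk_stats.classify_run`; classification is not
    repeated.  Thresholds must be sorted ascending and non-empty.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list is empty")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    n = len(outcomes)
    seg_p = outcomes[_segment_columns(strategy)].to_numpy(dtype=float)
    labels = outcomes["label"].to_numpy()
    controls = set(enumerate_control_pairs(sheet))
    is_control = np.array(
        [(i5, i7) in controls for i5, i7 in zip(outcomes["i5"], outcomes["i7"])],
        dtype=bool,
    ) if n else np.zeros(0, dtype=bool)
    rows = []
    for q in thresholds:
        p_max = q_to_error_prob(q)
        keep = (seg_p <= p_max).all(axis=1) if n else np.zeros(0, dtype=bool)
        label_remaining = {
            l.value: int(np.sum(keep & (labels == l.value))) for l in Classification
        }
        row = {
            "q_thresh": q,
            "reads_retained": int(keep.sum()),
            "fraction_retained": float(keep.sum() / n) if n else float("nan"),
            **{f"remaining_{k}": v for k, v in label_remaining.items()},
            "misassigned_remaining": sum(label_remaining[l] for l in _MIS_LABELS),
            "epsilon_sum": int(np.sum(keep & is_control)),
        }
        rows.append(row)
    return SweepCurve(strategy=strategy, table=pd.DataFrame(rows))


def sweep(
    triplets: Iterable[ReadTriplet],
    sheet: SampleSheet,
    refs: ReferenceSet,
    strategy: FilterStrategy,
    thresholds: Sequence[float] = DEFAULT_Q_GRID,
    max_mismatch: int = 1,
    max_edit: int = 4,
) -> SweepCurve:
    """Classify a run once, then evaluate every threshold for a strategy."""
    outcomes = classify_run(triplets, sheet, refs, max_mismatch, max_edit)
    return sweep_outcomes(outcomes, sheet, strategy, thresholds)


def choose_threshold(curve: SweepCurve, max_epsilon_fraction: float) -> float:
    """Pick Q_thresh from a sweep: the smallest threshold whose remaining
    epsilon is at most ``max_epsilon_fraction`` of the unfiltered epsilon.

    If no threshold attains the target, returns the epsilon-minimizing
    threshold, ties broken toward more retained reads (then the smaller
    threshold).  If the run has no control signal at all (epsilon already
    zero unfiltered), the smallest threshold wins: there is nothing to
    remove.
    """
    table = curve.table
    if table.empty:
        raise ValueError("empty sweep curve")
    eps0 = int(table.iloc[0]["epsilon_sum"])
    if eps0 == 0:
        return float(table.iloc[0]["q_thresh"])
    frac = table["epsilon_sum"] / eps0
    attaining = table[frac <= max_epsilon_fraction]
    if not attaining.empty:
        return float(attaining.iloc[0]["q_thresh"])
    min_eps = table["epsilon_sum"].min()
    candidates = table[table["epsilon_sum"] == min_eps]
    best = candidates.sort_values(
        ["reads_retained", "q_thresh"], ascending=[False, True]
    ).iloc[0]
    return float(best["q_thresh"])


def plot_sweep(curves: Sequence[SweepCurve], path) -> None:
    """Trade-off plot: misassignment signal vs reads remaining, one line
    per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(
            curve.table["reads_retained"],
            curve.table["epsilon_sum"],
            marker="o",
            markersize=3,
            label=curve.strategy.name,
        )
    ax.set_xlabel("reads remaining")
    ax.set_ylabel("control-pair misassignments remaining (sum of epsilon)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
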