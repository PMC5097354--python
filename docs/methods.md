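# Methods

## The error mode

A dual-indexed Illumina cluster produces three reads — the sequence read
and the i5 and i7 index reads — and de-multiplexing trusts the index pair.
Cross-talk arises when one read step of a cluster reports another sample's
content: a single foreign index read (index misassignment), or a foreign
sequence read under a correct, expected index pair (sequence
misassignment). Because the three steps are read in separate sequencing
reactions, the package treats each step's assignment as an independent
measurement and classifies the triplet afterwards, rather than forcing
every cluster onto a sample during demultiplexing.

## Demultiplexing model

**Index matching.** An observed index read matches an expected index when
their Hamming distance is at most `max_mismatch` (default 1, the
de-facto standard for on-instrument demultiplexing). If two or more
expected indices qualify the read is *ambiguous*; if none qualifies it is
*unmatched*. Both outcomes are excluded from "mapped" reads and from every
rate denominator. `N` counts as a mismatch against every base including
`N` — the conservative choice, since `N` asserts no evidence; a wildcard
interpretation is available via `n_wildcard=True`.

**Sequence assignment.** The sequence read is assigned to the nearest
expected amplicon by full-string Levenshtein distance (unit-cost
substitutions, insertions, deletions), accepted within `max_edit`
(default 4) and computed banded at the cutoff (edlib). Full-string rather
than semi-global alignment is used because reads and references have the
same cycle count; length differences are genuine indel evidence and are
charged. Ties at the minimum distance are ambiguous. Unambiguous
assignment requires the reference set's minimum pairwise distance to
exceed `2 * max_edit`; the design validator warns otherwise (the same
`2 * max_mismatch` rule is applied to each index set).

**Classification.** With all three steps matched:

* expected (i5, i7) pair + that sample's sequence → `CORRECT`;
* expected pair + another sample's sequence → `SEQ_MIS` (this includes the
  case where the pair and the sequence each belong to complete, different
  samples: from the pair's point of view the sequence is foreign);
* unexpected pair: the sequence read — unique per sample — anchors the
  read's origin, and whichever single index disagrees with the anchor
  gives `INDEX_MIS_I5` or `INDEX_MIS_I7`; two disagreeing steps give
  `MULTI_MIS`.

Any unmatched or ambiguous step → `UNASSIGNED`. The labels are exhaustive
and mutually exclusive; counts always sum to the number of input reads.

**Rates.** The sequence-misassignment rate is `SEQ_MIS / (CORRECT +
SEQ_MIS)` (reads with expected pairs that mapped to the wrong sequence,
over mapped reads with expected pairs); the index-misassignment rate is
`(INDEX_MIS_I5 + INDEX_MIS_I7) / mapped`; the overall incorrect rate
counts every misassigned label over mapped reads. A zero denominator
yields an explicitly undefined rate (`None`), never a silent 0. Rates are
also reported per sample, but pooled values are the headline numbers —
per-sample denominators are small enough that single events move them.

## Negative controls and ε

Under unique dual indexing an n-sample design leaves n² − n index pairs
whose components both occur in the run but which belong to no sample.
Reads whose matched pair is such a control pair cannot be legitimate;
their count ε(pair) — and the sum over all control pairs — estimates the
misassignment burden without requiring knowledge of any sample's
sequence, and can be recomputed under any quality filter. ε counts reads
whose *indices* both matched uniquely, whatever the sequence read did.

## Quality filtering

Phred score Q maps to error probability p = 10^(−Q/10). A read segment
passes threshold Q when its **mean error probability** is ≤ 10^(−Q/10),
boundary inclusive, so a segment uniformly at Q26 passes a ≥ 26 filter
exactly. Averaging is done over probabilities, not over Q values: the mean
error probability is what bounds the expected number of wrong bases, and
the probability-domain mean is dominated by the low-quality tail, which is
precisely the signal that distinguishes misassigned reads. Q-domain
averaging (`mean_quality`, `passes_filter(..., q_domain=True)`) is exposed
for sensitivity analysis; by Jensen's inequality it is always the more
permissive of the two.

Three strategies are compared: filter the sequence read only, both index
reads (each must pass), or all three. The sweep classifies the run once,
stores per-segment mean error probabilities, and re-applies each threshold
of the grid (default integer Q = 0..40) as a vector comparison — identical
results to filtering before demultiplexing, at one pass.

`choose_threshold` picks the smallest Q whose remaining ε is at most a
target fraction (default 10 %) of the unfiltered ε; if the target is
unattainable it falls back to the ε-minimizing threshold, ties broken
toward more retained reads, then toward the smaller threshold. If the run
shows no control signal at all, the smallest threshold in the grid is
returned — there is nothing to remove.

## The independent-substitution null model

If misassignments were caused by misread index bases, the probability that
an index transmitted as A is accepted as a specific wrong index B at
Hamming distance d follows from independent per-base substitution
(probability p, uniform over the 3 alternative bases). Splitting positions
into the d where A and B differ (read as B's base with probability p/3,
kept as A's with 1 − p, turned into a third base with 2p/3) and the L − d
where they agree (misread with probability p), the closed form sums the
multinomial terms whose distance to B is ≤ k. By default the term is also
required to have distance to A **greater than** k, mirroring the
unique-match acceptance rule (A present in the expected set would
otherwise make the read ambiguous, not misassigned); the unconditioned
variant is available via `condition_on_true_reject=False`. At d = 0 the
function returns the self-match probability P(≤ k misreads). The
implementation is verified against exhaustive enumeration over all 4^L
corrupted reads for L ≤ 6 to 1e-12.

This null model decays geometrically in d; plotting observed
misassignment rates by index Hamming distance against it
(`rate_vs_distance_table`) is the diagnostic that rules substitution
errors out: injected, distance-independent swaps produce a flat observed
column where the model predicts orders of magnitude of decay.

Two order-of-magnitude companions: `independent_misread_prob(p, n)` is the
leading-order p^n figure for n simultaneous misreads (1e-6 for a triple
misread at p = 0.01, 1e-12 for both indices crossing over);
`misread_tail_exact` keeps the binomial coefficient and is accordingly
larger (5.4e-5 for ≥ 3 misreads in an 8-bp index at p = 0.01, and
≈ 1.3e-21 for ≥ 17 substitutions within 51 bases at p = 0.01). Where an
order-of-magnitude argument is quoted, it is the leading-order form; the
exact tails are what the package computes.

## The simulator

`simulate_run` emulates the statistical structure the analysis relies on,
not the physics of a flow cell:

* a design of `n_samples` (default 14) with unique 8-bp i5 and i7 indices,
  rejection-sampled to pairwise Hamming distance ≥ 3 within each index
  set, and unique 51-base amplicons at pairwise edit distance ≥ 14 — so
  read errors essentially never move a read between samples on their own;
* per-read misassignment labels drawn independently of index distance
  (defaults `p_index_mis_i5 = p_index_mis_i7 = 0.0008`,
  `p_seq_mis = 0.0009`, the magnitude of a real lane's cross-talk), with
  the swapped segment taken from a uniformly chosen other sample;
* quality coupling: correct segments draw a segment-level mean quality
  ~ Normal(35, 3), misassigned index reads draw the low regime
  ~ Normal(15, 3) in the swapped step only, and sequence misassignments
  draw the low regime in all three steps; per-base jitter sd 2, clamped to
  the RTA binning extremes [2, 41]. The flat low-quality profile (rather
  than a position-dependent one) reflects misassigned reads being
  low-quality along their whole length;
* calibrated substitutions: each base is then substituted to a uniform
  alternative with its own probability 10^(−Q/10)
  (`substitution_errors=False` disables this for exact-zero baselines).

All randomness flows from one seeded generator; the same configuration is
byte-identical across runs. The simulator does **not** model position
dependent error profiles, indels in reads, adapter or PhiX contamination,
cluster-overlap mechanics, or miscalibrated quality scores. Passing tests
therefore demonstrate that the pipeline's inference is correct when
quality scores mean what they claim and misassignment follows the
swap-with-low-quality structure — they do not certify any particular real
lane, which is exactly why the control-pair ε and per-run threshold
optimization exist.

## Problem sizes and numerical choices

Integration tests and the acceptance script run a 14-sample lane of
~100,000 reads (7,143 reads per sample), where each injected misassignment
mode produces ~80–90 events — enough for 3-standard-error recovery checks
while a full run completes in well under a minute. Rate recovery is
binomial: |recovered − np| ≤ 3·sqrt(np(1−p)). A few injected events whose
low-quality segment corrupts its own match become `UNASSIGNED` rather than
misassigned; this loss (~2–5 % of events) is part of what any real
classifier would see and stays inside the binomial band.

Determinism: demultiplexing and classification are pure functions of
their input; sweeps reuse the stored classification, so `classify` and
`sweep` are bit-reproducible and `simulate` is byte-identical under a
fixed seed.

## Known limitations

* The classifier needs per-sample unique sequences to anchor index
  misassignments; designs where samples share an amplicon can still use
  ε from control pairs but cannot attribute index misassignments.
* Chastity ("pass filter") screening is assumed already applied upstream;
  the package neither reimplements it nor handles raw BCL data.
* Quality offsets other than Phred+33 are rejected, not auto-detected.
* Single-end runs only; a mate read (R2) is out of scope.
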