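# dualdemux

Quantify and mitigate **sample cross-talk** in dual-indexed Illumina
sequencing runs.

When many samples are multiplexed on one lane, each cluster yields a
*triplet* of reads — the sequence read plus the i5 and i7 index reads — and
de-multiplexing assigns the cluster to the sample whose (i5, i7) pair the
index reads match. A small fraction of reads end up with an *unexpected*
triplet: a correct sequence but one foreign index (**index misassignment**),
or a correct, expected index pair carrying another sample's sequence
(**sequence misassignment**). These misassignments leak reads between
samples at rates around one per thousand — far above what independent
per-base misreads can explain — which is fatal for rare-variant detection
and grows with the number of multiplexed samples.

`dualdemux` implements the full analysis around this error mode:

- **Triplet demultiplexing** — index reads matched by Hamming distance with
  a mismatch budget (default 1, bcl2fastq-compatible); sequence reads
  assigned to the nearest expected amplicon by banded Levenshtein distance
  (default cutoff 4, substitutions + indels). Each of the three read steps
  is matched independently, so misassigned reads surface instead of being
  forced onto a sample.
- **Cross-talk classification and rates** — every read labelled
  `CORRECT / INDEX_MIS_I5 / INDEX_MIS_I7 / SEQ_MIS / MULTI_MIS /
  UNASSIGNED`; pooled and per-sample misassignment rates over mapped reads.
- **Negative controls without extra samples** — under unique dual indexing,
  every (i5, i7) combination whose parts exist in the run but which belongs
  to no sample is a built-in control: the count of reads landing on it,
  ε, estimates misassignment with no knowledge of the sample sequences
  (an n-sample design has n² − n such pairs).
- **Index-read quality filtering** — misassigned reads carry low Phred
  quality in the misassigned step, so filtering on the *index* reads
  (mean error probability ≤ 10^(−Q/10), i.e. average quality ≥ Q) removes
  them while sequence-read filtering cannot; a threshold sweep over
  Q = 0..40 tracks ε and retention so Q_thresh can be optimized per run.
- **The substitution null model** — the closed-form probability that
  independent per-base misreads (rate p, uniform across the 3 alternative
  bases) convert one index into another at Hamming distance d, verified
  against exhaustive enumeration; its geometric decay with d is the
  signature that real misassignment data do not show.
- **A run simulator** — generates the three synchronized FASTQ files plus
  ground truth for a lane with configurable injected misassignment rates
  and quality coupling, so the whole pipeline is testable end to end.

## Worked example

```python
import tempfile
from dualdemux import (SimConfig, generate_design, simulate, read_triplets,
                       classify_run, build_report, sweep_outcomes,
                       choose_threshold, FilterStrategy)

config = SimConfig(reads_per_sample=2000, seed=7)   # 14 samples, 28,000 reads
sheet, refs = generate_design(config)
with tempfile.TemporaryDirectory() as td:
    run = simulate(config, sheet, refs, td)
    outcomes = classify_run(read_triplets(run.r1_path, run.i7_path, run.i5_path),
                            sheet, refs)
report = build_report(outcomes, sheet)
print(report.label_counts)
r = report.rates
print(f"seq {100*r.seq_mis_rate:.3f}%  index {100*r.index_mis_rate:.3f}%  "
      f"overall {100*r.overall_incorrect_rate:.3f}%")
print(len(report.control_pairs), "control pairs, epsilon_sum =", report.epsilon_sum)

curve = sweep_outcomes(outcomes, sheet, FilterStrategy.INDEX_ONLY, range(41))
q = choose_threshold(curve, max_epsilon_fraction=0.1)
row = curve.row(q)
print(f"Q_thresh={q:g}, retained {100*row['fraction_retained']:.1f}%, "
      f"epsilon {row['epsilon_sum']} of {curve.table.iloc[0]['epsilon_sum']}")
```

prints

```
{'CORRECT': 27935, 'INDEX_MIS_I5': 22, 'INDEX_MIS_I7': 17, 'SEQ_MIS': 22,
 'MULTI_MIS': 0, 'UNASSIGNED': 4}
seq 0.079%  index 0.139%  overall 0.218%
182 control pairs, epsilon_sum = 39
Q_thresh=19, retained 99.8%, epsilon 0.0 of 39.0
```

Reading it: of 28,000 simulated reads, 61 were misassigned (0.22 % overall
cross-talk — index misassignments about twice as frequent as sequence
misassignments). The 182 unused index pairs caught 39 of those reads as the
control signal ε. Filtering both index reads at average quality ≥ Q19
removed the entire control signal while keeping 99.8 % of the run.

The same pipeline is available from the shell:

```bash
dualdemux simulate --outdir run/ --seed 7 --reads-per-sample 2000
dualdemux classify --r1 run/R1.fastq --i7 run/I1.fastq --i5 run/I2.fastq \
    --samplesheet run/samplesheet.tsv --references run/references.fasta \
    --outdir results/
dualdemux sweep --r1 run/R1.fastq --i7 run/I1.fastq --i5 run/I2.fastq \
    --samplesheet run/samplesheet.tsv --references run/references.fasta \
    --strategy index --epsilon-target 0.1 --outdir results/
dualdemux report --report-json results/report.json
```

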