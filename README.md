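# srnaspike

Synthetic spike-in sets for small-RNA sequencing: design, read counting,
size-range quality control, and spike-in-anchored normalization — with a
full library simulator so every step can be validated end to end without
real sequencing data.

## The problem

Small-RNA-seq has two chronic technical weaknesses. First, every protocol
size-selects (columns, ethanol precipitation, gel cuts), and those steps
drift between samples — a shifted selection window silently converts a
protocol artifact into apparent differential expression. Second, the sRNA
pool is low-complexity: a handful of miRNAs can consume half the reads, so
total-count (or miRNA-mapped-count) normalization breaks down exactly when
groups differ in global sRNA content.

`srnaspike` implements two spike-in systems that address these:

* **SRQC** (size-range quality control): 11 oligoribonucleotides of graded
  length (10–70 nt, ids `SS-10`…`SS-70`) spiked into total RNA. Their
  counts trace the size-selection profile; a monotone length trend in
  per-spike-in *fold abundance* (sample ÷ reference, after miRNA-total
  scaling) flags a shifted selection window.
* **ERDN** (external reference for data normalization): 19 oligos of 25 nt
  (`DN-01`…`DN-19`) mixed in a 2-fold concentration ladder spanning a 2¹⁸
  dynamic range, added at a fixed amount per µg of total RNA. Per-sample
  size factors are the median-of-ratios over the ERDN counts,

  sf_j = median_i ( k_ij / (∏_s k_is)^(1/n) ),

  anchoring normalization to total-RNA input rather than to read totals, so
  genuine global expression shifts survive normalization.

Design enforces: homopolymer runs ≤ 2, GC in [40%, 60%], minimum hairpin
ΔG ≥ −0.5 kcal/mol at 37 °C (nearest-neighbor single-hairpin scan), and no
shared 12-mer between any two spike-ins (either strand). Counting uses
exact affine-gap end-to-end dynamic programming with the quality-blind
scheme match 0 / mismatch −6 / gap −5−3g and acceptance threshold
−1 − 0.6·L (~10% mismatches). Recovery of designed fold-changes is scored
with the fixed-slope-1 coefficient of determination on log2 counts vs log2
input. See `docs/methods.md` for the models and their limits.

## Worked example

Simulated eight-mix 2-fold serial-dilution experiment: constant background
and ERDN ladder, graded-length fold-change controls halving per mix,
per-library depths jittered by log-normal(0, 0.5) factors, 10⁵ reads per
library:

```python
from srnaspike import workflows

res = workflows.run_dilution_study(seed=0, n_seeds=3)
print(f"included fold-change oligos: {res.included_oligos}")
print(f"mean R2 (ERDN-normalized): {res.mean_r2_erdn:.3f}")
print(f"mean R2 (raw counts):      {res.mean_r2_raw:.3f}")
print(f"mean delta R2:             {res.mean_delta_r2:.3f}")
```

```
included fold-change oligos: ['SS-16', 'SS-19', 'SS-22', 'SS-25', 'SS-28', 'SS-34', 'SS-40']
mean R2 (ERDN-normalized): 0.980
mean R2 (raw counts):      0.904
mean delta R2:             0.076
```

Reading this: oligos whose expected counts stay above the shot-noise floor
(mean ≥ 100 over mixes) track their designed 2-fold dilutions almost
perfectly once ERDN size factors remove the depth jitter (R² = 0.98 against
the slope-1 line); raw counts are visibly worse (0.90), and the per-oligo
improvement ΔR² is positive. The long spike-ins SS-50/60/70 are excluded by
the count filter because the size-selection curve leaves them few reads —
the same behavior the SRQC profile is designed to expose.

The same pipelines are scriptable from the shell:

```bash
srnaspike design   --seed 0 --outdir out            # spikeins.fasta + mixes
srnaspike simulate --seed 0 --depth 50000 --outdir out
srnaspike count    out/reads.fastq.gz out/spikeins.fasta --outdir out
srnaspike evaluate --study dilution --seed 0 --n-seeds 3 --outdir out
```

Each subcommand writes its resolved configuration (YAML) next to its
outputs for exact replay. Other built-in studies: `replicate-sd`
(normalization shrinks replicate variance under unequal depths),
`global-shift` (ERDN preserves a true global miRNA shift that
mapped-reads normalization levels out), and `qc-shift` (±4-nt
size-selection shifts are flagged from SRQC profiles).

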