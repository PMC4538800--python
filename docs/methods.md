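# Methods

`srnaspike` implements two synthetic spike-in systems for small-RNA
sequencing and everything needed to design, count, and evaluate them on
simulated data. This note records the models, the defaults and why they were
chosen, and the limits of what the simulations can demonstrate.

## Spike-in design

Candidate oligoribonucleotides are drawn uniformly over {A, C, G, U} and
accepted when they pass, in order:

1. **Homopolymer filter** — longest single-base run ≤ 2.
2. **GC filter** — GC content in [0.40, 0.60].
3. **Hairpin filter** — minimum single-hairpin ΔG ≥ −0.5 kcal/mol at 37 °C
   (see below). Skipped for oligos ≤ 10 nt, which cannot form a meaningful
   stem–loop.
4. **Cross-similarity filter** — no 12-mer of the candidate (either strand)
   occurs in any previously accepted or supplied sequence. A shared exact
   12-mer is the shortest match we consider worrisome at 25-mer scale; this
   offline screen takes the structural place of an online database search
   and is likewise skipped at ≤ 10 nt.

The SRQC set is one accepted oligo per length in
{10, 16, 19, 22, 25, 28, 34, 40, 50, 60, 70} (ids `SS-10` … `SS-70`); the
ERDN set is nineteen 25-mers (`DN-01` … `DN-19`), screened against the SRQC
pool so the two sets never cross-map. Acceptance rates fall steeply with
length (~3×10⁻⁴ for 70-mers, dominated by the hairpin filter), so the
rejection-sampling cap is 200,000 draws per oligo — large enough that a
full design essentially never aborts (expected ≈ 3,000 draws for the
70-mer; a whole two-set design takes well under a second) while still
failing loudly on infeasible constraint combinations.

Mixes are represented as relative molar concentrations summing to 1 plus a
`molecules_per_ug` scalar (default 1.9×10¹⁰ for the SRQC mix). The ERDN
ladder assigns concentration ∝ 2^(i−1) to the i-th oligo, giving a 2¹⁸
dynamic range with 2-fold steps. `rebalance_mix` implements concentration
levelling: modelling reads ∝ concentration × (unknown per-oligo
efficiency), one rebalance against observed read fractions makes the
implied efficiencies cancel exactly.

## Hairpin free-energy model

The design filter only needs to know whether *any* self-structure is more
stable than −0.5 kcal/mol on ≤ 70-mers, so folding is restricted to single
hairpins: a contiguous stem of ≥ 2 Watson–Crick or G·U pairs closing a loop
of ≥ 3 unpaired bases. The energy is the sum of nearest-neighbor stack
terms, a loop-size initiation penalty, and a +0.45 kcal/mol penalty when
the outer helix end is A·U or G·U. Every structure scored this way is also
a legal structure under a full secondary-structure model, so the scan
under-calls stability relative to a complete folding program (no bulges,
internal loops, multiloops, coaxial stacks, or terminal-mismatch bonuses);
the threshold is configurable to compensate if a stricter screen is wanted.

The parameter table (`src/srnaspike/data/rna_nn_params.tsv`) carries
Turner-style unified Watson–Crick stack free energies at 37 °C, approximate
literature values for common wobble stacks, a weak default (−0.5 kcal/mol)
for unlisted wobble combinations, hairpin-loop penalties for sizes 3–9, and
Jacobson–Stockmayer extrapolation (1.75·R·T·ln(n/9)) beyond. Whether the
−0.5 kcal/mol criterion refers to an MFE or an ensemble energy is ambiguous
in the protocols this mirrors; we define it as the single-hairpin minimum.

## Alignment and counting

Reads are aligned end-to-end (every read base participates) against a
contiguous target substring with free target end-gaps — exact affine-gap
dynamic programming, not seed-and-extend, which is affordable because the
reference sets are tiny. Scoring: match 0, mismatch −6, gap of length g
−5 − 3g, acceptance threshold −1 − 0.6·L for read length L (asymptotically
~10% mismatching bases). Mismatch −6 is the quality-blind maximum of a
quality-scaled penalty; qualities are carried but never used. Because the
DP is exact, scores can only be equal to or better than a heuristic
aligner's on the same scheme. Ties are broken toward the smallest target
start, then fewest gap bases.

Counting rules: spike-in mode requires score ≥ threshold and aligned target
span > 80% of a denominator; miRNA/piRNA modes require perfect full-read
matches (piRNA on both strands). The stated 80%-of-target rule makes 50–70
nt spike-ins uncountable once reads are cropped to 40 nt, yet those
spike-ins are observed in real libraries, so the denominator is
configurable and the built-in studies use `min(read, target)`; the default
object follows the stricter published wording.

`count_reads` is exact but engineered for throughput: a read equal to a
target substring has the globally optimal score 0 and is resolved by hash
lookup (in perfect-only mode a dictionary miss already proves
unassignability); all other reads run the DP against targets sharing a
7-mer with the read. The prefilter is lossless by a pigeonhole argument:
under the default scheme a read of length L ≥ 16 can absorb at most
⌊(1+0.6L)/6⌋ penalty events, which leaves an exact run of ≥ 7 matching
bases in any alignment that could pass the threshold (the minimum over
L ∈ [16, 70] is exactly 7, attained around L = 30–39); reads shorter than
16 nt are aligned against every target. Duplicate read sequences are
collapsed before assignment.

## Simulator

`simulate_library` draws reads multinomially with probability ∝ molar
abundance × size-selection efficiency, then applies i.i.d. substitution
errors (default 0.5% per base; indels are not modelled — they would
interact with the aligner and are left as a configuration extension).
Components:

* **Background** — random-sequence species in three classes: miRNA-like
  (lengths ≈ N(22, 1.2), clipped 18–26), piRNA-like (≈ N(28, 1.5), clipped
  25–33), other (uniform 15–45); abundances log-normal with σ = 2,
  regenerated (incremented sub-seed) until the top-10 species hold 30–70%
  of the pool, the concentration regime of real miRNA populations.
  Background sequences are random, not real miRNAs, so no database is
  required; class labels drive only length and grouping.
* **Size selection** — product of two logistics,
  plateau·σ((L−13)/1.2)·(1−σ((L−45)/7)): near-full efficiency for 16–25
  nt, ~0.08 at 10 nt, ~0.03 at 70 nt. Protocol perturbations are modelled
  by shifting both midpoints by a common offset.
* **Truth** — every library returns expected (pre-sampling) and realized
  counts per feature, so counting can be validated exactly on error-free
  input.

What the simulator does *not* capture: PCR/GC bias, platform-specific indel
errors, adapter artifacts, partial degradation, or any sequence-dependent
ligation efficiency beyond the per-oligo efficiencies that mix balancing
absorbs. Passing the studies therefore shows the statistical machinery is
correct under the stated noise model, not that any particular wet-lab
protocol meets it.

## Normalization and evaluation

Size factors are classic median-of-ratios: per-feature ratios to the
feature's across-sample geometric mean, median over features per sample.
Features with any zero are excluded (and reported); no pseudo-count enters
the estimator. Note the raw estimator has no fixed normalization: scaling
one of n samples by c moves its factor by c^(1−1/n) and the others by
c^(−1/n), so only ratios of size factors scale by exactly c. The native
implementation is cross-checked in the test suite against an independent
DESeq2-style implementation.

Evaluation statistics use log2(count + 1) (pseudo-count configurable;
applied only here). Fixed-slope R² estimates the intercept as mean(y − x)
and compares slope-1 residuals to the variance of y; the intercept is free
because only the slope is constrained. Replicate SD uses the unbiased
(n−1) estimator. Distribution summaries report the median and the mode of
a Gaussian KDE with Silverman bandwidth. The size-bias flag fires when
|Spearman ρ| of log2 fold abundance vs length ≥ 0.8 AND some spike-in
deviates ≥ 2-fold; both thresholds are configurable, and the raw profile is
always reported alongside the verdict.

## Study designs and problem sizes

The built-in studies are desk-scale versions of the evaluation experiments,
with sizes chosen by power analysis at design time:

* **Dilution** — 8 mixes, depth 10⁵ reads × log-normal(0, 0.5) factors,
  fold-change oligos (the SRQC sequences reused as graded-length controls)
  at molar fraction 0.08 halving per mix, ERDN at 0.03, 20 seeds. Oligos
  with mean expected count < 100 across mixes are excluded from the R²
  average, mirroring low-count reporting rules; in practice that keeps
  SS-16 through SS-50 and drops SS-10/SS-60/SS-70, whose counts sit in the
  shot-noise floor after size selection.
* **Replicate SD** — 6 replicates at depth 55,000 down-sampled to
  25–50×10³, 20 seeds.
* **Global shift** — miRNA read fractions 10% vs 29%, 4 + 4 samples at
  depth 150,000, 60 miRNA-like and 60 piRNA-like species, 3 seeds. The
  depth is set so that the log2(mean+1) pseudo-count compression at median
  feature counts stays well inside the ±0.2 evaluation band (the bias
  shrinks roughly inversely with per-feature counts).
* **QC shift** — ±4 nt midpoint shifts, SRQC at molar fraction 0.1
  (balanced ∝ 1/efficiency), depth 6×10⁵, 40 seeds. The depth is the power
  driver: the middle of the size-response curve (19–28 nt) is nearly flat
  and the −4 nt profile carries a genuine tail rank inversion, so the
  Spearman trend statistic needs on the order of 800 reads per spike-in
  (Monte Carlo of the flag statistic: per-trial detection ≈ 0.94 at ~260
  reads/oligo vs ≈ 0.999 at ~780) before rank noise stops breaking the
  |ρ| ≥ 0.8 condition.

All randomness flows through a single master seed via spawned child seeds;
every study is bit-reproducible.

## Known limitations

* The hairpin model is a filter, not a folding program; reported ΔG values
  should not be compared against full secondary-structure predictions.
* The aligner is for small reference sets; it has no index and scales
  linearly in targets (the 7-mer prefilter mitigates, but a genome-scale
  reference is out of scope).
* Wobble stack energies outside the shipped table fall back to a single
  weak constant.
* The simulator's substitution-only error model flatters aligner recall
  relative to indel-heavy platforms.
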