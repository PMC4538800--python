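"""End-to-end simulation studies tying the modules together.

Each study mirrors one of the evaluation experiments the spike-in systems
were designed for, at desk scale:

* **dilution study** — eight 2-fold serial dilutions of fold-change control
  oligos on a constant background, with log-normal per-library depth
  variation; measures fixed-slope R² of ERDN-normalized vs raw counts.
* **replicate-SD study** — technical replicates down-sampled to unequal
  depths; measures whether ERDN normalization reduces the median
  per-feature SD of log2 miRNA counts.
* **global-shift study** — two groups with different global miRNA content
  (e.g. 10% vs 29% of reads); measures whether ERDN normalization preserves
  the true shift while miRNA-mapped-reads normalization levels it out.
* **QC shift study** — size-selection midpoints shifted by ±4 nt; measures
  whether the SRQC fold-abundance profile flags the bias and resolves its
  direction.

These functions are the single implementation used by the test suite, the
command line and the reproduction script. Spike-in read counting uses the
``min(read, target)`` span denominator so that 40-nt-cropped reads can still
cover the 50–70 nt spike-ins (with the strict target-length rule those
spike-ins would be structurally uncountable, contradicting their observed
behavior in real libraries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align, design, evaluate, normalize, qc, simulate
from .align import AcceptanceRule, TargetIndex, count_table
from .reads import crop_reads, downsample, filter_min_length
from .simulate import child_seeds

#: Reads are cropped to 40 nt before spike-in counting and to 30 nt (with a
#: 15-nt minimum) before miRNA counting; piRNA counting crops to 40 nt with
#: a 12-nt minimum.
SPIKE_CROP = 40
MIRNA_CROP = 30
MIRNA_MIN_LEN = 15
PIRNA_CROP = 40
PIRNA_MIN_LEN = 12

SPIKE_RULE = AcceptanceRule(
    length_fraction_denominator="min_of_read_and_target")
PERFECT_RULE = AcceptanceRule(
    perfect_only=True, length_fraction_denominator="min_of_read_and_target")


def design_sets(seed: int = 0,
                constraints: design.DesignConstraints = design.DesignConstraints()
                ) -> tuple[design.SpikeInSet, design.SpikeInSet]:
    """Design the SRQC and ERDN sets, mutually k-mer dissimilar."""
    srqc = design.build_srqc_set(constraints, seed=seed)
    erdn = design.build_erdn_set(constraints, seed=seed + 1,
                                 pool=[o.seq for o in srqc])
    return srqc, erdn


def _count_spikes(libs: dict[str, simulate.LibraryResult],
                  index: TargetIndex) -> pd.DataFrame:
    samples = {name: crop_reads(lib.reads, SPIKE_CROP)
               for name, lib in libs.items()}
    counts, _ = count_table(samples, index, SPIKE_RULE)
    return counts


def _count_mirna(libs: dict[str, simulate.LibraryResult],
                 index: TargetIndex) -> pd.DataFrame:
    samples = {
        name: filter_min_length(crop_reads(lib.reads, MIRNA_CROP),
                                MIRNA_MIN_LEN)
        for name, lib in libs.items()
    }
    counts, _ = count_table(samples, index, PERFECT_RULE)
    return counts


@dataclass(frozen=True)
class DilutionStudyResult:
    mean_r2_erdn: float
    mean_r2_raw: float
    mean_delta_r2: float
    per_seed_r2_erdn: list[float]
    per_seed_delta_r2: list[float]
    included_oligos: list[str]


def run_dilution_study(seed: int = 0,
                       n_seeds: int = 20,
                       depth: int = 100_000,
                       depth_sigma: float = 0.5,
                       n_mixes: int = 8,
                       error_rate: float = 0.005,
                       min_expected: float = 100.0,
                       n_species: int = 300) -> DilutionStudyResult:
    """Serial-dilution recovery of designed 2-fold changes.

    For each seed: simulate ``n_mixes`` libraries sharing a background and a
    constant ERDN ladder while the fold-change oligos (the graded-length
    SRQC sequences reused as fold-change controls) are diluted 2-fold per
    mix; count reads; normalize by ERDN median-of-ratios size factors; and
    score each fold-change oligo's log2 counts against its log2 relative
    input with the fixed-slope-1 R². Oligos whose mean expected count over
    mixes falls below ``min_expected`` are excluded (their counts sit in the
    shot-noise floor). Reports R² and ΔR² = R²(normalized) − R²(raw)
    averaged over oligos and seeds.
    """
    srqc, erdn = design_sets(child_seeds(seed, 1)[0] % 10_000)
    targets = TargetIndex(list(srqc) + list(erdn))
    fc_ids = srqc.ids
    erdn_ids = erdn.ids

    seeds = child_seeds(seed + 1, n_seeds)
    per_seed_r2: list[float] = []
    per_seed_raw: list[float] = []
    per_seed_delta: list[float] = []
    included_union: set[str] = set()
    for s in seeds:
        bg_seed, sim_seed = child_seeds(s, 2)
        background = simulate.make_background(n_species=n_species,
                                              seed=bg_seed)
        scenarios, log2_input = simulate.dilution_series_scenario(
            srqc, erdn, background, n_mixes=n_mixes, depth=depth,
            depth_sigma=depth_sigma, error_rate=error_rate, seed=sim_seed)
        libs = {sc.label: simulate.simulate_library(sc) for sc in scenarios}
        counts = _count_spikes(libs, targets)
        expected = pd.DataFrame(
            {name: lib.truth["expected"] for name, lib in libs.items()})
        included = [o for o in fc_ids
                    if expected.loc[o].mean() >= min_expected]
        included_union.update(included)
        sf = normalize.size_factors(counts.loc[erdn_ids], "ERDN")
        norm_fc = normalize.normalize_counts(counts.loc[included], sf)
        r2_norm = evaluate.dilution_r2(norm_fc, log2_input)
        r2_raw = evaluate.dilution_r2(counts.loc[included], log2_input)
        per_seed_r2.append(float(r2_norm.mean()))
        per_seed_raw.append(float(r2_raw.mean()))
        per_seed_delta.append(float((r2_norm - r2_raw).mean()))

    return DilutionStudyResult(
        mean_r2_erdn=float(np.mean(per_seed_r2)),
        mean_r2_raw=float(np.mean(per_seed_raw)),
        mean_delta_r2=float(np.mean(per_seed_delta)),
        per_seed_r2_erdn=per_seed_r2,
        per_seed_delta_r2=per_seed_delta,
        included_oligos=sorted(included_union),
    )


@dataclass(frozen=True)
class ReplicateSdStudyResult:
    n_seeds: int
    n_reduced: int
    median_sd_raw: list[float]
    median_sd_erdn: list[float]


def run_replicate_sd_study(seed: int = 0,
                           n_seeds: int = 20,
                           n_replicates: int = 6,
                           depth: int = 55_000,
                           downsample_depths: tuple[int, ...] = (
                               25_000, 30_000, 35_000, 40_000, 45_000, 50_000),
                           error_rate: float = 0.005,
                           n_species: int = 200) -> ReplicateSdStudyResult:
    """Replicate-variance reduction under unequal sequencing depths.

    Technical replicates of one spiked sample are down-sampled to a spread
    of depths (mimicking deliberately increased depth variance), miRNA
    features are counted, and the median per-feature SD of log2 counts is
    compared between raw and ERDN-normalized tables. Reports in how many
    seeds normalization reduced the median SD.
    """
    if len(downsample_depths) != n_replicates:
        raise ValueError("one down-sampling depth per replicate is required")
    _, erdn = design_sets(child_seeds(seed, 1)[0] % 10_000)
    erdn_index = TargetIndex(list(erdn))
    erdn_mix = simulate.SpikeMix(erdn, design.ladder_mix(erdn), 0.03)

    seeds = child_seeds(seed + 1, n_seeds)
    n_reduced = 0
    med_raw: list[float] = []
    med_norm: list[float] = []
    for s in seeds:
        bg_seed, *rep_seeds = child_seeds(s, n_replicates + 1)
        background = simulate.make_background(n_species=n_species,
                                              seed=bg_seed)
        mirna_index = TargetIndex({sp.id: sp.seq for sp in background
                                   if sp.cls == simulate.CLASS_MIRNA})
        libs: dict[str, simulate.LibraryResult] = {}
        for r, rs in enumerate(rep_seeds):
            scen = simulate.SimScenario(
                background=background, mixes=(erdn_mix,),
                selection=simulate.SizeSelectionCurve(), depth=depth,
                error_rate=error_rate, seed=rs, label=f"rep{r + 1}")
            lib = simulate.simulate_library(scen)
            sub = downsample(lib.reads, downsample_depths[r], seed=rs + 1)
            libs[scen.label] = simulate.LibraryResult(sub, lib.truth,
                                                      lib.meta)
        mirna_counts = _count_mirna(libs, mirna_index)
        erdn_counts = _count_spikes(libs, erdn_index)
        sf = normalize.size_factors(erdn_counts, "ERDN")
        sd_raw = evaluate.replicate_sd(mirna_counts)
        sd_norm = evaluate.replicate_sd(
            normalize.normalize_counts(mirna_counts, sf))
        med_raw.append(float(sd_raw.median()))
        med_norm.append(float(sd_norm.median()))
        if med_norm[-1] < med_raw[-1]:
            n_reduced += 1
    return ReplicateSdStudyResult(n_seeds, n_reduced, med_raw, med_norm)


@dataclass(frozen=True)
class GlobalShiftStudyResult:
    true_log2_shift: float
    mirna_median_mapped: float
    mirna_median_erdn: float
    pirna_median_erdn: float
    per_seed: pd.DataFrame


def run_global_shift_study(seed: int = 0,
                           n_seeds: int = 3,
                           mirna_fraction_a: float = 0.10,
                           mirna_fraction_b: float = 0.29,
                           n_per_group: int = 4,
                           depth: int = 150_000,
                           error_rate: float = 0.005,
                           n_species: int = 150,
                           n_mirna_like: int = 60) -> GlobalShiftStudyResult:
    """Global miRNA-content contrast between two sample groups.

    Group B carries a higher per-µg miRNA load such that the expected miRNA
    read fractions are ``mirna_fraction_a`` vs ``mirna_fraction_b``; piRNA
    per-µg abundance is identical. The study reports the median per-feature
    log2 ratio (B over A) of miRNAs under miRNA-mapped-reads normalization
    (expected ≈ 0: the shift is leveled out) and under ERDN normalization
    (expected ≈ the true shift), plus the piRNA median under ERDN
    normalization (expected ≈ 0), averaged over seeds.
    """
    _, erdn = design_sets(child_seeds(seed, 1)[0] % 10_000)
    erdn_index = TargetIndex(list(erdn))
    erdn_mix = simulate.SpikeMix(erdn, design.ladder_mix(erdn), 0.03)
    class_mix = {
        simulate.CLASS_MIRNA: n_mirna_like / n_species,
        simulate.CLASS_PIRNA: n_mirna_like / n_species,
        simulate.CLASS_OTHER: 1 - 2 * n_mirna_like / n_species,
    }

    rows = []
    true_shift = np.nan
    for s in child_seeds(seed + 1, n_seeds):
        bg_seed, design_seed = child_seeds(s, 2)
        background = simulate.make_background(
            n_species=n_species, class_mix=class_mix, seed=bg_seed)
        study = simulate.global_shift_scenario(
            mirna_fraction_a, mirna_fraction_b, n_per_group,
            background=background, mixes=(erdn_mix,), depth=depth,
            error_rate=error_rate, seed=design_seed)
        true_shift = study.true_log2_mirna_shift
        libs = {name: simulate.simulate_library(sc)
                for name, sc in study.scenarios.items()}
        mirna_counts = _count_mirna(libs, TargetIndex(study.mirna_refs))
        pirna_samples = {
            name: filter_min_length(crop_reads(lib.reads, PIRNA_CROP),
                                    PIRNA_MIN_LEN)
            for name, lib in libs.items()}
        pirna_counts, _ = count_table(
            pirna_samples, TargetIndex(study.pirna_refs,
                                       strand_mode=align.BOTH_STRANDS),
            PERFECT_RULE, strand_mode=align.BOTH_STRANDS)
        erdn_counts = _count_spikes(libs, erdn_index)

        sf_erdn = normalize.size_factors(erdn_counts, "ERDN")
        sf_mapped = normalize.size_factors(mirna_counts, "miRNA_mapped")

        def median_ratio(counts, sf):
            ratios, _ = evaluate.group_log_ratio(
                normalize.normalize_counts(counts, sf),
                study.group_b, study.group_a)
            return float(ratios.median())

        rows.append({
            "mirna_mapped": median_ratio(mirna_counts, sf_mapped),
            "mirna_erdn": median_ratio(mirna_counts, sf_erdn),
            "pirna_erdn": median_ratio(pirna_counts, sf_erdn),
        })
    per_seed = pd.DataFrame(rows)
    return GlobalShiftStudyResult(
        true_log2_shift=float(true_shift),
        mirna_median_mapped=float(per_seed["mirna_mapped"].mean()),
        mirna_median_erdn=float(per_seed["mirna_erdn"].mean()),
        pirna_median_erdn=float(per_seed["pirna_erdn"].mean()),
        per_seed=per_seed,
    )


@dataclass(frozen=True)
class QcShiftStudyResult:
    n_seeds: int
    detection_rate: dict[float, float]  # shift -> flagged-with-correct-sign
    false_positive_rate: float


def run_qc_shift_study(seed: int = 0,
                       n_seeds: int = 40,
                       shifts: tuple[float, ...] = (4.0, -4.0),
                       depth: int = 600_000,
                       srqc_fraction: float = 0.1,
                       error_rate: float = 0.005,
                       n_species: int = 150) -> QcShiftStudyResult:
    """Detection of size-selection window shifts from SRQC profiles.

    Per seed, a reference library (standard selection), an unshifted
    replicate, and one library per midpoint shift are simulated with a
    balanced SRQC mix (concentrations ∝ 1/efficiency, the concentration
    levelling applied when compounding the real mix). Fold abundances
    versus the reference (after miRNA-total scaling) feed the size-bias
    flag; a detection counts only when the flag fires AND the sign of the
    length trend matches the sign of the shift. The unshifted replicate
    estimates the false-positive rate.
    """
    srqc, _ = design_sets(child_seeds(seed, 1)[0] % 10_000)
    srqc_index = TargetIndex(list(srqc))
    selection = simulate.SizeSelectionCurve()
    eff = {o.id: float(selection.efficiency(o.length)) for o in srqc}
    balanced = design.efficiency_balanced_mix(srqc, eff)
    srqc_mix = simulate.SpikeMix(srqc, balanced, srqc_fraction)
    lengths = {o.id: o.length for o in srqc}

    detections = {sh: 0 for sh in shifts}
    false_pos = 0
    for s in child_seeds(seed + 1, n_seeds):
        bg_seed, *lib_seeds = child_seeds(s, 3 + len(shifts))
        background = simulate.make_background(n_species=n_species,
                                              seed=bg_seed)
        mirna_index = TargetIndex({sp.id: sp.seq for sp in background
                                   if sp.cls == simulate.CLASS_MIRNA})
        conditions: dict[str, simulate.SizeSelectionCurve] = {
            "reference": selection, "replicate": selection}
        for sh in shifts:
            conditions[f"shift{sh:+g}"] = selection.shifted(sh)
        libs = {}
        for (name, sel), ls in zip(conditions.items(), lib_seeds):
            scen = simulate.SimScenario(
                background=background, mixes=(srqc_mix,), selection=sel,
                depth=depth, error_rate=error_rate, seed=ls, label=name)
            libs[name] = simulate.simulate_library(scen)
        srqc_counts = _count_spikes(libs, srqc_index)
        mirna_totals = _count_mirna(libs, mirna_index).sum(axis=0)
        _table, reports = qc.qc_report(srqc_counts, mirna_totals,
                                       "reference", lengths)
        for sh in shifts:
            rep = reports[f"shift{sh:+g}"]
            if rep.flagged and np.sign(rep.spearman_rho) == np.sign(sh):
                detections[sh] += 1
        if reports["replicate"].flagged:
            false_pos += 1
    return QcShiftStudyResult(
        n_seeds=n_seeds,
        detection_rate={sh: detections[sh] / n_seeds for sh in shifts},
        false_positive_rate=false_pos / n_seeds,
    )
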