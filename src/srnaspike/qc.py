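"""Size-range quality-control statistics from SRQC spike-in counts.

The SRQC spike-ins are graded in length (10–70 nt), so their read counts
trace the size-selection profile of the whole library-prep chain. Comparing
a sample's profile with a reference sample exposes length-dependent biases:
a shift of the size-selection window (for example from an altered ethanol
concentration during sRNA isolation) shows up as a monotone length trend in
the per-spike-in fold abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, NormalizationError


def mirna_scaled_counts(srqc_counts: pd.DataFrame,
                        mirna_totals: pd.Series | Mapping[str, float]
                        ) -> pd.DataFrame:
    """Scale SRQC counts by each sample's miRNA-mapped read total.

    Each sample's counts are divided by its total miRNA-mapped reads and
    multiplied by the mean total over samples, so samples become comparable
    while within-sample ratios between spike-ins are preserved exactly.
    """
    totals = pd.Series(mirna_totals).astype(float)
    missing = [s for s in srqc_counts.columns if s not in totals.index]
    if missing:
        raise NormalizationError(f"no miRNA total for sample(s) {missing}")
    totals = totals.loc[srqc_counts.columns]
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise NormalizationError(
            f"zero miRNA-mapped reads in sample(s) {zero}")
    return srqc_counts / totals * totals.mean()


def fold_abundance(profile_table: pd.DataFrame,
                   reference_sample: str) -> pd.DataFrame:
    """Per-spike-in ratio of each sample to the reference sample.

    Entries whose reference count is zero are undefined and reported as NaN
    rather than infinity. The reference column itself is excluded.
    """
    if reference_sample not in profile_table.columns:
        raise KeyError(reference_sample)
    ref = profile_table[reference_sample].astype(float)
    others = profile_table.drop(columns=[reference_sample]).astype(float)
    fa = others.div(ref.where(ref > 0), axis=0)
    return fa


@dataclass(frozen=True)
class SizeBiasReport:
    flagged: bool
    spearman_rho: float
    max_abs_log2_fa: float
    fold_abundance: pd.Series  # indexed by spike-in length
    n_defined: int

    def to_dict(self) -> dict:
        return {
            "flagged": bool(self.flagged),
            "spearman_rho": float(self.spearman_rho),
            "max_abs_log2_fa": float(self.max_abs_log2_fa),
            "n_defined": int(self.n_defined),
            "fold_abundance": {int(k): float(v)
                               for k, v in self.fold_abundance.items()},
        }


def size_bias_flag(profile: pd.Series | Mapping[int, float],
                   rho_threshold: float = 0.8,
                   fold_threshold: float = 2.0) -> SizeBiasReport:
    """Flag a length-dependent size-selection bias in one sample's profile.

    *profile* maps spike-in length → fold abundance versus the reference
    condition. A bias is flagged when the log2 fold abundances show a strong
    rank correlation with length (|Spearman ρ| ≥ ``rho_threshold``) AND at
    least one spike-in deviates by ``fold_threshold``-fold or more. Undefined
    entries (NaN) are excluded; at least four defined points are required.
    """
    fa = pd.Series(profile, dtype=float).sort_index()
    fa = fa.dropna()
    if len(fa) < 4:
        raise InsufficientDataError(
            f"need >= 4 defined fold abundances, got {len(fa)}")
    log2fa = np.log2(fa.values)
    if np.ptp(log2fa) == 0:  # constant profile: no trend by definition
        rho = 0.0
    else:
        rho, _ = stats.spearmanr(fa.index.values.astype(float), log2fa)
    max_abs = float(np.max(np.abs(log2fa)))
    flagged = bool(abs(rho) >= rho_threshold
                   and max_abs >= np.log2(fold_threshold))
    return SizeBiasReport(flagged, float(rho), max_abs, fa, len(fa))


def qc_report(srqc_counts: pd.DataFrame,
              mirna_totals: pd.Series | Mapping[str, float],
              reference_sample: str,
              lengths: Mapping[str, int],
              rho_threshold: float = 0.8,
              fold_threshold: float = 2.0
              ) -> tuple[pd.DataFrame, dict[str, SizeBiasReport]]:
    """Full per-sample QC: scaled counts, fold abundances, bias flags.

    *lengths* maps spike-in id → length in nt. Returns a long-format table
    (spike_in, length, sample, count, scaled_count, fold_abundance) and one
    :class:`SizeBiasReport` per non-reference sample.
    """
    scaled = mirna_scaled_counts(srqc_counts, mirna_totals)
    fa = fold_abundance(scaled, reference_sample)
    rows = []
    for sample in srqc_counts.columns:
        for spike in srqc_counts.index:
            rows.append({
                "spike_in": spike,
                "length": lengths[spike],
                "sample": sample,
                "count": srqc_counts.at[spike, sample],
                "scaled_count": scaled.at[spike, sample],
                "fold_abundance": (fa.at[spike, sample]
                                   if sample in fa.columns else 1.0),
            })
    table = pd.DataFrame(rows)
    reports = {}
    for sample in fa.columns:
        profile = pd.Series(
            {lengths[s]: fa.at[s, sample] for s in srqc_counts.index})
        reports[sample] = size_bias_flag(profile, rho_threshold,
                                         fold_threshold)
    return table, reports
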