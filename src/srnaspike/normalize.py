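"""Median-of-ratios size factors anchored on a reference feature set.

The estimator is the classic RNA-seq size-factor construction: each
feature's counts are divided by the feature's geometric mean across samples,
and a sample's size factor is the median of those ratios over features.
Anchoring it on the ERDN spike-ins — present in every sample at a fixed
amount per µg of total RNA — normalizes samples to their total-RNA input,
which stays valid even when the biological sRNA composition differs wildly
between groups (the situation that defeats total-count normalization).

Features containing a zero in any sample are excluded from the median (the
geometric mean would vanish); exclusions are reported on the result.
Implemented natively so the package is self-contained; an external
implementation serves as a cross-check in the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, NormalizationError


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scaling constants.

    ``reference_kind`` records what the factors were derived from (e.g.
    "ERDN", "miRNA_mapped"); ``excluded_features`` lists reference features
    dropped because they contained a zero count.
    """

    factors: pd.Series
    reference_kind: str = "other"
    excluded_features: tuple[str, ...] = ()

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise NormalizationError("size factors must be positive")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def size_factors(reference_counts: pd.DataFrame,
                 reference_kind: str = "other") -> SizeFactors:
    """Median-of-ratios size factors from a reference count table.

    Requires at least one feature with positive counts in every sample.
    """
    counts = reference_counts.astype(float)
    if counts.empty:
        raise NormalizationError("empty reference count table")
    positive = (counts > 0).all(axis=1)
    excluded = tuple(counts.index[~positive])
    usable = counts.loc[positive]
    if usable.empty:
        raise NormalizationError(
            "no reference feature has positive counts in every sample")
    log_geo_mean = np.log(usable).mean(axis=1)
    ratios = np.log(usable).sub(log_geo_mean, axis=0)
    sf = np.exp(ratios.median(axis=0))
    return SizeFactors(sf, reference_kind, excluded)


def normalize_counts(feature_counts: pd.DataFrame,
                     sf: SizeFactors | pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = sf.factors if isinstance(sf, SizeFactors) else pd.Series(sf)
    missing = [s for s in feature_counts.columns if s not in factors.index]
    if missing:
        raise KeyError(f"no size factor for sample(s) {missing}")
    return feature_counts.astype(float).div(factors[feature_counts.columns],
                                            axis=1)


def low_count_exclusion(counts: pd.DataFrame, min_reads: int = 10,
                        max_failing_samples: int = 3) -> pd.Index:
    """Features reliably measured often enough to report.

    A feature is retained when its count falls below ``min_reads`` in at
    most ``max_failing_samples`` samples — the reporting rule used to drop
    spike-ins that the size selection leaves with too few reads.
    """
    failing = (counts < min_reads).sum(axis=1)
    return counts.index[failing <= max_failing_samples]


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.select_dtypes(include=[np.number]) < 0).any().any():
        raise InputError(f"negative counts in {path}")
    return df


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id", na_rep=".")


def write_size_factors(sf: SizeFactors, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsize_factor\n")
        for sample, factor in sf.factors.items():
            fh.write(f"{sample}\t{factor:.10g}\n")
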