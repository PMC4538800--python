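"""FASTQ I/O, 3′ cropping, length filtering, and seeded down-sampling.

Reads are carried as lightweight records with id, RNA sequence (T on input
is mapped to U) and a per-base quality string. Qualities are preserved
through every operation but never used in scoring — the alignment scheme
deliberately ignores them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._seq import dna_to_rna, rna_to_dna, validate_rna
from .exceptions import InputError, ParameterError, SamplingError


@dataclass(frozen=True, slots=True)
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise InputError(
                f"read {self.id!r}: sequence and quality lengths differ")

    @property
    def length(self) -> int:
        return len(self.seq)


def _open(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path, validate: bool = False) -> list[Read]:
    """Parse a (optionally gzipped) FASTQ file; T is mapped to U."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    reads: list[Read] = []
    seen: set[str] = set()
    with _open(path, "r") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid = title.split()[0]
            if rid in seen:
                raise InputError(f"duplicate read id {rid!r} in {path}")
            seen.add(rid)
            rna = dna_to_rna(seq)
            if validate:
                validate_rna(rna, allow_n=True)
            reads.append(Read(rid, rna, qual))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path,
                dna: bool = True) -> None:
    """Write 4-line FASTQ (gzipped if the path ends in .gz).

    ``dna=True`` (default) writes T, matching what a sequencer would emit;
    round-trips through :func:`read_fastq` are lossless either way.
    """
    with _open(path, "w") as fh:
        for r in reads:
            seq = rna_to_dna(r.seq) if dna else r.seq
            fh.write(f"@{r.id}\n{seq}\n+\n{r.qual}\n")


def crop_reads(reads: Sequence[Read], n: int) -> list[Read]:
    """Trim every read to its 5′-most *n* bases (Trimmomatic CROP semantics).

    Bases are removed from the 3′ end; reads already ≤ *n* are unchanged
    (and kept as the same objects). Qualities are cropped identically.
    """
    if n < 1:
        raise ParameterError("crop length must be >= 1")
    return [r if r.length <= n else Read(r.id, r.seq[:n], r.qual[:n])
            for r in reads]


def filter_min_length(reads: Sequence[Read], m: int) -> list[Read]:
    """Keep reads of length ≥ *m*, preserving order."""
    if m < 1:
        raise ParameterError("minimum length must be >= 1")
    return [r for r in reads if r.length >= m]


def downsample(reads: Sequence[Read], n: int, seed: int) -> list[Read]:
    """Draw exactly *n* reads uniformly without replacement (seeded).

    Input order is preserved among the retained reads, mimicking streaming
    reservoir down-sampling of a FASTQ file.
    """
    total = len(reads)
    if n > total:
        raise SamplingError(f"cannot sample {n} reads from {total}")
    rng = np.random.default_rng(seed)
    keep = rng.choice(total, size=n, replace=False)
    keep.sort()
    return [reads[i] for i in keep]
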