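"""Design of synthetic spike-in oligoribonucleotides and their mixes.

Two spike-in sets are produced for small-RNA sequencing:

* **SRQC** (size-range quality control): 11 single-stranded oligos of
  10, 16, 19, 22, 25, 28, 34, 40, 50, 60 and 70 nt, added to total RNA to
  report on the size-selection behavior of the whole library-prep chain.
* **ERDN** (external reference for data normalization): 19 oligos of 25 nt
  mixed in a 2-fold concentration ladder spanning a 2^18 dynamic range, used
  as invariant anchors for between-sample normalization.

Candidates are drawn uniformly over {A,C,G,U} and accepted only if they pass
a filter stack: homopolymer runs ≤ 2, GC content in [40%, 60%], minimum
hairpin ΔG ≥ −0.5 kcal/mol at 37 °C (see :mod:`srnaspike.thermo`), and no
shared k-mer (k = 12, either strand) with any previously accepted or
supplied sequence. A shared 12-mer is the shortest exact match that is
biologically worrisome at these lengths, and the k-mer screen replaces an
online BLAST search so the designer runs fully offline. Structure and
similarity checks are skipped for oligos of ≤ 10 nt, which are too short for
either to be meaningful.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import thermo
from ._seq import reverse_complement, rna_to_dna, validate_rna
from .exceptions import (
    DesignInfeasibleError,
    ParameterError,
    RebalanceError,
)

SRQC_LENGTHS = (10, 16, 19, 22, 25, 28, 34, 40, 50, 60, 70)

#: Total SRQC spike-in molecules added per µg of total RNA.
SRQC_MOLECULES_PER_UG = 1.9e10

ROLE_SRQC = "SRQC"
ROLE_ERDN = "ERDN"
ROLE_FOLDCHANGE = "FOLDCHANGE"


@dataclass(frozen=True)
class Oligo:
    """One spike-in sequence."""

    id: str
    seq: str
    role: str = ROLE_SRQC

    def __post_init__(self):
        validate_rna(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DesignConstraints:
    """Filter parameters for candidate oligo acceptance.

    ``skip_structure_below`` is the length at or below which the hairpin and
    cross-similarity checks are waived (the shortest spike-in is exempt, as
    too short for meaningful structure or database hits).
    """

    max_homopolymer: int = 2
    gc_min: float = 0.40
    gc_max: float = 0.60
    dg_min: float = -0.5
    min_kmer_distance: int = 12
    skip_structure_below: int = 10
    # The hairpin filter accepts only ~3e-4 of random 70-mers; the cap is
    # sized so a full design practically never aborts (yet still terminates
    # with a clear error on truly infeasible constraint combinations).
    max_draws_per_oligo: int = 200_000

    def __post_init__(self):
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ParameterError("require 0 <= gc_min < gc_max <= 1")
        if self.max_homopolymer < 1:
            raise ParameterError("max_homopolymer must be >= 1")
        if self.min_kmer_distance < 1:
            raise ParameterError("min_kmer_distance must be >= 1")


@dataclass(frozen=True)
class MixSpec:
    """Relative molar composition of a spike-in mix.

    ``entries`` maps oligo id → relative molar concentration (positive,
    summing to 1). ``molecules_per_ug`` records the absolute amount of the
    whole mix added per µg of total RNA and is carried as metadata.
    """

    entries: Mapping[str, float]
    molecules_per_ug: float = SRQC_MOLECULES_PER_UG

    def __post_init__(self):
        if not self.entries:
            raise ParameterError("mix must contain at least one oligo")
        if any(c <= 0 for c in self.entries.values()):
            raise ParameterError("all concentrations must be positive")
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"concentrations must sum to 1 (got {total!r})")

    @classmethod
    def from_weights(cls, weights: Mapping[str, float],
                     molecules_per_ug: float = SRQC_MOLECULES_PER_UG) -> "MixSpec":
        total = sum(weights.values())
        if total <= 0:
            raise ParameterError("weights must have a positive sum")
        return cls({k: v / total for k, v in weights.items()}, molecules_per_ug)


@dataclass(frozen=True)
class SpikeInSet:
    """An ordered collection of designed oligos with unique ids."""

    oligos: tuple[Oligo, ...]

    def __post_init__(self):
        ids = [o.id for o in self.oligos]
        if len(set(ids)) != len(ids):
            raise ParameterError("oligo ids must be unique within a set")

    def __iter__(self):
        return iter(self.oligos)

    def __len__(self):
        return len(self.oligos)

    @property
    def ids(self) -> list[str]:
        return [o.id for o in self.oligos]

    @property
    def sequences(self) -> dict[str, str]:
        return {o.id: o.seq for o in self.oligos}

    def by_id(self, oligo_id: str) -> Oligo:
        for o in self.oligos:
            if o.id == oligo_id:
                return o
        raise KeyError(oligo_id)


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in an RNA sequence."""
    validate_rna(seq)
    counts = Counter(seq)
    return (counts["G"] + counts["C"]) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    validate_rna(seq)
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_dissimilar(seq: str, pool: Iterable[str], k: int) -> bool:
    """True iff no k-mer of *seq* (either strand) occurs in any pool member."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    validate_rna(seq)
    if k > len(seq):
        raise ParameterError(f"k={k} exceeds sequence length {len(seq)}")
    query = _kmers(seq, k) | _kmers(reverse_complement(seq), k)
    for member in pool:
        if not query.isdisjoint(_kmers(member, k)):
            return False
    return True


@dataclass(frozen=True)
class ConstraintReport:
    """Which filters a candidate passed; ``ok`` is the overall verdict."""

    homopolymer_ok: bool
    gc_ok: bool
    structure_checked: bool
    dg_ok: bool = True
    kmer_ok: bool = True
    dg_value: float | None = None

    @property
    def ok(self) -> bool:
        return self.homopolymer_ok and self.gc_ok and self.dg_ok and self.kmer_ok

    @property
    def failed(self) -> list[str]:
        out = []
        if not self.homopolymer_ok:
            out.append("homopolymer")
        if not self.gc_ok:
            out.append("gc_content")
        if not self.dg_ok:
            out.append("hairpin_dG")
        if not self.kmer_ok:
            out.append("kmer_similarity")
        return out


def check_constraints(seq: str, constraints: DesignConstraints,
                      pool: Iterable[str] = ()) -> ConstraintReport:
    """Apply every active design filter to *seq* and report the outcome.

    Cheap filters run first; the hairpin scan and k-mer screen only run for
    sequences longer than ``skip_structure_below``.
    """
    homo_ok = max_homopolymer_run(seq) <= constraints.max_homopolymer
    gc = gc_content(seq)
    gc_ok = constraints.gc_min <= gc <= constraints.gc_max
    if len(seq) <= constraints.skip_structure_below:
        return ConstraintReport(homo_ok, gc_ok, structure_checked=False)
    dg = thermo.min_hairpin_dG(seq)
    dg_ok = dg >= constraints.dg_min
    kmer_ok = kmer_dissimilar(seq, pool, constraints.min_kmer_distance)
    return ConstraintReport(homo_ok, gc_ok, True, dg_ok, kmer_ok, dg)


def passes_constraints(oligo: Oligo, constraints: DesignConstraints,
                       pool: Iterable[str] = ()) -> bool:
    return check_constraints(oligo.seq, constraints, pool).ok


def generate_candidates(n: int, length: int,
                        constraints: DesignConstraints = DesignConstraints(),
                        seed: int = 0,
                        pool: Iterable[str] = (),
                        role: str = ROLE_SRQC,
                        id_prefix: str = "RS") -> list[Oligo]:
    """Rejection-sample *n* accepted oligos of the given length.

    Each accepted sequence joins the similarity pool before the next is
    drawn, so the output is mutually k-mer dissimilar (for lengths above the
    structure-check cutoff) and mutually distinct in all cases. Deterministic
    in (n, length, constraints, seed, pool).

    Raises
    ------
    DesignInfeasibleError
        If ``constraints.max_draws_per_oligo`` draws fail to yield an
        accepted sequence; the error names the most frequently violated
        filter.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if length < 6:
        raise ParameterError("length must be >= 6")
    rng = np.random.default_rng(seed)
    pool = list(pool)
    accepted: list[Oligo] = []
    seen: set[str] = set(pool)
    bases = np.array(list("ACGU"))
    for idx in range(n):
        failures: Counter[str] = Counter()
        for _ in range(constraints.max_draws_per_oligo):
            seq = "".join(rng.choice(bases, size=length))
            if seq in seen:
                failures["duplicate"] += 1
                continue
            report = check_constraints(seq, constraints, pool)
            if report.ok:
                accepted.append(Oligo(f"{id_prefix}-{idx + 1:02d}", seq, role))
                pool.append(seq)
                seen.add(seq)
                break
            for name in report.failed:
                failures[name] += 1
        else:
            binding = failures.most_common(1)[0][0] if failures else "unknown"
            raise DesignInfeasibleError(
                f"no {length}-mer accepted after "
                f"{constraints.max_draws_per_oligo} draws "
                f"(most violated filter: {binding})",
                binding_constraint=binding,
            )
    return accepted


def build_srqc_set(constraints: DesignConstraints = DesignConstraints(),
                   seed: int = 0,
                   pool: Iterable[str] = ()) -> SpikeInSet:
    """Design the 11-oligo size-range QC set (ids SS-10 … SS-70).

    Longer oligos are designed first so each length is screened against the
    accumulated pool; the result is mutually k-mer dissimilar wherever the
    similarity check applies.
    """
    pool = list(pool)
    oligos = []
    for length in sorted(SRQC_LENGTHS, reverse=True):
        (cand,) = generate_candidates(
            1, length, constraints, seed=seed + length, pool=pool,
            role=ROLE_SRQC, id_prefix=f"SS{length}")
        oligo = Oligo(f"SS-{length}", cand.seq, ROLE_SRQC)
        oligos.append(oligo)
        pool.append(oligo.seq)
    oligos.sort(key=lambda o: o.length)
    return SpikeInSet(tuple(oligos))


def build_erdn_set(constraints: DesignConstraints = DesignConstraints(),
                   seed: int = 0,
                   pool: Iterable[str] = ()) -> SpikeInSet:
    """Design the 19-oligo, 25-nt normalization set (ids DN-01 … DN-19).

    Pass the SRQC sequences as *pool* to guarantee cross-set dissimilarity.
    """
    cands = generate_candidates(19, 25, constraints, seed=seed, pool=pool,
                                role=ROLE_ERDN, id_prefix="DN")
    oligos = tuple(Oligo(f"DN-{i + 1:02d}", c.seq, ROLE_ERDN)
                   for i, c in enumerate(cands))
    return SpikeInSet(oligos)


def ladder_mix(spike_set: SpikeInSet, fold_step: float = 2.0,
               molecules_per_ug: float = SRQC_MOLECULES_PER_UG) -> MixSpec:
    """Geometric concentration ladder over a spike-in set.

    The i-th oligo receives a relative concentration proportional to
    ``fold_step**(i-1)``, so consecutive spike-ins differ by ``fold_step``
    and the mix spans a dynamic range of ``fold_step**(n-1)`` (2^18 for the
    19-oligo ERDN set at the default step). ``fold_step == 1`` yields an
    equimolar mix.
    """
    if fold_step < 1:
        raise ParameterError("fold_step must be >= 1")
    if len(spike_set) == 0:
        raise ParameterError("spike set is empty")
    weights = {o.id: fold_step ** i for i, o in enumerate(spike_set)}
    return MixSpec.from_weights(weights, molecules_per_ug)


def rebalance_mix(mix: MixSpec, observed_counts: Mapping[str, float],
                  target_fractions: Mapping[str, float] | None = None) -> MixSpec:
    """Adjust mix concentrations so observed read fractions hit targets.

    Models each oligo's reads as concentration × (unknown per-oligo
    efficiency): the new concentration is
    ``c'_i ∝ c_i * target_i / observed_fraction_i``, which exactly
    compensates the implied efficiencies. With equal targets this is the
    concentration-balancing step used to level out per-oligo sequencing
    efficiency differences. Idempotent once observed fractions equal the
    targets.
    """
    ids = list(mix.entries)
    if target_fractions is None:
        target_fractions = {i: 1.0 / len(ids) for i in ids}
    zero = [i for i in ids if not observed_counts.get(i, 0) > 0]
    if zero:
        raise RebalanceError(
            f"cannot rebalance oligo(s) with zero observed reads: {zero}")
    total = sum(observed_counts[i] for i in ids)
    weights = {
        i: mix.entries[i] * target_fractions[i] / (observed_counts[i] / total)
        for i in ids
    }
    return MixSpec.from_weights(weights, mix.molecules_per_ug)


def efficiency_balanced_mix(spike_set: SpikeInSet,
                            efficiency: Mapping[str, float] | None = None,
                            molecules_per_ug: float = SRQC_MOLECULES_PER_UG,
                            ) -> MixSpec:
    """Equal-read-share mix given known per-oligo efficiencies.

    Convenience constructor for the balanced SRQC mix: concentrations are
    proportional to 1/efficiency so every oligo is expected to draw a similar
    share of reads. With no efficiencies given, the mix is equimolar.
    """
    if efficiency is None:
        weights = {o.id: 1.0 for o in spike_set}
    else:
        if any(efficiency[o.id] <= 0 for o in spike_set):
            raise ParameterError("efficiencies must be positive")
        weights = {o.id: 1.0 / efficiency[o.id] for o in spike_set}
    return MixSpec.from_weights(weights, molecules_per_ug)


# ---------------------------------------------------------------------------
# I/O

def write_fasta(oligos: Iterable[Oligo], path: str | Path,
                dna: bool = False) -> None:
    """Write oligos as FASTA; ``dna=True`` writes T instead of U."""
    with open(path, "w") as fh:
        for o in oligos:
            seq = rna_to_dna(o.seq) if dna else o.seq
            fh.write(f">{o.id} role={o.role} length={o.length}\n{seq}\n")


def read_fasta(path: str | Path, role: str = ROLE_SRQC) -> SpikeInSet:
    """Read a spike-in FASTA (T converted to U)."""
    from Bio import SeqIO

    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        oligos.append(Oligo(rec.id, seq, role))
    return SpikeInSet(tuple(oligos))


def write_mix(mix: MixSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# molecules_per_ug\t{mix.molecules_per_ug:g}\n")
        fh.write("oligo_id\trelative_concentration\n")
        for oid, conc in mix.entries.items():
            fh.write(f"{oid}\t{conc:.10g}\n")


def read_mix(path: str | Path) -> MixSpec:
    molecules = SRQC_MOLECULES_PER_UG
    entries: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# molecules_per_ug"):
                molecules = float(line.split("\t")[1])
            elif line and not line.startswith(("#", "oligo_id")):
                oid, conc = line.split("\t")
                entries[oid] = float(conc)
    return MixSpec(entries, molecules)
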