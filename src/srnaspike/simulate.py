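"""Forward simulation of spiked small-RNA sequencing libraries.

The generator reproduces the statistical structure of spike-in experiments
without any real data: a background population of small-RNA species (random
sequences with miRNA-like ~22 nt and piRNA-like ~28 nt length modes and
log-normal abundances concentrated enough that the top-10 species hold
roughly half the reads), one or more spike-in mixes added at a fixed molar
fraction, a smooth band-pass size-selection curve (near-full efficiency for
16–25 nt, declining toward 10 and 50–70 nt, and shiftable to emulate e.g.
altered ethanol concentrations), multinomial read sampling at a requested
depth, and per-base substitution errors.

Every library also returns its ground truth (expected and realized counts
per source), so downstream counting, normalization and evaluation can be
validated against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._seq import decode, encode
from .design import MixSpec, SpikeInSet, ladder_mix
from .exceptions import ParameterError, SimulationError
from .reads import Read

CLASS_MIRNA = "miRNA-like"
CLASS_PIRNA = "piRNA-like"
CLASS_OTHER = "other"

_CLASS_PREFIX = {CLASS_MIRNA: "mi", CLASS_PIRNA: "pi", CLASS_OTHER: "ot"}

DEFAULT_CLASS_MIX = {CLASS_MIRNA: 0.5, CLASS_PIRNA: 0.3, CLASS_OTHER: 0.2}


@dataclass(frozen=True)
class SizeSelectionCurve:
    """Band-pass retention efficiency as a function of RNA length.

    efficiency(L) = plateau · σ((L − low_mid)/low_scale)
                            · (1 − σ((L − high_mid)/high_scale))

    with σ the logistic function. The defaults give near-full efficiency in
    the 16–25 nt band and a decline toward 10 nt and 50–70 nt. ``shifted``
    moves both midpoints, emulating a protocol change that moves the whole
    size-selection window.
    """

    plateau: float = 1.0
    low_mid: float = 13.0
    low_scale: float = 1.2
    high_mid: float = 45.0
    high_scale: float = 7.0

    def __post_init__(self):
        if not (0 < self.plateau <= 1):
            raise ParameterError("plateau must be in (0, 1]")

    def efficiency(self, length) -> np.ndarray | float:
        length = np.asarray(length, dtype=float)
        eff = (self.plateau
               * expit((length - self.low_mid) / self.low_scale)
               * (1.0 - expit((length - self.high_mid) / self.high_scale)))
        return eff if eff.ndim else float(eff)

    def shifted(self, delta: float) -> "SizeSelectionCurve":
        return replace(self, low_mid=self.low_mid + delta,
                       high_mid=self.high_mid + delta)

    @classmethod
    def flat(cls) -> "SizeSelectionCurve":
        """No size selection: efficiency 1 at every length."""
        return cls(plateau=1.0, low_mid=-1e6, low_scale=1.0,
                   high_mid=1e6, high_scale=1.0)


@dataclass(frozen=True)
class BackgroundSpecies:
    id: str
    seq: str
    abundance: float
    cls: str


@dataclass(frozen=True)
class SpikeMix:
    """A spike-in set plus its mix composition and molar spiking fraction."""

    spike_set: SpikeInSet
    mix: MixSpec
    fraction: float

    def __post_init__(self):
        if not (0 < self.fraction <= 0.1):
            raise ParameterError("spiking fraction must be in (0, 0.1]")
        missing = set(self.mix.entries) - set(self.spike_set.ids)
        if missing:
            raise ParameterError(f"mix references unknown oligos: {missing}")


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one synthetic library."""

    background: tuple[BackgroundSpecies, ...]
    mixes: tuple[SpikeMix, ...]
    selection: SizeSelectionCurve
    depth: int
    error_rate: float = 0.005
    seed: int = 0
    label: str = "sim"

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ParameterError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class LibraryResult:
    reads: list[Read]
    truth: pd.DataFrame  # index: feature id; expected/realized/length/kind
    meta: dict


def make_background(n_species: int = 300,
                    class_mix: Mapping[str, float] | None = None,
                    sigma: float = 2.0,
                    seed: int = 0,
                    top10_share_range: tuple[float, float] | None = (0.3, 0.7),
                    max_regenerations: int = 50
                    ) -> tuple[BackgroundSpecies, ...]:
    """Generate a background small-RNA population.

    Abundances are log-normal with shape ``sigma``; at the default σ = 2 the
    population is regenerated (with an incremented sub-seed) until the ten
    most abundant species hold 30–70% of the total abundance, matching the
    concentration observed in real miRNA pools. Pass
    ``top10_share_range=None`` to disable the check (e.g. for σ → 0).
    """
    if n_species < 10:
        raise ParameterError("n_species must be >= 10")
    class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    unknown = set(class_mix) - set(_CLASS_PREFIX)
    if unknown:
        raise ParameterError(f"unknown background class(es): {unknown}")
    total = sum(class_mix.values())
    if total <= 0 or any(v < 0 for v in class_mix.values()):
        raise ParameterError("class_mix fractions must be >= 0, sum > 0")

    # largest-remainder apportionment of species counts to classes
    raw = {c: n_species * v / total for c, v in class_mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_species - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    for attempt in range(max_regenerations):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        species: list[BackgroundSpecies] = []
        for cls in sorted(counts):
            n_cls = counts[cls]
            if n_cls == 0:
                continue
            if cls == CLASS_MIRNA:
                lengths = np.clip(np.rint(rng.normal(22, 1.2, n_cls)),
                                  18, 26).astype(int)
            elif cls == CLASS_PIRNA:
                lengths = np.clip(np.rint(rng.normal(28, 1.5, n_cls)),
                                  25, 33).astype(int)
            else:
                lengths = rng.integers(15, 46, n_cls)
            abundances = rng.lognormal(0.0, sigma, n_cls)
            for k, (length, ab) in enumerate(zip(lengths, abundances)):
                seq = decode(rng.integers(0, 4, int(length)))
                species.append(BackgroundSpecies(
                    f"{_CLASS_PREFIX[cls]}-{k + 1:04d}", seq, float(ab), cls))
        if top10_share_range is None:
            return tuple(species)
        ab = np.array([s.abundance for s in species])
        share = np.sort(ab)[-10:].sum() / ab.sum()
        if top10_share_range[0] <= share <= top10_share_range[1]:
            return tuple(species)
    raise SimulationError(
        f"no background with top-10 share in {top10_share_range} "
        f"after {max_regenerations} regenerations")


def _mutate(seq_codes: np.ndarray, count: int, error_rate: float,
            rng: np.random.Generator) -> list[str]:
    """Emit *count* copies of a sequence with i.i.d. substitution errors."""
    length = seq_codes.shape[0]
    clean = decode(seq_codes)
    if error_rate == 0 or count == 0:
        return [clean] * count
    mask = rng.random((count, length)) < error_rate
    dirty_rows = np.nonzero(mask.any(axis=1))[0]
    out = [clean] * count
    for row in dirty_rows:
        codes = seq_codes.copy()
        pos = np.nonzero(mask[row])[0]
        codes[pos] = (codes[pos] + rng.integers(1, 4, pos.size)) % 4
        out[row] = decode(codes)
    return out


def simulate_library(scenario: SimScenario) -> LibraryResult:
    """Draw one sequencing library from a scenario.

    Reads are sampled multinomially with probability proportional to
    molar abundance × size-selection efficiency, then corrupted with
    substitution errors. The truth table records each feature's expected
    (pre-sampling) and realized read counts.
    """
    feats: list[tuple[str, str, str, float]] = []  # id, seq, kind, weight
    spike_total = sum(m.fraction for m in scenario.mixes)
    if spike_total >= 1:
        raise SimulationError("spiking fractions must sum to < 1")
    bg_ab = np.array([s.abundance for s in scenario.background], dtype=float)
    if len(scenario.background):
        bg_ab = bg_ab / bg_ab.sum() * (1.0 - spike_total)
        for s, w in zip(scenario.background, bg_ab):
            feats.append((s.id, s.seq, s.cls, w))
    for m in scenario.mixes:
        seqs = m.spike_set.sequences
        for oid, conc in m.mix.entries.items():
            feats.append((oid, seqs[oid], "spike", m.fraction * conc))
    if not feats:
        raise SimulationError("scenario has no features to sequence")

    ids = [f[0] for f in feats]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate feature ids across background/mixes")
    lengths = np.array([len(f[1]) for f in feats])
    weights = np.array([f[3] for f in feats])
    eff = np.asarray(scenario.selection.efficiency(lengths))
    w_eff = weights * eff
    if w_eff.sum() <= 0:
        raise SimulationError("size selection removed every feature")
    p = w_eff / w_eff.sum()

    rng = np.random.default_rng(scenario.seed)
    realized = rng.multinomial(scenario.depth, p)

    reads: list[Read] = []
    for (fid, seq, kind, _w), count in zip(feats, realized):
        if count == 0:
            continue
        seqs = _mutate(encode(seq), int(count), scenario.error_rate, rng)
        qual = "I" * len(seq)
        reads.extend(Read(f"{scenario.label}:{fid}:{k}", s, qual)
                     for k, s in enumerate(seqs))

    truth = pd.DataFrame({
        "kind": [f[2] for f in feats],
        "length": lengths,
        "expected": scenario.depth * p,
        "realized": realized,
    }, index=pd.Index(ids, name="feature_id"))
    meta = {
        "depth": scenario.depth,
        "error_rate": scenario.error_rate,
        "seed": scenario.seed,
        "spike_fraction_molar": spike_total,
    }
    return LibraryResult(reads, truth, meta)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive *n* independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


_child_seeds = child_seeds


def dilution_series_scenario(fold_change_set: SpikeInSet,
                             erdn_set: SpikeInSet,
                             background: tuple[BackgroundSpecies, ...],
                             n_mixes: int = 8,
                             fold_step: float = 2.0,
                             depth: int = 100_000,
                             depth_sigma: float = 0.0,
                             fc_fraction: float = 0.08,
                             erdn_fraction: float = 0.03,
                             selection: SizeSelectionCurve = SizeSelectionCurve(),
                             error_rate: float = 0.005,
                             seed: int = 0
                             ) -> tuple[list[SimScenario], pd.Series]:
    """Serial-dilution design: fold-change oligos halve per mix.

    The background and the ERDN ladder are identical across mixes; only the
    fold-change mix is diluted by ``fold_step`` from one mix to the next,
    and per-library depths are scaled by log-normal factors of shape
    ``depth_sigma``. Returns the scenarios (samples ``mix1`` … ``mixN``) and
    the true log2 relative input per mix (0, −1, …).
    """
    if n_mixes < 2:
        raise ParameterError("need >= 2 dilution mixes")
    if fold_step < 1:
        raise ParameterError("fold_step must be >= 1")
    erdn_mix = SpikeMix(erdn_set, ladder_mix(erdn_set), erdn_fraction)
    fc_equi = MixSpec.from_weights({o.id: 1.0 for o in fold_change_set})
    rng = np.random.default_rng(seed)
    depth_factors = np.exp(rng.normal(0.0, depth_sigma, n_mixes)) \
        if depth_sigma > 0 else np.ones(n_mixes)
    seeds = _child_seeds(seed, n_mixes)
    scenarios = []
    for k in range(n_mixes):
        fc_mix = SpikeMix(fold_change_set, fc_equi,
                          fc_fraction * fold_step ** (-k))
        scenarios.append(SimScenario(
            background=background,
            mixes=(erdn_mix, fc_mix),
            selection=selection,
            depth=max(1, int(round(depth * depth_factors[k]))),
            error_rate=error_rate,
            seed=seeds[k],
            label=f"mix{k + 1}",
        ))
    log2_input = pd.Series(
        {f"mix{k + 1}": -k * np.log2(fold_step) for k in range(n_mixes)})
    return scenarios, log2_input


@dataclass(frozen=True)
class GlobalShiftDesign:
    scenarios: dict[str, SimScenario]
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    true_log2_mirna_shift: float
    mirna_refs: dict[str, str]
    pirna_refs: dict[str, str]


def global_shift_scenario(mirna_fraction_a: float = 0.10,
                          mirna_fraction_b: float = 0.29,
                          n_per_group: int = 4,
                          background: tuple[BackgroundSpecies, ...] | None = None,
                          mixes: Sequence[SpikeMix] = (),
                          depth: int = 80_000,
                          selection: SizeSelectionCurve = SizeSelectionCurve(),
                          error_rate: float = 0.005,
                          seed: int = 0) -> GlobalShiftDesign:
    """Two sample groups differing only in global miRNA content.

    Both groups share the same species and the same per-µg piRNA/other
    abundance; the miRNA class is rescaled per group so that the *expected*
    fraction of reads mapping to miRNA equals the requested targets (e.g.
    10% vs 29%) at a fixed per-µg spike-in amount. The per-µg rescaling
    implies a true global miRNA log2 shift (group B over group A) that
    spike-anchored normalization should recover and total-count
    normalization should erase.
    """
    for f in (mirna_fraction_a, mirna_fraction_b):
        if not (0 < f < 1):
            raise ParameterError("miRNA read fractions must be in (0, 1)")
    if background is None:
        background = make_background(seed=seed)
    if not mixes:
        raise ParameterError("at least one spike mix is required")

    eff = {s.id: float(selection.efficiency(len(s.seq))) for s in background}
    ab = {s.id: s.abundance for s in background}
    ab_total = sum(ab.values())
    spike_frac = sum(m.fraction for m in mixes)
    bg_molar = {s.id: (1 - spike_frac) * ab[s.id] / ab_total
                for s in background}

    m_eff = sum(bg_molar[s.id] * eff[s.id] for s in background
                if s.cls == CLASS_MIRNA)
    rest_eff = sum(bg_molar[s.id] * eff[s.id] for s in background
                   if s.cls != CLASS_MIRNA)
    for m in mixes:
        seqs = m.spike_set.sequences
        rest_eff += sum(
            m.fraction * conc * float(selection.efficiency(len(seqs[oid])))
            for oid, conc in m.mix.entries.items())
    if m_eff <= 0:
        raise ParameterError("background has no miRNA-like species")

    def solve_x(f: float) -> float:
        return f * rest_eff / ((1 - f) * m_eff)

    x = {"a": solve_x(mirna_fraction_a), "b": solve_x(mirna_fraction_b)}

    mirna_molar = sum(bg_molar[s.id] for s in background
                      if s.cls == CLASS_MIRNA)
    rest_molar = (1 - spike_frac) - mirna_molar

    scenarios: dict[str, SimScenario] = {}
    groups: dict[str, tuple[str, ...]] = {}
    seeds = _child_seeds(seed, 2 * n_per_group)
    for gi, g in enumerate(("a", "b")):
        # total molar per µg after rescaling the miRNA class
        total_g = spike_frac + x[g] * mirna_molar + rest_molar
        bg_g = tuple(
            replace(s, abundance=s.abundance * (x[g] if s.cls == CLASS_MIRNA
                                                else 1.0))
            for s in background)
        mixes_g = tuple(replace(m, fraction=m.fraction / total_g)
                        for m in mixes)
        names = []
        for r in range(n_per_group):
            name = f"{g}{r + 1}"
            names.append(name)
            scenarios[name] = SimScenario(
                background=bg_g, mixes=mixes_g, selection=selection,
                depth=depth, error_rate=error_rate,
                seed=seeds[gi * n_per_group + r], label=name)
        groups[g] = tuple(names)

    return GlobalShiftDesign(
        scenarios=scenarios,
        group_a=groups["a"],
        group_b=groups["b"],
        true_log2_mirna_shift=float(np.log2(x["b"] / x["a"])),
        mirna_refs={s.id: s.seq for s in background if s.cls == CLASS_MIRNA},
        pirna_refs={s.id: s.seq for s in background if s.cls == CLASS_PIRNA},
    )
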