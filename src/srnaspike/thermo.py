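"""Minimum hairpin folding free energy of short RNAs at 37 °C.

The spike-in designer rejects candidate oligoribonucleotides that can fold
back on themselves: a sequence is kept only if its most stable hairpin is
weaker (less negative) than a free-energy cutoff (default −0.5 kcal/mol).
For that pass/fail decision a full secondary-structure partition function is
unnecessary; this module scores every *single* hairpin — a contiguous stem of
Watson–Crick or G·U pairs closed by a loop of at least three unpaired bases —
with a nearest-neighbor model:

    ΔG(hairpin) = Σ stack energies + loop initiation penalty
                  + terminal A·U/G·U penalty (outer helix end)

and returns the minimum over all stem/loop placements, or 0 (the unfolded
reference state) if no hairpin is formable or none is stabilizing.

Bulges, internal loops and multiloops are not modeled; every modeled
structure is also a legal structure in a full folding model, so the scan can
only under-call (never over-call) hairpin stability, which is the
conservative direction for a rejection filter whose threshold is
configurable.

The parameter table ships as a plain-text file (``data/rna_nn_params.tsv``)
and can be overridden via :func:`NNParameters.from_file`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

from ._seq import encode, validate_rna
from .exceptions import ParameterError

# Jacobson–Stockmayer loop-size extrapolation coefficient:
# 1.75 * R * T with R = 1.9872e-3 kcal/(mol*K), T = 310.15 K.
_JS_COEFF = 1.75 * 1.9872e-3 * 310.15

_MAX_LOOP = 512

# Base codes (A=0, C=1, G=2, U=3); allowed pairs include the G*U wobble.
_PAIRS = ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2))
_WOBBLE = {(2, 3), (3, 2)}
_AU_OR_GU = {(0, 3), (3, 0), (2, 3), (3, 2)}


@dataclass(frozen=True)
class NNParameters:
    """Nearest-neighbor energy table for the hairpin scan.

    Attributes
    ----------
    stack_energies
        Mapping ``"XY/ZW"`` → kcal/mol for the stack 5'XY3'/3'ZW5'
        (outer pair X·Z, inner pair Y·W). Symmetric rotations are filled in
        at load time.
    loop_penalty
        Hairpin-loop initiation penalty by loop size (≥ 3), kcal/mol.
    terminal_au_penalty
        Penalty applied when the outer helix end is closed by A·U or G·U.
    default_wobble
        Fallback energy for wobble-containing stacks absent from the table.
    """

    stack_energies: dict[str, float]
    loop_penalty: dict[int, float]
    terminal_au_penalty: float
    default_wobble: float = -0.5

    def __post_init__(self):
        if any(size < 3 for size in self.loop_penalty):
            raise ParameterError("hairpin loops smaller than 3 are disallowed")
        if any(pen <= 0 for pen in self.loop_penalty.values()):
            raise ParameterError("loop penalties must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "NNParameters":
        stacks: dict[str, float] = {}
        loops: dict[int, float] = {}
        terminal = 0.45
        default_wobble = -0.5
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                section, key, value = line.split("\t")
                if section == "stack":
                    stacks[key] = float(value)
                elif section == "loop":
                    loops[int(key)] = float(value)
                elif section == "terminal_au":
                    terminal = float(value)
                elif section == "default_wobble":
                    default_wobble = float(value)
                else:
                    raise ParameterError(f"unknown section {section!r} in {path}")
        # fill duplex-rotation symmetry: 5'XY/3'ZW == 5'WZ/3'YX
        for key, e in list(stacks.items()):
            x, y, _, z, w = key
            sym = f"{w}{z}/{y}{x}"
            stacks.setdefault(sym, e)
        return cls(stacks, loops, terminal, default_wobble)

    @classmethod
    def default(cls) -> "NNParameters":
        global _DEFAULT
        if _DEFAULT is None:
            with resources.as_file(
                resources.files("srnaspike.data") / "rna_nn_params.tsv"
            ) as p:
                _DEFAULT = cls.from_file(p)
        return _DEFAULT

    def loop_energy(self, size: int) -> float:
        """Loop initiation penalty, extrapolated beyond the tabled sizes."""
        if size < 3:
            raise ParameterError("hairpin loop must have >= 3 unpaired bases")
        if size in self.loop_penalty:
            return self.loop_penalty[size]
        largest = max(self.loop_penalty)
        return self.loop_penalty[largest] + _JS_COEFF * np.log(size / largest)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Dense arrays for the numba kernel (cached on the instance)."""
        cached = _ARRAY_CACHE.get(id(self))
        if cached is not None:
            return cached
        stack = np.full((5, 5, 5, 5), np.inf)
        bases = "ACGU"
        for a, b in _PAIRS:
            for c, d in _PAIRS:
                key = f"{bases[a]}{bases[c]}/{bases[b]}{bases[d]}"
                if key in self.stack_energies:
                    e = self.stack_energies[key]
                elif (a, b) in _WOBBLE or (c, d) in _WOBBLE:
                    e = self.default_wobble
                else:  # pragma: no cover - table ships complete WC set
                    raise ParameterError(f"missing Watson-Crick stack {key}")
                stack[a, c, b, d] = e
        loops = np.array([self.loop_energy(s) if s >= 3 else np.inf
                          for s in range(_MAX_LOOP)])
        _ARRAY_CACHE[id(self)] = (stack, loops, self.terminal_au_penalty)
        return _ARRAY_CACHE[id(self)]


_DEFAULT: NNParameters | None = None
_ARRAY_CACHE: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}


@njit(cache=True)
def _pairable(a, b):
    return ((a == 0 and b == 3) or (a == 3 and b == 0)
            or (a == 1 and b == 2) or (a == 2 and b == 1)
            or (a == 2 and b == 3) or (a == 3 and b == 2))


@njit(cache=True)
def _scan_hairpins(x, stack, loops, term_au):
    """Minimum energy over all single hairpins; 0 if none stabilizes."""
    n = x.shape[0]
    best = 0.0
    for i in range(n - 6):
        for j in range(i + 6, n):
            if not _pairable(x[i], x[j]):
                continue
            eterm = 0.0
            ai, aj = x[i], x[j]
            if (ai == 0 and aj == 3) or (ai == 3 and aj == 0) \
               or (ai == 2 and aj == 3) or (ai == 3 and aj == 2):
                eterm = term_au
            stacksum = 0.0
            s = 1
            while True:
                # candidate next pair (i+s, j-s), keeping loop >= 3
                if j - i - (2 * (s + 1) - 1) < 3:
                    break
                if not _pairable(x[i + s], x[j - s]):
                    break
                stacksum += stack[x[i + s - 1], x[i + s], x[j - s + 1], x[j - s]]
                s += 1
                loop_size = j - i - (2 * s - 1)
                e = stacksum + loops[loop_size] + eterm
                if e < best:
                    best = e
    return best


def min_hairpin_dG(seq: str, params: NNParameters | None = None) -> float:
    """Minimum single-hairpin folding free energy (kcal/mol, 37 °C).

    Sequences shorter than 8 nt cannot form a stem-2/loop-3 hairpin and
    return 0 by convention. A return value of 0 means the unfolded state is
    the most stable modeled state.
    """
    validate_rna(seq)
    if len(seq) < 8:
        return 0.0
    if params is None:
        params = NNParameters.default()
    stack, loops, term_au = params._arrays()
    return float(_scan_hairpins(encode(seq), stack, loops, term_au))
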