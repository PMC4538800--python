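"""Independent reference implementations used only to check the package.

These deliberately re-derive results through different formulations than the
production code: the alignment oracle is a backward recursion over all
alignment paths (with an additional plain path-enumeration variant for tiny
cases to validate the recursion itself), and the hairpin oracle enumerates
stem/loop placements with direct string-keyed dictionary lookups.
"""

from __future__ import annotations

from functools import lru_cache

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
          ("G", "U"), ("U", "G")}
_AU_GU = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def oracle_fit_score(read: str, target: str, mismatch: float = -6.0,
                     gap_open: float = -5.0, gap_extend: float = -3.0
                     ) -> float:
    """Optimal fitting-alignment score by recursion over all alignments.

    The read is consumed end-to-end; the target contributes a contiguous
    substring (both its ends are free). A gap of length g costs
    gap_open + g * gap_extend.
    """
    m, n = len(read), len(target)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == m:
            return 0.0  # remaining target is a free suffix
        best = float("-inf")
        if j < n:
            sub = 0.0 if read[i] == target[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1, "M"))
            del_cost = gap_extend if state == "Y" else gap_open + gap_extend
            best = max(best, del_cost + rec(i, j + 1, "Y"))
        ins_cost = gap_extend if state == "X" else gap_open + gap_extend
        best = max(best, ins_cost + rec(i + 1, j, "X"))
        return best

    return max(rec(0, j, "M") for j in range(n + 1))


def enumerate_fit_score(read: str, target: str, mismatch: float = -6.0,
                        gap_open: float = -5.0, gap_extend: float = -3.0
                        ) -> float:
    """Plain enumeration of every alignment path (tiny inputs only)."""
    m, n = len(read), len(target)
    best = [float("-inf")]

    def walk(i: int, j: int, state: str, score: float) -> None:
        if i == m:
            best[0] = max(best[0], score)
            return
        if j < n:
            sub = 0.0 if read[i] == target[j] else mismatch
            walk(i + 1, j + 1, "M", score + sub)
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            walk(i, j + 1, "Y", score + cost)
        cost = gap_extend if state == "X" else gap_open + gap_extend
        walk(i + 1, j, "X", score + cost)

    for start in range(n + 1):
        walk(0, start, "M", 0.0)
    return best[0]


def oracle_min_hairpin(seq: str, params) -> float:
    """Exhaustive stem/loop enumeration with the same parameter table."""
    n = len(seq)
    best = 0.0
    for i in range(n):
        for j in range(i + 6, n):
            if (seq[i], seq[j]) not in _PAIRS:
                continue
            term = params.terminal_au_penalty \
                if (seq[i], seq[j]) in _AU_GU else 0.0
            s = 2
            while j - i - (2 * s - 1) >= 3:
                if any((seq[i + t], seq[j - t]) not in _PAIRS
                       for t in range(s)):
                    break
                e = term + params.loop_energy(j - i - (2 * s - 1))
                for t in range(s - 1):
                    key = (f"{seq[i + t]}{seq[i + t + 1]}/"
                           f"{seq[j - t]}{seq[j - t - 1]}")
                    if key in params.stack_energies:
                        e += params.stack_energies[key]
                    else:
                        e += params.default_wobble
                best = min(best, e)
                s += 1
    return best
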