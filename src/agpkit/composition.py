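"""Amino-acid composition metrics used as classification gates.

The defining compositional bias of an AGP backbone is its PAST content —
the fraction of residues that are Pro, Ala, Ser or Thr.  PVKCYT content
(Pro, Val, Lys, Cys, Tyr, Thr) is the analogous bias reported for
extensin-leaning backbones.  A windowed Lys-density scan flags the Lys-rich
insert that distinguishes Lys-rich classical AGPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

PAST_RESIDUES = frozenset("PAST")
PVKCYT_RESIDUES = frozenset("PVKCYT")


def _fraction(sequence: str, residues: frozenset[str]) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    # 'X' (unknown) counts in the denominator only.
    return sum(1 for c in sequence if c in residues) / len(sequence)


def past_fraction(sequence: str) -> float:
    """Fraction of residues that are P, A, S or T."""
    return _fraction(sequence, PAST_RESIDUES)


def pvkcyt_fraction(sequence: str) -> float:
    """Fraction of residues that are P, V, K, C, Y or T."""
    return _fraction(sequence, PVKCYT_RESIDUES)


@dataclass(frozen=True)
class LysRichRegion:
    """A contiguous Lys-dense segment (1-based inclusive coordinates)."""

    start: int
    end: int
    lys_fraction: float


def detect_lys_rich(
    sequence: str,
    window_len: int = 15,
    min_lys_fraction: float = 0.30,
) -> Optional[LysRichRegion]:
    """Find the densest Lys-rich window, greedily extended.

    Scans all windows of length ``window_len``; among those whose K fraction
    is at least ``min_lys_fraction`` the one with the most lysines wins (ties
    to the leftmost).  That seed window is then extended one residue at a
    time, rightward then leftward, as long as the K fraction of the extended
    region stays at or above the threshold.  Returns ``None`` when no window
    qualifies (including sequences shorter than the window).

    The quantitative rule (window 15, >= 30% K) is this package's own
    operational definition — the literature describes Lys-rich AGPs only
    qualitatively — so both knobs are parameters.
    """
    if window_len < 5:
        raise ValueError("window_len must be >= 5")
    n = len(sequence)
    if n < window_len:
        return None
    is_k = [1 if c == "K" else 0 for c in sequence]
    prefix = [0]
    for v in is_k:
        prefix.append(prefix[-1] + v)

    def k_count(i: int, j: int) -> int:  # 0-based half-open
        return prefix[j] - prefix[i]

    best_i, best_k = -1, -1
    for i in range(n - window_len + 1):
        k = k_count(i, i + window_len)
        if k / window_len >= min_lys_fraction and k > best_k:
            best_i, best_k = i, k
    if best_i < 0:
        return None

    lo, hi = best_i, best_i + window_len  # 0-based half-open
    while hi < n and k_count(lo, hi + 1) / (hi + 1 - lo) >= min_lys_fraction:
        hi += 1
    while lo > 0 and k_count(lo - 1, hi) / (hi - lo + 1) >= min_lys_fraction:
        lo -= 1
    return LysRichRegion(start=lo + 1, end=hi, lys_fraction=k_count(lo, hi) / (hi - lo))


@dataclass(frozen=True)
class CompositionProfile:
    length: int
    past_fraction: float
    pvkcyt_fraction: float
    lys_rich_region: Optional[LysRichRegion] = None


def composition_profile(
    sequence: str,
    window_len: int = 15,
    min_lys_fraction: float = 0.30,
) -> CompositionProfile:
    return CompositionProfile(
        length=len(sequence),
        past_fraction=past_fraction(sequence),
        pvkcyt_fraction=pvkcyt_fraction(sequence),
        lys_rich_region=detect_lys_rich(sequence, window_len, min_lys_fraction),
    )
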