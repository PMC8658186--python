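"""Sequence-motif scanners for AGP identification.

Four motif families drive the classification:

* arabinosylation glycomodules — contiguous hydroxyproline stretches,
  ``[A/S/T/G]-P(2-4)``;
* galactosylation glycomodules — non-contiguous pairs, ``[A/S/T/G]-P``
  followed within a bounded spacer by another ``[A/S/T/G]-P`` (the two
  prolines separated by at most 11 residues);
* extensin SP(3-5) repeats, the hallmark of AGP/extensin hybrids;
* the eight-cysteine motif C1-X-C2-X-C3C4-X-C5-[L/I/V]-C6-X-C7-X-C8 that
  distinguishes xylogen-like proteins (XYLPs) among nsLTP2-domain proteins.

All coordinates are 1-based inclusive.  Arabinosylation and SP-repeat
scanning is leftmost, non-overlapping, maximal-munch (capped at 4 and 5
prolines respectively); galactosylation pairs chain consecutive dipeptide
occurrences only, so counts stay linear in occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class GlycoKind(str, Enum):
    ARABINOSYLATION = "ARABINOSYLATION"
    GALACTOSYLATION = "GALACTOSYLATION"


@dataclass(frozen=True)
class GlycomoduleHit:
    kind: GlycoKind
    start: int  # 1-based inclusive
    end: int
    matched: str


@dataclass(frozen=True)
class ExtMotifHit:
    n_pro: int
    start: int
    end: int


@dataclass(frozen=True)
class EightCysMotif:
    cys_positions: tuple[int, ...]
    hydrophobic_residue: str
    hydrophobic_position: int


_ARAB_RE = re.compile(r"[ASTG]P{2,4}")
_AGP_DIPEP_RE = re.compile(r"(?=([ASTG]P))")
_EXT_RE = re.compile(r"SP{3,5}")

#: Maximum number of residues allowed between the two prolines of a
#: galactosylation pair ("two consecutive Pros are not separated by more
#: than 11 amino acid residues").
GALACTOSYLATION_MAX_PRO_GAP = 11


def scan_arabinosylation(sequence: str) -> list[GlycomoduleHit]:
    """All non-overlapping ``[ASTG]P{2,4}`` matches, left to right."""
    return [
        GlycomoduleHit(GlycoKind.ARABINOSYLATION, m.start() + 1, m.end(), m.group())
        for m in _ARAB_RE.finditer(sequence)
    ]


def scan_galactosylation(
    sequence: str,
    max_pro_gap: int = GALACTOSYLATION_MAX_PRO_GAP,
) -> list[GlycomoduleHit]:
    """Pairs of consecutive ``[ASTG]P`` dipeptides within the proline gap bound.

    All dipeptide occurrences (overlapping allowed) are located first; a hit
    is emitted for each consecutive pair whose prolines are separated by at
    most ``max_pro_gap`` residues.  The hit spans the first dipeptide's start
    through the second's end.
    """
    starts = [m.start(1) for m in _AGP_DIPEP_RE.finditer(sequence)]
    hits = []
    for a, b in zip(starts, starts[1:]):
        p1, p2 = a + 1, b + 1  # 0-based proline positions
        if p2 - p1 - 1 <= max_pro_gap:
            hits.append(
                GlycomoduleHit(
                    GlycoKind.GALACTOSYLATION,
                    start=a + 1,
                    end=b + 2,
                    matched=sequence[a:b + 2],
                )
            )
    return hits


def has_ag_glycomodules(
    sequence: str,
    min_hits: int = 2,
    region: Optional[tuple[int, int]] = None,
) -> tuple[bool, list[GlycomoduleHit]]:
    """Whether the sequence (or a 1-based inclusive region of it) carries at
    least ``min_hits`` AG glycomodules of either kind."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    hits = scan_arabinosylation(sequence) + scan_galactosylation(sequence)
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= len(sequence)):
            raise ValueError(f"region {region} outside sequence of length {len(sequence)}")
        hits = [h for h in hits if h.start >= lo and h.end <= hi]
    hits.sort(key=lambda h: (h.start, h.end))
    return len(hits) >= min_hits, hits


def scan_ext_repeats(sequence: str) -> list[ExtMotifHit]:
    """All non-overlapping extensin Ser-Pro(3-5) repeats, maximal munch."""
    return [
        ExtMotifHit(n_pro=m.end() - m.start() - 1, start=m.start() + 1, end=m.end())
        for m in _EXT_RE.finditer(sequence)
    ]


def scan_eight_cys(
    sequence: str,
    min_gap: int = 1,
    max_gap: int = 60,
) -> Optional[EightCysMotif]:
    """Leftmost assignment of eight cysteines to the conserved motif.

    Spacer gaps (residues strictly between consecutive assigned cysteines)
    must lie in ``[min_gap, max_gap]`` for the C1-C2, C2-C3, C4-C5, C6-C7 and
    C7-C8 intervals; C3 and C4 are adjacent; exactly one residue sits between
    C5 and C6 and it must be Leu, Ile or Val.  Spacers may contain further
    cysteines — the motif is an assignment over a subset.  Returns the
    lexicographically smallest (leftmost) assignment, or ``None``.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    cys = [i for i, c in enumerate(sequence) if c == "C"]  # 0-based
    n = len(cys)
    if n < 8:
        return None

    # gap constraint between consecutive motif cysteines, by slot index:
    # slot k is the interval between assigned cysteine k and k+1 (0-based).
    def gap_ok(k: int, p: int, q: int) -> bool:
        gap = q - p - 1
        if k == 2:            # C3-C4 adjacent
            return gap == 0
        if k == 4:            # C5-x-C6 with x hydrophobic
            return gap == 1 and sequence[p + 1] in "LIV"
        return min_gap <= gap <= max_gap

    assignment: list[int] = []

    def search(slot: int, from_idx: int) -> bool:
        if slot == 8:
            return True
        for idx in range(from_idx, n):
            p = cys[idx]
            if slot > 0:
                if not gap_ok(slot - 1, assignment[-1], p):
                    # positions are ascending: once past max_gap, stop
                    if slot - 1 not in (2, 4) and p - assignment[-1] - 1 > max_gap:
                        break
                    continue
            assignment.append(p)
            if search(slot + 1, idx + 1):
                return True
            assignment.pop()
        return False

    if not search(0, 0):
        return None
    positions = tuple(p + 1 for p in assignment)
    hyd_pos = assignment[4] + 2  # residue between C5 and C6, 1-based
    return EightCysMotif(
        cys_positions=positions,
        hydrophobic_residue=sequence[hyd_pos - 1],
        hydrophobic_position=hyd_pos,
    )
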