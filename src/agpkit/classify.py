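"""The AGP subfamily decision tree.

Each protein is assigned to exactly one of nine AGP subfamilies or rejected
(``NOT_AGP``), with a full evidence trail.  Rules are evaluated in a fixed
order, first match wins, mirroring the screening order of the underlying
workflow (chimeric candidates, hybrids and AG-peptides are removed before
classical AGPs are considered):

1. domain-bearing (chimeric) path — a recognised conserved domain plus AG
   glycomodules: FAS -> FLA, PCNL -> PLA, nsLTP2 -> XYLP when the
   eight-cysteine motif is present (else other chimeric), anything else ->
   other chimeric; a chimeric protein that additionally carries two or more
   extensin SP(3-5) repeats becomes a chimeric AGP/extensin hybrid (CHAE);
2. HAE — no domain, PAST >= 50%, glycomodules, and >= 2 SP(3-5) repeats;
3. AG-peptide — 50-90 aa, PAST >= 35%, glycomodules, signal peptide;
4. classical — PAST > 50%, glycomodules, signal peptide; a detected
   Lys-rich insert refines the label to Lys-rich classical;
5. non-classical — PAST >= 50% with glycomodules but failing a classical
   gate (no signal peptide, or PAST exactly at the threshold under the
   strict comparison);
6. otherwise NOT_AGP.

A GPI anchor is recorded as supporting evidence but is never a hard filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .composition import CompositionProfile, composition_profile
from .io_formats import AnnotationRecord, DomainCall, DomainName, ProteinRecord
from .motif_scan import (
    EightCysMotif,
    ExtMotifHit,
    GlycomoduleHit,
    has_ag_glycomodules,
    scan_eight_cys,
    scan_ext_repeats,
)

logger = logging.getLogger(__name__)


class Subfamily(str, Enum):
    CLASSICAL = "CLASSICAL"
    LYS_RICH = "LYS_RICH"
    AG_PEPTIDE = "AG_PEPTIDE"
    NON_CLASSICAL = "NON_CLASSICAL"
    FLA = "FLA"
    PLA = "PLA"
    XYLP = "XYLP"
    OTHER_CAGP = "OTHER_CAGP"
    CHAE = "CHAE"
    HAE = "HAE"
    NOT_AGP = "NOT_AGP"


#: Chimeric routing priority: the first domain class found decides the label.
_CHIMERIC_PRIORITY = (DomainName.FAS, DomainName.PCNL, DomainName.NSLTP2)


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the decision tree.

    ``past_classical`` is compared strictly (``>``) for the classical gate by
    default; proteins sitting exactly at the threshold are routed to
    non-classical.  Set ``classical_strict=False`` to use ``>=``.
    """

    past_classical: float = 0.50
    past_agpeptide: float = 0.35
    agpeptide_len: tuple[int, int] = (50, 90)   # inclusive
    min_glyco_hits: int = 2
    ext_min_repeats: int = 2
    require_signal_classical: bool = True
    require_signal_agpeptide: bool = True
    classical_strict: bool = True
    lys_window_len: int = 15
    lys_min_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0 < self.past_agpeptide <= self.past_classical < 1):
            raise ValueError("require 0 < past_agpeptide <= past_classical < 1")


@dataclass(frozen=True)
class Evidence:
    profile: CompositionProfile
    glyco_hits: tuple[GlycomoduleHit, ...]
    ext_repeats: tuple[ExtMotifHit, ...]
    eight_cys: Optional[EightCysMotif]
    domains: tuple[DomainCall, ...]
    has_signal_peptide: bool
    has_gpi_anchor: bool

    @property
    def n_glyco_hits(self) -> int:
        return len(self.glyco_hits)

    @property
    def n_ext_repeats(self) -> int:
        return len(self.ext_repeats)


@dataclass(frozen=True)
class Classification:
    protein_id: str
    subfamily: Subfamily
    evidence: Evidence
    notes: tuple[str, ...] = ()


def classify_protein(
    record: ProteinRecord,
    annotation: AnnotationRecord,
    params: ClassifyParams = ClassifyParams(),
) -> Classification:
    """Assign one protein to a subfamily with an evidence trail."""
    if annotation.protein_id != record.id:
        raise ValueError(
            f"annotation id {annotation.protein_id!r} does not match record {record.id!r}"
        )
    for dom in annotation.domains:
        if dom.end > len(record.sequence):
            raise ValueError(
                f"{record.id}: domain {dom.name.value} end {dom.end} beyond "
                f"sequence length {len(record.sequence)}"
            )

    seq = record.sequence
    profile = composition_profile(seq, params.lys_window_len, params.lys_min_fraction)
    glyco_ok, glyco_hits = has_ag_glycomodules(seq, min_hits=params.min_glyco_hits)
    ext_hits = scan_ext_repeats(seq)
    eight_cys = scan_eight_cys(seq)
    evidence = Evidence(
        profile=profile,
        glyco_hits=tuple(glyco_hits),
        ext_repeats=tuple(ext_hits),
        eight_cys=eight_cys,
        domains=annotation.domains,
        has_signal_peptide=annotation.has_signal_peptide,
        has_gpi_anchor=annotation.has_gpi_anchor,
    )
    notes: list[str] = []

    def result(subfamily: Subfamily) -> Classification:
        if annotation.has_gpi_anchor and subfamily is not Subfamily.NOT_AGP:
            notes.append("GPI anchor present (supporting evidence)")
        return Classification(record.id, subfamily, evidence, tuple(notes))

    past = profile.past_fraction
    ext_ok = len(ext_hits) >= params.ext_min_repeats

    # (1) chimeric path
    if annotation.domains:
        if glyco_ok:
            label = Subfamily.OTHER_CAGP
            for wanted in _CHIMERIC_PRIORITY:
                match = next((d for d in annotation.domains if d.name is wanted), None)
                if match is None:
                    continue
                if wanted is DomainName.FAS:
                    label = Subfamily.FLA
                elif wanted is DomainName.PCNL:
                    label = Subfamily.PLA
                else:  # nsLTP2: eight-cys motif decides XYLP vs other chimeric
                    if eight_cys is not None:
                        label = Subfamily.XYLP
                    else:
                        notes.append("nsLTP2 domain without eight-cysteine motif")
                        label = Subfamily.OTHER_CAGP
                break
            notes.insert(0, f"conserved domain + glycomodules -> {label.value}")
            if ext_ok:
                notes.append(
                    f"{len(ext_hits)} SP3-5 repeats: chimeric AGP/extensin hybrid"
                )
                label = Subfamily.CHAE
            return result(label)
        notes.append("conserved domain but no AG glycomodules")
    # (2) HAE
    elif past >= params.past_classical and glyco_ok and ext_ok:
        notes.append("high PAST + glycomodules + SP3-5 repeats -> AGP/extensin hybrid")
        return result(Subfamily.HAE)

    if not annotation.domains:
        # (3) AG-peptide
        lo, hi = params.agpeptide_len
        if (
            lo <= len(seq) <= hi
            and past >= params.past_agpeptide
            and glyco_ok
            and (annotation.has_signal_peptide or not params.require_signal_agpeptide)
        ):
            notes.append(f"length {len(seq)} in [{lo},{hi}], PAST {past:.2f} -> AG-peptide")
            return result(Subfamily.AG_PEPTIDE)

        classical_past_ok = (
            past > params.past_classical if params.classical_strict
            else past >= params.past_classical
        )
        signal_ok = annotation.has_signal_peptide or not params.require_signal_classical
        # (4) classical / Lys-rich
        if classical_past_ok and glyco_ok and signal_ok:
            if profile.lys_rich_region is not None:
                r = profile.lys_rich_region
                notes.append(
                    f"Lys-rich region {r.start}-{r.end} ({r.lys_fraction:.0%} K)"
                )
                return result(Subfamily.LYS_RICH)
            notes.append(f"PAST {past:.2f} > {params.past_classical:.2f} -> classical")
            return result(Subfamily.CLASSICAL)
        # (5) non-classical
        if past >= params.past_classical and glyco_ok:
            if not signal_ok or not annotation.has_signal_peptide:
                notes.append("classical gate failed: no signal peptide")
            if not classical_past_ok:
                notes.append("classical gate failed: PAST exactly at threshold")
            return result(Subfamily.NON_CLASSICAL)

    # (6)
    notes.append("no rule matched")
    return result(Subfamily.NOT_AGP)


def classify_proteome(
    records: Sequence[ProteinRecord],
    annotations: Iterable[AnnotationRecord],
    params: ClassifyParams = ClassifyParams(),
) -> list[Classification]:
    """Classify every record; missing annotations default to all-absent."""
    by_id: dict[str, AnnotationRecord] = {}
    for ann in annotations:
        if ann.protein_id in by_id:
            raise ValueError(f"duplicate annotation for {ann.protein_id!r}")
        by_id[ann.protein_id] = ann
    out = []
    for rec in records:
        ann = by_id.get(rec.id)
        if ann is None:
            logger.warning("no annotation for %s; treating features as absent", rec.id)
            ann = AnnotationRecord(protein_id=rec.id)
        out.append(classify_protein(rec, ann, params))
    return out


def summarize_subfamilies(
    classifications: Iterable[Classification | Subfamily],
) -> tuple[dict[Subfamily, int], int]:
    """Counts per AGP subfamily (NOT_AGP excluded) and the family total."""
    counts = {s: 0 for s in Subfamily if s is not Subfamily.NOT_AGP}
    for c in classifications:
        sub = c if isinstance(c, Subfamily) else c.subfamily
        if sub is not Subfamily.NOT_AGP:
            counts[sub] += 1
    return counts, sum(counts.values())
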