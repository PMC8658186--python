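"""Domain types and file formats.

Every downstream module consumes only the types defined here.  External
formats are deliberately minimal and text-based: protein FASTA, and a family
of tab-separated tables (UTF-8, ``#`` comment lines ignored, mandatory header
row).  All sequence coordinates are 1-based and inclusive, matching the
convention biologists use for protein positions; every writer emits them that
way and every reader expects them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_AA_RE = re.compile(r"^[A-Z]+$")


class DomainName(str, Enum):
    """Conserved domains recognised by the chimeric-AGP decision path."""

    FAS = "FAS"          # fasciclin -> FLA subfamily
    PCNL = "PCNL"        # plastocyanin-like -> PLA subfamily
    NSLTP2 = "nsLTP2"    # non-specific lipid transfer protein 2 -> XYLP
    PKINASE = "PKinase"
    GH = "GH"
    FH2 = "FH2"
    GDPD = "GDPD"
    POEI = "POeI"
    LRR = "LRR"
    X8 = "X8"
    PMEI = "PMEI"
    OTHER = "OTHER"


_DOMAIN_BY_UPPER = {d.value.upper(): d for d in DomainName}


class Subgenome(str, Enum):
    """Brassica rapa subgenomes left by whole-genome triplication."""

    LF = "LF"      # least fractionated
    MF1 = "MF1"    # medium fractionated
    MF2 = "MF2"    # most fractionated
    NONE = "NONE"


class Genotype(str, Enum):
    A_STERILE = "sterile"
    B_FERTILE = "fertile"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein core backbone: unique id plus amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if not _AA_RE.match(self.sequence):
            bad = next(i for i, c in enumerate(self.sequence) if not c.isalpha() or not c.isupper())
            raise ValueError(
                f"{self.id}: non-letter character {self.sequence[bad]!r} at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainCall:
    """A conserved-domain prediction with 1-based inclusive coordinates."""

    name: DomainName
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain coordinates {self.start}-{self.end}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Externally predicted features for one protein.

    Stands in for the outputs of signal-peptide, GPI-anchor, N-glycosylation
    and domain predictors, which the pipeline consumes but never runs.
    """

    protein_id: str
    has_signal_peptide: bool = False
    has_gpi_anchor: bool = False
    n_glyc_site_count: int = 0
    domains: tuple[DomainCall, ...] = ()

    def __post_init__(self) -> None:
        if self.n_glyc_site_count < 0:
            raise ValueError(f"{self.protein_id}: negative N-glycosylation count")
        object.__setattr__(self, "domains", tuple(self.domains))


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    block: str = ""
    subgenome: Subgenome = Subgenome.NONE

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: chromosome label must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class SyntenyRecord:
    """One B. rapa gene with its (possibly absent) Arabidopsis syntenic ortholog."""

    br_gene: str
    at_ortholog: str
    subgenome: Subgenome


@dataclass(frozen=True)
class SampleInfo:
    genotype: Genotype
    stage: int
    replicate: int

    def __post_init__(self) -> None:
        if not 1 <= self.stage <= 5:
            raise ValueError(f"stage must be 1-5, got {self.stage}")

    @property
    def label(self) -> str:
        return f"{self.genotype.value}_s{self.stage}_r{self.replicate}"


@dataclass
class ExpressionTable:
    """genes x samples matrix of non-negative FPKM (or count) values."""

    genes: list[str]
    samples: list[SampleInfo]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    def columns(self, genotype: Genotype, stage: int) -> np.ndarray:
        """Submatrix of replicate columns for one genotype at one stage."""
        idx = [
            j for j, s in enumerate(self.samples)
            if s.genotype is genotype and s.stage == stage
        ]
        if not idx:
            raise ValueError(f"no samples for {genotype.value} at stage {stage}")
        return self.values[:, idx]

    @property
    def stages(self) -> list[int]:
        return sorted({s.stage for s in self.samples})


_ALIGNED_RE = re.compile(r"^[A-Z.\-]+$")


@dataclass(frozen=True)
class AlignedRecord:
    """A row of a multiple alignment: amino acids plus gap characters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("aligned record id must be non-empty")
        if not self.sequence or not _ALIGNED_RE.match(self.sequence):
            raise ValueError(f"{self.id}: aligned sequence may hold A-Z, '-' and '.' only")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and wrapped lines joined.  Trailing stop codons
    (``*``) are stripped with a logged warning — proteome dumps often include
    them.  Duplicate ids and non-letter residues are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("%s: stripping %d stop codon(s) from %s", path, seq.count("*"), rec.id)
            seq = seq.replace("*", "")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_aligned_fasta(path: str | Path) -> list[AlignedRecord]:
    """Read a pre-aligned protein FASTA (gap characters permitted)."""
    path = Path(path)
    records: list[AlignedRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(AlignedRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord | AlignedRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=getattr(r, "description", ""))
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# TSV plumbing

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(text: str, context: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{context}: cannot parse boolean from {text!r}")


_DOMAIN_FIELD_RE = re.compile(r"^(?P<name>[A-Za-z0-9]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_domains(text: str, context: str) -> tuple[DomainCall, ...]:
    text = text.strip()
    if not text:
        return ()
    calls = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        m = _DOMAIN_FIELD_RE.match(part)
        if not m:
            raise ValueError(f"{context}: malformed domain field {part!r}")
        name = _DOMAIN_BY_UPPER.get(m.group("name").upper())
        if name is None:
            raise ValueError(f"{context}: unknown domain name {m.group('name')!r}")
        calls.append(DomainCall(name=name, start=int(m.group("start")), end=int(m.group("end"))))
    return tuple(calls)


ANNOTATION_COLUMNS = ["protein_id", "signal_peptide", "gpi_anchor", "n_glyc_sites", "domains"]


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path} line {i}"
        records.append(
            AnnotationRecord(
                protein_id=row.protein_id,
                has_signal_peptide=_parse_bool(row.signal_peptide, ctx),
                has_gpi_anchor=_parse_bool(row.gpi_anchor, ctx),
                n_glyc_site_count=int(row.n_glyc_sites),
                domains=_parse_domains(row.domains, ctx),
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "protein_id": r.protein_id,
            "signal_peptide": int(r.has_signal_peptide),
            "gpi_anchor": int(r.has_gpi_anchor),
            "n_glyc_sites": r.n_glyc_site_count,
            "domains": ";".join(f"{d.name.value}:{d.start}-{d.end}" for d in r.domains),
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


LOCUS_COLUMNS = ["gene_id", "chromosome", "start", "end", "block", "subgenome"]


def read_loci(path: str | Path) -> list[GeneLocus]:
    df = _read_tsv(path, LOCUS_COLUMNS)
    loci = []
    for row in df.itertuples(index=False):
        sub = row.subgenome.strip() or "NONE"
        loci.append(
            GeneLocus(
                gene_id=row.gene_id,
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                block=row.block,
                subgenome=Subgenome(sub),
            )
        )
    return loci


def write_loci(loci: Iterable[GeneLocus], path: str | Path) -> None:
    rows = [
        {
            "gene_id": l.gene_id, "chromosome": l.chromosome, "start": l.start,
            "end": l.end, "block": l.block, "subgenome": l.subgenome.value,
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


SYNTENY_COLUMNS = ["br_gene", "at_ortholog", "subgenome"]


def read_synteny(path: str | Path) -> list[SyntenyRecord]:
    df = _read_tsv(path, SYNTENY_COLUMNS)
    return [
        SyntenyRecord(
            br_gene=row.br_gene,
            at_ortholog=row.at_ortholog.strip(),
            subgenome=Subgenome(row.subgenome),
        )
        for row in df.itertuples(index=False)
    ]


def write_synteny(records: Iterable[SyntenyRecord], path: str | Path) -> None:
    rows = [
        {"br_gene": r.br_gene, "at_ortholog": r.at_ortholog, "subgenome": r.subgenome.value}
        for r in records
    ]
    pd.DataFrame(rows, columns=SYNTENY_COLUMNS).to_csv(path, sep="\t", index=False)


_SAMPLE_RE = re.compile(r"^(?P<genotype>sterile|fertile)_s(?P<stage>\d+)_r(?P<rep>\d+)$")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a genes-by-samples FPKM table.

    The first column is ``gene_id``; every other column header encodes the
    sample as ``<genotype>_s<stage>_r<replicate>``, e.g. ``fertile_s3_r1``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    samples = []
    for col in df.columns[1:]:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(f"{path}: cannot parse sample column {col!r}")
        samples.append(
            SampleInfo(Genotype(m.group("genotype")), int(m.group("stage")), int(m.group("rep")))
        )
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative expression value")
    return ExpressionTable(genes=list(df["gene_id"]), samples=samples, values=values)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=[s.label for s in table.samples])
    df.insert(0, "gene_id", table.genes)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
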