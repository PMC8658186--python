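"""Genomic context of the gene family: chromosome distribution, tandem
duplication with alignment-based amino-acid similarity, and segmental
duplication inferred from cross-genome synteny.

Tandem candidates are pairs of family genes on the same chromosome separated
by at most ``max_intervening`` other family genes in genomic order; each pair
carries a global-alignment similarity and a boolean marking the >= 70%
similarity rule.  Segmental groups are B. rapa genes sharing an Arabidopsis
syntenic ortholog across subgenomes, the signature of copies retained after
whole-genome triplication.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneLocus, Subgenome, SyntenyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    chromosome: str
    intervening_genes: int
    similarity_pct: float
    passes_threshold: bool


@dataclass(frozen=True)
class SegmentalGroup:
    at_ortholog: str
    br_genes: tuple[tuple[str, Subgenome], ...]


def _make_aligner(
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def nw_similarity(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent similarity from an end-to-end affine-gap global alignment.

    Similarity follows the EMBOSS convention: the percentage of alignment
    columns (gap columns included in the denominator) where both residues
    are present and their substitution score is positive.  Symmetric in its
    arguments; identical sequences score 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    matrix = aligner.substitution_matrix
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    a_row, b_row = str(alignment[0]), str(alignment[1])
    similar = sum(
        1
        for x, y in zip(a_row, b_row)
        if x != "-" and y != "-" and matrix[x, y] > 0
    )
    return 100.0 * similar / len(a_row)


def find_tandem_duplicates(
    loci: Sequence[GeneLocus],
    sequences: Mapping[str, str],
    max_intervening: int = 1,
    min_similarity: float = 70.0,
    **aligner_kwargs,
) -> list[TandemPair]:
    """All same-chromosome family-gene pairs within the adjacency window.

    ``max_intervening`` counts other *family* genes lying between the pair in
    genomic order (0 = immediately adjacent within the family).  Every
    candidate pair is reported; ``passes_threshold`` marks the similarity
    rule, so sub-threshold pairs remain visible.
    """
    by_chrom: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        by_chrom[locus.chromosome].append(locus)
    pairs: list[TandemPair] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        for i, a in enumerate(ordered):
            for j in range(i + 1, min(i + 2 + max_intervening, len(ordered))):
                b = ordered[j]
                for locus in (a, b):
                    if locus.gene_id not in sequences:
                        raise ValueError(f"no sequence for gene {locus.gene_id!r}")
                sim = nw_similarity(
                    sequences[a.gene_id], sequences[b.gene_id], **aligner_kwargs
                )
                pairs.append(
                    TandemPair(
                        gene_a=a.gene_id,
                        gene_b=b.gene_id,
                        chromosome=chrom,
                        intervening_genes=j - i - 1,
                        similarity_pct=sim,
                        passes_threshold=sim >= min_similarity,
                    )
                )
    return pairs


def find_segmental_duplicates(synteny: Iterable[SyntenyRecord]) -> list[SegmentalGroup]:
    """Group B. rapa genes by shared Arabidopsis ortholog; keep groups >= 2."""
    by_ortholog: dict[str, list[tuple[str, Subgenome]]] = defaultdict(list)
    for rec in synteny:
        if rec.at_ortholog:
            by_ortholog[rec.at_ortholog].append((rec.br_gene, rec.subgenome))
    return [
        SegmentalGroup(at_ortholog=ort, br_genes=tuple(sorted(members)))
        for ort, members in sorted(by_ortholog.items())
        if len(members) >= 2
    ]


def chromosome_distribution(
    loci: Iterable[GeneLocus],
) -> tuple[dict[str, int], int]:
    """Per-chromosome gene counts plus a separate unplaced (scaffold) count."""
    counts: Counter[str] = Counter()
    unplaced = 0
    for locus in loci:
        if locus.chromosome.lower().startswith("scaffold"):
            unplaced += 1
        else:
            counts[locus.chromosome] += 1
    return dict(sorted(counts.items())), unplaced
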