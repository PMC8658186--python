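"""End-to-end orchestration: classify -> genome context -> expression ->
reports, with a machine-readable summary.

Reported percentages are rounded half-up to two decimals (the convention of
the printed literature on this family, e.g. 194/293 -> 66.21).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, genome_context, io_formats
from .classify import Classification, ClassifyParams, classify_proteome, summarize_subfamilies
from .expression import format_deg_table, screen_expression, summarize_deg_by_subfamily

logger = logging.getLogger(__name__)


def percent(count: float, total: float) -> float:
    """100 * count / total, rounded half-up to two decimals."""
    if total == 0:
        raise ValueError("total must be non-zero")
    value = Decimal(100) * Decimal(count) / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    fasta: str
    annotations: Optional[str] = None
    loci: Optional[str] = None
    synteny: Optional[str] = None
    expression: Optional[str] = None
    out_dir: str = "agp_out"
    params: ClassifyParams = field(default_factory=ClassifyParams)
    max_intervening: int = 1
    min_similarity: float = 70.0
    detection_threshold: float = 1.0
    fdr_threshold: float = 0.05
    abs_log2fc: float = 1.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = ClassifyParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("params", {}).items()
        })
        if "fasta" not in raw:
            raise ValueError(f"{path}: missing required config field 'fasta'")
        return cls(params=params, **raw)


def _classes_frame(classifications: list[Classification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        e = c.evidence
        rows.append({
            "protein_id": c.protein_id,
            "subfamily": c.subfamily.value,
            "length": e.profile.length,
            "past_fraction": round(e.profile.past_fraction, 4),
            "pvkcyt_fraction": round(e.profile.pvkcyt_fraction, 4),
            "n_glyco_hits": e.n_glyco_hits,
            "n_ext_repeats": e.n_ext_repeats,
            "eight_cys": int(e.eight_cys is not None),
            "signal": int(e.has_signal_peptide),
            "gpi": int(e.has_gpi_anchor),
            "domains": ";".join(f"{d.name.value}:{d.start}-{d.end}" for d in e.domains),
            "rule_trace": " | ".join(c.notes),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the summary dict (also written
    to ``summary.json`` in the output directory)."""
    for name in ("fasta", "annotations", "loci", "synteny", "expression"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"config field {name!r}: no such file {value!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": 1,
        "agpkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            **dataclasses.asdict(config.params),
            "max_intervening": config.max_intervening,
            "min_similarity": config.min_similarity,
            "detection_threshold": config.detection_threshold,
            "fdr_threshold": config.fdr_threshold,
            "abs_log2fc": config.abs_log2fc,
            "pseudocount": config.pseudocount,
        },
    }
    logger.info("parameters: %s", summary["parameters"])

    records = io_formats.read_fasta(config.fasta)
    annotations = (
        io_formats.read_annotations(config.annotations) if config.annotations else []
    )
    classifications = classify_proteome(records, annotations, config.params)
    _classes_frame(classifications).to_csv(out / "classes.tsv", sep="\t", index=False)
    counts, total = summarize_subfamilies(classifications)
    count_rows = [{"subfamily": s.value, "count": n} for s, n in counts.items()]
    pd.DataFrame(count_rows).to_csv(out / "subfamily_counts.tsv", sep="\t", index=False)
    summary["n_proteins"] = len(records)
    summary["subfamily_counts"] = {s.value: n for s, n in counts.items()}
    summary["total_agp"] = total
    summary["pct_agp_of_proteome"] = percent(total, len(records)) if records else 0.0

    if config.loci is not None:
        dupes_dir = out / "dupes"
        dupes_dir.mkdir(exist_ok=True)
        loci = io_formats.read_loci(config.loci)
        sequences = {r.id: r.sequence for r in records}
        pairs = genome_context.find_tandem_duplicates(
            loci, sequences, config.max_intervening, config.min_similarity
        )
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            dupes_dir / "tandem_pairs.tsv", sep="\t", index=False
        )
        chrom_counts, unplaced = genome_context.chromosome_distribution(loci)
        chrom_rows = [{"chromosome": c, "count": n} for c, n in chrom_counts.items()]
        chrom_rows.append({"chromosome": "unplaced", "count": unplaced})
        pd.DataFrame(chrom_rows).to_csv(
            dupes_dir / "chromosome_counts.tsv", sep="\t", index=False
        )
        by_id = {l.gene_id: l for l in loci}
        link_rows = [
            {
                "gene_a": p.gene_a, "gene_b": p.gene_b,
                "chr_a": by_id[p.gene_a].chromosome, "pos_a": by_id[p.gene_a].start,
                "chr_b": by_id[p.gene_b].chromosome, "pos_b": by_id[p.gene_b].start,
            }
            for p in pairs
        ]
        pd.DataFrame(link_rows).to_csv(dupes_dir / "links.tsv", sep="\t", index=False)
        tandem_genes = sorted(
            {g for p in pairs if p.passes_threshold for g in (p.gene_a, p.gene_b)}
        )
        summary["n_tandem_genes"] = len(tandem_genes)
        summary["n_chromosome_placed"] = sum(chrom_counts.values())
        summary["n_unplaced"] = unplaced

        if config.synteny is not None:
            synteny = io_formats.read_synteny(config.synteny)
            groups = genome_context.find_segmental_duplicates(synteny)
            group_rows = [
                {
                    "at_ortholog": g.at_ortholog,
                    "br_genes": ";".join(f"{gene}({sub.value})" for gene, sub in g.br_genes),
                    "n_members": len(g.br_genes),
                }
                for g in groups
            ]
            pd.DataFrame(group_rows).to_csv(
                dupes_dir / "segmental_groups.tsv", sep="\t", index=False
            )
            segmental_genes = {gene for g in groups for gene, _ in g.br_genes}
            summary["n_segmental_genes"] = len(segmental_genes)
            duplicated = segmental_genes | set(tandem_genes)
            summary["n_duplicated_genes"] = len(duplicated)
            if total:
                summary["pct_duplicated"] = percent(len(duplicated), total)

    if config.expression is not None:
        table = io_formats.read_expression(config.expression)
        results = screen_expression(
            table,
            pseudocount=config.pseudocount,
            detection_threshold=config.detection_threshold,
            fdr_threshold=config.fdr_threshold,
            abs_log2fc=config.abs_log2fc,
        )
        subfamily_by_gene = {c.protein_id: c.subfamily.value for c in classifications}
        format_deg_table(results, subfamily_by_gene).to_csv(
            out / "degs.tsv", sep="\t", index=False
        )
        deg_counts, n_deg = summarize_deg_by_subfamily(results, subfamily_by_gene)
        summary["deg_counts_by_subfamily"] = deg_counts
        summary["n_differential_genes"] = n_deg
        summary["pct_differential"] = (
            percent(n_deg, total) if total else 0.0
        )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
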