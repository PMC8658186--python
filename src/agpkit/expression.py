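"""Differential-expression screening for a two-genotype, five-stage design.

The screen mirrors a male-fertility comparison: floral-bud FPKM of a
male-fertile genotype against a male-sterile one at five microspore
developmental stages.  Per stage, each gene gets a log2 fold change
(fertile over sterile, positive = depressed in the sterile line), a
Benjamini-Hochberg adjusted p-value, and a call:

* ``UP``   — log2FC >= 1 and FDR < 0.05 (boundary inclusive on the effect);
* ``DOWN`` — log2FC <= -1 and FDR < 0.05;
* ``F_SPECIFIC`` / ``S_SPECIFIC`` — mean expression above the detection
  threshold in exactly one genotype (fertile / sterile);
* ``NOT_EXPRESSED`` — below the detection threshold in both;
* ``NS`` otherwise.

P-values come from a two-sample Welch test on log-transformed replicate
FPKM (the statistic is computed here; only the t-distribution tail is taken
from scipy); externally computed p-values can be supplied instead via
:func:`screen_degs`, which is the entry point shared by both paths.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ExpressionTable, Genotype


class Call(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"
    F_SPECIFIC = "F_SPECIFIC"
    S_SPECIFIC = "S_SPECIFIC"
    NOT_EXPRESSED = "NOT_EXPRESSED"


#: Calls that make a gene count as differential.
DIFFERENTIAL_CALLS = frozenset(
    {Call.UP, Call.DOWN, Call.F_SPECIFIC, Call.S_SPECIFIC}
)


@dataclass(frozen=True)
class StageStats:
    """Per-gene, per-stage inputs to the screening rule."""

    gene_id: str
    stage: int
    log2fc: float
    pvalue: Optional[float]
    fertile_mean: float
    sterile_mean: float


@dataclass
class DEResult:
    gene_id: str
    log2fc: dict[int, float] = field(default_factory=dict)
    fdr: dict[int, Optional[float]] = field(default_factory=dict)
    call: dict[int, Call] = field(default_factory=dict)

    @property
    def is_differential(self) -> bool:
        return any(c in DIFFERENTIAL_CALLS for c in self.call.values())


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1 and returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch two-sample test; returns (t, p).

    The statistic and Welch-Satterthwaite degrees of freedom are computed
    directly; the tail probability uses the t distribution's survival
    function.  Degenerate inputs (fewer than two replicates per group, or
    zero variance in both) yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        return 0.0, 1.0
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def stage_log2fc(
    table: ExpressionTable,
    stage: int,
    pseudocount: float = 1.0,
    detection_threshold: float = 1.0,
) -> list[StageStats]:
    """Per-gene log2 fold change (fertile/sterile) and Welch p at one stage."""
    fertile = table.columns(Genotype.B_FERTILE, stage)
    sterile = table.columns(Genotype.A_STERILE, stage)
    f_mean = fertile.mean(axis=1)
    s_mean = sterile.mean(axis=1)
    log2fc = np.log2((f_mean + pseudocount) / (s_mean + pseudocount))
    log_f = np.log2(fertile + pseudocount)
    log_s = np.log2(sterile + pseudocount)
    out = []
    for g, gene in enumerate(table.genes):
        _, p = welch_t_test(log_f[g], log_s[g])
        out.append(
            StageStats(
                gene_id=gene,
                stage=stage,
                log2fc=float(log2fc[g]),
                pvalue=p,
                fertile_mean=float(f_mean[g]),
                sterile_mean=float(s_mean[g]),
            )
        )
    return out


def _call_for(
    s: StageStats,
    fdr: Optional[float],
    fdr_threshold: float,
    abs_log2fc: float,
    detection_threshold: float,
) -> Call:
    f_on = s.fertile_mean >= detection_threshold
    s_on = s.sterile_mean >= detection_threshold
    if not f_on and not s_on:
        return Call.NOT_EXPRESSED
    if f_on and not s_on:
        return Call.F_SPECIFIC
    if s_on and not f_on:
        return Call.S_SPECIFIC
    if fdr is not None and fdr < fdr_threshold:
        if s.log2fc >= abs_log2fc:
            return Call.UP
        if s.log2fc <= -abs_log2fc:
            return Call.DOWN
    return Call.NS


def screen_degs(
    stats: Iterable[StageStats],
    fdr_threshold: float = 0.05,
    abs_log2fc: float = 1.0,
    detection_threshold: float = 1.0,
) -> list[DEResult]:
    """Apply BH within each stage and emit per-gene calls.

    Accepts precomputed per-stage statistics (so an external differential
    test can drive the screen) or the output of :func:`stage_log2fc`.
    """
    by_stage: dict[int, list[StageStats]] = defaultdict(list)
    order: list[str] = []
    seen: set[str] = set()
    for s in stats:
        by_stage[s.stage].append(s)
        if s.gene_id not in seen:
            seen.add(s.gene_id)
            order.append(s.gene_id)
    results = {g: DEResult(gene_id=g) for g in order}
    for stage, stage_stats in sorted(by_stage.items()):
        with_p = [s for s in stage_stats if s.pvalue is not None]
        q = bh_adjust([s.pvalue for s in with_p]) if with_p else np.array([])
        fdr_by_gene = {s.gene_id: float(v) for s, v in zip(with_p, q)}
        for s in stage_stats:
            fdr = fdr_by_gene.get(s.gene_id)
            res = results[s.gene_id]
            res.log2fc[stage] = s.log2fc
            res.fdr[stage] = fdr
            res.call[stage] = _call_for(
                s, fdr, fdr_threshold, abs_log2fc, detection_threshold
            )
    return [results[g] for g in order]


def screen_expression(
    table: ExpressionTable,
    pseudocount: float = 1.0,
    detection_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    abs_log2fc: float = 1.0,
) -> list[DEResult]:
    """Full synthetic-replicate path: Welch test + BH + calls, all stages."""
    stats: list[StageStats] = []
    for stage in table.stages:
        stats.extend(stage_log2fc(table, stage, pseudocount, detection_threshold))
    return screen_degs(stats, fdr_threshold, abs_log2fc, detection_threshold)


def summarize_deg_by_subfamily(
    results: Iterable[DEResult],
    subfamily_by_gene: Mapping[str, str],
) -> tuple[dict[str, int], int]:
    """Counts of differential genes per subfamily, plus the distinct total.

    Genes missing from the classification mapping are counted under
    ``"unclassified"``.
    """
    counts: Counter[str] = Counter()
    total = 0
    for res in results:
        if not res.is_differential:
            continue
        total += 1
        counts[subfamily_by_gene.get(res.gene_id, "unclassified")] += 1
    return dict(sorted(counts.items())), total


# ---------------------------------------------------------------------------
# Curated DEG tables (one row per differential gene; per-stage cells hold a
# log2 fold change, "S"/"F" for genotype-specific expression, or "." for no
# difference / no expression).

DEG_TABLE_COLUMNS = ["subfamily", "gene_name", "locus", "s1", "s2", "s3", "s4", "s5"]


def _cell_to_call(cell: str) -> tuple[Call, Optional[float]]:
    cell = cell.strip()
    if cell == ".":
        return Call.NS, None
    if cell == "S":
        return Call.S_SPECIFIC, None
    if cell == "F":
        return Call.F_SPECIFIC, None
    value = float(cell)
    return (Call.UP if value > 0 else Call.DOWN), value


def read_deg_table(path: str | Path) -> tuple[list[DEResult], dict[str, str]]:
    """Parse a curated DEG table into results plus a gene->subfamily map."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in DEG_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    results = []
    subfamily = {}
    for row in df.itertuples(index=False):
        res = DEResult(gene_id=row.gene_name)
        for stage in range(1, 6):
            call, value = _cell_to_call(getattr(row, f"s{stage}"))
            res.call[stage] = call
            if value is not None:
                res.log2fc[stage] = value
        results.append(res)
        subfamily[row.gene_name] = row.subfamily
    return results, subfamily


def curated_deg_table_path() -> Path:
    """Path of the bundled B. rapa floral-bud DEG table."""
    return Path(resources.files("agpkit").joinpath("data/brapa_floral_bud_degs.tsv"))


def format_deg_table(
    results: Iterable[DEResult],
    subfamily_by_gene: Mapping[str, str],
    only_differential: bool = True,
) -> pd.DataFrame:
    """Render screen results in the curated-table layout."""
    rows = []
    for res in results:
        if only_differential and not res.is_differential:
            continue
        row = {
            "subfamily": subfamily_by_gene.get(res.gene_id, "unclassified"),
            "gene_name": res.gene_id,
            "locus": res.gene_id,
        }
        for stage in range(1, 6):
            call = res.call.get(stage, Call.NS)
            if call is Call.S_SPECIFIC:
                cell = "S"
            elif call is Call.F_SPECIFIC:
                cell = "F"
            elif call in (Call.UP, Call.DOWN):
                cell = f"{res.log2fc[stage]:.1f}"
            else:
                cell = "."
            row[f"s{stage}"] = cell
        rows.append(row)
    return pd.DataFrame(rows, columns=DEG_TABLE_COLUMNS)
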