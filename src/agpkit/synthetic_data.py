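"""Seeded generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure each stage assumes rather
than real evolutionary sequences:

* proteomes — for each requested subfamily label, a sequence engineered to
  satisfy exactly that label's classification gates with a configurable
  margin (plus negative controls that each violate exactly one gate).
  Backbones are drawn from residues outside P/A/S/T/K/C so that PAST
  content, glycomodules, Lys-rich windows and cysteine motifs appear only
  where planted; composition is then tuned by targeted substitutions, which
  guarantees the margins without rejection sampling.
* expression — log-normal FPKM for a 2-genotype x 5-stage x n-replicate
  design with planted log2 fold changes and genotype-specific genes.
* loci/synteny — tandem gene pairs placed adjacently with engineered
  above/below-threshold protein similarity, and ortholog triplets spread
  across the three subgenomes.

Signal peptides and GPI anchors are emitted as annotation flags, not
sequence features: the pipeline treats them as external predictions.
All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import Subfamily
from .composition import detect_lys_rich, past_fraction
from .io_formats import (
    AnnotationRecord,
    DomainCall,
    DomainName,
    ExpressionTable,
    GeneLocus,
    Genotype,
    ProteinRecord,
    SampleInfo,
    Subgenome,
    SyntenyRecord,
)
from .motif_scan import has_ag_glycomodules, scan_eight_cys, scan_ext_repeats

#: Residues that can never contribute to PAST content, PVKCYT/Lys windows,
#: glycomodules or the eight-cysteine motif.
_NEUTRAL_ALPHABET = tuple("DEFHILMNQRVWY")

_GLYCO_MOTIF = "APP"          # one arabinosylation glycomodule
_EXT_MOTIF = "SPPP"           # one extensin SP3 repeat (also a glycomodule)
_EIGHT_CYS_INSERT = "CACACCACLCACAC"
_LYS_INSERT = "K" * 15

_DEFAULT_COUNTS: dict[Subfamily, int] = {
    Subfamily.CLASSICAL: 5,
    Subfamily.LYS_RICH: 5,
    Subfamily.AG_PEPTIDE: 5,
    Subfamily.NON_CLASSICAL: 5,
    Subfamily.FLA: 5,
    Subfamily.PLA: 5,
    Subfamily.XYLP: 5,
    Subfamily.OTHER_CAGP: 5,
    Subfamily.CHAE: 5,
    Subfamily.HAE: 5,
}

#: Negative controls, each violating exactly one gate.
NEGATIVE_KINDS = ("high_past_no_glyco", "domain_no_glyco", "short_no_signal")


@dataclass(frozen=True)
class ProteomeSpec:
    counts: Mapping[Subfamily, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    negatives: Mapping[str, int] = field(
        default_factory=lambda: {k: 3 for k in NEGATIVE_KINDS}
    )
    past_margin: float = 0.05
    len_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.past_margin <= 0 or self.len_margin <= 0:
            raise ValueError("margins must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        for kind in self.negatives:
            if kind not in NEGATIVE_KINDS:
                raise ValueError(f"unknown negative-control kind {kind!r}")


@dataclass
class ProteomeBundle:
    records: list[ProteinRecord]
    annotations: list[AnnotationRecord]
    truth: dict[str, Subfamily]


def _compose(parts: Sequence[tuple[str, str]]) -> tuple[list[str], dict[str, tuple[int, int]], list[int]]:
    """Concatenate tagged parts; return sequence chars, 1-based spans of
    tagged parts, and 0-based indices of tunable backbone positions."""
    chars: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    backbone_idx: list[int] = []
    for tag, text in parts:
        start = len(chars)
        chars.extend(text)
        if tag == "backbone":
            backbone_idx.extend(range(start, len(chars)))
        elif tag:
            spans[tag] = (start + 1, len(chars))
    return chars, spans, backbone_idx


def _backbone(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NEUTRAL_ALPHABET, size=n)) if n > 0 else ""


def _tune_past(
    chars: list[str],
    backbone_idx: Sequence[int],
    target_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Raise PAST content to (at least) the target by substituting Ala into
    backbone positions; never creates new motifs since backbones hold no P."""
    current = sum(1 for c in chars if c in "PAST")
    need = math.ceil(target_fraction * len(chars)) - current
    if need <= 0:
        return
    if need > len(backbone_idx):
        raise ValueError("infeasible spec: not enough tunable positions")
    for i in rng.choice(len(backbone_idx), size=need, replace=False):
        chars[backbone_idx[i]] = "A"


def _build(
    rng: np.random.Generator,
    layout: Sequence[tuple[str, object]],
    past_target: Optional[float] = None,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """layout entries: ("backbone", n) or (tag, literal_text)."""
    parts = [
        (tag, _backbone(rng, val) if tag == "backbone" else str(val))
        for tag, val in layout
    ]
    chars, spans, backbone_idx = _compose(parts)
    if past_target is not None:
        _tune_past(chars, backbone_idx, past_target, rng)
    return "".join(chars), spans


def _domain_call(name: DomainName, spans: Mapping[str, tuple[int, int]]) -> DomainCall:
    start, end = spans["domain"]
    return DomainCall(name=name, start=start, end=end)


def generate_proteome(spec: ProteomeSpec) -> ProteomeBundle:
    """Build a proteome whose classification truth is known by construction.

    Every positive example passes its subfamily's gates with at least the
    configured margin; every negative control fails exactly its designated
    gate.  Construction-time assertions verify both.  Deterministic given
    the spec (including its seed).
    """
    lo, hi = 50 + spec.len_margin, 90 - spec.len_margin
    if lo > hi:
        raise ValueError("infeasible spec: length margin leaves no AG-peptide lengths")
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    annotations: list[AnnotationRecord] = []
    truth: dict[str, Subfamily] = {}
    counter = 0

    def emit(
        seq: str,
        label: Subfamily,
        signal: bool = False,
        gpi: bool = False,
        domains: tuple[DomainCall, ...] = (),
    ) -> None:
        nonlocal counter
        counter += 1
        pid = f"syn{counter:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq, description=f"synthetic {label.value}"))
        annotations.append(
            AnnotationRecord(
                protein_id=pid,
                has_signal_peptide=signal,
                has_gpi_anchor=gpi,
                n_glyc_site_count=int(rng.integers(0, 4)),
                domains=domains,
            )
        )
        truth[pid] = label

    glyco3 = [
        ("backbone", 8), ("g0", _GLYCO_MOTIF),
        ("backbone", 8), ("g1", _GLYCO_MOTIF),
        ("backbone", 8), ("g2", _GLYCO_MOTIF),
    ]
    high_past = 0.50 + spec.past_margin

    for label, n in spec.counts.items():
        for _ in range(n):
            if label in (Subfamily.CLASSICAL, Subfamily.LYS_RICH, Subfamily.NON_CLASSICAL):
                layout: list[tuple[str, object]] = [("backbone", 30), *glyco3, ("backbone", 60)]
                if label is Subfamily.LYS_RICH:
                    layout.insert(3, ("lys", _LYS_INSERT))
                seq, _ = _build(rng, layout, past_target=high_past)
                signal = label is not Subfamily.NON_CLASSICAL
                assert past_fraction(seq) > 0.50
                if label is Subfamily.LYS_RICH:
                    assert detect_lys_rich(seq) is not None
                else:
                    assert detect_lys_rich(seq) is None
                emit(seq, label, signal=signal, gpi=bool(rng.integers(0, 2)))
            elif label is Subfamily.AG_PEPTIDE:
                length = int(rng.integers(lo, hi + 1))
                seq, _ = _build(
                    rng,
                    [("backbone", length - 33), *glyco3],
                    past_target=0.35 + spec.past_margin,
                )
                assert lo <= len(seq) <= hi and past_fraction(seq) >= 0.35 + spec.past_margin - 1e-9
                emit(seq, label, signal=True, gpi=True)
            elif label is Subfamily.HAE:
                seq, _ = _build(
                    rng,
                    [
                        ("backbone", 20), ("e0", _EXT_MOTIF), ("backbone", 20),
                        ("e1", _EXT_MOTIF), *glyco3, ("backbone", 40),
                    ],
                    past_target=high_past,
                )
                assert past_fraction(seq) >= 0.50 and len(scan_ext_repeats(seq)) >= 2
                emit(seq, label, signal=bool(rng.integers(0, 2)))
            else:  # chimeric path
                domain_name = {
                    Subfamily.FLA: DomainName.FAS,
                    Subfamily.PLA: DomainName.PCNL,
                    Subfamily.XYLP: DomainName.NSLTP2,
                    Subfamily.OTHER_CAGP: DomainName.PKINASE,
                    Subfamily.CHAE: DomainName.GH,
                }[label]
                core = _EIGHT_CYS_INSERT if label is Subfamily.XYLP else ""
                domain_text = _backbone(rng, 25) + core + _backbone(rng, 95 - len(core))
                layout = [("backbone", 10), *glyco3, ("backbone", 10), ("domain", domain_text)]
                if label is Subfamily.CHAE:
                    layout += [("backbone", 5), ("e0", _EXT_MOTIF), ("backbone", 5), ("e1", _EXT_MOTIF)]
                layout += [("backbone", 30)]
                seq, spans = _build(rng, layout)
                assert has_ag_glycomodules(seq)[0]
                if label is Subfamily.XYLP:
                    assert scan_eight_cys(seq) is not None
                else:
                    assert scan_eight_cys(seq) is None
                if label is Subfamily.CHAE:
                    assert len(scan_ext_repeats(seq)) >= 2
                emit(
                    seq, label,
                    signal=bool(rng.integers(0, 2)),
                    gpi=bool(rng.integers(0, 2)),
                    domains=(_domain_call(domain_name, spans),),
                )

    for kind, n in spec.negatives.items():
        for _ in range(n):
            if kind == "high_past_no_glyco":
                seq, _ = _build(rng, [("backbone", 120)], past_target=high_past)
                assert not has_ag_glycomodules(seq)[0]
                emit(seq, Subfamily.NOT_AGP, signal=True)
            elif kind == "domain_no_glyco":
                domain_text = _backbone(rng, 120)
                seq, spans = _build(rng, [("backbone", 40), ("domain", domain_text), ("backbone", 40)])
                assert not has_ag_glycomodules(seq)[0]
                emit(
                    seq, Subfamily.NOT_AGP, signal=True,
                    domains=(_domain_call(DomainName.FAS, spans),),
                )
            else:  # short_no_signal: an AG-peptide missing only its signal
                seq, _ = _build(
                    rng, [("backbone", 37), *glyco3], past_target=0.35 + spec.past_margin
                )
                assert has_ag_glycomodules(seq)[0]
                emit(seq, Subfamily.NOT_AGP, signal=False)

    return ProteomeBundle(records=records, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class ExpressionSpec:
    """2-genotype x 5-stage log-normal FPKM design with planted effects.

    ``planted_effects`` entries are (gene_id, stage, log2fc): the fertile
    genotype's log-mean is shifted by log2fc * ln 2 at that stage.
    ``planted_specific`` entries are (gene_id, stage, "F" | "S"): the other
    genotype draws sub-threshold values at that stage.  Gene baselines are
    log-uniform between ``baseline_fpkm_range`` so that unperturbed genes sit
    safely above the detection threshold.
    """

    n_genes: int = 200
    n_replicates: int = 3
    baseline_fpkm_range: tuple[float, float] = (20.0, 200.0)
    noise_log_sd: float = 0.10
    off_fpkm: float = 0.05
    planted_effects: tuple[tuple[str, int, float], ...] = ()
    planted_specific: tuple[tuple[str, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for the testing path")
        for _, stage, _ in self.planted_effects + self.planted_specific:
            if not 1 <= stage <= 5:
                raise ValueError(f"planted stage {stage} outside 1-5")


@dataclass
class ExpressionBundle:
    table: ExpressionTable
    #: gene -> {(stage, expected call name)}
    truth: dict[str, set[tuple[int, str]]]


def gene_ids(n: int) -> list[str]:
    return [f"gene{k:04d}" for k in range(1, n + 1)]


def default_expression_spec(
    seed: int = 0,
    n_genes: int = 200,
    n_effects: int = 44,
    n_specific: int = 6,
    log2fc: float = 3.0,
) -> ExpressionSpec:
    """A spec with randomly placed +/- effects and specific genes.

    Defaults plant differential behaviour in a quarter of the genes,
    mirroring the fraction of family members that real floral-bud screens
    of this design report as differential.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    chosen = rng.choice(n_genes, size=n_effects + n_specific, replace=False)
    effects = []
    for k in chosen[:n_effects]:
        stage = int(rng.integers(1, 6))
        sign = 1.0 if rng.integers(0, 2) else -1.0
        effects.append((genes[k], stage, sign * log2fc))
    specific = []
    for k in chosen[n_effects:]:
        stage = int(rng.integers(1, 6))
        which = "F" if rng.integers(0, 2) else "S"
        specific.append((genes[k], stage, which))
    return ExpressionSpec(
        n_genes=n_genes,
        planted_effects=tuple(effects),
        planted_specific=tuple(specific),
        seed=seed,
    )


def generate_expression(spec: ExpressionSpec) -> ExpressionBundle:
    rng = np.random.default_rng(spec.seed)
    genes = gene_ids(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    lo, hi = spec.baseline_fpkm_range
    base_log = rng.uniform(math.log(lo), math.log(hi), size=spec.n_genes)

    samples = [
        SampleInfo(genotype, stage, rep)
        for genotype in (Genotype.A_STERILE, Genotype.B_FERTILE)
        for stage in range(1, 6)
        for rep in range(1, spec.n_replicates + 1)
    ]
    effect = np.zeros((spec.n_genes, 2, 6))   # [gene, genotype(0=sterile,1=fertile), stage]
    off = np.zeros((spec.n_genes, 2, 6), dtype=bool)
    truth: dict[str, set[tuple[int, str]]] = {}
    for gene, stage, lfc in spec.planted_effects:
        effect[gene_index[gene], 1, stage] = lfc * math.log(2)
        truth.setdefault(gene, set()).add((stage, "UP" if lfc > 0 else "DOWN"))
    for gene, stage, which in spec.planted_specific:
        genotype = 0 if which == "F" else 1   # the OFF genotype
        off[gene_index[gene], genotype, stage] = True
        truth.setdefault(gene, set()).add(
            (stage, "F_SPECIFIC" if which == "F" else "S_SPECIFIC")
        )

    values = np.empty((spec.n_genes, len(samples)))
    for j, s in enumerate(samples):
        gt = 0 if s.genotype is Genotype.A_STERILE else 1
        mu = base_log + effect[:, gt, s.stage]
        mu = np.where(off[:, gt, s.stage], math.log(spec.off_fpkm), mu)
        values[:, j] = np.exp(rng.normal(mu, spec.noise_log_sd))
    return ExpressionBundle(
        table=ExpressionTable(genes=genes, samples=samples, values=values),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Loci / synteny


_FULL_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class LociSyntenyBundle:
    loci: list[GeneLocus]
    synteny: list[SyntenyRecord]
    sequences: dict[str, str]
    #: (gene_a, gene_b, engineered_above_threshold)
    truth_tandem: list[tuple[str, str, bool]]
    #: Arabidopsis ortholog ids of planted triplet groups
    truth_triplets: list[str]


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_FULL_ALPHABET, size=n))


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    chars = list(seq)
    k = max(1, int(round(fraction * len(chars))))
    for i in rng.choice(len(chars), size=k, replace=False):
        choices = [c for c in _FULL_ALPHABET if c != chars[i]]
        chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def generate_loci_synteny(
    n_genes: int = 30,
    n_tandem_pairs: int = 3,
    n_triplet_groups: int = 3,
    seed: int = 0,
    n_tandem_below: int = 1,
    protein_len: int = 120,
) -> LociSyntenyBundle:
    """Plant tandem arrays and subgenome ortholog triplets.

    ``n_tandem_pairs`` pairs are placed at adjacent loci; the first
    ``n_tandem_below`` of them get unrelated sequences (similarity far below
    the 70% rule), the rest near-identical copies (10% substitutions).
    Triplet groups share one Arabidopsis ortholog across LF/MF1/MF2.
    """
    needed = 2 * n_tandem_pairs + 3 * n_triplet_groups
    if n_genes < needed:
        raise ValueError(f"n_genes={n_genes} < {needed} required by planted structures")
    rng = np.random.default_rng(seed)
    genes = [f"locus{k:04d}" for k in range(1, n_genes + 1)]
    chroms = [f"A{c:02d}" for c in range(1, 11)]
    sequences: dict[str, str] = {}
    loci: list[GeneLocus] = []
    synteny: list[SyntenyRecord] = []
    truth_tandem: list[tuple[str, str, bool]] = []
    truth_triplets: list[str] = []

    pos = {c: 10_000 for c in chroms}

    def place(gene: str, chrom: str) -> None:
        start = pos[chrom]
        end = start + 1_500
        pos[chrom] += 10_000
        loci.append(
            GeneLocus(
                gene_id=gene, chromosome=chrom, start=start, end=end,
                block=chr(ord("A") + (int(chrom[1:]) - 1) % 24),
                subgenome=Subgenome.NONE,
            )
        )

    it = iter(genes)
    for p in range(n_tandem_pairs):
        a, b = next(it), next(it)
        chrom = chroms[p % len(chroms)]
        place(a, chrom)
        place(b, chrom)
        seq_a = _random_protein(rng, protein_len)
        below = p < n_tandem_below
        seq_b = _random_protein(rng, protein_len) if below else _mutate(rng, seq_a, 0.10)
        sequences[a], sequences[b] = seq_a, seq_b
        truth_tandem.append((a, b, not below))
        synteny.append(SyntenyRecord(a, "", Subgenome.LF))
        synteny.append(SyntenyRecord(b, "", Subgenome.LF))

    for t in range(n_triplet_groups):
        ortholog = f"AT{t + 1}G{10_000 + t * 10:05d}"
        truth_triplets.append(ortholog)
        for k, sub in enumerate((Subgenome.LF, Subgenome.MF1, Subgenome.MF2)):
            gene = next(it)
            # spread triplet members over different chromosomes
            place(gene, chroms[(n_tandem_pairs + t * 3 + k) % len(chroms)])
            sequences[gene] = _random_protein(rng, protein_len)
            synteny.append(SyntenyRecord(gene, ortholog, sub))

    for k, gene in enumerate(it):
        chrom = chroms[int(rng.integers(0, len(chroms)))] if k % 7 else "Scaffold000096"
        if chrom.startswith("Scaffold"):
            loci.append(GeneLocus(gene, chrom, 1_000, 2_500))
        else:
            place(gene, chrom)
        sequences[gene] = _random_protein(rng, protein_len)
        synteny.append(SyntenyRecord(gene, f"AT5G{60_000 + k:05d}", Subgenome.MF2))

    return LociSyntenyBundle(
        loci=loci,
        synteny=synteny,
        sequences=sequences,
        truth_tandem=truth_tandem,
        truth_triplets=truth_triplets,
    )
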