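# agpkit

Identification and analysis of **arabinogalactan protein (AGP)** gene
families — the hydroxyproline-rich cell-surface proteoglycans of plants —
from a proteome and its external annotations.

AGPs lack a single diagnostic domain. Their backbones are recognised by a
compositional bias toward Pro/Ala/Ser/Thr (**PAST content**) and by short
Pro-containing **AG glycomodules** that predict O-glycosylation:
arabinosylation modules `[A/S/T/G]P₂₋₄` and galactosylation modules
`[A/S/T/G]P–X₍₀,₁₀₎–[A/S/T/G]P` (prolines ≤ 11 residues apart). `agpkit`
combines these sequence statistics with externally predicted features
(signal peptide, GPI anchor, conserved domains — supplied as a table, never
recomputed) in a fixed-order decision tree that assigns each protein to one
of nine subfamilies or rejects it:

| subfamily | rule sketch |
|---|---|
| FLA / PLA / XYLP / other chimeric | conserved domain (FAS / PCNL / nsLTP2 / other) **and** glycomodules; XYLP additionally requires the eight-cysteine motif `C₁-X-C₂-X-C₃C₄-X-C₅-[L/I/V]-C₆-X-C₇-X-C₈` |
| CHAE | any chimeric AGP that also carries ≥ 2 extensin SP₃₋₅ repeats |
| HAE | no domain, PAST ≥ 50 %, glycomodules, ≥ 2 SP₃₋₅ repeats |
| AG-peptide | 50–90 aa, PAST ≥ 35 %, glycomodules, signal peptide |
| classical / Lys-rich | PAST > 50 %, glycomodules, signal peptide; a Lys-dense insert refines to Lys-rich |
| non-classical | PAST ≥ 50 % with glycomodules but failing a classical gate |

Around the classifier the package provides the other stages of a
genome-wide family survey: chromosome distribution and tandem/segmental
duplication analysis (global-alignment similarity with the ≥ 70 % rule;
ortholog groups across the LF/MF1/MF2 subgenomes left by *Brassica rapa*'s
genome triplication), neighbor-joining phylogenies with bootstrap support
from pre-aligned sequences, and a differential-expression screen for a
two-genotype (male-sterile vs male-fertile) × five-stage floral-bud design
(per-stage log₂ fold changes, Welch tests on replicates, Benjamini–Hochberg
FDR, genotype-specificity flags). Seeded synthetic-data generators produce
proteomes, expression matrices and loci/synteny tables with known ground
truth, so every stage is testable without downloads. See
`docs/methods.md` for the full model description.

## Worked example

Generate a synthetic proteome with planted subfamily labels, classify it,
and run the whole pipeline:

```bash
agp simulate proteome --seed 7 --out sim/
agp classify --fasta sim/proteome.fa --annotations sim/annotations.tsv --out classes.tsv
head -3 classes.tsv
```

```text
protein_id  subfamily  length  past_fraction  pvkcyt_fraction  n_glyco_hits  n_ext_repeats  eight_cys  signal  gpi  domains  rule_trace
syn0001     CLASSICAL  123     0.5528         0.1301           5             0              0          1       1            PAST 0.55 > 0.50 -> classical | GPI anchor present (supporting evidence)
syn0002     CLASSICAL  123     0.5528         0.122            5             0              0          1       0            PAST 0.55 > 0.50 -> classical
```

Each row is one protein: its assigned subfamily, the statistics the
decision tree used (PAST fraction 0.55 exceeds the 0.50 classical
threshold; 5 AG glycomodules ≥ the required 2), the external flags, and a
human-readable trace of the rules that fired.

```bash
printf 'fasta: sim/proteome.fa\nannotations: sim/annotations.tsv\nout_dir: out\n' > config.yaml
agp run --config config.yaml
```

```text
{"total_agp": 50}
```

`out/summary.json` then holds the machine-readable report — for this
bundle, 50 AGPs in ten subfamilies of five
(`{'AG_PEPTIDE': 5, 'CHAE': 5, 'CLASSICAL': 5, 'FLA': 5, 'HAE': 5,
'LYS_RICH': 5, 'NON_CLASSICAL': 5, 'OTHER_CAGP': 5, 'PLA': 5, 'XYLP': 5}`),
exactly the generator's planted truth — plus every parameter used.

A neighbor-joining tree with bootstrap support from a pre-aligned FASTA:

```bash
agp phylo --aligned msa.fa --bootstrap 100 --seed 42 --out tree.nwk
cat tree.nwk
```

```text
(c:2.7755575615628914e-17,d:0.1,(a:1.3877787807814457e-17,b:0.09999999999999999)97.0:0.2);
```

The internal label `97.0` is the bootstrap support (percent of 100
replicates containing that bipartition).

Other subcommands: `agp glycoscan` (one row per glycomodule hit),
`agp dupes` (tandem pairs, segmental groups, chromosome counts),
`agp express` (DEG table in the S/F/"." layout of published floral-bud
screens), `agp simulate expression|loci`. Everything is also available as
a library (`agpkit.classify`, `agpkit.motif_scan`, `agpkit.phylo`, …).

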