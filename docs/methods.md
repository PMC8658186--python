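# Methods

`agpkit` implements a genome-scale identification and analysis workflow for
arabinogalactan proteins (AGPs), the hydroxyproline-rich cell-surface
proteoglycans of plants. This note records the models and procedures the
package implements, the parameters that matter and why they default the way
they do, what the synthetic-data generators do and do not emulate, and the
design choices made where the underlying methodology was genuinely open.

## Classification model

AGP backbones are recognised by compositional bias and short glycosylation
motifs rather than by a single diagnostic domain, so classification is a
decision tree over a handful of sequence statistics plus externally
predicted features (signal peptide, GPI anchor, conserved domains). The
package never runs those external predictors; it consumes their results as
an annotation table, which keeps the pipeline deterministic and testable.

Statistics computed from the sequence itself:

* **PAST content** — fraction of residues that are Pro, Ala, Ser or Thr.
  `X` (unknown) counts in the denominator only, a conservative choice that
  can only lower, never raise, the bias estimate.
* **AG glycomodules** — arabinosylation modules `[A/S/T/G]P{2,4}`
  (contiguous prolines, scanned non-overlapping, leftmost, maximal munch
  capped at four prolines) and galactosylation modules, pairs of
  consecutive `[A/S/T/G]P` dipeptides whose prolines are separated by at
  most 11 residues. Pairing only *consecutive* dipeptide occurrences keeps
  the count linear in occurrences and avoids quadratic double-counting of
  dense Pro-rich regions. The published motif notation ("X(0,10)" between
  the first Pro and the next dipeptide, versus "not separated by more than
  11 residues" between prolines) is self-consistent only under one reading;
  we adopt it (≤ 11 residues between prolines) and expose the bound as a
  parameter.
* **Extensin SP(3–5) repeats** — Ser followed by 3–5 prolines, same
  non-overlap/maximal-munch policy; runs longer than five prolines count
  once with `n_pro = 5`.
* **Eight-cysteine motif** — `C1-X-C2-X-C3C4-X-C5-[L/I/V]-C6-X-C7-X-C8`,
  found as the leftmost assignment over a *subset* of the sequence's
  cysteines (spacers may contain further cysteines, as real nsLTP2 regions
  do). Spacer gaps default to `[1, 60]` residues: the motif notation writes
  bare `X` spacers with no bounds, and 60 comfortably spans an nsLTP2
  domain while excluding pathological genome-length assignments. Both
  bounds are parameters.
* **Lys-rich region** — the literature describes Lys-rich classical AGPs
  only qualitatively (a Lys-dense insert interrupting the PAST-rich
  backbone). Our operational rule — a 15-residue window with ≥ 30 % Lys,
  greedily extended while the density holds — is this package's own
  definition, surfaced as two parameters (`lys_window_len`,
  `lys_min_fraction`) precisely because it is not community ground truth.

Rules fire in a fixed order, first match wins, mirroring the screening
order of published family surveys (chimeric candidates, hybrids and
AG-peptides are removed before classical AGPs are considered): chimeric
(domain + glycomodules; FAS→FLA, PCNL→PLA, nsLTP2→XYLP if the
eight-cysteine motif is present else other chimeric; ≥ 2 SP(3–5) repeats
upgrade any chimeric label to CHAE) → HAE → AG-peptide → classical /
Lys-rich → non-classical → not an AGP. A GPI anchor is recorded as
supporting evidence but never filters: family surveys treat it the same
way.

Thresholds: classical PAST > 50 % (strict), AG-peptide length 50–90 aa
inclusive with PAST ≥ 35 %, at least two glycomodules
(`min_glyco_hits = 2`; the literature says "glycomodules", plural, but
never states a count). Published descriptions disagree on whether the
classical gate is "greater than 50 %" or "at least 50 %"; we default to
strict `>` and route exact ties to non-classical, with the comparison
configurable (`classical_strict`). "Non-classical" itself is defined here
as high-PAST + glycomodules but failing a classical gate (missing signal
peptide or the threshold tie) — the source surveys never state their
criterion for the class, so this is artifact semantics, recorded in each
protein's rule trace. Proteins without an annotation row are treated as
having no external features (with a logged warning), so sequence-only runs
are possible; they can only yield HAE, non-classical or not-AGP.

## Genome context

**Tandem duplication.** Candidate pairs are family genes on the same
chromosome separated by at most `max_intervening = 1` other family genes in
genomic order. "Tandem" has no universal definition; nearest-neighbour
within the family is the minimal reading consistent with published tandem
clusters, and the window is a parameter. Every candidate pair is reported
with its similarity; `passes_threshold` marks the conventional ≥ 70 % rule
so that sub-threshold pairs (which published surveys also report) stay
visible. Similarity is computed from an end-to-end global alignment with
affine gaps (BLOSUM62, gap open 10, extend 0.5 — EMBOSS-style defaults) as
the percentage of alignment columns, gap columns included in the
denominator, where both residues are present and their substitution score
is positive. The alignment engine is Biopython's `PairwiseAligner`; tests
verify its optimal score against an independent Gotoh dynamic program.

**Segmental duplication.** B. rapa descends from a whole-genome
triplication; retained copies sit in collinear blocks assigned to the LF,
MF1 and MF2 subgenomes. Segmental groups are simply sets of ≥ 2 family
genes sharing the same Arabidopsis syntenic ortholog. Genes with no
ortholog are excluded. No collinearity detection is performed here — the
synteny table is an input.

**Chromosome distribution** counts genes per chromosome, with
scaffold-placed genes tallied separately; the counts always sum to the
input size.

## Phylogeny

Distances from a user-supplied multiple alignment are p-distances with
pairwise gap deletion (mismatches over gap-free site pairs) — the simplest
auditable model; pairs with zero comparable sites are an error. Tree
building is classic neighbor joining: Q-criterion join selection with ties
broken deterministically on the lowest index pair, standard branch-length
formulas, negative branch lengths clamped to zero with the deficit logged.
On an additive matrix the output tree's path-length matrix reproduces the
input to ~1e-15 (tested at 1e-9). Bootstrap support resamples alignment
columns with replacement under a seeded generator, rebuilds the tree per
replicate, and scores each internal bipartition of the point tree by the
percentage of replicates containing it; replicates that produce an
incomparable pair are skipped and the denominator adjusted. Trees are
scikit-bio `TreeNode` objects, so newick serialization and parsing are the
library's; supports round-trip as internal-node labels.

## Differential expression

The screen models a two-genotype (male-sterile vs male-fertile), five-stage
floral-bud FPKM design. Per stage and gene: `log2FC = log2((mean_F + c) /
(mean_S + c))` with pseudocount `c = 1` (keeps ratios finite; positive
values mean depressed expression in the sterile line), a two-sample Welch
test on `log2(FPKM + c)` across replicates (statistic and
Welch–Satterthwaite degrees of freedom computed here; only the
t-distribution tail is delegated), and Benjamini–Hochberg adjustment
applied within each stage (five families of tests, one per pairwise
comparison). Calls: UP/DOWN at |log2FC| ≥ 1 (boundary inclusive) and
FDR < 0.05; F-/S-specific when the mean exceeds the detection threshold
(1 FPKM, a parameter — "specifically expressed" is never quantified in the
source literature) in exactly one genotype; NOT_EXPRESSED when below in
both. A gene is differential if any stage call is UP, DOWN or specific.
In rendered tables, NS and NOT_EXPRESSED both print as "." — the
convention of published DEG tables, whose footnotes define "." as "no
difference or no expression".

The original screen of this design used DESeq (2010) on a no-replicate
layout. We deliberately do not reimplement DESeq: the defined computation
is the screening criteria (BH FDR < 0.05, |log2FC| ≥ 1), which accept any
p-value source. The synthetic path supplies replicates and the Welch test;
the real-data path accepts externally computed p-values through
`screen_degs`.

## Synthetic data

The generators emulate the *statistical structure* each stage assumes, not
evolutionary realism — no codon-level simulation, no indel history, no
predictor behaviour (signal peptide and GPI are annotation flags, not
sequence features).

* **Proteomes.** Backbones are drawn uniformly from residues outside
  P/A/S/T/K/C, so PAST content, glycomodules, Lys windows and cysteine
  motifs exist only where planted; composition is then tuned by targeted
  Ala substitutions, which guarantees each label's gates are satisfied with
  a configurable margin (default 0.05 in composition, 5 aa in length)
  without rejection sampling. Negative controls each violate exactly one
  gate (high-PAST without glycomodules; domain without glycomodules;
  AG-peptide-like without signal peptide). Construction-time assertions
  enforce all of this, and generators are pure functions of their spec.
  Consequently, 100 % label recovery on these proteomes shows the decision
  tree implements its stated rules — not that the rules are easy to satisfy
  on real proteomes, where margins are not guaranteed and annotations are
  noisy.
* **Expression.** FPKM is log-normal: gene baselines log-uniform on
  20–200 FPKM (unperturbed genes sit safely above the detection threshold),
  replicate noise sd 0.1 on the natural-log scale (~10 % CV, the low-noise
  regime of well-replicated RNA-seq for expressed genes), n = 3 replicates
  per genotype × stage. Planted effects shift the fertile mean by
  `log2FC·ln 2` at one stage (default |log2FC| = 3); planted specific genes
  draw ~0.05 FPKM in the off genotype. The default spec makes a quarter of
  genes differential, matching the fraction real floral-bud screens of this
  design report. Under these conditions the screen recalls ≥ 95 % of
  planted effects with realized false-discovery proportion ≤ 0.10 at
  FDR 0.05 (measured, not assumed — see `scripts/acceptance.py`).
* **Loci/synteny.** Tandem pairs are placed at adjacent loci with
  engineered similarity (near-identical copies at 10 % substitutions, or
  unrelated sequences for below-threshold pairs); ortholog triplets span
  LF/MF1/MF2.

## Numerical choices

* Q-matrix minimisation scans the upper triangle only: floating-point
  summation order makes Q asymmetric in the last ulp, and a full-matrix
  minimum can otherwise live strictly below the diagonal; row-major
  argmin over the upper triangle also realises the documented tie-break.
* BH adjustment is the vectorised step-up (`minimum.accumulate` over the
  reversed order statistics), exact against the definitional oracle.
* Welch test returns p = 1 for degenerate inputs (fewer than two
  replicates, or zero variance in both groups).
* Reported percentages round half-up to two decimals, the convention of
  the printed literature this pipeline's reports mirror (e.g. 194/293 →
  66.21).
* All sequence coordinates are 1-based inclusive everywhere.

## Problem sizes

The test suite and acceptance script run at desk scale by design: planted
proteomes of ~59 proteins over 20 seeds, 200-gene expression designs over
10 seeds, 100 random additive matrices of 4–10 taxa, 1000-sequence scanner
oracle sweeps, exhaustive topology enumeration up to 6 taxa. These sizes
exercise every code path and statistical property; nothing in the
implementation is size-limited beyond memory (the classifier is linear in
sequence length, NJ cubic in taxa).

## Known limitations

* Classification quality on real proteomes is bounded by the quality of the
  external annotations supplied; the pipeline cannot rescue a missed signal
  peptide or domain call.
* The Lys-rich and non-classical criteria are package definitions, not
  community standards (both are parameterised and traced in the output).
* PLA sub-subfamily labels (ENODL/UCL/SCL) and chimeric naming are accepted
  from user-supplied ortholog-derived labels, never computed: the published
  split rests on motif constitution of an external clustering this package
  does not reproduce.
* p-distance NJ is a coarse model for diverged protein families; the
  distance model is swappable but nothing model-based (ML/Bayesian) is
  provided.
* The no-replicate real-data path depends on externally computed p-values;
  the built-in Welch test requires ≥ 2 replicates per group and is
  conservative at n = 3 (attainable p is floored by df ≈ 2).
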