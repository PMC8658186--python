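"""Distance-based phylogenetics: p-distances from a pre-aligned protein
FASTA, neighbor-joining tree construction, and bootstrap support.

The distance model is the proportion of mismatching sites among sites where
neither sequence has a gap (p-distance with pairwise deletion) — the
simplest auditable choice, and swappable since every stage consumes a plain
:class:`DistanceMatrix`.  Multiple alignment is an input, not a stage.

Trees are :class:`skbio.TreeNode` objects, so newick serialization and
parsing use the library's reader/writer; the neighbor-joining agglomeration
itself (Q-criterion, branch-length formulas, deterministic tie-breaking on
the lowest index pair, clamping of negative branch lengths to zero) is
implemented here.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import AlignedRecord, ProteinRecord

AlignedInput = Sequence["AlignedRecord | ProteinRecord"]

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix entries must be finite")


def p_distance_matrix(aligned: AlignedInput) -> DistanceMatrix:
    """Pairwise p-distances over gap-free site pairs of an alignment."""
    if len(aligned) < 3:
        raise ValueError("need at least 3 aligned sequences")
    length = len(aligned[0].sequence)
    for rec in aligned:
        if len(rec.sequence) != length:
            raise ValueError(
                f"{rec.id}: aligned length {len(rec.sequence)} != {length}"
            )
    seqs = np.array([list(r.sequence) for r in aligned])
    gaps = np.isin(seqs, list(GAP_CHARS))
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable (gap-free) sites between "
                    f"{aligned[i].id!r} and {aligned[j].id!r}"
                )
            mism = int((seqs[i][ok] != seqs[j][ok]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(labels=[r.id for r in aligned], d=d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.3g at %s", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties broken by the lowest (i, j) index pair in current matrix
    order); branch lengths follow the standard formulas and negative values
    are clamped to zero.  On an additive matrix the output tree's path-length
    matrix reproduces the input exactly (up to numerical tolerance).  The
    result is unrooted: the returned root is an unnamed trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # scan the upper triangle only: row-major argmin gives the lowest
        # (i, j) pair on ties, and sidesteps last-ulp asymmetry in q
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li, f"join({child_i.name},{child_j.name})")
        child_j.length = _clamp(lj, f"join({child_i.name},{child_j.name})")
        parent = TreeNode(children=[child_i, child_j])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal 3-node star: three-point formulas
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length = _clamp(la, "root")
    b.length = _clamp(lb, "root")
    c.length = _clamp(lc, "root")
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode) -> dict[TreeNode, frozenset[frozenset[str]]]:
    """Map each internal (non-root) node to its unordered tip bipartition."""
    tips = frozenset(t.name for t in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out[node] = frozenset({side, tips - side})
    return out


def bootstrap_support(
    aligned: AlignedInput,
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ point tree with per-edge bootstrap support percentages.

    Alignment columns are resampled with replacement ``n_replicates`` times;
    each replicate alignment is rebuilt into an NJ tree and the support of an
    internal edge of the point tree is the percentage of replicates whose
    tree contains the same tip bipartition.  Replicates in which some pair
    has no comparable sites are skipped with a warning and the denominator
    adjusted.  Supports are stored on internal nodes (``node.support`` and
    the newick internal label).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(aligned))
    point_biparts = _bipartitions(tree)
    counts = {node: 0 for node in point_biparts}
    rng = np.random.default_rng(seed)
    length = len(aligned[0].sequence)
    cols = np.array([list(r.sequence) for r in aligned])
    used = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        replicate = [
            AlignedRecord(id=r.id, sequence="".join(cols[k][idx]))
            for k, r in enumerate(aligned)
        ]
        try:
            rep_tree = neighbor_joining(p_distance_matrix(replicate))
        except ValueError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        used += 1
        rep_biparts = set(_bipartitions(rep_tree).values())
        for node, bipart in point_biparts.items():
            if bipart in rep_biparts:
                counts[node] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates failed")
    for node, c in counts.items():
        node.support = round(100.0 * c / used, 4)
    return tree


def write_newick(tree: TreeNode, path: Optional[str] = None) -> str:
    """Serialize a tree to newick (supports appear as internal-node labels)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source: str) -> TreeNode:
    """Parse newick text (or a path) into a tree."""
    if "(" in source:
        tree = TreeNode.read(io.StringIO(source), format="newick")
    else:
        tree = TreeNode.read(source, format="newick")
    tree.assign_supports()
    return tree
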