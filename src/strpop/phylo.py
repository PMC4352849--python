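"""Distance-based trees: UPGMA, neighbor joining, bootstrap-over-loci.

Trees are :class:`skbio.TreeNode` objects (Newick-serializable).  Both
agglomerations break ties deterministically on the lexicographically
smallest pair of cluster labels (a cluster's label is its smallest leaf
name), so a given matrix always yields the same tree on any platform.

UPGMA produces a rooted ultrametric tree (merge heights halved into
branch lengths).  NJ (Saitou & Nei) produces an unrooted tree,
represented with a trifurcating root; negative branch-length estimates
are clipped to zero with the deficit moved to the sister branch, so
path lengths between leaves are preserved.

Bootstrap support resamples loci with replacement, rebuilds the DA
distance matrix and tree per replicate, and annotates each internal
edge of the full-locus reference tree with the fraction of replicates
containing the same leaf bipartition.
"""

from __future__ import annotations

import io as _io
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .popdiff import PopulationDistances, da_matrix, nei_da
from .tables import AlleleFrequencyTable

__all__ = [
    "upgma",
    "neighbor_joining",
    "bootstrap_over_loci",
    "to_newick",
    "from_newick",
    "bipartitions",
]


def _as_distance_matrix(d) -> DistanceMatrix:
    if isinstance(d, PopulationDistances):
        return d.matrix
    if isinstance(d, DistanceMatrix):
        return d
    return DistanceMatrix(d)  # validates symmetry / hollowness


def upgma(d) -> TreeNode:
    """Average-linkage (UPGMA) rooted ultrametric tree from a distance matrix."""
    dm = _as_distance_matrix(d)
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    # cluster key = lexicographically smallest member name
    nodes: dict[str, TreeNode] = {}
    heights: dict[str, float] = {}
    sizes: dict[str, int] = {}
    dist: dict[frozenset[str], float] = {}
    for name in ids:
        nodes[name] = TreeNode(name=name)
        heights[name] = 0.0
        sizes[name] = 1
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[frozenset((a, b))] = dm[a, b]

    while len(nodes) > 1:
        keys = sorted(nodes)
        best = min(
            ((dist[frozenset((a, b))], a, b)
             for i, a in enumerate(keys) for b in keys[i + 1 :]),
        )
        d_ab, a, b = best
        height = d_ab / 2.0
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = height - heights[a]
        child_b.length = height - heights[b]
        parent = TreeNode(children=[child_a, child_b])
        merged = min(a, b)
        size_a, size_b = sizes.pop(a), sizes.pop(b)
        heights.pop(a), heights.pop(b)
        for other in list(nodes):
            dist[frozenset((merged, other))] = (
                size_a * dist.pop(frozenset((a, other)))
                + size_b * dist.pop(frozenset((b, other)))
            ) / (size_a + size_b)
        dist.pop(frozenset((a, b)))
        nodes[merged] = parent
        heights[merged] = height
        sizes[merged] = size_a + size_b
    (root,) = nodes.values()
    root.length = None
    return root


def neighbor_joining(d) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted tree with a trifurcating root."""
    dm = _as_distance_matrix(d)
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[frozenset((a, b))] = dm[a, b]

    def clip(la: float, lb: float) -> tuple[float, float]:
        # negative estimate -> zero, deficit moved to the sister branch
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(nodes) > 3:
        keys = sorted(nodes)
        n = len(keys)
        r = {a: sum(dist[frozenset((a, b))] for b in keys if b != a) for a in keys}
        best = min(
            (
                ((n - 2) * dist[frozenset((a, b))] - r[a] - r[b], a, b)
                for i, a in enumerate(keys)
                for b in keys[i + 1 :]
            )
        )
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d_ab - la
        la, lb = clip(la, lb)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = la
        child_b.length = lb
        parent = TreeNode(children=[child_a, child_b])
        merged = min(a, b)
        for other in list(nodes):
            d_new = 0.5 * (
                dist.pop(frozenset((a, other)))
                + dist.pop(frozenset((b, other)))
                - d_ab
            )
            dist[frozenset((merged, other))] = d_new
        dist.pop(frozenset((a, b)))
        nodes[merged] = parent

    (a, b, c) = sorted(nodes)
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    for key, length in ((a, la), (b, lb), (c, lc)):
        nodes[key].length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick; internal-node ``support`` becomes the label."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    """Parse Newick; numeric internal-node labels are read back as support."""
    tree = TreeNode.read(_io.StringIO(text), format="newick")
    tree.assign_supports()
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized to the side
    not containing the lexicographically smallest leaf name."""
    tips = frozenset(t.name for t in tree.tips())
    anchor = min(tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = tips - side
        if 1 < len(side) < len(tips) - 1:
            out.add(side)
    return out


def bootstrap_over_loci(
    populations: Sequence[AlleleFrequencyTable],
    loci: Sequence[str] | None = None,
    n_replicates: int = 1000,
    method: str = "upgma",
    seed: int | None = None,
) -> TreeNode:
    """Tree with bootstrap-over-loci support on internal edges.

    Loci are resampled with replacement ``n_replicates`` times; each
    replicate rebuilds the DA matrix and the tree; each internal edge of
    the reference (full-locus) tree gets the fraction of replicates whose
    tree contains the same leaf bipartition (``node.support``).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    build = {"upgma": upgma, "nj": neighbor_joining}.get(method)
    if build is None:
        raise ValueError(f"unknown method {method!r}")
    loci = list(loci) if loci is not None else populations[0].loci
    if len(loci) < 2:
        raise ValueError("bootstrap over a single locus is degenerate")
    reference = build(da_matrix(populations, loci))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, len(loci), size=(n_replicates, len(loci)))
    for row in resamples:
        rep_loci = [loci[i] for i in row]
        rep_tree = build(da_matrix(populations, rep_loci))
        for side in bipartitions(rep_tree):
            counts[side] = counts.get(side, 0) + 1
    tips = frozenset(t.name for t in reference.tips())
    anchor = min(tips)
    for node in reference.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = tips - side
        if len(side) > 1 and len(tips) - len(side) > 1:
            node.support = counts.get(side, 0) / n_replicates
    return reference
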