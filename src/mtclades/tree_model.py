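"""Rooted weighted trees: Newick I/O, leaf path distances, max-clade clustering.

The clustering implemented here partitions the leaves of a rooted tree into
*maximal valid clades*: every cluster is the full leaf set of one clade, the
maximum pairwise path distance inside a cluster never exceeds the threshold,
and no cluster could be enlarged to its parent clade without breaking that
bound.  Because clades are nested or disjoint and the constraint is monotone
in the threshold, partitions at smaller thresholds refine partitions at
larger ones — the property that makes multi-threshold haplotype addresses
(`mthg_address`) well defined.

The algorithm is linear in the number of nodes: a post-order pass tracks, for
each node, the largest leaf depth through each child and the largest
intra-clade leaf-pair distance; a pre-order pass then emits a cluster at
every highest node whose clade satisfies the bound.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidThresholdError, NewickError

__all__ = [
    "TreeNode",
    "Phylogeny",
    "ClusterPartition",
    "read_newick",
    "write_newick",
    "leaf_distance_matrix",
    "max_clade_partition",
    "threshold_sweep",
]

#: Absolute tolerance guarding floating-point summation noise in threshold
#: comparisons (the bound itself is inclusive: "at most equal").
THRESHOLD_ATOL = 1e-12


@dataclass
class TreeNode:
    """One node of a rooted phylogeny."""

    label: Optional[str] = None
    branch_length: Optional[float] = None  # None only at the root
    children: List["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique leaf labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()
        self._validate()

    def _index(self) -> None:
        # Postorder node list; children before parents, leaves in left-to-right order.
        post: List[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                post.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    child.parent = node
                    stack.append((child, False))
        self.postorder: List[TreeNode] = post
        self.leaves: List[TreeNode] = [n for n in post if n.is_leaf]
        self.leaf_labels: List[str] = [n.label for n in self.leaves]

    def _validate(self) -> None:
        labels = self.leaf_labels
        if any(lbl is None or lbl == "" for lbl in labels):
            raise NewickError("every leaf must carry a label")
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise NewickError(f"duplicate leaf labels: {sorted(dup)}")
        for node in self.postorder:
            if node is self.root:
                continue
            if node.branch_length is None:
                raise NewickError(f"missing branch length above {node.label or 'internal node'}")
            if node.branch_length < 0:
                raise NewickError(
                    f"negative branch length {node.branch_length} above "
                    f"{node.label or 'internal node'}"
                )

    def __len__(self) -> int:
        return len(self.leaves)

    def scale_branch_lengths(self, factor: float) -> None:
        """Multiply every branch length in place."""
        for node in self.postorder:
            if node.branch_length is not None:
                node.branch_length *= factor

    def leaf_depths(self) -> Dict[str, float]:
        """Path length from the root to each leaf."""
        depth: Dict[int, float] = {id(self.root): 0.0}
        for node in reversed(self.postorder):  # preorder
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + node.branch_length
        return {leaf.label: depth[id(leaf)] for leaf in self.leaves}

    def diameter(self) -> float:
        """Largest leaf-pair path distance."""
        _, diam = _node_stats(self)
        return diam


def read_newick(text: str, *, default_branch_length: Optional[float] = None) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    dendropy does the tokenising (quoted labels, ``[...]`` comments); this
    wrapper enforces the package's tree contract: rooted interpretation,
    unique non-empty leaf labels, and branch lengths present (or defaulted
    via ``default_branch_length``) and non-negative.  An explicit ``[&U]``
    (unrooted) token is rejected: clades — and therefore clusters and
    addresses — are undefined on unrooted trees; root the tree (the usual
    choice for human mtDNA is an RSRS outgroup) before clustering.
    """
    import dendropy

    if "[&U]" in text.upper().replace(" ", ""):
        raise NewickError(
            "tree is explicitly unrooted ([&U]); root it (e.g. on RSRS) before use"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None and default_branch_length is not None:
            length = default_branch_length
        node = TreeNode(label=label, branch_length=length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.branch_length = None  # a root edge length carries no leaf-pair information
    return Phylogeny(root)


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "()[]{}/\\,;:=*'\"`<>+- \t\n")


def _format_label(label: Optional[str]) -> str:
    if not label:
        return ""
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, *, precision: int = 12) -> str:
    """Serialise a phylogeny to a Newick string (round-trips with read_newick)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = _format_label(node.label)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + _format_label(node.label)
        if node.branch_length is not None:
            body += ":" + repr(round(node.branch_length, precision))
        return body

    return fmt(tree.root) + ";"


def _node_stats(tree: Phylogeny):
    """Post-order pass: per node, (max leaf depth below, max intra-clade pair distance).

    Returns the stats dict keyed by node identity and the tree diameter.
    """
    stats: Dict[int, tuple] = {}
    diameter = 0.0
    for node in tree.postorder:
        if node.is_leaf:
            stats[id(node)] = (0.0, 0.0)
            continue
        child_depths = []
        max_pair = 0.0
        for child in node.children:
            cdepth, cpair = stats[id(child)]
            child_depths.append(cdepth + child.branch_length)
            max_pair = max(max_pair, cpair)
        child_depths.sort(reverse=True)
        if len(child_depths) >= 2:
            max_pair = max(max_pair, child_depths[0] + child_depths[1])
        stats[id(node)] = (child_depths[0], max_pair)
        diameter = max(diameter, max_pair)
    return stats, diameter


def leaf_distance_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Symmetric matrix of leaf-pair path distances (sum of branch lengths)."""
    labels = tree.leaf_labels
    idx = {lbl: i for i, lbl in enumerate(labels)}
    depths = tree.leaf_depths()
    d = np.zeros((len(labels), len(labels)))
    # d(x, y) = depth(x) + depth(y) - 2 * depth(mrca): accumulate per internal
    # node over leaf pairs whose paths meet there (pairs in different child
    # subtrees), which visits each unordered pair exactly once.
    below: Dict[int, List[str]] = {}
    node_depth: Dict[int, float] = {id(tree.root): 0.0}
    for node in reversed(tree.postorder):
        if node is not tree.root:
            node_depth[id(node)] = node_depth[id(node.parent)] + node.branch_length
    for node in tree.postorder:
        if node.is_leaf:
            below[id(node)] = [node.label]
            continue
        groups = [below[id(c)] for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        dist = depths[a] + depths[b] - 2.0 * node_depth[id(node)]
                        d[idx[a], idx[b]] = dist
                        d[idx[b], idx[a]] = dist
        below[id(node)] = [lbl for g in groups for lbl in g]
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class ClusterPartition:
    """Leaf partition into maximal valid clades at one distance threshold."""

    threshold: float
    assignment: Dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> Dict[int, List[str]]:
        groups: Dict[int, List[str]] = {}
        for leaf, cid in self.assignment.items():
            groups.setdefault(cid, []).append(leaf)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.assignment), "cluster_id": list(self.assignment.values())}
        )

    def metadata(self) -> dict:
        return {"threshold": self.threshold, "n_clusters": self.n_clusters}


def max_clade_partition(tree: Phylogeny, threshold: float) -> ClusterPartition:
    """Partition leaves into maximal clades whose diameter is ≤ ``threshold``.

    The bound is inclusive, compared with an absolute tolerance of 1e-12.
    Every leaf gets a cluster id (singletons included); ids are dense
    integers numbered by the order of each cluster's first leaf in the
    canonical left-to-right traversal, so identical inputs always yield
    identical ids.
    """
    if threshold < 0:
        raise InvalidThresholdError(f"threshold must be non-negative, got {threshold}")
    stats, _ = _node_stats(tree)
    assignment: Dict[str, int] = {}
    next_id = 0

    def leaves_below(node: TreeNode) -> List[str]:
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.append(cur.label)
            else:
                stack.extend(reversed(cur.children))
        return out

    stack = [tree.root]
    while stack:
        node = stack.pop()
        _, max_pair = stats[id(node)]
        if max_pair <= threshold + THRESHOLD_ATOL:
            nonlocal_id = next_id
            for leaf in leaves_below(node):
                assignment[leaf] = nonlocal_id
            next_id += 1
        else:
            stack.extend(reversed(node.children))
    return ClusterPartition(threshold=threshold, assignment=assignment)


def threshold_sweep(tree: Phylogeny, thresholds: Sequence[float]) -> List[ClusterPartition]:
    """Run max-clade clustering over a strictly decreasing threshold ladder."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidThresholdError("threshold ladder must be non-empty")
    if any(t < 0 for t in thresholds):
        raise InvalidThresholdError("all thresholds must be non-negative")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidThresholdError(
            f"thresholds must be strictly decreasing, got {thresholds}"
        )
    return [max_clade_partition(tree, t) for t in thresholds]


def write_partition(partition: ClusterPartition, out_prefix: str, tree_hash: str = "") -> None:
    """Write a partition as TSV plus a JSON run-metadata sidecar."""
    partition.to_frame().to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
    meta = partition.metadata()
    if tree_hash:
        meta["tree_sha256"] = tree_hash
    with io.open(f"{out_prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
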