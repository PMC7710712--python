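"""Phylogeny manipulation: consensus, polytomy resolution, sister tips, VCV.

Trees are dendropy objects treated as *rooted* throughout (the candidate
trees from birdtree.org are rooted), so consensus works on clades — sets of
tip labels descending from an internal node — rather than unrooted
bipartitions.  A clade enters the majority-rule consensus when it occurs in
strictly more than the threshold fraction of input trees; its branch length
is the mean (or median) of that branch over the supporting trees.

The species covariance matrix C has C[i, j] equal to the shared root-to-tip
path length of tips i and j, i.e. the depth of their most recent common
ancestor, and C[i, i] equal to the root-to-tip distance.  Pagel's lambda
rescaling multiplies the off-diagonal entries by lambda and leaves the
diagonal alone.
"""

from __future__ import annotations

import copy
import random
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .data_io import TreeSet, canonical_name

__all__ = [
    "VCVMatrix",
    "majority_consensus",
    "resolve_polytomies",
    "add_sister_tips",
    "vcv_from_tree",
    "lambda_scale",
    "prune_and_align",
    "clade_counts",
]


@dataclass
class VCVMatrix:
    """A labeled phylogenetic covariance (or correlation) matrix."""

    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def index_of(self, label: str) -> int:
        key = canonical_name(label).casefold()
        for i, lab in enumerate(self.labels):
            if canonical_name(lab).casefold() == key:
                return i
        raise KeyError(f"label {label!r} not in matrix")

    def submatrix(self, labels: Sequence[str]) -> "VCVMatrix":
        idx = [self.index_of(lab) for lab in labels]
        return VCVMatrix(labels=list(labels), C=self.C[np.ix_(idx, idx)])

    def to_correlation(self) -> "VCVMatrix":
        d = np.sqrt(np.diag(self.C))
        if np.any(d <= 0):
            raise ValueError("zero root-to-tip distance; correlation undefined")
        return VCVMatrix(labels=list(self.labels), C=self.C / np.outer(d, d))


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clade_counts(trees: Iterable[dendropy.Tree]):
    """Count clades (frozensets of tip labels) and collect their edge lengths.

    Returns (counts, lengths, tip_lengths, n_trees).  The root clade (all
    tips) is excluded; tip terminal-branch lengths are collected separately.
    """
    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    tip_lengths: dict[str, list[float]] = {}
    n_trees = 0
    for tree in trees:
        n_trees += 1
        all_tips = frozenset(_leaf_labels(tree))
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                tip_lengths.setdefault(label, []).append(node.edge.length or 0.0)
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if clade == all_tips:
                continue
            counts[clade] = counts.get(clade, 0) + 1
            lengths.setdefault(clade, []).append(node.edge.length or 0.0)
    return counts, lengths, tip_lengths, n_trees


def majority_consensus(
    trees: TreeSet | Sequence[dendropy.Tree],
    threshold: float = 0.5,
    length_rule: str = "mean",
) -> dendropy.Tree:
    """Majority-rule consensus of rooted trees sharing one tip set.

    A clade is retained iff it occurs in strictly more than ``threshold`` of
    the input trees; retained branch lengths are the mean (default) or median
    over the supporting trees, and tip branch lengths average over all trees.
    Regions without a majority clade stay as polytomies.
    """
    tree_list = list(trees)
    if not tree_list:
        raise ValueError("empty tree set")
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if length_rule not in ("mean", "median"):
        raise ValueError(f"unknown length rule {length_rule!r}")
    tip_sets = {frozenset(_leaf_labels(t)) for t in tree_list}
    if len(tip_sets) != 1:
        raise ValueError("input trees do not share a common tip set")
    summarize = statistics.mean if length_rule == "mean" else statistics.median

    counts, lengths, tip_lengths, n_trees = clade_counts(tree_list)
    all_tips = next(iter(tip_sets))
    retained = [c for c, n in counts.items() if n / n_trees > threshold]
    # majority clades are pairwise compatible, so sorting by size gives a
    # valid nesting order (ties broken lexicographically for determinism)
    retained.sort(key=lambda c: (-len(c), tuple(sorted(c))))

    taxa = dendropy.TaxonNamespace(sorted(all_tips))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    node_for: dict[frozenset, dendropy.Node] = {all_tips: tree.seed_node}
    placed: list[frozenset] = [all_tips]
    for clade in retained:
        parent = min(
            (c for c in placed if clade < c), key=len
        )  # smallest strict superset already placed
        node = dendropy.Node()
        node.edge.length = summarize(lengths[clade])
        node_for[parent].add_child(node)
        node_for[clade] = node
        placed.append(clade)
    for label in sorted(all_tips):
        parent = min((c for c in placed if label in c), key=len)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        leaf.edge.length = summarize(tip_lengths[label])
        node_for[parent].add_child(leaf)
    return tree


def resolve_polytomies(
    tree: dendropy.Tree, epsilon: float = 1e-8, seed: int = 0
) -> dendropy.Tree:
    """Resolve every polytomy into a binary subtree with epsilon branches.

    Each polytomy is resolved by repeatedly splitting off a seeded-randomly
    chosen pair of children into a new internal node whose subtending branch
    has length ``epsilon``; root-to-tip distances therefore change by at most
    epsilon times the number of insertions.  A binary tree is returned
    unchanged (as a copy).
    """
    out = copy.deepcopy(tree)
    rng = random.Random(seed)
    for node in list(out.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            i, j = sorted(rng.sample(range(len(children)), 2))
            pair = [children[i], children[j]]
            new = dendropy.Node()
            new.edge.length = epsilon
            for child in pair:
                node.remove_child(child)
                new.add_child(child)
            node.add_child(new)
            children = node.child_nodes()
    return out


def add_sister_tips(
    tree: dendropy.Tree,
    species: str,
    k: int,
    seed: int = 0,
    epsilon: float = 1e-8,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Replace a tip with k sister tips of the original terminal branch length.

    The new tips ("species#1" ... "species#k" unless ``labels`` is given)
    attach at the original tip's parent, forming a polytomy that is then
    resolved with epsilon branches, so the pairwise covariance among the k
    tips equals the original tip's parent depth up to a few epsilon.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (use the original tip for k = 1)")
    out = copy.deepcopy(tree)
    key = canonical_name(species).casefold()
    target = None
    for leaf in out.leaf_node_iter():
        if canonical_name(leaf.taxon.label).casefold() == key:
            target = leaf
            break
    if target is None:
        raise KeyError(f"species {species!r} is not a tip of the tree")
    parent = target.parent_node
    blen = target.edge.length or 0.0
    if labels is None:
        labels = [f"{target.taxon.label}#{i + 1}" for i in range(k)]
    elif len(labels) != k:
        raise ValueError("labels length must equal k")
    parent.remove_child(target)
    out.taxon_namespace.remove_taxon(target.taxon)
    for lab in labels:
        taxon = dendropy.Taxon(label=lab)
        out.taxon_namespace.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        node.edge.length = blen
        parent.add_child(node)
    return resolve_polytomies(out, epsilon=epsilon, seed=seed)


def vcv_from_tree(tree: dendropy.Tree, scale: str = "covariance") -> VCVMatrix:
    """Species covariance matrix of shared root-to-tip path lengths.

    ``scale='correlation'`` divides each entry by the geometric mean of the
    paired diagonals (for an ultrametric tree, by the tree depth), forcing a
    unit diagonal.
    """
    if scale not in ("covariance", "correlation"):
        raise ValueError(f"unknown scale {scale!r}")
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise ValueError("negative branch length")
        depth[id(node)] = depth[id(node.parent_node)] + length

    # postorder: tips below each node, filling cross-child pairs at MRCA depth
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            C[i, i] = depth[id(node)]
            below[id(node)] = [i]
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = d
        merged: list[int] = []
        for s in child_sets:
            merged.extend(s)
        below[id(node)] = merged

    vcv = VCVMatrix(labels=labels, C=C)
    return vcv.to_correlation() if scale == "correlation" else vcv


def lambda_scale(C: VCVMatrix | np.ndarray, lam: float):
    """Pagel's lambda rescaling: off-diagonals times lambda, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda={lam} outside [0, 1]")
    if isinstance(C, VCVMatrix):
        return VCVMatrix(labels=list(C.labels), C=lambda_scale(C.C, lam))
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def prune_and_align(
    tree: dendropy.Tree, species: Sequence[str]
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Prune the tree to the requested species, preserving path lengths.

    Returns the pruned tree and a map from canonical species key to the row
    index used by :func:`vcv_from_tree` on the pruned tree (its leaf order).
    """
    keys = [canonical_name(s).casefold() for s in species]
    tip_map = {
        canonical_name(l.taxon.label).casefold(): l.taxon.label
        for l in tree.leaf_node_iter()
    }
    missing = [s for s, k in zip(species, keys) if k not in tip_map]
    if missing:
        raise KeyError(f"species absent from tree: {missing}")
    keep = {k for k in keys}

    pruned = copy.deepcopy(tree)
    pruned.is_rooted = True
    # drop unwanted leaves (repeatedly: removals can expose new leaves)
    while True:
        victims = [
            leaf
            for leaf in pruned.leaf_node_iter()
            if leaf.taxon is None
            or canonical_name(leaf.taxon.label).casefold() not in keep
        ]
        if not victims:
            break
        for leaf in victims:
            leaf.parent_node.remove_child(leaf)
            if leaf.taxon is not None:
                pruned.taxon_namespace.remove_taxon(leaf.taxon)
    # suppress degree-2 internal nodes, merging edge lengths so every
    # root-to-tip path length is preserved (the root itself may keep a
    # single child: its depth stays zero either way)
    for node in list(pruned.postorder_node_iter()):
        if node is pruned.seed_node or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    # a root unifurcation (root-to-MRCA chain collapsed onto one edge) is
    # kept as-is: the child's edge length preserves the shared path depth
    index_map = {
        canonical_name(l.taxon.label).casefold(): i
        for i, l in enumerate(pruned.leaf_node_iter())
    }
    return pruned, index_map
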