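"""Phylogenetic diversity and phylogenetic gain of leaf sets on a fixed tree.

Phylogenetic diversity (PD) of a leaf set is the total branch length of
the minimal subtree connecting those leaves, computed on the unrooted
edge set (the root edge is excluded, so the measure is invariant to where
the input tree happens to be rooted).  Phylogenetic gain of a focal leaf
set over a base set is the additional branch length the focal leaves
contribute: PD(focal u base) - PD(base).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy

from .io_formats import read_newick, total_tree_length


@dataclass
class PDResult:
    diversity: float
    diversity_percent: float   # of total tree length
    gain: float | None = None
    gain_percent: float | None = None  # of PD(focal u base)


def _leaf_sets_below(tree: dendropy.Tree) -> dict:
    """Map each node to the set of leaf labels in its subtree."""
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= below[ch]
            below[node] = frozenset(s)
    return below


def _validate_leaves(tree: dendropy.Tree, leaves: Iterable[str]) -> frozenset:
    want = frozenset(leaves)
    have = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = want - have
    if unknown:
        raise KeyError(f"leaf labels not in tree: {sorted(unknown)}")
    return want

def phylogenetic_diversity(
    tree: dendropy.Tree, leaves: Iterable[str]
) -> PDResult:
    """PD of a leaf set: an edge contributes its length iff the set has
    leaves on both of its sides, which on the unrooted edge set is exactly
    the minimal spanning subtree.  Sets of fewer than two leaves span no
    edges (PD = 0)."""
    want = _validate_leaves(tree, leaves)
    total = total_tree_length(tree)
    if len(want) < 2:
        return PDResult(0.0, 0.0)
    below = _leaf_sets_below(tree)
    pd_sum = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        inside = len(want & below[node])
        if 0 < inside < len(want):
            pd_sum += node.edge.length or 0.0
    pct = 100.0 * pd_sum / total if total > 0 else 0.0
    return PDResult(pd_sum, pct)


def phylogenetic_gain(
    tree: dendropy.Tree, focal: Iterable[str], base: Iterable[str]
) -> PDResult:
    """Additional branch length contributed by ``focal`` beyond ``base``:
    gain = PD(focal u base) - PD(base); the percentage is relative to the
    combined PD (absolute units are always reported alongside)."""
    focal_set = _validate_leaves(tree, focal)
    base_set = _validate_leaves(tree, base)
    if focal_set & base_set:
        raise ValueError(
            f"focal and base leaf sets overlap: {sorted(focal_set & base_set)}"
        )
    union_pd = phylogenetic_diversity(tree, focal_set | base_set)
    base_pd = phylogenetic_diversity(tree, base_set)
    gain = union_pd.diversity - base_pd.diversity
    gain_pct = 100.0 * gain / union_pd.diversity if union_pd.diversity > 0 else 0.0
    return PDResult(
        union_pd.diversity, union_pd.diversity_percent, gain, gain_pct
    )


def pd_from_files(
    tree_path, focal_path, base_path=None
) -> PDResult:
    """Convenience wrapper: newick file plus leaf-list text files (one
    label per line)."""
    tree = read_newick(tree_path)
    focal = _read_leaf_list(focal_path)
    if base_path is None:
        return phylogenetic_diversity(tree, focal)
    return phylogenetic_gain(tree, focal, _read_leaf_list(base_path))


def _read_leaf_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
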