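"""Majority-rule consensus of gene trees via bipartition counting.

Every internal edge of an unrooted tree splits the leaf set in two; the
majority-rule consensus retains exactly the splits found in strictly more
than a threshold fraction (default one half) of the input trees. For any
threshold >= 0.5 the retained splits are pairwise compatible, so they
assemble into a unique (possibly multifurcating) tree whose edges carry the
split frequencies as percent support.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from .errors import ConfigError, ValidationError


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each split is canonicalized as the side *not* containing the reference
    taxon (the lexicographically smallest leaf label). Trees with fewer than
    4 leaves have no non-trivial splits.
    """
    labels = _leaf_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate leaf labels in tree")
    if len(labels) < 4:
        return set()
    all_leaves = frozenset(labels)
    ref = min(labels)
    splits: set[frozenset[str]] = set()
    # leaf set under each internal node (iterating postorder, unrooted view)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if ref in side:
            side = all_leaves - side
        if len(side) >= 2:
            splits.add(side)
    return splits


@dataclass
class ConsensusTree:
    tree: dendropy.Tree
    supports: dict[frozenset[str], float]  # split -> percent of input trees
    n_trees: int

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _build_from_clusters(
    all_leaves: frozenset[str],
    clusters: Sequence[frozenset[str]],
    supports: dict[frozenset[str], float],
) -> str:
    """Assemble a Newick string from a laminar family of leaf clusters.

    Clusters are inserted largest-first into a containment tree; leaves not
    claimed by any child cluster attach directly to their smallest enclosing
    cluster. Edge labels carry integer-percent support.
    """
    nodes: list[dict] = [{"leaves": all_leaves, "children": [], "support": None}]
    for cl in sorted(clusters, key=lambda c: (-len(c), sorted(c))):
        # parent = smallest existing cluster strictly containing cl
        candidates = [i for i, nd in enumerate(nodes) if cl < nd["leaves"]]
        parent_idx = min(candidates, key=lambda i: len(nodes[i]["leaves"]))
        new_idx = len(nodes)
        nodes.append({"leaves": cl, "children": [], "support": supports.get(cl)})
        parent = nodes[parent_idx]
        moved = [ci for ci in parent["children"] if nodes[ci]["leaves"] <= cl]
        parent["children"] = [ci for ci in parent["children"] if ci not in moved]
        parent["children"].append(new_idx)
        nodes[new_idx]["children"] = moved

    def render(idx: int) -> str:
        nd = nodes[idx]
        claimed: set[str] = set()
        for ci in nd["children"]:
            claimed |= nodes[ci]["leaves"]
        parts = [render(ci) for ci in sorted(nd["children"], key=lambda c: sorted(nodes[c]["leaves"]))]
        parts.extend(_quote(l) for l in sorted(nd["leaves"] - claimed))
        inner = ",".join(parts)
        if idx == 0:
            return f"({inner});"
        sup = nd["support"]
        label = "" if sup is None else str(int(round(sup)))
        return f"({inner}){label}"

    return render(0)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> ConsensusTree:
    """Majority-rule consensus: keep splits present in strictly more than
    ``threshold`` of the input trees (a split in exactly half is excluded).

    All trees must share one identical leaf set. Unresolved parts of the
    consensus remain polytomies; supports are percent of input trees.
    """
    if not trees:
        raise ConfigError("consensus requires at least one tree")
    if not 0.5 <= threshold < 1.0:
        raise ConfigError("threshold must be in [0.5, 1); lower values can yield incompatible splits")
    ref_leaves = frozenset(_leaf_labels(trees[0]))
    for i, t in enumerate(trees):
        leaves = frozenset(_leaf_labels(t))
        if leaves != ref_leaves:
            raise ValidationError(
                f"tree {i + 1} has a different leaf set "
                f"(extra: {sorted(leaves - ref_leaves)}, missing: {sorted(ref_leaves - leaves)})"
            )
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    n = len(trees)
    retained = {split: 100.0 * c / n for split, c in counts.items() if c / n > threshold}
    newick = _build_from_clusters(ref_leaves, list(retained), retained)
    tns = trees[0].taxon_namespace
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    return ConsensusTree(tree=tree, supports=retained, n_trees=n)


def same_topology(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Unrooted topological identity via bipartition-set equality."""
    if frozenset(_leaf_labels(a)) != frozenset(_leaf_labels(b)):
        return False
    return bipartitions(a) == bipartitions(b)
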