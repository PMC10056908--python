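"""Consensus trees and bipartition bookkeeping.

Splits are canonical leaf bitmasks in a fixed taxon order: the side of the
bipartition *not* containing the first taxon (for the packaged dataset the
root outgroup comes first, so clades are read directly off the mask).
Consensus trees may be multifurcating and are returned as dendropy trees.
"""

from __future__ import annotations

import numpy as np
import dendropy


def split_masks(tree: dendropy.Tree, taxa: list[str]) -> frozenset[int]:
    """Non-trivial canonical splits of a (possibly multifurcating) tree."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    full = (1 << n) - 1
    splits = set()

    def walk(node) -> int:
        if node.is_leaf():
            if node.taxon.label not in index:
                raise ValueError(f"leaf {node.taxon.label!r} not in taxon set")
            return 1 << index[node.taxon.label]
        mask = 0
        for ch in node.child_nodes():
            mask |= walk(ch)
        m = mask
        if m & 1:
            m = full ^ m
        if 2 <= bin(m).count("1") <= n - 2:
            splits.add(m)
        return mask

    seen = walk(tree.seed_node)
    if seen != full:
        raise ValueError("tree does not cover the full taxon set")
    return frozenset(splits)


def mask_to_clade(mask: int, taxa: list[str]) -> frozenset[str]:
    return frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)


def clade_to_mask(clade, taxa: list[str]) -> int:
    """Canonical split mask for a set of taxon labels."""
    n = len(taxa)
    full = (1 << n) - 1
    m = 0
    for t in clade:
        m |= 1 << taxa.index(t)
    if m & 1:
        m = full ^ m
    return m


def tree_from_splits(
    splits: frozenset[int],
    taxa: list[str],
    labels: dict[int, str] | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Build the (multifurcating) tree containing exactly the given
    pairwise-compatible canonical splits, rooted at the first taxon's side.

    ``labels`` optionally maps a split mask to an internal node label
    (e.g. a support value)."""
    n = len(taxa)
    for a in splits:
        for b in splits:
            if a & b and a | b != max(a, b) and (a & b) not in (a, b):
                raise ValueError("splits are not pairwise compatible")
    ordered = sorted(splits, key=lambda m: bin(m).count("1"))

    def name(i: int) -> str:
        return f"'{taxa[i]}'" if " " in taxa[i] else taxa[i]

    # nest each split under its smallest strict superset
    children: dict[int | None, list] = {None: []}
    parent_of: dict[int, int | None] = {}
    for m in sorted(splits, key=lambda m: -bin(m).count("1")):
        sups = [s for s in splits if s != m and (s & m) == m]
        parent_of[m] = min(sups, key=lambda s: bin(s).count("1")) if sups else None
        children.setdefault(m, [])
        children[parent_of[m]].append(m)
    leaf_parent: dict[int, int | None] = {}
    for i in range(n):
        bit = 1 << i
        holders = [s for s in splits if s & bit]
        leaf_parent[i] = min(holders, key=lambda s: bin(s).count("1")) if holders else None

    def render(m: int | None) -> str:
        parts = [render(c) for c in children.get(m, [])]
        parts += [name(i) for i in range(n) if leaf_parent[i] == m]
        if m is None:
            return "(" + ",".join(parts) + ")"
        lab = labels.get(m, "") if labels else ""
        return "(" + ",".join(parts) + ")" + lab

    newick = render(None) + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxon_namespace,
                             preserve_underscores=True)


def _common_taxa(trees) -> list[str]:
    taxa = sorted({lf.taxon.label for lf in trees[0].leaf_node_iter()})
    for t in trees[1:]:
        if sorted({lf.taxon.label for lf in t.leaf_node_iter()}) != taxa:
            raise ValueError("trees are over different taxon sets")
    return taxa


def strict_consensus(trees: list[dendropy.Tree], taxa: list[str] | None = None) -> dendropy.Tree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValueError("need at least one tree")
    taxa = list(taxa) if taxa else _common_taxa(trees)
    common = None
    for t in trees:
        s = split_masks(t, taxa)
        common = s if common is None else (common & s)
    return tree_from_splits(frozenset(common), taxa)


def majority_rule_consensus(
    trees: list[dendropy.Tree],
    threshold: float = 0.5,
    taxa: list[str] | None = None,
) -> dendropy.Tree:
    """Splits occurring in a fraction > threshold of the trees, annotated
    with their percentage frequency as internal node labels."""
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 can yield incompatible splits")
    if not trees:
        raise ValueError("need at least one tree")
    taxa = list(taxa) if taxa else _common_taxa(trees)
    counts: dict[int, int] = {}
    for t in trees:
        for m in split_masks(t, taxa):
            counts[m] = counts.get(m, 0) + 1
    keep = {m: c for m, c in counts.items() if c / len(trees) > threshold}
    labels = {m: f"{100.0 * c / len(trees):g}" for m, c in keep.items()}
    return tree_from_splits(frozenset(keep), taxa, labels=labels)
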