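"""Bit-parallel encoding of character matrices and an array representation
of unrooted binary trees used by the search kernels.

Characters are packed into 7 "state planes" of 64-bit blocks: plane ``s``
has bit ``c`` set for a taxon iff state ``s`` belongs to the taxon's state
set for character ``c``.  Missing ('?') and inapplicable ('-') cells carry
the full state set.  Fitch set operations then run on whole 64-character
blocks at once.

Unrooted binary trees over ``n`` leaves are arrays ``nbr`` of shape
``(2n-2, 3)``: rows ``0..n-1`` are leaves (single neighbour in column 0),
rows ``n..2n-3`` internal nodes; unused slots hold ``-1``.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .matrix import MAX_STATE, CharacterMatrix

N_PLANES = MAX_STATE + 1
FULL_MASK = (1 << N_PLANES) - 1


def pack_matrix(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pack a matrix into ``(leafsets, active)``.

    ``leafsets`` has shape ``(n_taxa, 7, n_blocks)`` uint64; ``active`` is the
    per-block mask of valid character bits.
    """
    return pack_states(matrix.states)


def pack_states(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    states = np.asarray(states, dtype=np.int8)
    ntax, nchar = states.shape
    nb = max(1, (nchar + 63) // 64)
    leafsets = np.zeros((ntax, N_PLANES, nb), dtype=np.uint64)
    for c in range(nchar):
        blk, bit = divmod(c, 64)
        bitval = np.uint64(1) << np.uint64(bit)
        col = states[:, c]
        for s in range(N_PLANES):
            hit = (col == s) | (col < 0)  # missing/inapplicable: any state
            leafsets[hit, s, blk] |= bitval
    active = np.zeros(nb, dtype=np.uint64)
    for c in range(nchar):
        blk, bit = divmod(c, 64)
        active[blk] |= np.uint64(1) << np.uint64(bit)
    return leafsets, active


# ------------------------------------------------------------- tree arrays

def n_nodes(n_leaves: int) -> int:
    return 2 * n_leaves - 2


def tree_to_nbr(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Convert a (binary, possibly rooted) dendropy tree to the array form.

    A bifurcating root is suppressed so the result is unrooted.  Leaf ids
    follow the order of ``taxa``.
    """
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    leaves = list(tree.leaf_node_iter())
    if len(leaves) != n:
        raise ValueError(f"tree has {len(leaves)} leaves, expected {n}")
    nbr = np.full((n_nodes(n), 3), -1, dtype=np.int64)
    ids: dict[int, int] = {}
    next_internal = n
    edges = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or node.taxon.label not in index:
                raise ValueError(f"leaf {node.taxon} not in taxon set")
            ids[id(node)] = index[node.taxon.label]
        else:
            ids[id(node)] = next_internal
            next_internal += 1
    root = tree.seed_node
    root_children = root.child_nodes()
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            edges.append((ids[id(node)], ids[id(ch)]))
    if len(root_children) == 2:
        # suppress degree-2 root
        a, b = (ids[id(c)] for c in root_children)
        r = ids[id(root)]
        edges = [e for e in edges if r not in e]
        edges.append((a, b))
        # shift internal ids above r down by one
        def fix(x):
            return x - 1 if x > r else x
        edges = [(fix(a), fix(b)) for a, b in edges]
    elif len(root_children) not in (0, 3):
        raise ValueError("tree is not binary (root must have 2 or 3 children)")
    for a, b in edges:
        _connect_np(nbr, a, b, n)
    deg = (nbr >= 0).sum(axis=1)
    if not (deg[:n] == 1).all() or not (deg[n:] == 3).all():
        raise ValueError("tree is not a binary unrooted tree over the taxon set")
    return nbr


def _connect_np(nbr: np.ndarray, a: int, b: int, n: int) -> None:
    for x, y in ((a, b), (b, a)):
        row = nbr[x]
        slot = np.flatnonzero(row < 0)
        if slot.size == 0:
            raise ValueError(f"node {x} already has full degree")
        row[slot[0]] = y


def nbr_to_newick(nbr: np.ndarray, taxa: list[str]) -> str:
    """Serialize an array tree as Newick, rooted on the pendant edge of
    leaf 0 (an arbitrary, deterministic convention)."""
    n = len(taxa)

    def sub(node: int, parent: int) -> str:
        if node < n:
            label = taxa[node]
            return f"'{label}'" if " " in label else label
        parts = [sub(x, node) for x in nbr[node] if x >= 0 and x != parent]
        return "(" + ",".join(parts) + ")"

    r = int(nbr[0, 0])
    return f"({sub(0, r)},{sub(r, 0)});"


def nbr_to_tree(
    nbr: np.ndarray, taxa: list[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=nbr_to_newick(nbr, taxa),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def splits_of_nbr(nbr: np.ndarray, n: int) -> frozenset[int]:
    """Canonical non-trivial splits (leaf-set bitmasks on the side not
    containing leaf 0) of an array tree; requires n <= 64."""
    full = (1 << n) - 1
    masks = {}
    order, parent = _postorder_np(nbr, n)
    below = np.zeros(nbr.shape[0], dtype=np.int64)
    for x in reversed(order):
        if x < n:
            below[x] = 1 << x
        else:
            below[x] = 0
            for y in nbr[x]:
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
    splits = set()
    for x in order:
        if x >= n and parent[x] >= n:  # internal edge
            m = int(below[x])
            if m & 1:
                m = full ^ m
            if 2 <= bin(m).count("1") <= n - 2:
                splits.add(m)
    return frozenset(splits)


def _postorder_np(nbr: np.ndarray, n: int) -> tuple[list[int], np.ndarray]:
    """Preorder node list and parent array, rooted at leaf 0's neighbour."""
    start = int(nbr[0, 0])
    parent = np.full(nbr.shape[0], -1, dtype=np.int64)
    parent[start] = 0
    order = [start]
    stack = [start]
    while stack:
        x = stack.pop()
        for y in nbr[x]:
            y = int(y)
            if y >= 0 and y != parent[x]:
                parent[y] = x
                order.append(y)
                stack.append(y)
    return order, parent
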