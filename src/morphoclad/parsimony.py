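"""Equal-weights Fitch parsimony scoring, homoplasy indices (CI, RI), and
character-change mapping.

Characters are unordered and equally weighted.  Unobserved ('?') and
inapplicable ('-') cells both contribute the full state set, so they never
force changes.  Tree length is independent of root placement; change maps
are directional and therefore require a rooted tree.

The ensemble consistency index is CI = sum(m_i) / sum(s_i) and the ensemble
retention index RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i)), where
for character i: s_i is its length on the tree, m_i the minimum conceivable
length (distinct observed states - 1) and g_i the maximum conceivable
length (its length on the star tree: observed taxa minus the count of the
most frequent observed state).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import numpy as np
import pandas as pd

from ._encode import N_PLANES, pack_matrix, tree_to_nbr
from ._kernels import tree_length_alloc
from .matrix import CharacterMatrix

INF = np.int32(1 << 20)


def _tree_as_nbr(tree, matrix: CharacterMatrix):
    """Accept a dendropy Tree or an nbr array; restrict matrix to its taxa."""
    if isinstance(tree, np.ndarray):
        return tree, matrix
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in labels if t not in matrix.taxa]
    if missing:
        raise ValueError(f"tree leaves absent from matrix: {missing}")
    sub = matrix if labels == matrix.taxa else matrix.subset_taxa(
        [t for t in matrix.taxa if t in set(labels)])
    return tree_to_nbr(tree, sub.taxa), sub


def fitch_length(tree, matrix: CharacterMatrix) -> int:
    """Parsimony length of an unrooted binary tree under Fitch optimization."""
    nbr, sub = _tree_as_nbr(tree, matrix)
    leafsets, active = pack_matrix(sub)
    return int(tree_length_alloc(nbr, leafsets, active, sub.n_taxa))


# ------------------------------------------------------ Sankoff machinery

def _leaf_costs(matrix: CharacterMatrix) -> np.ndarray:
    """(n_taxa, 7, n_chars) int32: 0 where a state is allowed, INF otherwise."""
    n, nc = matrix.n_taxa, matrix.n_characters
    costs = np.full((n, N_PLANES, nc), INF, dtype=np.int32)
    for s in range(N_PLANES):
        allowed = (matrix.states == s) | (matrix.states < 0)
        costs[:, s, :][allowed] = 0
    return costs


def _edge_fold(cost: np.ndarray) -> np.ndarray:
    """min over the far endpoint's state t of cost[t] + [t != s], per s."""
    m = cost.min(axis=0)
    return np.minimum(cost, m[None, :] + 1)


def _sankoff_vectors(nbr: np.ndarray, matrix: CharacterMatrix, root_leaf: int = 0):
    """Directed min-cost vectors on a binary unrooted tree.

    Roots the tree on the pendant edge of ``root_leaf``.  Returns
    (D, Up, parent, order, n): D[x][s, c] is the min cost of the subtree
    below x with x in state s; Up[x][s, c] the min cost of everything above
    the (parent[x], x) edge with parent[x] in state s (the pendant edge to
    the root leaf is folded into Up of its neighbour).
    """
    n, nc = matrix.n_taxa, matrix.n_characters
    leafcost = _leaf_costs(matrix)
    N = nbr.shape[0]
    parent = np.full(N, -1, dtype=np.int64)
    start = int(nbr[root_leaf, 0])
    parent[start] = root_leaf
    order = [start]
    stack = [start]
    while stack:
        x = stack.pop()
        for y in nbr[x]:
            y = int(y)
            if y >= 0 and y != parent[x]:
                parent[y] = x
                order.append(y)
                if y >= n:
                    stack.append(y)
    D = np.empty((N, N_PLANES, nc), dtype=np.int32)
    for x in reversed(order):
        if x < n:
            D[x] = leafcost[x]
        else:
            acc = np.zeros((N_PLANES, nc), dtype=np.int32)
            for y in nbr[x]:
                y = int(y)
                if y >= 0 and y != parent[x]:
                    acc += _edge_fold(D[y])
            D[x] = acc
    Up = np.empty((N, N_PLANES, nc), dtype=np.int32)
    Up[start] = _edge_fold(leafcost[root_leaf])
    for x in order:
        if x < n:
            continue
        kids = [int(y) for y in nbr[x] if y >= 0 and int(y) != parent[x]]
        for c in kids:
            acc = _edge_fold(Up[x]).copy()
            for sib in kids:
                if sib != c:
                    acc += _edge_fold(D[sib])
            Up[c] = acc
    return D, Up, parent, order, n


def per_character_lengths(tree, matrix: CharacterMatrix) -> np.ndarray:
    """Observed steps s_i for every character on the tree."""
    nbr, sub = _tree_as_nbr(tree, matrix)
    D, Up, parent, order, n = _sankoff_vectors(nbr, sub)
    start = order[0]
    return np.min(Up[start] + D[start], axis=0).astype(np.int64)


@dataclass
class CharacterFit:
    """Per-character homoplasy bookkeeping: observed steps ``s`` on a tree
    and the conceivable extremes ``m <= s <= g``."""

    index: int
    s: int
    m: int
    g: int

    @property
    def informative(self) -> bool:
        return self.g > self.m

    @property
    def observed(self) -> bool:
        return self.g > 0 or self.m > 0 or self.s > 0


def min_max_steps(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(m_i, g_i) per character from observed state frequencies only."""
    nc = matrix.n_characters
    m = np.zeros(nc, dtype=np.int64)
    g = np.zeros(nc, dtype=np.int64)
    for c in range(nc):
        col = matrix.states[:, c]
        obs = col[col >= 0]
        if obs.size == 0:
            continue
        _vals, counts = np.unique(obs, return_counts=True)
        m[c] = counts.size - 1
        g[c] = obs.size - counts.max()
    return m, g


def per_character_fit(tree, matrix: CharacterMatrix) -> list[CharacterFit]:
    s = per_character_lengths(tree, matrix)
    m, g = min_max_steps(matrix)
    return [CharacterFit(i, int(s[i]), int(m[i]), int(g[i]))
            for i in range(matrix.n_characters)]


def consistency_index(fits: list[CharacterFit], include_uninformative: bool = True) -> float:
    """Ensemble CI = sum(m) / sum(s); 1.0 (flagged by convention) when the
    tree requires no steps at all."""
    sel = fits if include_uninformative else [f for f in fits if f.informative]
    S = sum(f.s for f in sel)
    M = sum(f.m for f in sel)
    if S == 0:
        return 1.0
    return M / S


def retention_index(fits: list[CharacterFit], include_uninformative: bool = True) -> float:
    """Ensemble RI = (sum(g) - sum(s)) / (sum(g) - sum(m)); characters with
    g == m carry no retainable synapomorphy and cancel from both sums."""
    sel = fits if include_uninformative else [f for f in fits if f.informative]
    S = sum(f.s for f in sel)
    M = sum(f.m for f in sel)
    G = sum(f.g for f in sel)
    if G == M:
        return 1.0
    return (G - S) / (G - M)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding used for reporting (0.785 -> 0.79)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ------------------------------------------------------ change mapping

def map_changes(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    root_taxon: str | None = None,
    resolution: str = "unambiguous",
) -> pd.DataFrame:
    """Map character-state changes onto the branches of a rooted tree.

    Parameters
    ----------
    tree:
        A rooted tree (or any tree plus ``root_taxon`` naming the outgroup
        leaf to root on).
    resolution:
        ``"unambiguous"`` reports only changes present under every
        most-parsimonious reconstruction (from/to sets may list several
        states).  ``"acctran"``/``"deltran"`` report one full reconstruction
        that accelerates/delays changes.

    Returns a DataFrame with one row per (branch, character) change:
    ``clade`` (frozenset of taxa below the branch), ``character``,
    ``from_states``, ``to_states``, ``unambiguous``, ``unique`` (the
    character shows no homoplasy on this tree: s == m).
    """
    if resolution not in ("unambiguous", "acctran", "deltran"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if root_taxon is None:
        root_kids = tree.seed_node.child_nodes() if not isinstance(tree, np.ndarray) else []
        leaf_kids = [c for c in root_kids if c.is_leaf()]
        if len(root_kids) != 2 or not leaf_kids:
            raise ValueError(
                "tree is not rooted on an outgroup leaf; pass root_taxon= "
                "or root the tree first"
            )
        root_taxon = leaf_kids[0].taxon.label
    nbr, sub = _tree_as_nbr(tree, matrix)
    root_leaf = sub.taxa.index(root_taxon)
    D, Up, parent, order, n = _sankoff_vectors(nbr, sub, root_leaf=root_leaf)
    start = order[0]
    L = np.min(Up[start] + D[start], axis=0)
    m, _g = min_max_steps(sub)
    s_obs = np.min(Up[start] + D[start], axis=0)
    # leaf sets below each node (away from the root leaf)
    below: dict[int, set[int]] = {}
    for x in reversed(order):
        if x < n:
            below[x] = {x}
        else:
            below[x] = set()
            for y in nbr[x]:
                y = int(y)
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
    rows = []
    if resolution == "unambiguous":
        for x in order:
            same = np.min(Up[x] + D[x], axis=0)
            changed = same > L  # every MPR changes on this edge
            up_end = _edge_fold(D[x]) + Up[x]     # per parent state s
            dn_end = _edge_fold(Up[x]) + D[x]     # per child state t
            for c in np.flatnonzero(changed):
                from_states = tuple(int(s) for s in np.flatnonzero(up_end[:, c] == L[c]))
                to_states = tuple(int(t) for t in np.flatnonzero(dn_end[:, c] == L[c]))
                rows.append((frozenset(sub.taxa[i] for i in below[x]), int(c),
                             from_states, to_states, True,
                             bool(s_obs[c] == m[c])))
    else:
        prefer_change = resolution == "acctran"
        state = np.empty((nbr.shape[0], sub.n_characters), dtype=np.int32)
        root_tot = Up[start] + D[start]
        state[start] = np.argmin(root_tot, axis=0)
        for x in order:
            if x < n:
                continue
            sp = state[x]
            for y in nbr[x]:
                y = int(y)
                if y < 0 or y == parent[x]:
                    continue
                cost = D[y] + (np.arange(N_PLANES)[:, None] != sp[None, :])
                best = cost.min(axis=0)
                st = np.empty(sub.n_characters, dtype=np.int32)
                for c in range(sub.n_characters):
                    cands = np.flatnonzero(cost[:, c] == best[c])
                    keep_same = sp[c] in cands
                    if keep_same and not (prefer_change and cands.size > 1):
                        st[c] = sp[c]
                    else:
                        others = cands[cands != sp[c]]
                        st[c] = others[0] if others.size else sp[c]
                state[y] = st
        # pendant edge to the root leaf (oriented root -> rest of tree)
        for c in range(sub.n_characters):
            cell = sub.states[root_leaf, c]
            if cell >= 0 and cell != state[start, c]:
                rows.append((frozenset(sub.taxa[i] for i in below[start]),
                             int(c), (int(cell),), (int(state[start, c]),),
                             False, bool(s_obs[c] == m[c])))
        for x in order:
            p = int(parent[x])
            if p < n:
                continue  # root pendant edge handled above
            sp = state[p]
            for c in range(sub.n_characters):
                if x < n:
                    cell = sub.states[x, c]
                    if cell < 0 or cell == sp[c]:
                        continue
                    frm, to = int(sp[c]), int(cell)
                else:
                    if state[x, c] == sp[c]:
                        continue
                    frm, to = int(sp[c]), int(state[x, c])
                rows.append((frozenset(sub.taxa[i] for i in below[x]), int(c),
                             (frm,), (to,), False,
                             bool(s_obs[c] == m[c])))
    return pd.DataFrame(
        rows, columns=["clade", "character", "from_states", "to_states",
                       "unambiguous", "unique"],
    )
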