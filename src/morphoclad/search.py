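"""Most-parsimonious tree search: exhaustive enumeration, branch-and-bound,
and heuristic random-addition + TBR, with zero-length-branch collapsing.

All searches treat trees as unrooted and score them under equal-weights
Fitch parsimony with '?' and '-' as full ambiguity.  Distinct trees are
identified by their unrooted bipartition sets; heuristic results are
deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._encode import n_nodes, pack_matrix, splits_of_nbr
from .matrix import CharacterMatrix

EXHAUSTIVE_MAX_TAXA = 9
BNB_MAX_TAXA = 16
MAX_TAXA = 63  # leaf bitmask width (uint64 with headroom)


@dataclass
class SearchResult:
    """Outcome of a parsimony tree search.

    ``trees`` holds distinct optimal trees in the array (``nbr``)
    representation, deduplicated by unrooted bipartition set; every one of
    them rescoring to ``best_length``.  ``suboptimal`` optionally holds
    (length, tree) pairs within a slack of the optimum.
    """

    best_length: int
    trees: list[np.ndarray]
    taxa: list[str]
    method: str
    replicates_run: int = 0
    seed: int | None = None
    exact: bool = False
    bound_infeasible: bool = False
    truncated: bool = False
    suboptimal: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def split_sets(self) -> list[frozenset[int]]:
        return [splits_of_nbr(t, len(self.taxa)) for t in self.trees]


def _prepare(matrix: CharacterMatrix):
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa to build an unrooted tree")
    if n > MAX_TAXA:
        raise ValueError(f"searches support at most {MAX_TAXA} taxa (got {n})")
    leafsets, active = pack_matrix(matrix)
    return n, leafsets, active


def _splits_fast(t: np.ndarray, n: int, buf: np.ndarray) -> frozenset[int]:
    cnt = K.tree_splits(t, n, buf)
    return frozenset(int(x) for x in buf[:cnt])


def _dedup(nbrs: list[np.ndarray], n: int) -> list[np.ndarray]:
    buf = np.empty(2 * n, dtype=np.uint64)
    seen: set[frozenset[int]] = set()
    out = []
    for t in nbrs:
        key = _splits_fast(t, n, buf)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def exhaustive_search(matrix: CharacterMatrix, max_trees: int = 10000) -> SearchResult:
    """Enumerate every unrooted binary topology; exact optimum and all
    optimal trees.  Guarded to small taxon counts."""
    n, leafsets, active = _prepare(matrix)
    if n > EXHAUSTIVE_MAX_TAXA:
        raise ValueError(
            f"exhaustive search is limited to {EXHAUSTIVE_MAX_TAXA} taxa "
            f"(got {n}); use branch_and_bound_search or heuristic_search"
        )
    out = np.empty((max_trees, n_nodes(n), 3), dtype=np.int64)
    best, ntrees, _visited = K.bb_search(
        leafsets, active, n, np.int64(1 << 60), False, np.uint64(0), out, max_trees
    )
    trees = [out[i].copy() for i in range(min(ntrees, max_trees))]
    return SearchResult(int(best), trees, list(matrix.taxa), "exhaustive", exact=True,
                        truncated=ntrees >= max_trees)


def branch_and_bound_search(
    matrix: CharacterMatrix,
    upper_bound: int | None = None,
    max_trees: int = 10000,
    forbid_split: int = 0,
) -> SearchResult:
    """Exact search by stepwise-addition branch-and-bound.

    ``upper_bound`` (optional) primes the incumbent; if it is below the true
    optimum the result is empty and flagged ``bound_infeasible``.
    ``forbid_split`` (canonical leaf bitmask) restricts the search to trees
    lacking that bipartition (used for exact Bremer decay).
    """
    n, leafsets, active = _prepare(matrix)
    if n > BNB_MAX_TAXA:
        raise ValueError(
            f"branch-and-bound is limited to {BNB_MAX_TAXA} taxa (got {n})"
        )
    ub = np.int64(1 << 60) if upper_bound is None else np.int64(upper_bound)
    out = np.empty((max_trees, n_nodes(n), 3), dtype=np.int64)
    best, ntrees, _visited = K.bb_search(
        leafsets, active, n, ub, True, np.uint64(forbid_split), out, max_trees
    )
    if upper_bound is not None and best > upper_bound:
        return SearchResult(int(best), [], list(matrix.taxa), "branch_and_bound",
                            exact=True, bound_infeasible=True)
    trees = [out[i].copy() for i in range(min(ntrees, max_trees))]
    return SearchResult(int(best), trees, list(matrix.taxa), "branch_and_bound",
                        exact=True, truncated=ntrees >= max_trees)


def heuristic_search(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    trees_to_save: int = 10,
    seed: int = 0,
    swapper: str = "tbr",
    forbid_split: int = 0,
    collapse: str | None = "rule1",
    close_island: bool = False,
    plateau_max: int = 2000,
) -> SearchResult:
    """Random-addition-sequence Wagner trees with TBR branch swapping.

    Per replicate, a random addition order builds a starting tree which is
    swapped to a TBR local optimum.  Final trees at the overall best length
    are pooled, optionally expanded by zero-cost TBR moves to close the
    optimal "island" (``close_island``, capped at ``plateau_max``
    expansions; off by default -- the search then reports the optima its
    replicates actually visited, which is how tree counts are convention-
    ally reported), optionally collapsed (``collapse='rule1'``: contract
    branches whose minimum length over all most-parsimonious
    reconstructions is zero) and deduplicated by bipartition set, keeping
    up to ``trees_to_save`` distinct trees.

    Only ``swapper='tbr'`` is provided; TBR subsumes SPR and NNI
    neighbourhoods.  Deterministic for fixed ``seed``.
    """
    if replicates < 1 or trees_to_save < 1:
        raise ValueError("replicates and trees_to_save must be >= 1")
    if swapper not in ("tbr", "spr", "nni"):
        raise ValueError(f"unknown swapper {swapper!r}")
    if swapper != "tbr":
        warnings.warn("only TBR swapping is implemented; it subsumes "
                      f"{swapper.upper()} moves", stacklevel=2)
    n, leafsets, active = _prepare(matrix)
    if n == 3:
        # single topology
        res = exhaustive_search(matrix)
        res.method = "heuristic"
        res.seed = seed
        return res
    N = n_nodes(n)
    out_nbrs = np.empty((replicates, N, 3), dtype=np.int64)
    out_lens = np.empty(replicates, dtype=np.int64)
    best = K.ras_tbr_replicates(
        leafsets, active, n, replicates, np.int64(seed), np.uint64(forbid_split),
        out_nbrs, out_lens,
    )
    finals = [out_nbrs[r].copy() for r in range(replicates) if out_lens[r] == best]
    if forbid_split:
        finals = [t for t in finals
                  if not K.tree_has_split(t, n, np.uint64(forbid_split))]
        if not finals:
            return SearchResult(int(best), [], list(matrix.taxa), "heuristic",
                                replicates_run=replicates, seed=seed,
                                bound_infeasible=True)
    pool = _dedup(finals, n)
    if close_island:
        pool = _plateau_closure(pool, leafsets, active, n, int(best),
                                forbid_split, plateau_max)
    if collapse is not None:
        pool = _collapse_pool(pool, matrix, rule=collapse)
    truncated = len(pool) > trees_to_save
    if truncated:
        warnings.warn(
            f"{len(pool)} optimal trees found; keeping trees_to_save={trees_to_save}",
            stacklevel=2,
        )
    return SearchResult(int(best), pool[:trees_to_save], list(matrix.taxa),
                        "heuristic", replicates_run=replicates, seed=seed,
                        truncated=truncated)


def _plateau_closure(pool, leafsets, active, n, best, forbid_split, plateau_max):
    """Close the set of optimal binary trees under zero-cost TBR moves."""
    N = n_nodes(n)
    ws = K.make_workspace(N, active.shape[0])
    moves = np.empty((8192, 7), dtype=np.int64)
    buf = np.empty(2 * n, dtype=np.uint64)
    seen = {_splits_fast(t, n, buf): t for t in pool}
    queue = list(seen.values())
    expansions = 0
    while queue and expansions < plateau_max:
        t = queue.pop()
        expansions += 1
        cnt = K.equal_cost_moves(t, leafsets, active, n, np.int64(0), ws, moves)
        for i in range(cnt):
            u, v, a1, a2, b1, b2, cost = (int(x) for x in moves[i])
            if cost != best:
                continue
            t2 = t.copy()
            K._apply_move(t2, n, u, v, a1, a2, b1, b2)
            if forbid_split and K.tree_has_split(t2, n, np.uint64(forbid_split)):
                continue
            key = _splits_fast(t2, n, buf)
            if key not in seen:
                seen[key] = t2
                queue.append(t2)
    return list(seen.values())


# ------------------------------------------------------- branch collapsing

def min_branch_lengths(nbr: np.ndarray, matrix: CharacterMatrix) -> dict[tuple[int, int], int]:
    """Minimum number of changes on each edge over all most-parsimonious
    reconstructions (summed over characters), via directed Sankoff cost
    vectors.  Keys are (parent, child) node pairs in the traversal rooted
    at leaf 0's pendant edge."""
    from .parsimony import _sankoff_vectors

    D, R, parent, order, n = _sankoff_vectors(nbr, matrix)
    L_char = np.min(R[order[0]] + D[order[0]], axis=0)
    out = {}
    for x in order:
        zero_possible = np.min(R[x] + D[x], axis=0) <= L_char
        out[(int(parent[x]), int(x))] = int(np.sum(~zero_possible))
    return out


def collapse_zero_length_branches(nbr: np.ndarray, matrix: CharacterMatrix):
    """TNT-style "rule 1" collapse: contract every internal branch whose
    minimum length over all most-parsimonious reconstructions is zero.

    Returns a (possibly multifurcating) tree as a nested-tuple structure
    plus the set of retained canonical splits; use
    :func:`morphoclad.consensus.tree_from_splits` to materialize it."""
    from .consensus import tree_from_splits

    n = matrix.n_taxa
    minlens = min_branch_lengths(nbr, matrix)
    keep = []
    full = (1 << n) - 1
    from ._encode import _postorder_np

    order, parent = _postorder_np(nbr, n)
    below = {}
    for x in reversed(order):
        if x < n:
            below[x] = 1 << x
        else:
            below[x] = 0
            for y in nbr[x]:
                y = int(y)
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
    for x in order:
        if x >= n and parent[x] >= n and minlens[(int(parent[x]), int(x))] > 0:
            m = below[x]
            if m & 1:
                m = full ^ m
            keep.append(m)
    return tree_from_splits(frozenset(keep), matrix.taxa)


def collapsed_split_sets(result: SearchResult, matrix: CharacterMatrix) -> list[frozenset[int]]:
    """Distinct rule-1-collapsed trees of a search result, as split sets."""
    n = matrix.n_taxa
    seen = []
    for t in result.trees:
        minlens = min_branch_lengths(t, matrix)
        splits = splits_of_nbr(t, n)
        # recompute which splits survive
        kept = _kept_splits(t, matrix, minlens)
        if kept not in seen:
            seen.append(kept)
    return seen


def _kept_splits(nbr, matrix, minlens) -> frozenset[int]:
    from ._encode import _postorder_np

    n = matrix.n_taxa
    full = (1 << n) - 1
    order, parent = _postorder_np(nbr, n)
    below = {}
    for x in reversed(order):
        if x < n:
            below[x] = 1 << x
        else:
            below[x] = 0
            for y in nbr[x]:
                y = int(y)
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
    keep = set()
    for x in order:
        if x >= n and parent[x] >= n and minlens[(int(parent[x]), int(x))] > 0:
            m = below[x]
            if m & 1:
                m = full ^ m
            keep.add(m)
    return frozenset(keep)


def _collapse_pool(pool, matrix, rule="rule1"):
    """Deduplicate a pool of binary optimal trees by their collapsed split
    sets, keeping one binary representative per collapsed tree."""
    if rule not in ("rule1", "none"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if rule == "none":
        return pool
    reps: dict[frozenset[int], np.ndarray] = {}
    for t in pool:
        minlens = min_branch_lengths(t, matrix)
        key = _kept_splits(t, matrix, minlens)
        reps.setdefault(key, t)
    return list(reps.values())
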