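"""Numba kernels for parsimony scoring and tree search.

All kernels operate on the packed state-plane encoding (``_encode``) and the
``nbr`` array representation of unrooted binary trees.  The central
observation used throughout: if a tree is bisected at an edge into
components A and B, the length of any tree formed by reconnecting an edge
of A to an edge of B equals

    len(A) + len(B) + |{characters whose Fitch edge sets on the two
                        reconnection edges are disjoint}|

where the "edge set" of an edge is the Fitch combination of the two
directed state sets meeting at that edge.  This makes every TBR
reconnection evaluable in O(blocks) after one up/down pass per component.

The same identity with component B equal to a single leaf gives the exact
cost of stepwise addition during random-addition-sequence tree building.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NS = 7  # state planes (states 0..6)

U64 = np.uint64
_M1 = U64(0x5555555555555555)
_M2 = U64(0x3333333333333333)
_M4 = U64(0x0F0F0F0F0F0F0F0F)
_H01 = U64(0x0101010101010101)

# sentinel edge ids for TBR candidates
MERGED = -1      # reattach at the position the stub vacated
SINGLETON = -2   # component is a single leaf


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> U64(1)) & _M1)
    x = (x & _M2) + ((x >> U64(2)) & _M2)
    x = (x + (x >> U64(4))) & _M4
    return (x * _H01) >> U64(56)


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state[0]
    x ^= x >> U64(12)
    x ^= x << U64(25)
    x ^= x >> U64(27)
    state[0] = x
    return x * U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _rand_below(state, k):
    return int(_rng_next(state) % U64(k))


@njit(cache=True)
def seed_state(seed):
    s = np.empty(1, dtype=np.uint64)
    s[0] = U64(seed) * U64(6364136223846793005) + U64(1442695040888963407)
    if s[0] == U64(0):
        s[0] = U64(0x9E3779B97F4A7C15)
    # warm up
    for _ in range(8):
        _rng_next(s)
    return s


# ------------------------------------------------------------ set algebra

@njit(cache=True)
def _combine(a, b, out, active):
    """Fitch combine of two state-plane sets; returns the union-step count."""
    nb = active.shape[0]
    steps = 0
    for blk in range(nb):
        nonempty = U64(0)
        for s in range(NS):
            nonempty |= a[s, blk] & b[s, blk]
        empty = active[blk] & ~nonempty
        for s in range(NS):
            inter = a[s, blk] & b[s, blk]
            out[s, blk] = inter | ((a[s, blk] | b[s, blk]) & empty)
        steps += int(_popcount(empty))
    return steps


@njit(cache=True)
def _join(a, b, active):
    """Characters whose state sets are disjoint between a and b."""
    nb = active.shape[0]
    steps = 0
    for blk in range(nb):
        nonempty = U64(0)
        for s in range(NS):
            nonempty |= a[s, blk] & b[s, blk]
        steps += int(_popcount(active[blk] & ~nonempty))
    return steps


# ------------------------------------------------------------ tree plumbing

@njit(cache=True, inline="always")
def _connect(nbr, a, b):
    for j in range(3):
        if nbr[a, j] < 0:
            nbr[a, j] = b
            break
    for j in range(3):
        if nbr[b, j] < 0:
            nbr[b, j] = a
            break


@njit(cache=True, inline="always")
def _disconnect(nbr, a, b):
    for j in range(3):
        if nbr[a, j] == b:
            nbr[a, j] = -1
            break
    for j in range(3):
        if nbr[b, j] == a:
            nbr[b, j] = -1
            break


@njit(cache=True, inline="always")
def _adjacent(nbr, a, b):
    for j in range(3):
        if nbr[a, j] == b:
            return True
    return False


@njit(cache=True)
def _traverse(nbr, n, start, avoid, parent, order):
    """Preorder traversal of the component reachable from ``start`` without
    crossing the (start, avoid) edge.  Returns the node count."""
    parent[start] = avoid
    order[0] = start
    m = 1
    if start < n:
        return m
    stack = np.empty(order.shape[0], dtype=np.int64)
    top = 0
    stack[0] = start
    while top >= 0:
        x = stack[top]
        top -= 1
        for j in range(3):
            y = nbr[x, j]
            if y >= 0 and y != parent[x]:
                parent[y] = x
                order[m] = y
                m += 1
                if y >= n:
                    top += 1
                    stack[top] = y
    return m


@njit(cache=True)
def _down_pass(nbr, leafsets, active, n, parent, order, m, dsets):
    """Directed (rootward) Fitch sets for a traversed component; returns the
    component length (root = order[0], treated as having the remaining two
    neighbours as children)."""
    steps = 0
    for i in range(m - 1, -1, -1):
        x = order[i]
        if x < n:
            continue
        c1 = np.int64(-1)
        c2 = np.int64(-1)
        for j in range(3):
            y = nbr[x, j]
            if y >= 0 and y != parent[x]:
                if c1 < 0:
                    c1 = y
                else:
                    c2 = y
        a = leafsets[c1] if c1 < n else dsets[c1]
        b = leafsets[c2] if c2 < n else dsets[c2]
        steps += _combine(a, b, dsets[x], active)
    return steps


@njit(cache=True)
def _up_pass(nbr, leafsets, active, n, parent, order, m, dsets, usets, root_up):
    """Directed (tipward) sets: usets[x] = Fitch set of everything on the
    parent side of the edge (parent[x], x).  If ``root_up`` is True,
    usets[order[0]] must be pre-filled (set of the root's external parent);
    otherwise the root is a suppressed stub with exactly two children."""
    for i in range(m):
        x = order[i]
        if x < n:
            continue
        c1 = np.int64(-1)
        c2 = np.int64(-1)
        for j in range(3):
            y = nbr[x, j]
            if y >= 0 and y != parent[x]:
                if c1 < 0:
                    c1 = y
                else:
                    c2 = y
        s1 = leafsets[c1] if c1 < n else dsets[c1]
        s2 = leafsets[c2] if c2 < n else dsets[c2]
        if i == 0 and not root_up:
            for s in range(NS):
                for blk in range(active.shape[0]):
                    usets[c1, s, blk] = s2[s, blk]
                    usets[c2, s, blk] = s1[s, blk]
        else:
            _combine(usets[x], s2, usets[c1], active)
            _combine(usets[x], s1, usets[c2], active)
    return 0


@njit(cache=True)
def tree_length(nbr, leafsets, active, n, parent, order, dsets):
    """Fitch length of a binary unrooted tree (scored from leaf 0's edge)."""
    start = nbr[0, 0]
    m = _traverse(nbr, n, start, 0, parent, order)
    steps = _down_pass(nbr, leafsets, active, n, parent, order, m, dsets)
    return steps + _join(dsets[start], leafsets[0], active)


@njit(cache=True)
def tree_length_alloc(nbr, leafsets, active, n):
    N = nbr.shape[0]
    nb = active.shape[0]
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    dsets = np.empty((N, NS, nb), dtype=np.uint64)
    return tree_length(nbr, leafsets, active, n, parent, order, dsets)


@njit(cache=True)
def tree_leafmasks(nbr, n, parent, order, below):
    """below[x] = bitmask of leaves on x's side of the (parent[x], x) edge,
    rooted at leaf 0's neighbour.  Returns the traversal size."""
    start = nbr[0, 0]
    m = _traverse(nbr, n, start, 0, parent, order)
    for i in range(m - 1, -1, -1):
        x = order[i]
        if x < n:
            below[x] = U64(1) << U64(x)
        else:
            below[x] = U64(0)
            for j in range(3):
                y = nbr[x, j]
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
    return m


@njit(cache=True)
def tree_has_split(nbr, n, smask):
    """True if some internal edge induces the (canonicalized) split."""
    N = nbr.shape[0]
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    below = np.empty(N, dtype=np.uint64)
    full = (U64(1) << U64(n)) - U64(1)
    m = tree_leafmasks(nbr, n, parent, order, below)
    comp = full ^ smask
    for i in range(m):
        x = order[i]
        if x >= n and parent[x] >= n:
            if below[x] == smask or below[x] == comp:
                return True
    return False


@njit(cache=True)
def tree_splits(nbr, n, out):
    """Canonical internal-edge splits (side not containing leaf 0)."""
    N = nbr.shape[0]
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    below = np.empty(N, dtype=np.uint64)
    m = tree_leafmasks(nbr, n, parent, order, below)
    cnt = 0
    for i in range(m):
        x = order[i]
        if x >= n and parent[x] >= n:
            out[cnt] = below[x]
            cnt += 1
    return cnt


# ------------------------------------------------------------ TBR search

@njit(cache=True)
def _component_prep(nbr, leafsets, active, n, start, avoid,
                    parent, order, dsets, usets, esets, tin, tout, below):
    """Prepare one bisection component rooted at its stub ``start``.

    Fills, for every node x != start in the component, the edge set of the
    edge (parent[x], x) into esets[x], plus subtree leafmasks and Euler
    intervals for ancestry tests.  esets[start] is the merged-edge set.
    Returns (m, component_length, leafmask).
    """
    m = _traverse(nbr, n, start, avoid, parent, order)
    if start < n:
        return m, 0, U64(1) << U64(start)
    clen = _down_pass(nbr, leafsets, active, n, parent, order, m, dsets)
    _up_pass(nbr, leafsets, active, n, parent, order, m, dsets, usets, False)
    # Euler intervals and leafmasks
    cmask = U64(0)
    for i in range(m):
        tin[order[i]] = i
    for i in range(m - 1, -1, -1):
        x = order[i]
        if x < n:
            below[x] = U64(1) << U64(x)
            tout[x] = i
        else:
            below[x] = U64(0)
            tout[x] = i
            for j in range(3):
                y = nbr[x, j]
                if y >= 0 and y != parent[x]:
                    below[x] |= below[y]
                    if tout[y] > tout[x]:
                        tout[x] = tout[y]
    cmask = below[start]
    # edge sets
    for i in range(1, m):
        x = order[i]
        sx = leafsets[x] if x < n else dsets[x]
        _combine(sx, usets[x], esets[x], active)
    for s in range(NS):
        for blk in range(active.shape[0]):
            esets[start, s, blk] = dsets[start, s, blk]
    return m, clen, cmask


@njit(cache=True)
def _forbidden_side(x_child, setA1, n1, setA2, n2, tin, tout):
    """Would attaching the other component at edge (parent, x_child) recreate
    the forbidden split via this component's edges?"""
    for i in range(n1):
        x = setA1[i]
        strictly_under = (
            x_child >= 0 and tin[x] <= tin[x_child] and tin[x_child] <= tout[x]
            and x_child != x
        )
        if not strictly_under:
            return True
    for i in range(n2):
        x = setA2[i]
        if x_child >= 0 and tin[x] <= tin[x_child] and tin[x_child] <= tout[x]:
            return True
    return False


@njit(cache=True)
def tbr_improve(nbr, leafsets, active, n, forbid, cur_len, ws):
    """One pass of first-improvement TBR over all bisections.

    ``forbid``: canonical leafmask of a split that must not appear in any
    accepted tree (0 = unconstrained).  Returns the new length (== cur_len
    if no improving move exists; the tree is then a TBR local optimum).
    """
    (parentA, orderA, dsetsA, usetsA, esetsA, tinA, toutA, belowA,
     parentB, orderB, dsetsB, usetsB, esetsB, tinB, toutB, belowB) = ws
    N = nbr.shape[0]
    full = (U64(1) << U64(n)) - U64(1)
    improved = True
    while improved:
        improved = False
        for u in range(N):
            for j in range(3):
                v = nbr[u, j]
                if v < 0 or v < u:
                    continue
                # orient: singleton component must be the A side
                uu, vv = u, v
                if vv < n:
                    uu, vv = vv, uu
                mA, lenA, maskA = _component_prep(
                    nbr, leafsets, active, n, uu, vv,
                    parentA, orderA, dsetsA, usetsA, esetsA, tinA, toutA, belowA)
                mB, lenB, maskB = _component_prep(
                    nbr, leafsets, active, n, vv, uu,
                    parentB, orderB, dsetsB, usetsB, esetsB, tinB, toutB, belowB)
                base = lenA + lenB
                if base >= cur_len:
                    continue
                # forbidden-split bookkeeping
                fA1 = np.empty(8, dtype=np.int64)
                fA2 = np.empty(8, dtype=np.int64)
                fB1 = np.empty(8, dtype=np.int64)
                fB2 = np.empty(8, dtype=np.int64)
                nA1 = nA2 = nB1 = nB2 = 0
                if forbid != U64(0):
                    comp = full ^ forbid
                    for i in range(1, mA):
                        x = orderA[i]
                        if belowA[x] == forbid or belowA[x] == comp:
                            fA1[nA1] = x
                            nA1 += 1
                        bm = belowA[x] | maskB
                        if bm == forbid or bm == comp:
                            fA2[nA2] = x
                            nA2 += 1
                    for i in range(1, mB):
                        x = orderB[i]
                        if belowB[x] == forbid or belowB[x] == comp:
                            fB1[nB1] = x
                            nB1 += 1
                        bm = belowB[x] | maskA
                        if bm == forbid or bm == comp:
                            fB2[nB2] = x
                            nB2 += 1
                # enumerate reconnection pairs
                if uu < n:
                    # leaf SPR: A side is the single leaf uu
                    for ib in range(mB):
                        xb = orderB[ib]
                        eb = xb if ib > 0 else MERGED
                        if ib == 0 or parentB[xb] == vv:
                            continue  # original position (stub edges = merged)
                        cost = base + _join(leafsets[uu], esetsB[xb], active)
                        if cost < cur_len:
                            if forbid != U64(0) and _forbidden_side(
                                    xb if eb != MERGED else -1,
                                    fB1, nB1, fB2, nB2, tinB, toutB):
                                continue
                            _apply_move(nbr, n, uu, vv, SINGLETON, SINGLETON,
                                        parentB[xb] if eb != MERGED else -1,
                                        xb if eb != MERGED else -1)
                            cur_len = cost
                            improved = True
                            break
                else:
                    done = False
                    for ia in range(mA):
                        xa = orderA[ia]
                        if ia > 0 and parentA[xa] == uu:
                            continue  # stub edge duplicates the merged edge
                        ea = xa if ia > 0 else MERGED
                        ea_child = xa if ia > 0 else -1
                        if forbid != U64(0) and _forbidden_side(
                                ea_child, fA1, nA1, fA2, nA2, tinA, toutA):
                            continue
                        for ib in range(mB):
                            xb = orderB[ib]
                            if ib > 0 and parentB[xb] == vv:
                                continue
                            eb = xb if ib > 0 else MERGED
                            if ea == MERGED and eb == MERGED:
                                continue
                            cost = base + _join(esetsA[xa], esetsB[xb], active)
                            if cost < cur_len:
                                if forbid != U64(0) and _forbidden_side(
                                        xb if eb != MERGED else -1,
                                        fB1, nB1, fB2, nB2, tinB, toutB):
                                    continue
                                a1 = parentA[xa] if ea != MERGED else -1
                                a2 = xa if ea != MERGED else -1
                                b1 = parentB[xb] if eb != MERGED else -1
                                b2 = xb if eb != MERGED else -1
                                _apply_move(nbr, n, uu, vv, a1, a2, b1, b2)
                                cur_len = cost
                                improved = True
                                done = True
                                break
                        if done:
                            break
                if improved:
                    break
            if improved:
                break
    return cur_len


@njit(cache=True)
def _apply_move(nbr, n, u, v, a1, a2, b1, b2):
    """Apply a TBR reconnection for the bisection at edge (u, v).

    (a1, a2): target edge in u's component (-1,-1 = reinsert in place, or u
    is a leaf).  (b1, b2): likewise for v's component.
    """
    if u >= n and a1 >= 0:
        c1, c2 = np.int64(-1), np.int64(-1)
        for j in range(3):
            y = nbr[u, j]
            if y >= 0 and y != v:
                if c1 < 0:
                    c1 = y
                else:
                    c2 = y
        if not ((a1 == c1 and a2 == c2) or (a1 == c2 and a2 == c1)):
            _disconnect(nbr, u, c1)
            _disconnect(nbr, u, c2)
            _connect(nbr, c1, c2)
            _disconnect(nbr, a1, a2)
            _connect(nbr, a1, u)
            _connect(nbr, u, a2)
    if v >= n and b1 >= 0:
        c1, c2 = np.int64(-1), np.int64(-1)
        for j in range(3):
            y = nbr[v, j]
            if y >= 0 and y != u:
                if c1 < 0:
                    c1 = y
                else:
                    c2 = y
        if not ((b1 == c1 and b2 == c2) or (b1 == c2 and b2 == c1)):
            _disconnect(nbr, v, c1)
            _disconnect(nbr, v, c2)
            _connect(nbr, c1, c2)
            _disconnect(nbr, b1, b2)
            _connect(nbr, b1, v)
            _connect(nbr, v, b2)


@njit(cache=True)
def equal_cost_moves(nbr, leafsets, active, n, slack, ws, out_moves):
    """Collect TBR moves whose resulting length <= current length + slack.

    Each row of out_moves: (u, v, a1, a2, b1, b2, cost).  Returns the count
    (capped at out_moves.shape[0]).
    """
    (parentA, orderA, dsetsA, usetsA, esetsA, tinA, toutA, belowA,
     parentB, orderB, dsetsB, usetsB, esetsB, tinB, toutB, belowB) = ws
    N = nbr.shape[0]
    cur_len = tree_length(nbr, leafsets, active, n, parentA, orderA, dsetsA)
    cap = out_moves.shape[0]
    cnt = 0
    for u in range(N):
        for j in range(3):
            v = nbr[u, j]
            if v < 0 or v < u:
                continue
            uu, vv = u, v
            if vv < n:
                uu, vv = vv, uu
            mA, lenA, maskA = _component_prep(
                nbr, leafsets, active, n, uu, vv,
                parentA, orderA, dsetsA, usetsA, esetsA, tinA, toutA, belowA)
            mB, lenB, maskB = _component_prep(
                nbr, leafsets, active, n, vv, uu,
                parentB, orderB, dsetsB, usetsB, esetsB, tinB, toutB, belowB)
            base = lenA + lenB
            if base > cur_len + slack:
                continue
            for ia in range(mA):
                if uu < n and ia > 0:
                    break
                xa = orderA[ia]
                if ia > 0 and parentA[xa] == uu:
                    continue  # stub edge duplicates the merged edge
                for ib in range(mB):
                    if ia == 0 and ib == 0:
                        continue
                    xb = orderB[ib]
                    if ib > 0 and parentB[xb] == vv:
                        continue
                    if uu < n:
                        cost = base + _join(leafsets[uu], esetsB[xb], active)
                    else:
                        cost = base + _join(esetsA[xa], esetsB[xb], active)
                    if cost <= cur_len + slack and cnt < cap:
                        out_moves[cnt, 0] = uu
                        out_moves[cnt, 1] = vv
                        if uu < n or ia == 0:
                            out_moves[cnt, 2] = -1
                            out_moves[cnt, 3] = -1
                        else:
                            out_moves[cnt, 2] = parentA[xa]
                            out_moves[cnt, 3] = xa
                        if ib == 0:
                            out_moves[cnt, 4] = -1
                            out_moves[cnt, 5] = -1
                        else:
                            out_moves[cnt, 4] = parentB[xb]
                            out_moves[cnt, 5] = xb
                        out_moves[cnt, 6] = cost
                        cnt += 1
    return cnt


@njit(cache=True)
def make_workspace(N, nb):
    parentA = np.empty(N, dtype=np.int64)
    orderA = np.empty(N, dtype=np.int64)
    dsetsA = np.empty((N, NS, nb), dtype=np.uint64)
    usetsA = np.empty((N, NS, nb), dtype=np.uint64)
    esetsA = np.empty((N, NS, nb), dtype=np.uint64)
    tinA = np.empty(N, dtype=np.int64)
    toutA = np.empty(N, dtype=np.int64)
    belowA = np.empty(N, dtype=np.uint64)
    parentB = np.empty(N, dtype=np.int64)
    orderB = np.empty(N, dtype=np.int64)
    dsetsB = np.empty((N, NS, nb), dtype=np.uint64)
    usetsB = np.empty((N, NS, nb), dtype=np.uint64)
    esetsB = np.empty((N, NS, nb), dtype=np.uint64)
    tinB = np.empty(N, dtype=np.int64)
    toutB = np.empty(N, dtype=np.int64)
    belowB = np.empty(N, dtype=np.uint64)
    return (parentA, orderA, dsetsA, usetsA, esetsA, tinA, toutA, belowA,
            parentB, orderB, dsetsB, usetsB, esetsB, tinB, toutB, belowB)


# ------------------------------------------------------------ RAS building

@njit(cache=True)
def ras_build(leafsets, active, n, perm, rngstate, nbr):
    """Random-addition-sequence Wagner tree: insert taxa in ``perm`` order,
    each at a (randomly tie-broken) minimum-cost edge."""
    N = nbr.shape[0]
    nb = active.shape[0]
    nbr[:, :] = -1
    w0 = n
    _connect(nbr, perm[0], w0)
    _connect(nbr, perm[1], w0)
    _connect(nbr, perm[2], w0)
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    dsets = np.empty((N, NS, nb), dtype=np.uint64)
    usets = np.empty((N, NS, nb), dtype=np.uint64)
    eset = np.empty((NS, nb), dtype=np.uint64)
    best_edges = np.empty(2 * N, dtype=np.int64)
    for k in range(3, n):
        leaf = perm[k]
        l0 = perm[0]
        start = nbr[l0, 0]
        m = _traverse(nbr, n, start, l0, parent, order)
        _down_pass(nbr, leafsets, active, n, parent, order, m, dsets)
        for s in range(NS):
            for blk in range(nb):
                usets[start, s, blk] = leafsets[l0, s, blk]
        _up_pass(nbr, leafsets, active, n, parent, order, m, dsets, usets, True)
        best = np.int64(1 << 60)
        nbest = 0
        for i in range(m):
            x = order[i]
            sx = leafsets[x] if x < n else dsets[x]
            _combine(sx, usets[x], eset, active)
            c = _join(eset, leafsets[leaf], active)
            if c < best:
                best = c
                best_edges[0] = x
                nbest = 1
            elif c == best:
                best_edges[nbest] = x
                nbest += 1
        x = best_edges[_rand_below(rngstate, nbest)]
        p = parent[x]
        w = n + k - 2
        _disconnect(nbr, p, x)
        _connect(nbr, p, w)
        _connect(nbr, w, x)
        _connect(nbr, w, leaf)
    return nbr


@njit(cache=True)
def ras_tbr_replicates(leafsets, active, n, nreps, seed, forbid,
                       out_nbrs, out_lens):
    """nreps independent RAS starts each followed by TBR-to-local-optimum.

    Fills out_nbrs[r] and out_lens[r]; returns the best length found.
    When ``forbid`` is non-zero, start trees containing the forbidden split
    are perturbed by reattaching across that edge before descent, and the
    descent never accepts a tree containing the split.
    """
    N = 2 * n - 2
    nb = active.shape[0]
    rngstate = seed_state(seed)
    ws = make_workspace(N, nb)
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    dsets = np.empty((N, NS, nb), dtype=np.uint64)
    below = np.empty(N, dtype=np.uint64)
    perm = np.empty(n, dtype=np.int64)
    nbr = np.empty((N, 3), dtype=np.int64)
    best = np.int64(1 << 60)
    full = (U64(1) << U64(n)) - U64(1)
    for r in range(nreps):
        for i in range(n):
            perm[i] = i
        for i in range(n - 1, 0, -1):
            jj = _rand_below(rngstate, i + 1)
            t = perm[i]
            perm[i] = perm[jj]
            perm[jj] = t
        ras_build(leafsets, active, n, perm, rngstate, nbr)
        if forbid != U64(0):
            _break_split(nbr, n, forbid, parent, order, below)
        cur = tree_length(nbr, leafsets, active, n, parent, order, dsets)
        cur = tbr_improve(nbr, leafsets, active, n, forbid, cur, ws)
        out_lens[r] = cur
        for i in range(N):
            for j in range(3):
                out_nbrs[r, i, j] = nbr[i, j]
        if cur < best:
            best = cur
    return best


@njit(cache=True)
def _break_split(nbr, n, smask, parent, order, below):
    """If the tree contains the forbidden split, apply an NNI across that
    edge to remove it (repeat until absent)."""
    N = nbr.shape[0]
    full = (U64(1) << U64(n)) - U64(1)
    comp = full ^ smask
    for _ in range(N):
        m = tree_leafmasks(nbr, n, parent, order, below)
        hit = np.int64(-1)
        for i in range(m):
            x = order[i]
            if x >= n and parent[x] >= n and (below[x] == smask or below[x] == comp):
                hit = x
                break
        if hit < 0:
            return
        p = parent[hit]
        # children of hit, and hit's sibling under p
        c1 = np.int64(-1)
        for j in range(3):
            y = nbr[hit, j]
            if y >= 0 and y != p:
                c1 = y
                break
        sib = np.int64(-1)
        for j in range(3):
            y = nbr[p, j]
            if y >= 0 and y != hit and y != parent[p]:
                sib = y
                break
        if sib < 0:  # p is the traversal root: use its non-child neighbour
            sib = parent[p]
        # swap c1 and sib across the edge (p, hit)
        _disconnect(nbr, hit, c1)
        _disconnect(nbr, p, sib)
        _connect(nbr, hit, sib)
        _connect(nbr, p, c1)


# ------------------------------------------------------------ exact search

@njit(cache=True)
def bb_search(leafsets, active, n, ub0, prune, forbid, out_trees, max_trees):
    """Branch-and-bound (or exhaustive, prune=False) search by stepwise
    addition in taxon order.  Collects all distinct optimal trees (the
    addition-sequence enumeration generates each labelled topology once).

    When ``forbid`` is non-zero, complete trees containing the split are
    ignored (reverse-constraint search).  Returns (best_len, n_trees,
    n_complete_visited).
    """
    N = 2 * n - 2
    nb = active.shape[0]
    nbr = np.full((N, 3), -1, dtype=np.int64)
    parent = np.empty(N, dtype=np.int64)
    order = np.empty(N, dtype=np.int64)
    dsets = np.empty((N, NS, nb), dtype=np.uint64)
    _connect(nbr, 0, n)
    _connect(nbr, 1, n)
    _connect(nbr, 2, n)
    if n == 3:
        L = tree_length(nbr, leafsets, active, n, parent, order, dsets)
        for i in range(N):
            for j in range(3):
                out_trees[0, i, j] = nbr[i, j]
        return L, 1, 1
    # edge lists per depth
    max_edges = 2 * n - 3
    edge_a = np.empty((n, max_edges), dtype=np.int64)
    edge_b = np.empty((n, max_edges), dtype=np.int64)
    n_edges = np.empty(n, dtype=np.int64)
    choice = np.empty(n, dtype=np.int64)
    ub = ub0
    best = np.int64(1 << 60)
    ntrees = 0
    visited = 0
    k = 3
    choice[k] = -1
    _list_edges(nbr, N, edge_a[k], edge_b[k], n_edges, k)
    while k >= 3:
        # undo previous insertion at this depth
        if choice[k] >= 0:
            _undo_insert(nbr, n, k)
        choice[k] += 1
        if choice[k] >= n_edges[k]:
            choice[k] = -1
            k -= 1
            continue
        a = edge_a[k, choice[k]]
        b = edge_b[k, choice[k]]
        w = n + k - 2
        _disconnect(nbr, a, b)
        _connect(nbr, a, w)
        _connect(nbr, w, b)
        _connect(nbr, w, k)
        L = tree_length(nbr, leafsets, active, n, parent, order, dsets)
        if prune and L > ub:
            continue
        if k == n - 1:
            visited += 1
            if forbid != U64(0) and tree_has_split(nbr, n, forbid):
                continue
            if L < best:
                best = L
                if prune and L < ub:
                    ub = L
                ntrees = 0
            if L == best and ntrees < max_trees:
                for i in range(N):
                    for j in range(3):
                        out_trees[ntrees, i, j] = nbr[i, j]
                ntrees += 1
            continue
        k += 1
        choice[k] = -1
        _list_edges(nbr, N, edge_a[k], edge_b[k], n_edges, k)
    return best, ntrees, visited


@njit(cache=True, inline="always")
def _list_edges(nbr, N, ea, eb, n_edges, k):
    cnt = 0
    for x in range(N):
        for j in range(3):
            y = nbr[x, j]
            if y > x:
                ea[cnt] = x
                eb[cnt] = y
                cnt += 1
    n_edges[k] = cnt


@njit(cache=True, inline="always")
def _undo_insert(nbr, n, k):
    w = n + k - 2
    _disconnect(nbr, w, k)
    p = np.int64(-1)
    x = np.int64(-1)
    for j in range(3):
        y = nbr[w, j]
        if y >= 0:
            if p < 0:
                p = y
            else:
                x = y
    _disconnect(nbr, w, p)
    _disconnect(nbr, w, x)
    _connect(nbr, p, x)
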