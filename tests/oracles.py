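"""Independent brute-force oracles used by the test suite.

Deliberately naive: enumeration over ancestral-state assignments and over
tree topologies, kept entirely separate from the package's optimized code
paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from morphoclad.matrix import CharacterMatrix, MAX_STATE


def postorder_edges(nbr: np.ndarray, n: int) -> list[tuple[int, int]]:
    start = int(nbr[0, 0])
    parent = {start: 0}
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
    edges = [(0, start)] + [(parent[x], x) for x in order[1:]]
    return edges


def brute_force_length(nbr: np.ndarray, matrix: CharacterMatrix) -> int:
    """Minimum changes over all ancestral-state assignments, per character,
    summed.  Leaves with '?'/'-' range over all states seen for the
    character (plus state 0 for an all-missing character)."""
    n = matrix.n_taxa
    internals = sorted({x for x in range(nbr.shape[0]) if x >= n and (nbr[x] >= 0).any()})
    edges = postorder_edges(nbr, n)
    total = 0
    for c in range(matrix.n_characters):
        col = matrix.states[:, c]
        obs = sorted(set(int(s) for s in col if s >= 0)) or [0]
        free_leaves = [i for i in range(n) if col[i] < 0]
        best = None
        for internal_states in itertools.product(obs, repeat=len(internals)):
            assign = {x: s for x, s in zip(internals, internal_states)}
            for leaf_states in itertools.product(obs, repeat=len(free_leaves)):
                for i, s in zip(free_leaves, leaf_states):
                    assign[i] = s
                for i in range(n):
                    if col[i] >= 0:
                        assign[i] = int(col[i])
                cost = sum(1 for a, b in edges if assign[a] != assign[b])
                if best is None or cost < best:
                    best = cost
        total += best
    return total


def all_topologies(n: int):
    """Yield every unrooted binary topology over leaves 0..n-1 as nbr arrays."""
    N = 2 * n - 2

    def build(k: int, nbr: np.ndarray):
        if k == n:
            yield nbr.copy()
            return
        edges = []
        for x in range(N):
            for j in range(3):
                y = nbr[x, j]
                if y > x:
                    edges.append((x, int(y)))
        w = n + k - 2
        for a, b in edges:
            _disc(nbr, a, b)
            _conn(nbr, a, w)
            _conn(nbr, w, b)
            _conn(nbr, w, k)
            yield from build(k + 1, nbr)
            _disc(nbr, w, k)
            _disc(nbr, a, w)
            _disc(nbr, w, b)
            _conn(nbr, a, b)

    nbr = np.full((N, 3), -1, dtype=np.int64)
    _conn(nbr, 0, n)
    _conn(nbr, 1, n)
    _conn(nbr, 2, n)
    yield from build(3, nbr)


def _conn(nbr, a, b):
    for x, y in ((a, b), (b, a)):
        for j in range(3):
            if nbr[x, j] < 0:
                nbr[x, j] = y
                break


def _disc(nbr, a, b):
    for x, y in ((a, b), (b, a)):
        for j in range(3):
            if nbr[x, j] == y:
                nbr[x, j] = -1
                break


def star_tree_length(matrix: CharacterMatrix) -> int:
    """Fitch length on the star topology = sum over characters of
    (observed taxa - count of most frequent observed state)."""
    g = 0
    for c in range(matrix.n_characters):
        col = matrix.states[:, c]
        obs = col[col >= 0]
        if obs.size == 0:
            continue
        _v, counts = np.unique(obs, return_counts=True)
        g += int(obs.size - counts.max())
    return g


def bbm_marginal_bruteforce(children, blen, tip_state, gain, loss):
    """P(state=1) at every node by explicit summation over all joint
    internal-state assignments of the two-state CTMC."""
    import math

    nnode = len(children)
    internals = [i for i in range(nnode) if children[i]]
    tips = [i for i in range(nnode) if not children[i]]
    tot = gain + loss
    pi = [loss / tot, gain / tot]

    def ptrans(a, b, t):
        e = math.exp(-tot * t)
        p1 = gain / tot
        P = [[1 - p1 * (1 - e), p1 * (1 - e)],
             [(1 - p1) * (1 - e), 1 - (1 - p1) * (1 - e)]]
        return P[a][b]

    parent = [None] * nnode
    for i in range(nnode):
        for c in children[i]:
            parent[c] = i
    root = nnode - 1
    marg = np.zeros((nnode, 2))
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = {i: s for i, s in zip(internals, states)}
        for t in tips:
            assign[t] = int(tip_state[t])
        p = pi[assign[root]]
        for i in range(nnode):
            if i != root:
                p *= ptrans(assign[parent[i]], assign[i], blen[i])
        for i in range(nnode):
            marg[i, assign[i]] += p
    return marg[:, 1] / marg.sum(axis=1)
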