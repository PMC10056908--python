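"""Branch support: nonparametric bootstrap proportions and Bremer decay.

Bootstrap: characters are resampled with replacement; each pseudo-replicate
is analysed by a reduced-effort random-addition + TBR search and contributes
the splits of the strict consensus of its best trees.  Bremer decay of a
split: length of the shortest tree lacking the split minus the optimum,
found either by reverse-constraint search (TBR descent that never accepts a
tree containing the split; exact branch-and-bound on small inputs) or by a
suboptimal-buffer sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from ._encode import n_nodes, pack_matrix, pack_states, splits_of_nbr  # noqa: F401
from .consensus import mask_to_clade
from .matrix import CharacterMatrix
from .search import (
    BNB_MAX_TAXA,
    SearchResult,
    branch_and_bound_search,
    heuristic_search,
)


@dataclass
class BootstrapConfig:
    """Per-pseudoreplicate search effort (a deliberate reduction of the
    full search for tractability at 1000 replicates)."""

    replicates: int = 10       # random-addition starts per pseudo-replicate
    trees_to_save: int = 5     # strict-consensus buffer per pseudo-replicate


def bootstrap_support(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    cutoff: float = 50.0,
    seed: int = 0,
    search_config: BootstrapConfig | None = None,
    measure: str = "gc",
) -> pd.DataFrame:
    """Split support across bootstrap pseudo-replicates.

    Each pseudo-replicate contributes its strict-consensus splits; raw
    frequencies are tabulated from those.  ``measure`` selects the headline
    support value: ``"gc"`` (default) reports the frequency *difference* --
    a group's frequency minus that of its best-supported contradicting
    group, the default resampling summary of the major parsimony programs
    and what published "bb" values usually are -- while ``"frequency"``
    reports the raw percentage.  Returns a SupportTable DataFrame
    (``clade``, ``mask``, ``bootstrap``, ``frequency``) with splits whose
    headline value reaches ``cutoff``, sorted by decreasing support.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if measure not in ("gc", "frequency"):
        raise ValueError(f"unknown measure {measure!r}")
    cfg = search_config or BootstrapConfig()
    if cfg.replicates < 3:
        import warnings

        warnings.warn("per-replicate search effort is very low; support "
                      "values may be depressed", stacklevel=2)
    n = matrix.n_taxa
    N = n_nodes(n)
    rng = np.random.default_rng(seed)
    nc = matrix.n_characters
    counts: dict[int, int] = {}
    out_nbrs = np.empty((cfg.replicates, N, 3), dtype=np.int64)
    out_lens = np.empty(cfg.replicates, dtype=np.int64)
    split_buf = np.empty(2 * n, dtype=np.uint64)
    for _rep in range(replicates):
        cols = rng.integers(0, nc, nc)
        leafsets, active = pack_states(matrix.states[:, cols])
        kseed = int(rng.integers(1, 2**62))
        best = K.ras_tbr_replicates(
            leafsets, active, n, cfg.replicates, np.int64(kseed),
            np.uint64(0), out_nbrs, out_lens,
        )
        consensus: set[int] | None = None
        kept = 0
        seen = set()
        for r in range(cfg.replicates):
            if out_lens[r] != best or kept >= cfg.trees_to_save:
                continue
            cnt = K.tree_splits(out_nbrs[r], n, split_buf)
            s = frozenset(int(x) for x in split_buf[:cnt])
            if s in seen:
                continue
            seen.add(s)
            kept += 1
            consensus = set(s) if consensus is None else (consensus & s)
        for m in consensus or ():
            counts[m] = counts.get(m, 0) + 1
    items = list(counts.items())
    rows = []
    for m, c in items:
        freq = 100.0 * c / replicates
        conflict = 0
        for m2, c2 in items:
            inter = m & m2
            if inter and inter != m and inter != m2:
                conflict = max(conflict, c2)
        gc = 100.0 * (c - conflict) / replicates
        value = gc if measure == "gc" else freq
        if value >= cutoff:
            rows.append((mask_to_clade(m, matrix.taxa), m, value, freq))
    df = pd.DataFrame(rows, columns=["clade", "mask", "bootstrap", "frequency"])
    return df.sort_values("bootstrap", ascending=False, ignore_index=True)


def split_support(table: pd.DataFrame, clade, taxa: list[str]) -> float | None:
    """Bootstrap support of the split separating ``clade`` (labels) from
    the rest, or None if below the cutoff."""
    from .consensus import clade_to_mask

    m = clade_to_mask(clade, taxa)
    hit = table[table["mask"] == m]
    return float(hit["bootstrap"].iloc[0]) if len(hit) else None


def bremer_support(
    matrix: CharacterMatrix,
    mp_result: SearchResult,
    max_decay: int = 10,
    seed: int = 0,
    route: str = "constrained",
    replicates: int = 200,
) -> pd.DataFrame:
    """Bremer decay for every split in the strict consensus of the MP trees.

    ``route='constrained'``: per split, a reverse-constraint search (exact
    branch-and-bound when the matrix is small enough, otherwise
    random-addition + TBR descent that never accepts a tree containing the
    split).  ``route='buffer'``: sweep of suboptimal trees within
    ``max_decay`` of the optimum collected from heuristic-search finals and
    their TBR neighbourhoods.  Decay is reported as ``> max_decay``
    (value ``max_decay + 1``) when no tree lacking the split is found
    within the sweep bound.
    """
    if route not in ("constrained", "buffer"):
        raise ValueError(f"unknown route {route!r}")
    n = matrix.n_taxa
    best = mp_result.best_length
    split_sets = [splits_of_nbr(t, n) for t in mp_result.trees]
    consensus = set(split_sets[0])
    for s in split_sets[1:]:
        consensus &= s
    rows = []
    if route == "constrained":
        for m in sorted(consensus):
            if n <= BNB_MAX_TAXA:
                res = branch_and_bound_search(matrix, forbid_split=m)
                alt = res.best_length
            else:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = heuristic_search(
                        matrix, replicates=replicates, trees_to_save=1,
                        seed=seed, forbid_split=m, collapse=None,
                    )
                alt = best + max_decay + 1 if res.bound_infeasible else res.best_length
            decay = min(alt - best, max_decay + 1)
            rows.append((mask_to_clade(m, matrix.taxa), m, decay))
    else:
        pool = _suboptimal_pool(matrix, best, max_decay, seed, replicates)
        for m in sorted(consensus):
            lens = [ln for ln, ss in pool if m not in ss]
            decay = min(lens) - best if lens else max_decay + 1
            rows.append((mask_to_clade(m, matrix.taxa), m, min(decay, max_decay + 1)))
    df = pd.DataFrame(rows, columns=["clade", "mask", "bremer"])
    return df.sort_values("bremer", ascending=False, ignore_index=True)


def _suboptimal_pool(matrix, best, max_decay, seed, replicates):
    """(length, split-set) pairs for distinct trees within best + max_decay,
    from heuristic finals plus their in-slack TBR neighbourhoods."""
    n = matrix.n_taxa
    N = n_nodes(n)
    leafsets, active = pack_matrix(matrix)
    out_nbrs = np.empty((replicates, N, 3), dtype=np.int64)
    out_lens = np.empty(replicates, dtype=np.int64)
    K.ras_tbr_replicates(leafsets, active, n, replicates, np.int64(seed),
                         np.uint64(0), out_nbrs, out_lens)
    ws = K.make_workspace(N, active.shape[0])
    moves = np.empty((200000, 7), dtype=np.int64)
    pool: dict[frozenset[int], int] = {}
    for r in range(replicates):
        L = int(out_lens[r])
        if L > best + max_decay:
            continue
        t = out_nbrs[r].copy()
        key = splits_of_nbr(t, n)
        if key in pool:
            continue
        pool[key] = L
        slack = best + max_decay - L
        cnt = K.equal_cost_moves(t, leafsets, active, n, np.int64(slack), ws, moves)
        for i in range(cnt):
            u, v, a1, a2, b1, b2, cost = (int(x) for x in moves[i])
            t2 = t.copy()
            K._apply_move(t2, n, u, v, a1, a2, b1, b2)
            k2 = splits_of_nbr(t2, n)
            if k2 not in pool or pool[k2] > cost:
                pool[k2] = cost
    return [(L, ss) for ss, L in pool.items()]


def support_table(
    bootstrap: pd.DataFrame | None,
    bremer: pd.DataFrame | None,
    taxa: list[str],
) -> pd.DataFrame:
    """Merge bootstrap and Bremer tables on the split mask."""
    boot = {int(r["mask"]): float(r["bootstrap"]) for _, r in bootstrap.iterrows()} \
        if bootstrap is not None else {}
    brem = {int(r["mask"]): int(r["bremer"]) for _, r in bremer.iterrows()} \
        if bremer is not None else {}
    rows = []
    for m in sorted(set(boot) | set(brem)):
        rows.append((mask_to_clade(m, taxa), m, boot.get(m), brem.get(m)))
    return pd.DataFrame(rows, columns=["clade", "mask", "bootstrap", "bremer"])
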