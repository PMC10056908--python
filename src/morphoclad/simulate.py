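"""Synthetic data with known ground truth: discrete unordered characters
evolving on a tree under a symmetric k-state Markov (Mk) model, and binary
area gain/loss histories for the biogeographic model.

These generators exercise every pipeline stage without external data: the
Mk matrices feed the parsimony searches (with configurable missing-data
masking mirroring '?' and '-') and the area histories provide latent node
states against which ancestral-range reconstructions can be scored.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np

from .matrix import INAPPLICABLE, UNOBSERVED, AreaMatrix, CharacterMatrix


@dataclass
class MkSimConfig:
    """Settings for Mk-model character simulation.

    ``rate`` is the expected number of substitutions per unit branch
    length; state changes pick a different state uniformly.  ``p_unobserved``
    and ``p_inapplicable`` are independent per-cell masking probabilities
    (their sum must stay below 1)."""

    n_taxa: int = 8
    n_characters: int = 100
    n_states: int = 2
    rate: float = 0.5
    p_unobserved: float = 0.0
    p_inapplicable: float = 0.0
    tree: dendropy.Tree | None = None  # user tree overrides the Yule draw
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_states <= 7):
            raise ValueError("n_states must be in 2..7")
        for p in (self.p_unobserved, self.p_inapplicable):
            if not (0 <= p < 1):
                raise ValueError("masking proportions must be in [0, 1)")
        if self.p_unobserved + self.p_inapplicable >= 1:
            raise ValueError("masking proportions must sum below 1")
        if self.n_taxa < 4 and self.tree is None:
            raise ValueError("need at least 4 taxa")


def yule_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0,
              labels: list[str] | None = None) -> dendropy.Tree:
    """Random pure-birth tree with exponential branch lengths."""
    taxa = labels or [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_taxa, taxon_namespace=ns,
        rng=_random.Random(seed),
    )
    return tree


def _mk_transition(k: int, rate: float, t: float) -> tuple[float, float]:
    """(P(stay), P(move to one specific other state)) for the symmetric
    k-state model at total substitution rate ``rate``."""
    e = np.exp(-rate * k / (k - 1) * t)
    p_stay = 1.0 / k + (k - 1) / k * e
    p_each = (1.0 - p_stay) / (k - 1)
    return p_stay, p_each


def simulate_matrix(config: MkSimConfig) -> tuple[CharacterMatrix, dendropy.Tree]:
    """Evolve characters independently along a (Yule or user) tree.

    Returns the masked matrix and the true tree.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree or yule_tree(config.n_taxa, config.birth_rate,
                                    seed=int(rng.integers(2**31)))
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    k, nc = config.n_states, config.n_characters
    states_at = {}
    root = tree.seed_node
    states_at[id(root)] = rng.integers(0, k, nc)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length if nd.edge.length is not None else 1.0
        parent_states = states_at[id(nd.parent_node)]
        if config.rate <= 0 or t <= 0:
            states_at[id(nd)] = parent_states.copy()
            continue
        p_stay, _ = _mk_transition(k, config.rate, t)
        move = rng.uniform(size=nc) > p_stay
        new = parent_states.copy()
        # a move picks uniformly among the other k-1 states
        offs = rng.integers(1, k, size=int(move.sum()))
        new[move] = (new[move] + offs) % k
        states_at[id(nd)] = new
    rows = np.empty((len(tips), nc), dtype=np.int8)
    for i, lf in enumerate(tree.leaf_node_iter()):
        rows[i] = states_at[id(lf)]
    u = rng.uniform(size=rows.shape)
    rows[u < config.p_unobserved] = UNOBSERVED
    both = config.p_unobserved + config.p_inapplicable
    rows[(u >= config.p_unobserved) & (u < both)] = INAPPLICABLE
    return CharacterMatrix(tips, rows), tree


def simulate_area_history(
    tree: dendropy.Tree,
    n_areas: int = 4,
    gain: float = 0.3,
    loss: float = 0.3,
    seed: int = 0,
    max_retries: int = 1000,
) -> tuple[AreaMatrix, dict[frozenset, np.ndarray]]:
    """Independent two-state gain/loss history per area, root to tips.

    Root states draw from the stationary distribution.  A tip that ends up
    with an empty range has its presence vector redrawn (conditional on its
    parent's state) until at least one area is present, honouring the
    area-matrix invariant that every taxon occupies somewhere.  Returns the
    tip matrix and the latent presence vector of every node keyed by its
    descendant-taxon clade.
    """
    if gain <= 0 or loss <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    area_codes = [chr(ord("A") + i) for i in range(n_areas)]
    pi1 = gain / (gain + loss)
    node_state: dict[int, np.ndarray] = {}
    root = tree.seed_node
    node_state[id(root)] = (rng.uniform(size=n_areas) < pi1).astype(np.uint8)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length if nd.edge.length is not None else 1.0
        par = node_state[id(nd.parent_node)]
        e = np.exp(-(gain + loss) * t)
        p_present = np.where(par == 1,
                             pi1 + (1 - pi1) * e,   # stay present
                             pi1 * (1 - e))         # gained
        draw = (rng.uniform(size=n_areas) < p_present).astype(np.uint8)
        if nd.is_leaf():
            for _try in range(max_retries):
                if draw.sum() > 0:
                    break
                draw = (rng.uniform(size=n_areas) < p_present).astype(np.uint8)
            else:
                # pathological rates: force the most probable single area
                draw = np.zeros(n_areas, dtype=np.uint8)
                draw[int(np.argmax(p_present))] = 1
        node_state[id(nd)] = draw
    presence = np.array([node_state[id(lf)] for lf in tree.leaf_node_iter()])
    truth = {}
    for nd in tree.postorder_node_iter():
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        truth[clade] = node_state[id(nd)]
    return AreaMatrix(tips, area_codes, presence), truth
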