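"""Fitch scoring, homoplasy indices, and change mapping, checked against
brute-force enumeration and an independent library implementation."""

import numpy as np
import pytest

import morphoclad as mc
from morphoclad._encode import nbr_to_tree, tree_to_nbr
from morphoclad.matrix import CharacterMatrix
from morphoclad.parsimony import (
    min_max_steps,
    per_character_fit,
    per_character_lengths,
)
from morphoclad.io import read_tree

from conftest import random_matrix
from oracles import all_topologies, brute_force_length, star_tree_length


@pytest.mark.parametrize("seed", range(8))
def test_fitch_length_matches_bruteforce(seed):
    """Engine length equals the minimum over all ancestral assignments on
    random small trees with multistate and missing cells."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    m = random_matrix(rng, n, n_chars=6, n_states=3, p_missing=0.2)
    trees = list(all_topologies(n))
    t = trees[int(rng.integers(len(trees)))]
    assert mc.fitch_length(t, m) == brute_force_length(t, m)


def test_fitch_invariant_to_rooting_and_leaf_order(aphrodini, aphrodini_mp):
    nbr = aphrodini_mp.trees[0]
    L = mc.fitch_length(nbr, aphrodini)
    tree = nbr_to_tree(nbr, aphrodini.taxa)
    # rerooting the dendropy tree must not change the score
    for node in list(tree.preorder_node_iter())[2:5]:
        tree.reroot_at_edge(node.edge)
        assert mc.fitch_length(tree, aphrodini) == L
    # permuting taxon order in the matrix must not change the score
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(aphrodini.taxa))
    assert mc.fitch_length(tree, aphrodini.subset_taxa(perm)) == L


def test_fitch_agrees_with_dendropy():
    """Cross-check against dendropy's Fitch implementation."""
    import dendropy
    from dendropy.model.parsimony import fitch_down_pass

    rng = np.random.default_rng(3)
    m = random_matrix(rng, 8, n_chars=20, n_states=3)
    res = mc.branch_and_bound_search(m)
    nbr = res.trees[0]
    tree = nbr_to_tree(nbr, m.taxa)
    rows = ["".join(str(int(c)) for c in m.states[i]) for i in range(8)]
    nex = "\n".join(f"{m.taxa[i]} {rows[i]}" for i in range(8))
    dm = dendropy.StandardCharacterMatrix.get(
        data=f"#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=8 NCHAR=20;\n"
             f"FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456\";\nMATRIX\n{nex}\n;\nEND;\n",
        schema="nexus")
    dtree = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                              schema="newick",
                              taxon_namespace=dm.taxon_namespace)
    dtree.encode_bipartitions()
    taxon_state_sets_map = dm.taxon_state_sets_map(gaps_as_missing=True)
    score = fitch_down_pass(dtree.postorder_node_iter(),
                            taxon_state_sets_map=taxon_state_sets_map)
    assert score == res.best_length == mc.fitch_length(tree, m)


def test_constant_and_forced_characters():
    taxa = list("wxyz")
    const = CharacterMatrix(taxa, np.zeros((4, 3), dtype=np.int8))
    tree = read_tree("((w,x),(y,z));")
    assert mc.fitch_length(tree, const) == 0
    inf = CharacterMatrix(taxa, np.array([[0], [0], [1], [1]], dtype=np.int8))
    assert mc.fitch_length(tree, inf) == 1  # one change on the central edge
    # all-distinct 4-state character is forced to 3 steps on any topology
    dist = CharacterMatrix(taxa, np.array([[0], [1], [2], [3]], dtype=np.int8))
    for t in all_topologies(4):
        assert mc.fitch_length(t, dist) == 3


@pytest.mark.parametrize("seed", range(5))
def test_max_steps_equals_star_tree_length(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, 7, n_chars=10, n_states=4, p_missing=0.25)
    _mm, g = min_max_steps(m)
    assert int(g.sum()) == star_tree_length(m)


def test_per_character_fit_fixture(aphrodini, aphrodini_mp):
    fits = per_character_fit(aphrodini_mp.trees[0], aphrodini)
    # character 1: one taxon state 0, twenty-two state 1 -> m = 1, g = 1
    assert (fits[1].m, fits[1].g) == (1, 1)
    assert sum(f.s for f in fits) == aphrodini_mp.best_length
    for f in fits:
        assert f.m <= f.s <= f.g


def test_ci_ri_bounds_and_perfect_tree():
    taxa = [f"t{i}" for i in range(6)]
    # two congruent binary characters: a perfect tree exists
    states = np.array([[0, 0], [0, 0], [0, 0], [1, 1], [1, 1], [1, 1]],
                      dtype=np.int8)
    m = CharacterMatrix(taxa, states)
    res = mc.branch_and_bound_search(m)
    fits = per_character_fit(res.trees[0], m)
    assert mc.consistency_index(fits) == 1.0
    assert mc.retention_index(fits) == 1.0


def test_added_homoplasy_never_raises_ri(aphrodini, aphrodini_mp):
    """Flipping a leaf state to a convergent value cannot increase RI."""
    nbr = aphrodini_mp.trees[0]
    fits = per_character_fit(nbr, aphrodini)
    ri0 = mc.retention_index(fits)
    states = aphrodini.states.copy()
    # character 21 is 0 for outgroups, 1 for Planaphrodes: make one outgroup
    # convergently 1
    row = aphrodini.taxa.index("Anoscopus albiger")
    states[row, 21] = 1
    m2 = CharacterMatrix(list(aphrodini.taxa), states)
    ri1 = mc.retention_index(per_character_fit(nbr, m2))
    assert ri1 <= ri0


def test_deleting_a_character_never_increases_length(aphrodini, aphrodini_mp):
    nbr = aphrodini_mp.trees[0]
    L = mc.fitch_length(nbr, aphrodini)
    for c in (0, 13, 25, 38):
        keep = [j for j in range(aphrodini.n_characters) if j != c]
        assert mc.fitch_length(nbr, aphrodini.subset_characters(keep)) <= L


def test_per_character_lengths_sum(aphrodini, aphrodini_mp):
    s = per_character_lengths(aphrodini_mp.trees[0], aphrodini)
    assert int(s.sum()) == aphrodini_mp.best_length


class TestMapChanges:
    def test_flattened_shaft_is_unique_planaphrodes_synapomorphy(
            self, aphrodini, aphrodini_mp, planaphrodes_taxa):
        """Character 21 (aedeagal shaft flattened) changes 0->1 once, on the
        stem of the 16 Planaphrodes species, in every reconstruction."""
        tree = nbr_to_tree(aphrodini_mp.trees[0], aphrodini.taxa)
        df = mc.map_changes(tree, aphrodini, root_taxon=mc.ROOT_OUTGROUP)
        hits = df[df["character"] == 21]
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row["clade"] == frozenset(planaphrodes_taxa)
        assert row["from_states"] == (0,) and row["to_states"] == (1,)
        assert row["unique"] and row["unambiguous"]

    def test_aphrodes_planaphrodes_stem_synapomorphies(
            self, aphrodini, aphrodini_mp, planaphrodes_taxa):
        """Striate crown/pronotum (0:1), flat keeled crown (5:1), leathery
        wings (6:1) and trapezoidal valve (13:2) change on the stem of
        Aphrodes + Planaphrodes (ACCTRAN mapping; character 0's placement
        is ambiguous, the others are not)."""
        tree = nbr_to_tree(aphrodini_mp.trees[0], aphrodini.taxa)
        df = mc.map_changes(tree, aphrodini, root_taxon=mc.ROOT_OUTGROUP,
                            resolution="acctran")
        clade = frozenset(planaphrodes_taxa) | {
            t for t in aphrodini.taxa if t.startswith("Aphrodes")}
        stem = df[df["clade"] == clade]
        expect = {0: 1, 5: 1, 6: 1, 13: 2}
        for char, to in expect.items():
            row = stem[stem["character"] == char]
            assert len(row) == 1, f"character {char} missing on the stem"
            assert to in row.iloc[0]["to_states"]
        # the unambiguous map agrees for the unambiguous three
        dfu = mc.map_changes(tree, aphrodini, root_taxon=mc.ROOT_OUTGROUP)
        stemu = dfu[dfu["clade"] == clade]
        for char in (5, 6, 13):
            assert (stemu["character"] == char).sum() == 1

    def test_constant_character_maps_no_change(self):
        taxa = list("abcd")
        m = CharacterMatrix(taxa, np.zeros((4, 2), dtype=np.int8))
        tree = read_tree("(a,(b,(c,d)));")
        df = mc.map_changes(tree, m, root_taxon="a")
        assert df.empty

    def test_unrooted_input_rejected(self, aphrodini, aphrodini_mp):
        tree = nbr_to_tree(aphrodini_mp.trees[0], aphrodini.taxa)
        # nbr arrays carry no root: passing one without root_taxon must fail
        with pytest.raises(ValueError, match="root"):
            mc.map_changes(aphrodini_mp.trees[0], aphrodini)

    @pytest.mark.parametrize("resolution", ["acctran", "deltran"])
    def test_full_resolutions_account_for_all_steps(
            self, aphrodini, aphrodini_mp, resolution):
        """An ACCTRAN/DELTRAN reconstruction places exactly s_i changes for
        every character."""
        tree = nbr_to_tree(aphrodini_mp.trees[0], aphrodini.taxa)
        df = mc.map_changes(tree, aphrodini, root_taxon=mc.ROOT_OUTGROUP,
                            resolution=resolution)
        s = per_character_lengths(aphrodini_mp.trees[0], aphrodini)
        counts = df.groupby("character").size()
        for c in range(aphrodini.n_characters):
            assert counts.get(c, 0) == int(s[c])
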