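"""Binary ancestral-area model: exact marginals against brute-force joint
summation, MCMC behaviour, and qualitative reconstructions on the packaged
dataset's geography."""

import numpy as np
import pytest

import morphoclad as mc
from morphoclad.biogeo import BbmConfig, _index_tree, bbm_reconstruct, marginal_presence
from morphoclad.io import read_tree
from morphoclad.matrix import AreaMatrix

from oracles import bbm_marginal_bruteforce


def _areas(taxa, ranges, codes="AB"):
    pres = np.array([[1 if a in ranges[t] else 0 for a in codes]
                     for t in taxa], dtype=np.uint8)
    return AreaMatrix(list(taxa), list(codes), pres)


@pytest.mark.parametrize("seed", range(4))
def test_marginals_match_bruteforce_joint_sum(seed):
    """Pruning + up-down marginals equal explicit summation over all joint
    internal states on small trees (binary and multifurcating)."""
    rng = np.random.default_rng(seed)
    newick = ["((a,b),(c,d),e);", "(((a,b),c),(d,e));", "((a,b,c),(d,e));"][seed % 3]
    tree = read_tree(newick)
    taxa = list("abcde")
    ranges = {t: ("A" if rng.uniform() < 0.5 else "B") for t in taxa}
    ranges[taxa[0]] = "AB"
    am = _areas(taxa, ranges)
    gain, loss = float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 2))
    got = marginal_presence(tree, am, gain, loss)
    cfg = BbmConfig()
    nodes, children, blen, tip_label, clades = _index_tree(tree, cfg)
    row_of = {t: i for i, t in enumerate(am.taxa)}
    for a_idx, a in enumerate(am.areas):
        tip_state = np.zeros(len(nodes))
        for i, lab in enumerate(tip_label):
            if lab is not None:
                tip_state[i] = am.presence[row_of[lab], a_idx]
        oracle = bbm_marginal_bruteforce(children, blen, tip_state, gain, loss)
        for _, row in got.iterrows():
            i = next(k for k, cl in enumerate(clades) if cl == row["clade"])
            assert row[f"P({a})"] == pytest.approx(oracle[i], abs=1e-9)


def test_two_tip_symmetry():
    """Tips {A} and {B} with symmetric priors: the root is indifferent."""
    tree = read_tree("(a,b);")
    am = _areas(["a", "b"], {"a": "A", "b": "B"})
    cfg = BbmConfig(chain_length=6000, burnin=0.25, thin=5, seed=0)
    table = bbm_reconstruct(tree, am, cfg)
    root = table.iloc[0]
    assert abs(root["P(A)"] - root["P(B)"]) < 0.08


def test_monophyletic_area_clade_reconstructs_with_high_probability():
    """A clade whose tips all occupy exactly area D gets P(D) > 0.95 at its
    ancestor."""
    tree = read_tree("((((x1,x2),(x3,x4)),x5),((y1,y2),(y3,y4)));")
    taxa = [f"x{i}" for i in range(1, 6)] + [f"y{i}" for i in range(1, 5)]
    ranges = {t: ("D" if t.startswith("x") else "A") for t in taxa}
    am = _areas(taxa, ranges, codes="AD")
    cfg = BbmConfig(chain_length=4000, thin=5, seed=1)
    table = bbm_reconstruct(tree, am, cfg)
    mrca = table[table["clade"] == frozenset(["x1", "x2", "x3", "x4"])].iloc[0]
    assert mrca["P(D)"] > 0.95
    assert "D" in mrca["map_range"] and "A" not in mrca["map_range"]
    deeper = table[table["clade"] == frozenset(f"x{i}" for i in range(1, 6))]
    assert deeper.iloc[0]["P(D)"] > 0.9


def test_invariance_to_area_and_tip_order():
    tree = read_tree("((a,b),(c,d),e);")
    taxa = list("abcde")
    ranges = {"a": "A", "b": "AB", "c": "B", "d": "B", "e": "A"}
    g, l = 0.4, 0.7
    p1 = marginal_presence(tree, _areas(taxa, ranges, "AB"), g, l)
    # reversed area order
    am2 = _areas(taxa, ranges, "AB")
    am2 = AreaMatrix(am2.taxa, ["B", "A"], am2.presence[:, ::-1].copy())
    p2 = marginal_presence(tree, am2, g, l)
    for _, r1 in p1.iterrows():
        r2 = p2[p2["clade"] == r1["clade"]].iloc[0]
        assert r1["P(A)"] == pytest.approx(r2["P(A)"], abs=1e-12)
    # same ranges, permuted tip row order
    perm = ["e", "c", "a", "d", "b"]
    p3 = marginal_presence(tree, _areas(perm, ranges, "AB"), g, l)
    for _, r1 in p1.iterrows():
        r3 = p3[p3["clade"] == r1["clade"]].iloc[0]
        assert r1["P(A)"] == pytest.approx(r3["P(A)"], abs=1e-12)


def test_zero_variance_area_handled_analytically():
    tree = read_tree("((a,b),(c,d),e);")
    taxa = list("abcde")
    am = _areas(taxa, {t: "A" for t in taxa}, "AB")  # A everywhere, B nowhere
    table = bbm_reconstruct(tree, am, BbmConfig(chain_length=1500, seed=0))
    assert (table["P(A)"] == 1.0).all()
    assert (table["P(B)"] == 0.0).all()


def test_fixed_seed_reproducible_and_chain_stable(aphrodini=None):
    tree = read_tree("(((a,b),c),(d,e));")
    taxa = list("abcde")
    am = _areas(taxa, {"a": "A", "b": "AB", "c": "B", "d": "B", "e": "A"})
    cfg = BbmConfig(chain_length=3000, thin=5, seed=7)
    t1 = bbm_reconstruct(tree, am, cfg)
    t2 = bbm_reconstruct(tree, am, cfg)
    assert t1.drop(columns=["clade"]).equals(t2.drop(columns=["clade"]))
    long = bbm_reconstruct(tree, am, BbmConfig(chain_length=12000, thin=5, seed=8))
    for a in "AB":
        assert np.allclose(t1[f"P({a})"], long[f"P({a})"], atol=0.12)


def test_missing_tip_rejected():
    tree = read_tree("(a,(b,z));")
    am = _areas(["a", "b"], {"a": "A", "b": "B"})
    with pytest.raises(ValueError, match="z"):
        bbm_reconstruct(tree, am, BbmConfig(chain_length=1500))


def test_recovery_beats_baseline_on_simulated_histories():
    """Marginal presence calls at the generating rates recover latent node
    states better than a coin flip."""
    from morphoclad.simulate import simulate_area_history, yule_tree

    correct = total = 0
    for seed in range(6):
        tree = yule_tree(12, seed=seed)
        am, truth = simulate_area_history(tree, n_areas=2, gain=0.6,
                                          loss=0.6, seed=seed)
        got = marginal_presence(tree, am, 0.6, 0.6, branch_lengths="tree")
        for _, row in got.iterrows():
            tv = truth[row["clade"]]
            for j, a in enumerate(am.areas):
                call = row[f"P({a})"] > 0.5
                correct += int(call == bool(tv[j]))
                total += 1
    assert correct / total > 0.6


def test_qualitative_aphrodini_geography(aphrodini, aphrodini_mp):
    """East Asian trio's ancestor reconstructs in area D; the deeper
    ingroup nodes favour Europe (A)."""
    from morphoclad._encode import nbr_to_tree
    from morphoclad.consensus import strict_consensus

    areas = mc.load_area_matrix()
    trees = [nbr_to_tree(t, aphrodini.taxa) for t in aphrodini_mp.trees]
    cons = strict_consensus(trees, taxa=aphrodini.taxa)
    keep = [t for t in aphrodini.taxa if t in set(areas.taxa)]
    pruned = cons.extract_tree_with_taxa_labels(keep)
    table = bbm_reconstruct(pruned, areas.subset_taxa(keep),
                            BbmConfig(chain_length=4000, thin=5, seed=0))
    trio = frozenset(["Planaphrodes nigricans", "Planaphrodes baoxingensis",
                      "Planaphrodes faciems"])
    row = table[table["clade"] == trio]
    assert len(row) == 1, "East Asian trio not monophyletic in consensus"
    assert row.iloc[0]["P(D)"] > 0.5
    # the European subclade (laevus + lusitanicus) ancestor favours A
    pair = frozenset(["Planaphrodes laevus", "Planaphrodes lusitanicus"])
    rowp = table[table["clade"] == pair]
    if len(rowp):
        probs = {a: rowp.iloc[0][f"P({a})"] for a in areas.areas}
        assert max(probs, key=probs.get) == "A"
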