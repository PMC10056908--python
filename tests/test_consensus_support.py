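"""Consensus trees, bootstrap proportions, and Bremer decay, including
oracle equivalence of the two Bremer routes on exhaustively solvable
matrices."""

import numpy as np
import pytest

import morphoclad as mc
from morphoclad._encode import nbr_to_tree, splits_of_nbr
from morphoclad.consensus import clade_to_mask, split_masks
from morphoclad.io import read_tree
from morphoclad.matrix import CharacterMatrix
from morphoclad.support import bremer_support, bootstrap_support, split_support

from conftest import random_matrix
from oracles import all_topologies, brute_force_length


class TestConsensus:
    def test_identity_and_star(self):
        t = read_tree("((a,b),(c,d),e);")
        taxa = list("abcde")
        same = mc.strict_consensus([t, read_tree("((a,b),(c,d),e);")])
        assert split_masks(same, taxa) == split_masks(t, taxa)
        conflict = read_tree("((a,c),(b,d),e);")
        star = mc.strict_consensus([t, conflict])
        assert split_masks(star, taxa) == frozenset()

    def test_majority_counts_and_order_invariance(self):
        t = read_tree("((a,b),(c,d),e);")
        other = read_tree("((a,c),(b,d),e);")
        taxa = list("abcde")
        trees = [t, read_tree("((a,b),(c,d),e);"),
                 read_tree("((a,b),(c,d),e);"), other]
        maj = mc.majority_rule_consensus(trees, threshold=0.5)
        assert split_masks(maj, taxa) == split_masks(t, taxa)
        # frequency labels: 75%
        labels = {nd.label for nd in maj if nd.label}
        assert "75" in labels
        rev = mc.majority_rule_consensus(trees[::-1], threshold=0.5)
        assert split_masks(rev, taxa) == split_masks(maj, taxa)

    def test_threshold_validation_and_mismatched_taxa(self):
        t = read_tree("((a,b),(c,d),e);")
        with pytest.raises(ValueError):
            mc.majority_rule_consensus([t], threshold=0.3)
        with pytest.raises(ValueError):
            mc.strict_consensus([t, read_tree("((a,b),(c,x),e);")])

    def test_containment_chain(self, aphrodini, aphrodini_mp):
        """strict splits are a subset of majority splits, which come from
        the input trees."""
        trees = [nbr_to_tree(t, aphrodini.taxa) for t in aphrodini_mp.trees]
        strict = split_masks(mc.strict_consensus(trees, taxa=aphrodini.taxa),
                             aphrodini.taxa)
        maj = split_masks(
            mc.majority_rule_consensus(trees, 0.5, taxa=aphrodini.taxa),
            aphrodini.taxa)
        allsplits = set()
        for t in aphrodini_mp.trees:
            allsplits |= splits_of_nbr(t, aphrodini.n_taxa)
        assert strict <= maj <= allsplits


class TestBremer:
    def _oracle_decays(self, m):
        """Exact decay per strict-consensus split by full-topology
        enumeration (independent of the package's search code)."""
        lens = [(brute_force_length(t, m), splits_of_nbr(t, m.n_taxa))
                for t in all_topologies(m.n_taxa)]
        best = min(L for L, _ in lens)
        opt = [ss for L, ss in lens if L == best]
        consensus = set(opt[0])
        for ss in opt[1:]:
            consensus &= ss
        out = {}
        for mk in consensus:
            out[mk] = min(L for L, ss in lens if mk not in ss) - best
        return best, out

    @pytest.mark.parametrize("seed", range(3))
    def test_constrained_route_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = random_matrix(rng, 6, n_chars=10, n_states=2)
        best, oracle = self._oracle_decays(m)
        res = mc.branch_and_bound_search(m)
        assert res.best_length == best
        table = bremer_support(m, res, max_decay=20, route="constrained")
        got = {int(r["mask"]): int(r["bremer"]) for _, r in table.iterrows()}
        assert got == oracle

    @pytest.mark.parametrize("seed", range(3))
    def test_buffer_route_agrees_with_constrained(self, seed):
        rng = np.random.default_rng(300 + seed)
        m = random_matrix(rng, 7, n_chars=12, n_states=2)
        res = mc.branch_and_bound_search(m)
        a = bremer_support(m, res, max_decay=8, route="constrained")
        b = bremer_support(m, res, max_decay=8, route="buffer",
                           replicates=400, seed=seed)
        da = {int(r["mask"]): int(r["bremer"]) for _, r in a.iterrows()}
        db = {int(r["mask"]): int(r["bremer"]) for _, r in b.iterrows()}
        assert da == db

    def test_absent_split_is_not_in_table(self, aphrodini, aphrodini_mp):
        """Splits missing from some MP tree have decay 0 and are excluded
        (they are not in the strict consensus)."""
        table = bremer_support(aphrodini, aphrodini_mp, max_decay=4,
                               replicates=60, seed=0)
        assert (table["bremer"] >= 1).all()
        strict = set(splits_of_nbr(aphrodini_mp.trees[0], aphrodini.n_taxa))
        for t in aphrodini_mp.trees[1:]:
            strict &= splits_of_nbr(t, aphrodini.n_taxa)
        assert set(int(x) for x in table["mask"]) == strict


class TestBootstrap:
    def test_congruent_characters_give_full_support(self):
        """Many identical informative characters: every true split at
        ~100%."""
        cfg = mc.MkSimConfig(n_taxa=7, n_characters=200, rate=0.2, seed=3)
        m, truth = mc.simulate_matrix(cfg)
        table = bootstrap_support(m, replicates=100, cutoff=90, seed=0,
                                  search_config=mc.BootstrapConfig(3, 3))
        got = set(int(x) for x in table["mask"])
        truth_splits = split_masks(truth, m.taxa)
        # splits with real character support should all be near 100
        assert truth_splits <= got or len(truth_splits - got) <= 1

    def test_reproducible_for_fixed_seed(self, aphrodini):
        a = bootstrap_support(aphrodini, replicates=30, cutoff=0, seed=5,
                              search_config=mc.BootstrapConfig(3, 3))
        b = bootstrap_support(aphrodini, replicates=30, cutoff=0, seed=5,
                              search_config=mc.BootstrapConfig(3, 3))
        assert a.equals(b)

    def test_gc_never_exceeds_frequency(self, aphrodini):
        t = bootstrap_support(aphrodini, replicates=50, cutoff=0, seed=2,
                              search_config=mc.BootstrapConfig(3, 3))
        assert (t["bootstrap"] <= t["frequency"] + 1e-9).all()

    def test_bremer_and_bootstrap_rank_correlate(self):
        """Higher-decay splits tend to higher bootstrap on simulated data
        (sanity, not an exact law)."""
        from scipy.stats import spearmanr

        cfg = mc.MkSimConfig(n_taxa=8, n_characters=60, rate=0.4, seed=8)
        m, _ = mc.simulate_matrix(cfg)
        res = mc.branch_and_bound_search(m)
        brem = bremer_support(m, res, max_decay=20, route="constrained")
        boot = bootstrap_support(m, replicates=150, cutoff=0, seed=0,
                                 search_config=mc.BootstrapConfig(3, 3),
                                 measure="frequency")
        merged = brem.merge(boot[["mask", "bootstrap"]], on="mask", how="left")
        merged["bootstrap"] = merged["bootstrap"].fillna(0.0)
        if len(merged) >= 3 and merged["bremer"].nunique() > 1:
            rho, _p = spearmanr(merged["bremer"], merged["bootstrap"])
            assert rho > -0.5  # never strongly anti-correlated

    def test_planaphrodes_split_varies_within_binomial_error(self, aphrodini,
                                                             planaphrodes_taxa):
        """Across seeds the Planaphrodes frequency stays within binomial
        sampling error of its long-run mean."""
        vals = []
        for seed in (0, 1):
            t = bootstrap_support(aphrodini, replicates=150, cutoff=0,
                                  seed=seed, measure="frequency",
                                  search_config=mc.BootstrapConfig(5, 3))
            vals.append(split_support(t, planaphrodes_taxa, aphrodini.taxa))
        p = np.mean(vals) / 100
        se = 100 * np.sqrt(p * (1 - p) / 150)
        assert abs(vals[0] - vals[1]) < 6 * se + 1
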