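import itertools

import numpy as np
import pandas as pd
import pytest

from allometree.branchwise import (AncovaResult, ancova_tukey,
                                   bm_conditional_node_means, branch_changes,
                                   compact_letter_display,
                                   group_change_summary, node_groups)
from allometree.synthgen import generate_study, simulate_tree
from allometree.treeio import read_newick

from conftest import kriging_node_means


class TestBLUP:
    def test_two_tip_root_weighted_mean(self):
        tree = read_newick("(A:1,B:3);")
        out = bm_conditional_node_means(tree, np.array([0.0, 4.0]))
        # precisions 1/1 and 1/3: root = (0·1 + 4·(1/3)) / (4/3) = 1
        assert out[tree.root] == pytest.approx(1.0)

    def test_matches_dense_kriging_oracle(self, rng):
        for rep in range(25):
            nt = int(rng.integers(3, 9))
            tree = simulate_tree(nt, seed=500 + rep, age=10.0)
            vals = rng.normal(size=nt)
            means = 0.5 * rng.normal(size=tree.n_nodes)
            a = bm_conditional_node_means(tree, vals, node_means=means)
            b = kriging_node_means(tree, vals, means)
            assert np.allclose(a, b, atol=1e-8)

    def test_tips_reproduced_exactly(self, rng):
        tree = simulate_tree(12, seed=2, age=50.0)
        vals = rng.normal(size=12)
        out = bm_conditional_node_means(tree, vals)
        assert np.array_equal(out[tree.tip_indices], vals)

    def test_positive_trend_pulls_deep_nodes_down(self):
        """With prior means increasing along the tree (positive trend in
        time), deeper (older) nodes get smaller reconstructed values,
        monotonically in the adjustment."""
        tree = simulate_tree(10, seed=4, age=100.0)
        depth = tree.node_depths()
        tips = tree.tip_indices
        vals = np.full(10, 5.0)
        flat = bm_conditional_node_means(tree, vals)
        trended = bm_conditional_node_means(tree, vals,
                                            node_means=0.03 * depth)
        adj = trended - flat
        internal = [i for i in range(tree.n_nodes) if i not in set(tips)]
        # older nodes are adjusted downward relative to shallower ones
        order = np.argsort(depth[internal])
        a = adj[np.array(internal)[order]]
        assert a[0] < a[-1]
        assert adj[tree.root] < 0


class TestBranchChanges:
    def small_setup(self):
        tree = read_newick("((A:1,B:1):2,(C:1.5,D:1.5):1.5);")
        n = tree.n_nodes
        brain = np.linspace(0.0, 1.0, n)
        body = np.linspace(1.0, 0.5, n)
        return tree, brain, body

    def test_constant_values_give_zero_changes(self):
        tree, _, _ = self.small_setup()
        ch = branch_changes(tree, np.full(tree.n_nodes, 2.0),
                            np.full(tree.n_nodes, 3.0))
        assert np.allclose(ch["delta_brain"], 0.0)
        assert not ch["brain_increase"].any()
        assert np.allclose(ch["prop_brain_per_myr"], 0.0)

    def test_telescoping_conservation(self, rng):
        """Sum of per-branch Δ along any root-to-tip path equals
        tip − root."""
        tree = simulate_tree(20, seed=8, age=80.0)
        brain = rng.normal(size=tree.n_nodes)
        body = rng.normal(size=tree.n_nodes)
        ch = branch_changes(tree, brain, body).set_index("child")
        for tip in tree.tip_indices:
            total = 0.0
            node = int(tip)
            while tree.parent[node] >= 0:
                total += ch.loc[node, "delta_brain"]
                node = int(tree.parent[node])
            assert total == pytest.approx(brain[tip] - brain[tree.root])

    def test_proportions_match_direct_count(self):
        tree, brain, body = self.small_setup()
        groups = node_groups(tree, {"A": "g1", "B": "g1", "C": "g2",
                                    "D": "g2"})
        ch = branch_changes(tree, brain, body, groups=groups)
        summ = group_change_summary(ch)
        direct = ch[ch["group"] == "g1"]["brain_increase"].mean()
        got = summ.set_index("group").loc["g1", "prop_brain_increase"]
        assert got == pytest.approx(direct)

    def test_zero_length_branch_flagged(self):
        tree = read_newick("((A:0,B:1):2,C:3);")
        n = tree.n_nodes
        ch = branch_changes(tree, np.arange(n, dtype=float),
                            np.arange(n, dtype=float))
        flagged = ch[ch["zero_length"]]
        assert len(flagged) == 1
        assert np.isnan(flagged["prop_brain_per_myr"].iloc[0])

    def test_z_columns_standardized(self, rng):
        tree = simulate_tree(15, seed=3, age=50.0)
        ch = branch_changes(tree, rng.normal(size=tree.n_nodes),
                            rng.normal(size=tree.n_nodes))
        assert ch["z_brain"].mean() == pytest.approx(0.0, abs=1e-12)
        assert ch["z_brain"].std(ddof=0) == pytest.approx(1.0)
        assert np.allclose(ch["z_diff"], ch["z_brain"] - ch["z_body"])


def brute_force_cld(names, nonsig):
    """Exhaustive minimal clique cover of the non-significance graph."""
    sig = {frozenset(p) for p in itertools.combinations(names, 2)} - nonsig
    def is_clique(sub):
        return all(frozenset(p) in nonsig
                   for p in itertools.combinations(sub, 2))
    cliques = [frozenset(s) for r in range(1, len(names) + 1)
               for s in itertools.combinations(names, r) if is_clique(s)]
    for k in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, k):
            nodes = set().union(*combo)
            edges = {frozenset(p) for c in combo
                     for p in itertools.combinations(c, 2)}
            if nodes == set(names) and nonsig <= edges and not (edges & sig):
                return k
    raise AssertionError("no valid cover")


class TestTukeyLetters:
    def test_single_group_single_letter(self, rng):
        tree = simulate_tree(10, seed=6, age=50.0)
        ch = branch_changes(tree, rng.normal(size=tree.n_nodes),
                            rng.normal(size=tree.n_nodes),
                            groups=["only"] * tree.n_nodes)
        res = ancova_tukey(ch, include_ancestor=False)
        assert res.letters == {"only": "A"}
        assert res.pairwise.empty

    def test_textbook_three_groups(self, rng):
        """Two identical groups and one shifted by five standard deviations:
        the shifted group gets its own letter."""
        rows = []
        for g, mu in (("g1", 0.0), ("g2", 0.0), ("g3", 5.0)):
            for _ in range(30):
                cov = rng.normal()
                rows.append({"group": g, "delta_body": cov,
                             "delta_brain": mu + 0.5 * cov + rng.normal(),
                             "ancestor_brain": rng.normal()})
        ch = pd.DataFrame(rows)
        res = ancova_tukey(ch, include_ancestor=False)
        assert res.letters["g1"] == res.letters["g2"]
        assert res.letters["g3"] != res.letters["g1"]
        assert res.letters["g3"] == "A"   # highest adjusted mean
        assert res.group_p < 1e-6

    def test_letter_count_matches_bruteforce_cover(self, rng):
        """Compaction is minimal: letter count equals the exhaustive
        clique-cover optimum on random ≤5-group significance patterns."""
        names = list("abcde")
        for rep in range(40):
            pairs = list(itertools.combinations(names, 2))
            nonsig = {frozenset(p) for p in pairs
                      if rng.random() < 0.5}
            letters = compact_letter_display(names, nonsig)
            used = len(set("".join(letters.values())))
            assert used == brute_force_cld(names, nonsig)
            # validity: nonsig pairs share a letter, sig pairs never do
            for p in pairs:
                a, b = tuple(p)
                share = set(letters[a]) & set(letters[b])
                assert bool(share) == (frozenset(p) in nonsig)

    def test_ancestor_covariate_switch(self, rng):
        tree, table, truth, _ = generate_study(
            {"seed": 55, "tree": {"group_sizes": {"G1": 15, "G2": 15}},
             "shifts": {}, "trends": {}})
        brain = rng.normal(size=tree.n_nodes)
        body = rng.normal(size=tree.n_nodes)
        groups = node_groups(tree, dict(zip(table["species"],
                                            table["group"])))
        ch = branch_changes(tree, brain, body, groups=groups)
        with_anc = ancova_tukey(ch, include_ancestor=True)
        without = ancova_tukey(ch, include_ancestor=False)
        assert isinstance(with_anc, AncovaResult)
        assert with_anc.model.df_resid == without.model.df_resid - 1
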