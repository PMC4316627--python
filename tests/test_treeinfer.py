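"""Distances, neighbor joining, pruning likelihood, bootstrap."""

import itertools

import numpy as np
import pytest

from phyloroot.models import SubstitutionModel, poisson_p_distance
from phyloroot.simulate import evolve_alignment
from phyloroot.treeinfer import (DistanceError, DistanceMatrix,
                                 PruningEngine, bootstrap_support, correct_p,
                                 distance_matrix, neighbor_joining, nj_tree,
                                 optimize_branch_lengths, pairwise_distance,
                                 tree_log_likelihood)
from phyloroot.trees import Node, PhyloTree, TreeError, random_topology
from phyloroot.formats import parse_newick
from phyloroot.screen import bipartition_set
from tests.conftest import random_binary_tree


class TestDistances:
    @pytest.mark.parametrize("correction", ["p", "kimura", "ml-poisson"])
    def test_identical_rows_zero(self, correction):
        assert pairwise_distance("MKVL", "MKVL", correction) == 0.0

    def test_kimura_formula(self):
        row_a = "A" * 50 + "R" * 50
        row_b = "A" * 50 + "N" * 50
        d = pairwise_distance(row_a, row_b, "kimura")
        assert np.isclose(d, -np.log(1 - 0.5 - 0.2 * 0.25))

    def test_gaps_excluded_pairwise(self):
        assert pairwise_distance("MK-L", "MKX-", "p") == 0.0
        with pytest.raises(DistanceError):
            pairwise_distance("--", "AA", "p")

    def test_ml_poisson_inverts_expected_p(self):
        for t in (0.05, 0.3, 1.0):
            p = poisson_p_distance(t)
            assert np.isclose(correct_p(p, "ml-poisson"), t)

    def test_ml_poisson_close_to_kimura_at_small_p(self):
        for p in np.linspace(0.01, 0.1, 10):
            assert abs(correct_p(p, "ml-poisson") -
                       correct_p(p, "kimura")) < 0.01

    def test_corrections_monotone_in_p(self):
        grid = np.linspace(0, 0.8, 50)
        for corr in ("p", "kimura", "ml-poisson"):
            vals = [correct_p(p, corr) for p in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_simulated_pair_recovers_distance(self):
        """ML-Poisson distance at t=0.3 and 50k sites within 3 sigma."""
        model = SubstitutionModel.poisson(alpha=None)
        root = Node(None)
        root.add(Node("a", 0.15))
        root.add(Node("b", 0.15))
        fam = evolve_alignment(PhyloTree(root, validate=False), model,
                               50_000, seed=8)
        seqs = fam.sequences()
        d = pairwise_distance(seqs["a"], seqs["b"], "ml-poisson")
        p = poisson_p_distance(0.3)
        se_p = np.sqrt(p * (1 - p) / 50_000)
        se_d = se_p / (1 - p / 0.95)      # delta method on the inverse map
        assert abs(d - 0.3) < 3 * se_d

    def test_saturated_pairs_capped_and_flagged(self):
        seqs = {"a": "ARNDCQEGHILKMFPSTWYV" * 2,
                "b": "RNDCQEGHILKMFPSTWYVA" * 2,       # all mismatches
                "c": "ARNDCQEGHILKMFPSTWYV" * 2}
        dm = distance_matrix(seqs, "kimura")
        assert ("a", "b") in dm.saturated
        assert np.isfinite(dm.d).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {n.name: n.length for n in t.leaves()}
        assert np.isclose(lengths["A"], (3 + 4 - 5) / 2)
        assert np.isclose(lengths["B"], (3 + 5 - 4) / 2)
        assert np.isclose(lengths["C"], (4 + 5 - 3) / 2)

    def test_additive_quartet_exact(self):
        t = parse_newick("((A:1,B:2):1,C:3,D:4);")
        names = t.leaf_names
        d = np.zeros((4, 4))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    d[i, j] = d[j, i] = t.path_length(a, b)
        nj = neighbor_joining(DistanceMatrix(names, d))
        assert bipartition_set(nj) == bipartition_set(t)
        got = {n.name: n.length for n in nj.leaves()}
        assert got == {"A": 1, "B": 2, "C": 3, "D": 4}
        internal = [n.length for n in nj.edges() if not n.is_leaf]
        assert np.allclose(sorted(internal), [1.0])

    def test_exact_on_random_additive_matrices(self):
        """NJ recovers topology and branch lengths from additive matrices
        of 5-30 taxa (the classic consistency guarantee)."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            t = random_binary_tree(rng, n)
            names = t.leaf_names
            d = np.zeros((n, n))
            for i, a in enumerate(names):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = t.path_length(a, names[j])
            nj = neighbor_joining(DistanceMatrix(names, d))
            assert bipartition_set(nj) == bipartition_set(t)
            assert np.isclose(nj.total_length(), t.total_length())

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0., 1.], [1., 0.]])))


def brute_force_log_likelihood(tree, seqs, model):
    """Exhaustive summation over internal-node states (tiny trees only)."""
    states, n = model.states, model.n_states
    rates = model.category_rates()
    nodes = list(tree.nodes())
    internals = [x for x in nodes if not x.is_leaf]
    leaves = [x for x in nodes if x.is_leaf]
    L = len(next(iter(seqs.values())))
    total = 0.0
    for site in range(L):
        site_like = 0.0
        for r in rates:
            P = {id(x): model.transition_matrix(x.length, r) for x in nodes}
            s = 0.0
            for assign in itertools.product(range(n), repeat=len(internals)):
                amap = {id(x): a for x, a in zip(internals, assign)}
                for lf in leaves:
                    amap[id(lf)] = states.index(seqs[lf.name][site])
                p = model.frequencies[amap[id(tree.root)]]
                for x in nodes:
                    if x is not tree.root:
                        p *= P[id(x)][amap[id(x.parent)], amap[id(x)]]
                s += p
            site_like += s / len(rates)
        total += np.log(site_like)
    return total


@pytest.fixture(scope="module")
def dna_model():
    """Asymmetric reversible 4-state model (catches orientation bugs a
    symmetric Poisson model cannot)."""
    rng = np.random.default_rng(13)
    S = rng.random((4, 4))
    S = S + S.T
    np.fill_diagonal(S, 0)
    pi = rng.dirichlet(np.ones(4))
    return SubstitutionModel(S, pi / pi.sum(), alpha=0.8, n_categories=3,
                             states="ACGT")


class TestLikelihood:
    def test_pattern_likelihoods_sum_to_one(self, dna_model):
        """Summing site likelihoods over every possible 3-leaf pattern
        gives exactly 1 (the pruning recursion is a proper distribution)."""
        root = Node(None)
        root.add(Node("a", 0.2))
        root.add(Node("b", 0.45))
        root.add(Node("c", 0.9))
        tree = PhyloTree(root, validate=False)
        total = 0.0
        for pat in itertools.product("ACGT", repeat=3):
            seqs = dict(zip("abc", pat))
            total += np.exp(tree_log_likelihood(tree, seqs, dna_model))
        assert np.isclose(total, 1.0, atol=1e-10)

    def test_two_leaf_matches_closed_form(self):
        """One site on a two-leaf Poisson tree equals pi_x * P_xy(t)."""
        model = SubstitutionModel.poisson(alpha=None, states="ACGT")
        root = Node(None)
        root.add(Node("a", 0.1))
        root.add(Node("b", 0.2))
        tree = PhyloTree(root, validate=False)
        t = 0.3
        p_same = 0.25 + 0.75 * np.exp(-4 / 3 * t)
        lnl_same = tree_log_likelihood(tree, {"a": "A", "b": "A"}, model)
        lnl_diff = tree_log_likelihood(tree, {"a": "A", "b": "C"}, model)
        assert np.isclose(np.exp(lnl_same), 0.25 * p_same, atol=1e-12)
        assert np.isclose(np.exp(lnl_diff), 0.25 * (1 - p_same) / 3,
                          atol=1e-12)

    def test_matches_brute_force(self, dna_model):
        rng = np.random.default_rng(5)
        for n_leaves in (3, 4, 5):
            tree = random_binary_tree(rng, n_leaves)
            fam = evolve_alignment(tree, dna_model, 8, seed=n_leaves)
            seqs = fam.sequences()
            assert abs(tree_log_likelihood(tree, seqs, dna_model)
                       - brute_force_log_likelihood(tree, seqs, dna_model)) \
                < 1e-10

    def test_rerooting_invariance(self, dna_model):
        rng = np.random.default_rng(6)
        tree = random_binary_tree(rng, 6)
        fam = evolve_alignment(tree, dna_model, 40, seed=1)
        seqs = fam.sequences()
        ref = tree_log_likelihood(tree, seqs, dna_model)
        for edge in list(tree.edges()):
            rerooted = tree.reroot_on_edge(edge)
            assert abs(tree_log_likelihood(rerooted, seqs, dna_model)
                       - ref) < 1e-8

    def test_gaps_are_missing_data(self, dna_model):
        root = Node(None)
        root.add(Node("a", 0.2))
        root.add(Node("b", 0.4))
        tree = PhyloTree(root, validate=False)
        # an all-gap column contributes likelihood 1 (lnL contribution 0)
        base = tree_log_likelihood(tree, {"a": "AC", "b": "AG"}, dna_model)
        padded = tree_log_likelihood(tree, {"a": "AC-", "b": "AG-"},
                                     dna_model)
        assert np.isclose(base, padded, atol=1e-12)

    def test_missing_row_rejected(self, dna_model):
        rng = np.random.default_rng(2)
        tree = random_binary_tree(rng, 4)
        with pytest.raises(TreeError):
            tree_log_likelihood(tree, {"t0": "A", "t1": "A", "t2": "A"},
                                dna_model)


class TestOptimizeBranchLengths:
    def test_ascent_and_fixed_point(self, dna_model):
        rng = np.random.default_rng(9)
        tree = random_binary_tree(rng, 5)
        fam = evolve_alignment(tree, dna_model, 500, seed=3)
        seqs = fam.sequences()
        start = tree_log_likelihood(tree, seqs, dna_model)
        opt = optimize_branch_lengths(tree, seqs, dna_model, tol=1e-4)
        end = tree_log_likelihood(opt, seqs, dna_model)
        assert end >= start - 1e-9
        again = optimize_branch_lengths(opt, seqs, dna_model, tol=1e-4)
        for a, b in zip(opt.edges(), again.edges()):
            assert abs(a.length - b.length) < 5e-3

    def test_recovers_simulated_lengths(self, poisson_model):
        """On the true topology with plenty of signal, optimized lengths
        land within 10% of the generating values for edges >= 0.05."""
        tree = parse_newick(
            "((a:0.15,b:0.2):0.1,(c:0.25,d:0.1):0.15,e:0.3);")
        model = SubstitutionModel.poisson(alpha=None)
        fam = evolve_alignment(tree, model, 20_000, seed=4)
        seqs = fam.sequences()
        opt = optimize_branch_lengths(tree, seqs, model, tol=1e-3)
        truth = {n.name: n.length for n in tree.edges() if n.is_leaf}
        got = {n.name: n.length for n in opt.edges() if n.is_leaf}
        for name, t in truth.items():
            if t >= 0.05:
                assert abs(got[name] - t) / t < 0.10


class TestBootstrap:
    def test_degenerate_alignment_full_support(self):
        """Identical columns: every replicate reproduces the same tree, so
        all supports are 100 and stay in [0, 100]."""
        seqs = {"a": "A" * 30, "b": "R" * 30, "c": "N" * 30, "d": "D" * 30,
                "e": "C" * 30}
        t = bootstrap_support(seqs, B=10, seed=0, correction="p")
        sups = [n.support for n in t.edges() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_strong_signal_split_high_support(self, poisson_model):
        """Clean simulation with a 0.5 stem: the ingroup|outgroup split gets
        bootstrap support >= 95."""
        from phyloroot.simulate import WorldConfig, sample_species_tree
        from phyloroot.screen import is_monophyletic
        cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                          n_outgroup_phyla=4, stem_length=0.5, seed=21)
        tree, tax = sample_species_tree(cfg)
        fam = evolve_alignment(tree, poisson_model, 5000, seed=6)
        bt = bootstrap_support(fam.sequences(), B=100, seed=1, alpha=1.0)
        outgroup = frozenset(l for l in tree.leaf_names if tax.is_outgroup(l))
        assert is_monophyletic(bt, outgroup)
        for node in bt.edges():
            below = bt.leafset_below(node)
            if below in (outgroup, frozenset(bt.leaf_names) - outgroup):
                assert node.support >= 95

    def test_supports_in_range_and_deterministic(self, poisson_model,
                                                 small_world):
        _, tree, _ = small_world
        fam = evolve_alignment(tree, poisson_model, 200, seed=7)
        t1 = bootstrap_support(fam.sequences(), B=20, seed=3)
        t2 = bootstrap_support(fam.sequences(), B=20, seed=3)
        from phyloroot.formats import write_newick
        assert write_newick(t1) == write_newick(t2)
        assert all(0 <= n.support <= 100 for n in t1.edges()
                   if n.support is not None)
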