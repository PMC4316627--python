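"""Substitution model and synthetic gene-family generator."""

import numpy as np
import pytest
from scipy import stats

from phyloroot.formats import write_newick
from phyloroot.models import SubstitutionModel, poisson_p_distance
from phyloroot.simulate import (ConfigError, WorldConfig, clade_leaves,
                                degrade, evolve_alignment, inject_hgt,
                                inject_paralogy, make_benchmark,
                                sample_species_tree)
from phyloroot.trees import Node, PhyloTree


class TestSubstitutionModel:
    def test_rate_matrix_normalized(self):
        m = SubstitutionModel.poisson()
        Q = m.rate_matrix
        assert np.allclose(Q.sum(axis=1), 0)
        assert np.isclose(-(m.frequencies * np.diag(Q)).sum(), 1.0)

    def test_category_rates_have_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            r = SubstitutionModel.poisson(alpha=alpha).category_rates()
            assert len(r) == 6
            assert np.isclose(r.mean(), 1.0)
            assert np.all(np.diff(r) > 0)

    def test_transition_matrix_stochastic(self):
        m = SubstitutionModel.poisson(alpha=0.7)
        P = m.transition_matrix(0.37, 1.3)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(20))

    def test_poisson_closed_form_matches_expm(self):
        m = SubstitutionModel.poisson()
        for t in (0.05, 0.3, 1.2):
            P = m.transition_matrix(t)
            p_diff = 1.0 - P[0, 0]
            assert np.isclose(p_diff, poisson_p_distance(t), atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel.poisson(alpha=-1)
        S = np.ones((20, 20)) - np.eye(20)
        with pytest.raises(ValueError):
            SubstitutionModel(S, np.full(20, 0.9))   # frequencies don't sum


class TestSpeciesTree:
    def test_structure_and_stem(self):
        cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                          n_outgroup_phyla=3, species_per_outgroup_phylum=1,
                          seed=1)
        tree, tax = sample_species_tree(cfg)
        assert len(tree.leaf_names) == 11
        assert not tree.rooted
        outgroup = {l for l in tree.leaf_names if tax.is_outgroup(l)}
        from phyloroot.screen import is_monophyletic
        assert is_monophyletic(tree, outgroup)
        from phyloroot.rooting import interdomain_stem_length
        ingroup = set(tree.leaf_names) - outgroup
        assert interdomain_stem_length(tree, ingroup, outgroup) == \
            cfg.stem_length

    def test_every_class_and_phylum_monophyletic(self, small_world):
        from phyloroot.screen import is_monophyletic
        _, tree, tax = small_world
        for rank in ("class_", "phylum"):
            groups = {}
            for leaf in tree.leaf_names:
                groups.setdefault(getattr(tax.resolve(leaf), rank),
                                  set()).add(leaf)
            for leaves in groups.values():
                assert is_monophyletic(tree, leaves)

    def test_rate_multiplier_scales_inside_edges(self):
        cfg = WorldConfig(seed=3)
        base, tax = sample_species_tree(cfg)
        fast, _ = sample_species_tree(
            WorldConfig(seed=3, fast_clades=[("A1", 8.0)]))
        focal = clade_leaves(tax, "A1")
        for plain, scaled in zip(base.nodes(), fast.nodes()):
            below = base.leafset_below(plain)
            if below < focal:             # strictly inside the clade
                assert np.isclose(scaled.length, 8.0 * plain.length)
            elif not (below & focal):
                assert np.isclose(scaled.length, plain.length)

    def test_deterministic_given_seed(self):
        t1, _ = sample_species_tree(WorldConfig(seed=11))
        t2, _ = sample_species_tree(WorldConfig(seed=11))
        assert write_newick(t1) == write_newick(t2)

    def test_impossible_config_rejected(self):
        with pytest.raises(ConfigError):
            WorldConfig(n_species_per_class=0)
        with pytest.raises(ConfigError):
            WorldConfig(fast_clades=[("A1", 0.5)])


def two_leaf_tree(t1, t2):
    root = Node(None)
    root.add(Node("a", t1))
    root.add(Node("b", t2))
    return PhyloTree(root, validate=False)


class TestEvolveAlignment:
    def test_zero_branch_lengths_give_identical_sequences(self, poisson_model):
        tree = two_leaf_tree(0.0, 0.0)
        fam = evolve_alignment(tree, poisson_model, 100, seed=5)
        seqs = fam.sequences()
        assert seqs["a"] == seqs["b"]

    def test_observed_divergence_matches_matrix_exponential(self,
                                                            poisson_model):
        """Two leaves at total distance 0.1, 50k sites: the proportion of
        differing sites must sit within 3 SE of the closed-form p(t)."""
        model = SubstitutionModel.poisson(alpha=None)
        tree = two_leaf_tree(0.04, 0.06)
        n = 50_000
        fam = evolve_alignment(tree, model, n, seed=2)
        seqs = fam.sequences()
        p_obs = np.mean([x != y for x, y in zip(seqs["a"], seqs["b"])])
        p_exp = poisson_p_distance(0.1)
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_huge_alpha_matches_rate_homogeneous_limit(self):
        """alpha -> inf collapses the gamma categories to rate 1."""
        tree = two_leaf_tree(0.1, 0.1)
        n = 30_000
        m_inf = SubstitutionModel.poisson(alpha=1e7)
        m_one = SubstitutionModel.poisson(alpha=None)
        rates = m_inf.category_rates()
        assert np.allclose(rates, 1.0, atol=1e-3)
        p = []
        for m in (m_inf, m_one):
            fam = evolve_alignment(tree, m, n, seed=3)
            s = fam.sequences()
            p.append(np.mean([x != y for x, y in zip(s["a"], s["b"])]))
        se = np.sqrt(p[1] * (1 - p[1]) / n)
        assert abs(p[0] - p[1]) < 4 * se

    def test_leaf_frequencies_stationary(self, small_world, poisson_model):
        """Residue frequencies at a leaf pass a chi-squared goodness-of-fit
        test against the model equilibrium (alpha = 0.01)."""
        _, tree, _ = small_world
        fam = evolve_alignment(tree, poisson_model, 50_000, seed=4)
        seq = fam.members[0].sequence
        counts = np.array([seq.count(c) for c in poisson_model.states])
        expected = poisson_model.frequencies * len(seq)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)

    def test_invalid_site_count(self, small_world, poisson_model):
        _, tree, _ = small_world
        with pytest.raises(ConfigError):
            evolve_alignment(tree, poisson_model, 0, seed=1)


@pytest.fixture(scope="module")
def family(small_world, poisson_model):
    _, tree, _ = small_world
    return tree, evolve_alignment(tree, poisson_model, 400, seed=9)


class TestPlantedEvents:

    def test_hgt_zero_divergence_copies_donor(self, family, poisson_model):
        tree, fam = family
        out = inject_hgt(fam, tree, "P01_s1", "A1_s1", 0.0, poisson_model, 1)
        assert out.member("A1_s1").sequence == out.member("P01_s1").sequence
        assert len(out.truth) == len(fam.truth) + 1

    def test_hgt_recipient_nearest_neighbor_is_donor(self, family,
                                                     poisson_model):
        tree, fam = family
        out = inject_hgt(fam, tree, "P01_s1", "A1_s1", 0.01, poisson_model, 2)
        from phyloroot.treeinfer import pairwise_distance
        seqs = out.sequences()
        d = {l: pairwise_distance(seqs["A1_s1"], s, "p")
             for l, s in seqs.items() if l != "A1_s1"}
        assert min(d, key=d.get) == "P01_s1"

    def test_hgt_unknown_leaf_rejected(self, family, poisson_model):
        tree, fam = family
        with pytest.raises(KeyError):
            inject_hgt(fam, tree, "nope", "A1_s1", 0.1, poisson_model, 1)

    def test_paralogy_adds_diverged_copy(self, family, poisson_model):
        _, fam = family
        out = inject_paralogy(fam, "B1_s1", 0.0, poisson_model, 3)
        assert len(out.members) == len(fam.members) + 1
        assert out.member("B1_s1__2").sequence == out.member("B1_s1").sequence
        from phyloroot.treeinfer import pairwise_distance
        out2 = inject_paralogy(fam, "B1_s1", 0.01, poisson_model, 4)
        seqs = out2.sequences()
        d = {l: pairwise_distance(seqs["B1_s1__2"], s, "p")
             for l, s in seqs.items() if l != "B1_s1__2"}
        assert min(d, key=d.get) == "B1_s1"

    def test_truncate_gaps_out_complement(self, family):
        _, fam = family
        L = fam.n_sites
        out = degrade(fam, "A1_s1", "truncate", 5, fraction=0.4)
        seq = out.member("A1_s1").sequence
        assert seq.count("-") == L - round(0.4 * L)
        assert out.member("A1_s1").is_partial
        # kept block is contiguous
        kept = [i for i, c in enumerate(seq) if c != "-"]
        assert kept == list(range(kept[0], kept[-1] + 1))

    def test_mask_fraction_binomial(self, small_world, poisson_model):
        _, tree, _ = small_world
        fam = evolve_alignment(tree, poisson_model, 10_000, seed=10)
        out = degrade(fam, "A1_s1", "mask", 6, fraction=0.5)
        frac = out.member("A1_s1").sequence.count("-") / 10_000
        assert abs(frac - 0.5) <= 0.015

    def test_loss_and_errors(self, family):
        _, fam = family
        out = degrade(fam, ["A1_s1", "A1_s2"], "loss", 1)
        assert len(out.members) == len(fam.members) - 2
        with pytest.raises(ConfigError):
            degrade(fam, "missing_leaf", "loss", 1)
        with pytest.raises(ConfigError):
            degrade(fam, "A1_s1", "truncate", 1, fraction=1.5)


class TestMakeBenchmark:
    def test_zero_rates_all_clean(self):
        cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                          n_outgroup_phyla=3)
        bench = make_benchmark(cfg, 10, event_rates=(0, 0, 0),
                               n_sites_range=(50, 60), seed=2)
        assert bench.truth["clean"].all()

    def test_rate_one_all_hgt(self):
        cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                          n_outgroup_phyla=3)
        bench = make_benchmark(cfg, 20, event_rates=(1, 0, 0),
                               n_sites_range=(50, 60), seed=3)
        assert bench.truth["hgt"].all()

    def test_label_frequencies_match_rates(self, benchmark500):
        """Bernoulli label frequencies within 3 sigma of the event rates."""
        truth = benchmark500.truth
        n = len(truth)
        for label, p in (("hgt", 0.2), ("paralog", 0.1), ("partial", 0.1)):
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(truth[label].mean() - p) < 3 * sd

    def test_deterministic(self):
        cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                          n_outgroup_phyla=3)
        b1 = make_benchmark(cfg, 5, seed=4, n_sites_range=(50, 60))
        b2 = make_benchmark(cfg, 5, seed=4, n_sites_range=(50, 60))
        assert [f.sequences() for f in b1.families] == \
               [f.sequences() for f in b2.families]
        assert b1.truth.equals(b2.truth)
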