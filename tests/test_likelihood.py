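"""Likelihood engine: pruning vs enumeration, optimizers, invariances."""

import numpy as np
import pytest

import cpphylo as cp
from cpphylo.likelihood import MIN_BL, TreeLikelihood
from cpphylo.tree import Node, Tree
from oracles import enumeration_loglik


def two_taxon_alignment(n, p, seed=0):
    """Pair of sequences with proportion p of differing sites."""
    rng = np.random.default_rng(seed)
    s1 = rng.integers(0, 4, n)
    s2 = s1.copy()
    idx = rng.choice(n, int(round(n * p)), replace=False)
    s2[idx] = (s1[idx] + rng.integers(1, 4, idx.size)) % 4
    bases = np.array(list("ACGT"))
    return cp.Alignment(["a", "b"], np.array([bases[s1], bases[s2]])), (s1 != s2).mean()


def cherry(la, lb):
    root = Node()
    root.add(Node("a", la))
    root.add(Node("b", lb))
    return Tree(root)


class TestLogLikelihood:
    def test_identical_sequences_zero_lengths(self):
        aln, _ = two_taxon_alignment(500, 0.0)
        ll = cp.log_likelihood(aln, cherry(0.0, 0.0), cp.SubstModel())
        assert ll == pytest.approx(500 * np.log(0.25), abs=1e-9)

    def test_matches_enumeration_oracle_quartet(self, tiny_alignment, quartet_tree, gtr_model):
        expected = enumeration_loglik(tiny_alignment, quartet_tree, gtr_model)
        assert cp.log_likelihood(tiny_alignment, quartet_tree, gtr_model) == pytest.approx(
            expected, abs=1e-8
        )

    def test_matches_enumeration_oracle_five_taxa(self, gtr_model):
        tree = cp.parse_newick("(((a:0.11,b:0.21):0.06,c:0.14):0.04,d:0.3,e:0.09);")
        rng = np.random.default_rng(42)
        chars = np.array(list("ACGTACGTACGTN-"))  # mostly unambiguous
        mat = chars[rng.integers(0, len(chars), size=(5, 20))]
        aln = cp.Alignment(list("abcde"), mat)
        expected = enumeration_loglik(aln, tree, gtr_model)
        assert cp.log_likelihood(aln, tree, gtr_model) == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_rerooting(self, gtr_model):
        tree = cp.generate_tree(7, 1.2, seed=9)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 300, 1.0), seed=10)
        ref = cp.log_likelihood(aln, tree, gtr_model)
        for leaf in ("t02", "t06"):
            assert cp.log_likelihood(aln, tree.reroot(leaf), gtr_model) == pytest.approx(
                ref, abs=1e-10
            )

    def test_invariant_under_taxon_permutation(self, gtr_model):
        tree = cp.generate_tree(6, 1.0, seed=4)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 200, 1.0), seed=5)
        shuffled = aln.take_taxa(list(reversed(aln.taxa)))
        assert cp.log_likelihood(shuffled, tree, gtr_model) == pytest.approx(
            cp.log_likelihood(aln, tree, gtr_model), abs=1e-10
        )

    def test_taxon_mismatch_rejected(self, gtr_model, tiny_alignment):
        tree = cp.parse_newick("((a:0.1,b:0.1):0.1,c:0.1,zzz:0.1);")
        with pytest.raises(ValueError, match="zzz"):
            cp.log_likelihood(tiny_alignment, tree, gtr_model)


class TestBranchLengthOptimization:
    def test_two_taxon_jc_closed_form(self):
        aln, phat = two_taxon_alignment(2000, 0.12, seed=1)
        jc = cp.SubstModel(n_categories=1)
        opt = cp.optimize_branch_lengths(aln, cherry(0.05, 0.05), jc)
        expected = -0.75 * np.log(1 - 4 * phat / 3)
        assert opt.tree_length() == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_shrink_to_min(self):
        aln, _ = two_taxon_alignment(300, 0.0)
        opt = cp.optimize_branch_lengths(aln, cherry(0.3, 0.3), cp.SubstModel())
        for node in opt.postorder():
            if node.parent is not None:
                assert node.length <= 2 * MIN_BL

    def test_never_decreases_loglik(self, gtr_model):
        tree = cp.generate_tree(6, 1.0, seed=13)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 1500, 1.0), seed=14)
        perturbed = tree.copy()
        rng = np.random.default_rng(0)
        for n in perturbed.postorder():
            if n.parent is not None:
                n.length = max(float(n.length * rng.uniform(0.2, 3.0)), MIN_BL)
        before = cp.log_likelihood(aln, perturbed, gtr_model)
        after = cp.log_likelihood(aln, cp.optimize_branch_lengths(aln, perturbed, gtr_model), gtr_model)
        assert after >= before


class TestModelOptimization:
    def test_recovers_generating_parameters(self):
        truth = cp.SubstModel(
            np.array([1.5, 4.0, 0.9, 1.2, 5.0, 1.0]),
            np.array([0.35, 0.15, 0.18, 0.32]),
            alpha=0.6,
        )
        tree = cp.generate_tree(12, 1.5, seed=21)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 50000, 1.0, model=truth), seed=22)
        start = cp.SubstModel(base_freqs=cp.empirical_base_freqs(aln))
        engine = TreeLikelihood(aln, tree, start)
        engine.optimize_branch_lengths()
        fitted = engine.optimize_model()
        assert abs(fitted.alpha - truth.alpha) / truth.alpha < 0.25
        assert np.all(np.abs(fitted.base_freqs - truth.base_freqs) < 0.02)

    def test_fixed_point_when_already_optimal(self, gtr_model):
        tree = cp.generate_tree(6, 1.0, seed=2)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 2000, 1.0), seed=3)
        engine = TreeLikelihood(aln, tree, gtr_model)
        engine.optimize_branch_lengths()
        first = engine.optimize_model()
        before = engine.log_likelihood()
        engine.optimize_model()
        assert engine.log_likelihood() >= before - 1e-6

    def test_frequencies_stay_on_simplex(self, gtr_model):
        tree = cp.generate_tree(5, 0.8, seed=6)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 800, 1.0), seed=7)
        fitted = cp.optimize_model_parameters(aln, tree, gtr_model)
        assert fitted.base_freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert fitted.exchangeabilities[5] == 1.0

    def test_degenerate_alignment_returns_input_with_warning(self, gtr_model):
        aln = cp.Alignment(["a", "b", "c"], np.array([list("AAAA")] * 3))
        tree = cp.parse_newick("(a:0.1,b:0.1,c:0.1);")
        with pytest.warns(UserWarning, match="degenerate"):
            out = cp.optimize_model_parameters(aln, tree, gtr_model)
        assert out is gtr_model
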