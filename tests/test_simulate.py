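"""Synthetic data generator: trees, genes, whole datasets."""

import numpy as np
import pytest

import cpphylo as cp


class TestGenerateTree:
    def test_three_taxa_star(self):
        t = cp.generate_tree(3, 1.0, seed=0)
        assert len(t) == 3
        assert sum(1 for n in t.postorder() if n.parent is not None) == 3

    def test_deterministic(self):
        assert cp.generate_tree(10, 2.0, seed=5).newick() == cp.generate_tree(
            10, 2.0, seed=5
        ).newick()

    def test_rescaled_to_total_length(self):
        t = cp.generate_tree(12, 2.0, seed=3)
        assert t.tree_length() == pytest.approx(2.0, abs=1e-9)

    def test_binary_unrooted(self):
        t = cp.generate_tree(9, 1.0, seed=8)
        assert len(t.root.children) == 3
        for n in t.postorder():
            if n.parent is not None and not n.is_leaf:
                assert len(n.children) == 2


class TestSimulateGene:
    def test_zero_rate_keeps_root_state(self):
        tree = cp.generate_tree(6, 1.0, seed=1)
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 100, 0.0), seed=2)
        assert all(aln.sequence(t) == aln.sequence(aln.taxa[0]) for t in aln.taxa)

    def test_stationary_base_frequencies(self):
        tree = cp.generate_tree(4, 0.5, seed=3)
        model = cp.simulate.default_model()
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 50000, 1.0, model), seed=4)
        masks = aln.masks()
        freqs = np.array([(masks == 1 << i).mean() for i in range(4)])
        assert np.all(np.abs(freqs - model.base_freqs) < 0.01)

    def test_divergence_increases_with_multiplier(self):
        tree = cp.generate_tree(6, 0.6, seed=5)

        def mean_pairwise_diff(mult, seed):
            aln = cp.simulate_gene(tree, cp.GeneProfile("g", 4000, mult), seed=seed)
            m = aln.matrix
            diffs = [
                (m[i] != m[j]).mean()
                for i in range(len(m))
                for j in range(i + 1, len(m))
            ]
            return np.mean(diffs)

        d = [np.mean([mean_pairwise_diff(mult, s) for s in (11, 12, 13)]) for mult in (0.5, 1.0, 2.0)]
        assert d[0] < d[1] < d[2]

    def test_length_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            cp.GeneProfile("g", 10, 1.0)


class TestSimulateDataset:
    def test_partition_bookkeeping(self):
        cfg = cp.SimConfig(n_taxa=6, n_genes=3, seed=9)
        res = cp.simulate_dataset(cfg)
        assert res.alignment.n_sites == sum(p.length for p in res.profiles)
        assert len(res.alignment.partitions) == 3
        starts = [p.start for p in res.alignment.partitions]
        assert starts == sorted(starts)
        for part, prof in zip(res.alignment.partitions, res.profiles):
            assert part.length == prof.length

    def test_full_scale_defaults_near_145kb(self):
        # total simulated concatenation length ~145 kb at full scale
        cfg = cp.SimConfig(seed=17)
        profiles = cp.simulate.draw_profiles(cfg, seed=17)
        total = sum(p.length for p in profiles)
        assert abs(total - 145410) / 145410 < 0.10

    def test_multiplier_spread_about_an_order_of_magnitude(self):
        cfg = cp.SimConfig(seed=23)
        mults = np.array([p.rate_multiplier for p in cp.simulate.draw_profiles(cfg, 23)])
        ratio = np.quantile(mults, 0.95) / np.quantile(mults, 0.05)
        assert 5 < ratio < 20

    def test_write_dataset_round_trips(self, tmp_path):
        cfg = cp.SimConfig(n_taxa=5, n_genes=2, seed=3)
        res = cp.simulate_dataset(cfg)
        cp.write_dataset(res, tmp_path)
        aln = cp.read_fasta(tmp_path / "concat.fasta")
        assert aln == res.alignment
        parts = cp.read_partitions(tmp_path / "partitions.txt")
        assert parts == res.alignment.partitions
        tree = cp.read_newick(tmp_path / "true_tree.nwk")
        assert tree.bipartitions() == res.tree.bipartitions()
        manifest = (tmp_path / "manifest.tsv").read_text().splitlines()
        assert len(manifest) == 3  # header + 2 genes


class TestSimulatorInferenceRoundTrip:
    def test_ml_recovers_topology_and_lengths(self):
        """50 kb single-gene simulation: topology recovered exactly, branch
        lengths with small mean relative error."""
        tree = cp.generate_tree(12, 1.2, seed=41)
        for n in tree.postorder():  # keep internal branches comfortably long
            if n.parent is not None and not n.is_leaf:
                n.length = max(n.length, 0.05)
        model = cp.simulate.default_model()
        aln = cp.simulate_gene(tree, cp.GeneProfile("g", 50000, 1.0, model), seed=42)
        found = cp.search_ml_tree(aln, model, n_starts=1, seed=43)
        assert found.bipartitions() == tree.bipartitions()
        found = cp.optimize_branch_lengths(aln, found, model)

        # compare lengths via canonical split -> length maps
        def split_lengths(t):
            all_taxa = frozenset(t.taxa)
            below = {}
            out = {}
            for n in t.postorder():
                below[id(n)] = (
                    frozenset([n.label]) if n.is_leaf
                    else frozenset().union(*(below[id(c)] for c in n.children))
                )
                if n.parent is not None:
                    side = below[id(n)]
                    key = min(side, all_taxa - side, key=lambda s: tuple(sorted(s)))
                    out[key] = out.get(key, 0.0) + n.length
            return out

        t_map, f_map = split_lengths(tree), split_lengths(found)
        rel_errors = [
            abs(f_map[k] - t_map[k]) / t_map[k] for k in t_map if t_map[k] > 1e-6
        ]
        assert np.mean(rel_errors) < 0.15
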