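import numpy as np
import pytest
from scipy import stats

from raresyn import synth
from raresyn.geneorder import adjacencies, canonical_key
from raresyn.probcalc import rate_ratio
from raresyn.synth import PlantedFeature, SimConfig


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(n_group=0)

    def test_species_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            SimConfig(n_outside=60_000)

    def test_rate_multiplier_floor(self):
        with pytest.raises(ValueError):
            SimConfig(r_true=0.5)

    def test_planted_column_must_fit(self):
        with pytest.raises(ValueError, match="beyond alignment length"):
            SimConfig(
                genes=(("atp6", 10),),
                planted=(PlantedFeature("atp6", 50, "S", "W", 0.9, 0.01),),
            )

    def test_planted_residues_must_differ(self):
        with pytest.raises(ValueError):
            PlantedFeature("g", 0, "W", "W", 0.9, 0.01)


class TestSimulateTree:
    def test_deterministic_newick(self):
        cfg = SimConfig(seed=5, n_group=10, n_outside=20, n_query=2, genes=(("g", 10),), planted=())
        t1 = synth.simulate_tree(cfg).as_string(schema="newick")
        t2 = synth.simulate_tree(cfg).as_string(schema="newick")
        assert t1 == t2

    def test_group_is_monophyletic_with_query_nested(self):
        cfg = SimConfig(seed=3, n_group=12, n_outside=30, n_query=3, genes=(("g", 10),), planted=())
        tree = synth.simulate_tree(cfg)
        taxa = [tree.taxon_namespace.get_taxon(l) for l in cfg.group_labels()]
        mrca = tree.mrca(taxa=taxa)
        leaves = {l.taxon.label for l in mrca.leaf_iter()}
        assert leaves == set(cfg.group_labels()) | set(cfg.query_labels())

    def test_rate_multiplied_query_depth(self):
        cfg = SimConfig(seed=2, n_group=4, n_outside=2, n_query=1, r_true=10.0,
                        genes=(("g", 10),), planted=())
        tree = synth.simulate_tree(cfg)
        r = rate_ratio(tree, cfg.group_labels() + cfg.query_labels(), cfg.query_labels())
        assert r == pytest.approx(10.0, rel=0.25)

    def test_unit_rate_query_depths_look_like_group_depths(self):
        """With r_true = 1 the query clade is an ordinary subclade: a
        two-sample test on root-to-tip path lengths is almost never
        rejected at alpha = 0.01 across 200 replicates."""
        rejections = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_group=30, n_outside=2, n_query=3,
                            r_true=1.0, genes=(("g", 5),), planted=())
            tree = synth.simulate_tree(cfg)
            depths = {}
            stack = [(tree.seed_node, 0.0)]
            while stack:
                node, d = stack.pop()
                if node.is_leaf():
                    depths[node.taxon.label] = d
                for ch in node.child_nodes():
                    stack.append((ch, d + (ch.edge.length or 0.0)))
            q = [depths[l] for l in cfg.query_labels()]
            g = [depths[l] for l in cfg.group_labels()]
            if stats.ks_2samp(q, g).pvalue < 0.01:
                rejections += 1
        assert rejections <= 8  # ~1% nominal rate, generous binomial slack


class TestSimulateAlignment:
    def test_degenerate_retention_and_homoplasy(self):
        pf = PlantedFeature("g", 3, "S", "W", s_true=1.0, h_true=0.0, query_has=True)
        cfg = SimConfig(seed=4, n_group=20, n_outside=50, n_query=2,
                        genes=(("g", 10),), planted=(pf,))
        tree = synth.simulate_tree(cfg)
        aln = synth.simulate_alignment(tree, cfg.planted, cfg, "g")
        grp = [aln.row(s)[3] for s in cfg.group_labels()]
        out = [aln.row(s)[3] for s in cfg.outside_labels()]
        qry = [aln.row(s)[3] for s in cfg.query_labels()]
        assert set(grp) == {"W"} and set(qry) == {"W"}
        assert "W" not in out

    def test_byte_identical_given_seed(self):
        cfg = SimConfig(seed=9, n_group=8, n_outside=10, n_query=2, genes=(("g", 30),), planted=())
        tree = synth.simulate_tree(cfg)
        a1 = synth.simulate_alignment(tree, (), cfg, "g")
        a2 = synth.simulate_alignment(tree, (), cfg, "g")
        assert a1.rows == a2.rows

    def test_planted_frequencies_within_binomial_error(self):
        pf = PlantedFeature("g", 0, "S", "W", s_true=0.83, h_true=0.02)
        cfg = SimConfig(seed=21, n_group=157, n_outside=2000, n_query=2,
                        genes=(("g", 5),), planted=(pf,))
        tree = synth.simulate_tree(cfg)
        aln = synth.simulate_alignment(tree, cfg.planted, cfg, "g")
        s_hat = np.mean([aln.row(s)[0] == "W" for s in cfg.group_labels()])
        h_hat = np.mean([aln.row(s)[0] == "W" for s in cfg.outside_labels()])
        assert abs(s_hat - 0.83) <= 3 * (0.83 * 0.17 / 157) ** 0.5
        assert abs(h_hat - 0.02) <= 3 * (0.02 * 0.98 / 2000) ** 0.5

    def test_planted_column_out_of_range_rejected(self):
        cfg = SimConfig(seed=1, n_group=4, n_outside=4, n_query=1, genes=(("g", 10),), planted=())
        tree = synth.simulate_tree(cfg)
        bad = (PlantedFeature("g", 50, "S", "W", 0.9, 0.0),)
        with pytest.raises(ValueError, match="planted column"):
            synth.simulate_alignment(tree, bad, cfg, "g")


class TestSimulateGeneOrders:
    def test_zero_event_rate_keeps_ancestral_order_outside(self):
        cfg = SimConfig(seed=6, n_group=5, n_outside=10, n_query=2,
                        genes=(("g", 5),), planted=(), gene_order_rate=0.0)
        tree = synth.simulate_tree(cfg)
        orders = synth.simulate_gene_orders(tree, cfg)
        outside_strings = {orders[s].to_string() for s in cfg.outside_labels()}
        assert len(outside_strings) == 1  # no events: all identical
        # group orders differ only by the planted-adjacency move
        grp_strings = {orders[s].to_string() for s in cfg.group_labels()}
        assert len(grp_strings) == 1

    def test_planted_adjacency_fixed_in_group_and_derived(self):
        cfg = SimConfig(seed=8, n_group=20, n_outside=40, n_query=3,
                        genes=(("g", 5),), planted=(), gene_order_rate=1.0)
        tree = synth.simulate_tree(cfg)
        orders = synth.simulate_gene_orders(tree, cfg)
        key = canonical_key(("cytb", 1), ("trnW", 1))
        for sp in cfg.group_labels() + cfg.query_labels():
            assert key in adjacencies(orders[sp])
        # ancestral root order deliberately lacks the adjacency
        tokens, signs = synth._root_order(cfg)
        from raresyn.io_core import GeneOrder

        root = GeneOrder(species="root", tokens=tokens, signs=signs)
        assert key not in adjacencies(root)

    def test_high_event_rate_approaches_random_adjacency_frequency(self):
        """Heavily rearranged outside genomes carry a designated adjacency
        at about the random-order rate."""
        cfg = SimConfig(seed=12, n_group=2, n_outside=2000, n_query=1,
                        genes=(("g", 5),), planted=(), gene_order_rate=300.0)
        tree = synth.simulate_tree(cfg)
        orders = synth.simulate_gene_orders(tree, cfg)
        key = canonical_key(("cox1", 1), ("nad3", 1))  # arbitrary unplanted pair
        freq = np.mean([key in adjacencies(orders[s]) for s in cfg.outside_labels()])
        n = 37
        p_exact = 0.5 / (n - 1)
        se = (p_exact * (1 - p_exact) / len(cfg.outside_labels())) ** 0.5
        assert abs(freq - p_exact) < 3 * se
        # the quoted 1/(2n) bound is indistinguishable at this sample size
        assert abs(freq - 0.5 / n) < 3 * se


class TestBuildReferenceDB:
    def test_assembly_round_trip(self, small_dataset):
        db = small_dataset.db
        assert len(db) == 463
        assert set(db.genes) == {"atp6", "cytb"}
        assert db.in_taxon("GroupA") == set(small_dataset.config.group_labels())

    def test_species_mismatch_rejected(self, small_dataset):
        aln = small_dataset.alignments["atp6"]
        with pytest.raises(ValueError, match="outside the taxonomy"):
            synth.build_reference_db({"atp6": aln}, {}, {"onlyone": ("Metazoa",)})

    def test_dataset_fully_deterministic(self, small_sim_config, small_dataset):
        again = synth.simulate_dataset(small_sim_config)
        assert again.alignments["atp6"].rows == small_dataset.alignments["atp6"].rows
        assert {s: o.to_string() for s, o in again.orders.items()} == {
            s: o.to_string() for s, o in small_dataset.orders.items()
        }
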