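import json

import numpy as np
import pytest

from oracles import expected_p_distance, yule_expected_depth

from dsrpipe.errors import ConfigError
from dsrpipe.synthetic_data import (
    CLASS_LAYOUTS,
    SimulationConfig,
    _rng,
    assemble_genomes,
    evolve_family,
    export_dataset,
    load_ground_truth,
    simulate_dataset,
    simulate_species_tree,
)
from dsrpipe.trees import PhyloTree


class TestSpeciesTree:
    def test_small_tree_is_ultrametric(self):
        t = simulate_species_tree(SimulationConfig(seed=1, n_genomes=3))
        assert len(t) == 3 and t.rooted
        depths = list(t.leaf_depths().values())
        assert max(depths) - min(depths) < 1e-9

    def test_determinism(self):
        cfg = SimulationConfig(seed=7, n_genomes=12)
        assert (
            simulate_species_tree(cfg).to_newick()
            == simulate_species_tree(cfg).to_newick()
        )

    def test_pure_birth_depth_matches_yule_expectation(self):
        # E[depth] = (1/lambda) * sum_{k=2}^{n} 1/k for a pure-birth process
        # observed at a uniform time inside the n-lineage interval.
        depths = []
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed, n_genomes=16, birth_rate=1.0, death_rate=0.0,
                tree_height=None, min_internal_branch=0.0,
            )
            t = simulate_species_tree(cfg)
            depths.append(max(t.leaf_depths().values()))
        expected = yule_expected_depth(16, 1.0)
        se = np.std(depths, ddof=1) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 3 * se

    def test_min_internal_branch_enforced_and_ultrametric(self):
        cfg = SimulationConfig(seed=3, n_genomes=20)
        t = simulate_species_tree(cfg)
        internal = [n.length for n in t.root.non_tips(include_self=False)]
        assert min(internal) >= cfg.min_internal_branch - 1e-12
        assert t.is_ultrametric(1e-9)

    def test_extinction_heavy_settings_raise_eventually(self):
        with pytest.raises(ConfigError):
            simulate_species_tree(
                SimulationConfig(
                    seed=0, n_genomes=50, birth_rate=0.001, death_rate=10.0
                )
            )


class TestEvolution:
    def test_zero_branch_lengths_copy_root(self):
        tree = PhyloTree.from_newick("((a:0,b:0):0,c:0);")
        cfg = SimulationConfig(seed=1, n_genomes=3, seq_length=50)
        leaves, root, _ = evolve_family(tree, cfg, _rng(1, 9))
        for codes in leaves.values():
            assert np.array_equal(codes, root)

    def test_p_distance_matches_uniform_model_closed_form(self):
        # Two leaves at divergence 2t: p ~= (19/20)(1 - exp(-2rt*20/19)).
        t, rate, L = 0.5, 0.6, 500
        tree = PhyloTree.from_newick(f"(a:{t},b:{t});")
        cfg = SimulationConfig(seed=5, n_genomes=3, seq_length=L, subst_rate=rate)
        ps = []
        for rep in range(30):
            leaves, _, _ = evolve_family(tree, cfg, _rng(5, rep))
            ps.append(np.mean(leaves["a"] != leaves["b"]))
        expected = expected_p_distance(rate, 2 * t)
        se = np.sqrt(expected * (1 - expected) / (L * len(ps)))
        assert abs(np.mean(ps) - expected) < 3 * se

    def test_gamma_rates_increase_invariant_site_fraction(self):
        # At equal mean rate, rate heterogeneity concentrates change in hot
        # sites, leaving more sites untouched.
        tree = PhyloTree.from_newick("(a:1.0,b:1.0);")
        base = dict(seed=2, n_genomes=3, seq_length=4000, subst_rate=1.0)
        uniform = SimulationConfig(**base)
        gamma = SimulationConfig(**base, gamma_shape=0.5)
        lu, _, _ = evolve_family(tree, uniform, _rng(2, 0))
        lg, _, _ = evolve_family(tree, gamma, _rng(2, 1))
        same_u = np.mean(lu["a"] == lu["b"])
        same_g = np.mean(lg["a"] == lg["b"])
        assert same_g > same_u

    def test_short_sequences_rejected(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        cfg = SimulationConfig(seed=1, n_genomes=3)
        with pytest.raises(ConfigError):
            evolve_family(tree, cfg, _rng(1, 0), seq_length=5)


class TestAssembly:
    def test_complete_genomes_carry_full_class_repertoire(self, small_dataset):
        _, genomes, truth = small_dataset
        for genome in genomes:
            cls = truth.classes[genome.genome_id]
            layout = CLASS_LAYOUTS[cls]
            expected = {f for block in layout["blocks"] for f in block}
            present = {
                label for _, label in truth.layouts[genome.genome_id]
            }
            assert expected <= present

    def test_planted_cluster_block_is_contiguous(self, small_dataset):
        # The bacterial reductive Dsr genes form one consecutive cluster in
        # the planted order, with DsrT adjacent to DsrM.
        _, genomes, truth = small_dataset
        block = CLASS_LAYOUTS["bacterial_reductive"]["blocks"][0]
        checked = 0
        for genome in genomes:
            if truth.classes[genome.genome_id] != "bacterial_reductive":
                continue
            labels = [label for _, label in truth.layouts[genome.genome_id]]
            i = labels.index("DsrA")
            assert labels[i : i + len(block)] == block
            checked += 1
        assert checked > 0

    def test_incompleteness_fraction_matches_binomial(self):
        prob = 0.1
        cfg = SimulationConfig(
            seed=9, n_genomes=20, seq_length=60, cargo_length=40,
            incompleteness_prob=prob,
        )
        genomes, truth = simulate_dataset(cfg)
        planted = sum(len(lay) for lay in truth.layouts.values())
        deleted = len(truth.deleted)
        se = np.sqrt(prob * (1 - prob) * planted)
        assert abs(deleted - prob * planted) < 3 * se
        incomplete = [g for g in genomes if not g.complete]
        assert incomplete  # at 10% per gene some genome must lose something

    def test_lgt_replacement_grafts_recipient_next_to_donor(self):
        cfg = SimulationConfig(
            seed=13, n_genomes=10, seq_length=60,
            lgt_events=(("DsrA", "g006", "g002"),),
        )
        _, truth = simulate_dataset(cfg)
        tree = truth.gene_trees["DsrA"]
        ids, data = tree.tip_distances()
        i, j = ids.index("g002"), ids.index("g006")
        row = data[i].copy()
        row[i] = np.inf
        assert ids[int(np.argmin(row))] == "g006"
        assert data[i, j] <= 2 * cfg.lgt_branch_length + 1e-9

    def test_lgt_validation(self):
        with pytest.raises(ConfigError, match="carry"):
            simulate_dataset(
                SimulationConfig(
                    seed=1, n_genomes=20, seq_length=60,
                    # recipient class apr_only does not carry DsrA
                    lgt_events=(("DsrA", "g001", "g020"),),
                )
            )

    def test_determinism_bytewise(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_genomes=6, seq_length=60)
        for run in ("x", "y"):
            genomes, truth = simulate_dataset(cfg)
            export_dataset(genomes, truth, tmp_path / run)
        for name in ("proteins.faa", "genes.tsv", "ground_truth.json"):
            assert (tmp_path / "x" / name).read_bytes() == (
                tmp_path / "y" / name
            ).read_bytes()


class TestExport:
    def test_roundtrip_and_ledgers(self, tmp_path, small_dataset):
        from dsrpipe.pipeline import load_dataset

        _, genomes, truth = small_dataset
        paths = export_dataset(genomes, truth, tmp_path)
        reloaded, references, decoys = load_dataset(tmp_path)
        assert [g.genome_id for g in reloaded] == [g.genome_id for g in genomes]
        for old, new in zip(genomes, reloaded):
            assert [x.gene_id for x in old.genes] == [x.gene_id for x in new.genes]
            assert old.genus == new.genus and old.complete == new.complete
        assert sorted(decoys) == sorted(truth.decoys)
        blob = json.loads(paths["ground_truth"].read_text())
        assert blob["lgt_events"] == truth.lgt_events
        n_fasta = sum(
            1 for line in paths["proteins"].read_text().splitlines()
            if line.startswith(">")
        )
        assert n_fasta == sum(len(g.genes) for g in genomes)
        back = load_ground_truth(tmp_path)
        assert back.species_tree.rf_distance(truth.species_tree) == 0
        assert back.classes == truth.classes
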