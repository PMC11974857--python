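import math

import numpy as np
import pandas as pd
import pytest

from rhodoflag.errors import DataError
from rhodoflag import synthetic_data as syn
from rhodoflag.io_formats import write_newick


def _leaf_depths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def _identity(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSpeciesTree:
    def test_two_taxa_cherry_ultrametric(self):
        t = syn.simulate_species_tree(2, 0)
        depths = _leaf_depths(t)
        assert len(depths) == 2
        assert all(d == pytest.approx(1.0) for d in depths.values())

    def test_five_taxa_topology_counts(self):
        t = syn.simulate_species_tree(5, 1)
        leaves = [n for n in t if n.is_leaf()]
        # unrooted view: the degree-2 root merges away, leaving n-2 nodes
        internal = [
            n for n in t.preorder_internal_node_iter() if n.parent_node is not None
        ]
        assert len(leaves) == 5
        assert len(internal) == 3

    def test_ultrametric_over_many_seeds(self):
        for seed in range(200):
            depths = _leaf_depths(syn.simulate_species_tree(8, seed))
            assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(DataError):
            syn.simulate_species_tree(1, 0)

    def test_deterministic(self):
        a = write_newick(syn.simulate_species_tree(10, 42))
        b = write_newick(syn.simulate_species_tree(10, 42))
        assert a == b


class TestEvolveProteomes:
    def test_zero_rate_all_identical(self):
        t = syn.simulate_species_tree(4, 0)
        genomes = syn.evolve_proteomes(t, 3, 50, 1e-12, 0)
        ref = [g.sequence for g in genomes[0].genes()]
        for genome in genomes[1:]:
            assert [g.sequence for g in genome.genes()] == ref

    def test_closed_form_identity_at_distance_one(self):
        from rhodoflag.io_formats import read_newick

        tree = read_newick("(A:0.5,B:0.5);")
        rate, L = 0.1, 10000
        genomes = syn.evolve_proteomes(tree, 1, L, rate, 3)
        obs = _identity(genomes[0].genes()[0].sequence, genomes[1].genes()[0].sequence)
        expected = 1 / 20 + (19 / 20) * math.exp(-(20 / 19) * rate * 1.0)
        sd = math.sqrt(expected * (1 - expected) / L)
        assert abs(obs - expected) < 3 * sd

    def test_identity_nonincreasing_in_distance(self):
        # averaged over families and seeds, nearer taxa are more similar
        diffs = []
        for seed in range(1, 21):
            t = syn.simulate_species_tree(6, seed)
            genomes = syn.evolve_proteomes(t, 10, 60, 0.3, seed)
            depths = {}
            pdm = t.phylogenetic_distance_matrix()
            taxa = {x.label: x for x in t.taxon_namespace}
            by_id = {g.genome_id: g for g in genomes}
            ids = sorted(by_id)
            pairs = []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
                    idy = np.mean(
                        [
                            _identity(a.sequence, b.sequence)
                            for a, b in zip(by_id[ids[i]].genes(), by_id[ids[j]].genes())
                        ]
                    )
                    pairs.append((d, idy))
            pairs.sort()
            diffs.append(pairs[0][1] - pairs[-1][1])
        assert np.mean(diffs) > 0

    def test_short_sequences_rejected(self):
        t = syn.simulate_species_tree(3, 0)
        with pytest.raises(DataError):
            syn.evolve_proteomes(t, 2, 5, 0.1, 0)


class TestPlantFgcs:
    def test_no_loss_no_hgt_every_genome_fla1_only(self):
        t = syn.simulate_species_tree(6, 2)
        genomes = syn.evolve_proteomes(t, 10, 50, 0.1, 2)
        cfg = syn.SimConfig(
            n_taxa=6, n_families=10, loss_prob_fla1=0.0, n_hgt_fla2=0, n_hgt_fla3=0
        )
        # origin clades still plant one fla2 and one fla3 block; check fla1
        g2, truth = syn.plant_fgcs(genomes, t, cfg, 2)
        fla1 = truth.fgc_inventory.query("fla_type == 'fla1'")
        assert set(fla1["genome_id"]) == {g.genome_id for g in genomes}

    def test_total_loss_no_extant_fla1(self):
        t = syn.simulate_species_tree(6, 2)
        genomes = syn.evolve_proteomes(t, 10, 50, 0.1, 2)
        cfg = syn.SimConfig(
            n_taxa=6, n_families=10, loss_prob_fla1=1.0, n_hgt_fla2=0, n_hgt_fla3=0
        )
        g2, truth = syn.plant_fgcs(genomes, t, cfg, 2)
        assert truth.fgc_inventory.query("fla_type == 'fla1'").empty

    def test_truth_matches_label_scan(self, small_bundle):
        truth = small_bundle["truth"]
        scanned = set()
        for genome in small_bundle["genomes"]:
            for rep in genome.replicons:
                types = {
                    g.family_truth.split(":")[0]
                    for g in rep.genes
                    if g.family_truth and g.family_truth.startswith("fla")
                }
                for t in types:
                    scanned.add((genome.genome_id, t))
        expected = {
            (r.genome_id, r.fla_type) for r in truth.fgc_inventory.itertuples()
        }
        assert scanned == expected

    def test_fla2_never_with_fla3(self, small_bundle):
        inv = small_bundle["truth"].fgc_inventory
        per_genome = inv.groupby("genome_id")["fla_type"].agg(set)
        for types in per_genome:
            assert not ({"fla2", "fla3"} <= types)

    def test_blocks_are_contiguous(self, small_bundle):
        for genome in small_bundle["genomes"]:
            for rep in genome.replicons:
                for t in ("fla1", "fla2", "fla3"):
                    ords = [
                        g.ordinal
                        for g in rep.genes
                        if g.family_truth and g.family_truth.startswith(t + ":")
                    ]
                    if ords:
                        assert max(ords) - min(ords) + 1 == len(ords)

    def test_fla2_presence_needs_planted_transfers_under_dollo(self):
        # minimal gains without losses = number of maximal carrier clades
        for seed in (1, 3, 5):
            t = syn.simulate_species_tree(12, seed)
            genomes = syn.evolve_proteomes(t, 5, 50, 0.1, seed)
            cfg = syn.SimConfig(n_taxa=12, n_families=5, n_hgt_fla2=2, n_hgt_fla3=0)
            g2, truth = syn.plant_fgcs(genomes, t, cfg, seed)
            carriers = set(truth.fgc_inventory.query("fla_type=='fla2'")["genome_id"])

            def maximal_clades(node):
                leaves = {l.taxon.label for l in node.leaf_iter()}
                if leaves <= carriers:
                    return 1
                if not (leaves & carriers):
                    return 0
                return sum(maximal_clades(c) for c in node.child_nodes())

            assert maximal_clades(t.seed_node) >= cfg.n_hgt_fla2

    def test_determinism(self):
        t1 = syn.simulate_species_tree(8, 4)
        t2 = syn.simulate_species_tree(8, 4)
        cfg = syn.SimConfig(n_taxa=8, n_families=8)
        a, _ = syn.plant_fgcs(syn.evolve_proteomes(t1, 8, 50, 0.15, 4), t1, cfg, 4)
        b, _ = syn.plant_fgcs(syn.evolve_proteomes(t2, 8, 50, 0.15, 4), t2, cfg, 4)
        sa = [(g.gene_id, g.sequence) for gen in a for g in gen.genes()]
        sb = [(g.gene_id, g.sequence) for gen in b for g in gen.genes()]
        assert sa == sb


class TestDegradeAssemblies:
    def test_noop_settings_leave_genomes_unchanged(self, small_bundle):
        out = syn.degrade_assemblies(small_bundle["genomes"], 0.0, math.inf, 0)
        for a, b in zip(
            sorted(small_bundle["genomes"], key=lambda g: g.genome_id), out
        ):
            assert [(r.contig_id, len(r.genes)) for r in a.replicons] == [
                (r.contig_id, len(r.genes)) for r in b.replicons
            ]

    def test_dropout_count_binomial(self):
        t = syn.simulate_species_tree(2, 0)
        genomes = syn.evolve_proteomes(t, 500, 20, 0.1, 0)
        out = syn.degrade_assemblies(genomes, 0.1, math.inf, 1)
        kept = sum(len(g.genes()) for g in out)
        n, p = 1000, 0.9
        sd = math.sqrt(n * p * (1 - p))
        assert abs(kept - n * p) < 3 * sd

    def test_fragmentation_preserves_gene_order(self):
        t = syn.simulate_species_tree(3, 1)
        genomes = syn.evolve_proteomes(t, 100, 20, 0.1, 1)
        out = syn.degrade_assemblies(genomes, 0.05, 10.0, 2)
        for orig, new in zip(genomes, out):
            orig_order = [g.gene_id for g in orig.genes()]
            new_order = [g.gene_id for rep in new.replicons for g in rep.genes]
            # concatenated new contigs reproduce original order minus drops
            assert new_order == [g for g in orig_order if g in set(new_order)]

    def test_full_dropout_rejected(self, small_bundle):
        with pytest.raises(DataError):
            syn.degrade_assemblies(small_bundle["genomes"], 1.0, math.inf, 0)


class TestSimulateCounts:
    def test_nb_moment_relationship(self):
        cfg = syn.RegulonConfig(
            n_genes=2000, n_orthologs=100, n_shared=0, n_specific=0,
            contrasts=("ctrA",), n_replicates=10, dispersion=0.1,
            libsize_range=(1.0, 1.0),
        )
        b = syn.simulate_counts(cfg, 0)
        wt = b.counts_a.loc[:, b.conditions_a == "wt"].to_numpy(float)
        m = wt.mean(axis=1)
        v = wt.var(axis=1, ddof=1)
        keep = m > 50
        phi_hat = np.median((v[keep] - m[keep]) / m[keep] ** 2)
        assert 0.05 < phi_hat < 0.15

    def test_planted_strong_repression_ratio(self):
        cfg = syn.RegulonConfig(
            n_genes=20, n_orthologs=5, n_shared=1, n_specific=0,
            contrasts=("ctrA",), n_replicates=6, dispersion=0.01,
            baseline_log_mean=math.log(5000), baseline_log_sd=0.0,
            libsize_range=(1.0, 1.0), effect_low=6.0, effect_high=6.0,
            down_fraction=1.0,
        )
        for seed in range(1, 11):
            b = syn.simulate_counts(cfg, seed)
            wt = b.counts_a.loc["A_g0000", b.conditions_a == "wt"].mean()
            mut = b.counts_a.loc["A_g0000", b.conditions_a == "ctrA"].mean()
            assert abs(mut / wt - 2**-6) < 0.2 * 2**-6

    def test_zero_effects_empty_truth(self):
        cfg = syn.RegulonConfig(n_genes=50, n_orthologs=10, n_shared=0, n_specific=0)
        b = syn.simulate_counts(cfg, 0)
        assert b.truth.de_truth.empty

    def test_shared_core_same_direction_across_species(self):
        cfg = syn.RegulonConfig(n_genes=200, n_orthologs=150, n_shared=20, n_specific=5)
        b = syn.simulate_counts(cfg, 5)
        truth = b.truth.de_truth.query("shared")
        for (gene_idx, contrast), grp in truth.groupby(
            [truth.gene_id.str[2:], "contrast"]
        ):
            assert grp["direction"].nunique() == 1

    def test_too_few_replicates_rejected(self):
        with pytest.raises(DataError):
            syn.RegulonConfig(n_replicates=1)

    def test_determinism(self):
        cfg = syn.RegulonConfig(n_genes=100, n_orthologs=50, n_shared=5, n_specific=5)
        a = syn.simulate_counts(cfg, 9)
        b = syn.simulate_counts(cfg, 9)
        pd.testing.assert_frame_equal(a.counts_a, b.counts_a)
        pd.testing.assert_frame_equal(a.counts_b, b.counts_b)
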