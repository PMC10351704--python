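import filecmp
import math

import numpy as np
import pandas as pd
import pytest

import wsdgat as w
from wsdgat.simulate import (
    DEFAULT_SEED_PROTEIN,
    CommunityDesign,
    CopyNumberModel,
    build_taxonomy,
    evolve_family_sequences,
    leaf_sequences,
    simulate_genomes,
    simulate_metagenome,
    write_sample,
    ztp_mean,
)


def seq_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestBuildTaxonomy:
    def test_minimal_tree_is_a_path(self):
        t = build_taxonomy(seed=1, n_phyla=1, children_per_node=1)
        assert len(t) == 8
        assert len(t.leaves("species")) == 1

    def test_fanout_structure(self):
        t = build_taxonomy(seed=1, n_phyla=3, children_per_node=2)
        domain = t.children("root")[0]
        assert len(t.children(domain)) == 3
        assert len(t.leaves("species")) == 3 * 2**5

    def test_deterministic(self):
        a = build_taxonomy(seed=5, n_phyla=2, children_per_node=2)
        b = build_taxonomy(seed=5, n_phyla=2, children_per_node=2)
        assert [(n.taxon_id, n.parent_id, n.rank) for n in a] == [
            (n.taxon_id, n.parent_id, n.rank) for n in b
        ]

    def test_rejects_nonpositive_sizes(self):
        with pytest.raises(ValueError):
            build_taxonomy(seed=1, n_phyla=0, children_per_node=1)


class TestSimulateGenomes:
    def test_zero_prevalence_means_no_copies(self):
        t = build_taxonomy(1, 2, 2)
        genomes = simulate_genomes(t, CopyNumberModel(0.0, 2.0), seed=3)
        assert all(g.family_copy_count == 0 for g in genomes)
        assert all(len(g.panel_genes) == 12 for g in genomes)

    def test_zero_truncation_forces_carriers(self):
        t = build_taxonomy(1, 2, 2)
        genomes = simulate_genomes(t, CopyNumberModel(1.0, 0.05), seed=3)
        assert all(g.family_copy_count >= 1 for g in genomes)

    def test_moments_match_copy_model(self):
        """Prevalence and carrier mean agree with the zero-inflated
        zero-truncated Poisson within 3-sigma Monte-Carlo bands."""
        p, lam = 0.6, 3.0
        t = build_taxonomy(1, 8, 2)  # 256 species
        genomes = simulate_genomes(t, CopyNumberModel(p, lam), seed=7,
                                   genomes_per_species=8)  # 2048 genomes
        n = len(genomes)
        counts = np.array([g.family_copy_count for g in genomes])
        prev = (counts > 0).mean()
        assert abs(prev - p) <= 3 * math.sqrt(p * (1 - p) / n)
        carriers = counts[counts > 0]
        mu = ztp_mean(lam)
        # ZTP variance = mu(1 + lam - mu)
        var = mu * (1 + lam - mu)
        assert abs(carriers.mean() - mu) <= 3 * math.sqrt(var / len(carriers))

    def test_tree_without_species_rejected(self):
        from wsdgat.taxtree import TaxonNode, TaxonomyTree

        bare = TaxonomyTree([TaxonNode("root", None, "root", "root")])
        with pytest.raises(ValueError, match="no species"):
            simulate_genomes(bare, CopyNumberModel(), seed=0)


class TestEvolveSequences:
    def test_rate_zero_keeps_seed(self):
        t = build_taxonomy(1, 2, 2)
        leaves = leaf_sequences(DEFAULT_SEED_PROTEIN, t, 0.0, seed=1)
        assert all(s == DEFAULT_SEED_PROTEIN for s in leaves.values())

    def test_identity_decreases_with_path_length(self):
        t = build_taxonomy(1, 3, 2)
        leaves = leaf_sequences(DEFAULT_SEED_PROTEIN, t, 0.05, seed=2)
        sp = sorted(leaves)
        same_genus = [s for s in sp if s.rsplit(".", 1)[0] == sp[0].rsplit(".", 1)[0]]
        diff_phylum = [
            s for s in sp
            if t.ancestor_at(s, "phylum") != t.ancestor_at(sp[0], "phylum")
        ]
        within = seq_identity(leaves[same_genus[0]], leaves[same_genus[1]])
        between = seq_identity(leaves[sp[0]], leaves[diff_phylum[0]])
        assert within > between

    def test_planted_identity_levels(self):
        """Per-branch rate 0.05: within-genus identity ~0.90 and
        between-phylum ~0.55, bracketing the OPU cutoff from both sides."""
        t = build_taxonomy(1, 4, 2)
        leaves = leaf_sequences(DEFAULT_SEED_PROTEIN, t, 0.05, seed=4)
        sp = sorted(leaves)
        within, between = [], []
        for i, a in enumerate(sp):
            for b in sp[i + 1:]:
                ident = seq_identity(leaves[a], leaves[b])
                if a.rsplit(".", 1)[0] == b.rsplit(".", 1)[0]:
                    within.append(ident)
                elif t.ancestor_at(a, "phylum") != t.ancestor_at(b, "phylum"):
                    between.append(ident)
        assert 0.84 <= np.mean(within) <= 0.96
        assert 0.40 <= np.mean(between) <= 0.70

    def test_copy_counts_match_sequences(self):
        t = build_taxonomy(1, 2, 2)
        genomes = simulate_genomes(t, CopyNumberModel(0.8, 2.0), seed=5)
        evolve_family_sequences(DEFAULT_SEED_PROTEIN, t, genomes, 0.05, seed=5)
        assert all(len(g.family_protein_seqs) == g.family_copy_count
                   for g in genomes)

    def test_empty_seed_rejected(self):
        t = build_taxonomy(1, 1, 1)
        with pytest.raises(ValueError):
            leaf_sequences("", t, 0.05, seed=1)


def one_genome_design(genome_id, **kw):
    return CommunityDesign("S1", "A", {genome_id: 1.0}, **kw)


class TestSimulateMetagenome:
    def test_full_assembly_leaves_unassembled_empty(self):
        t = build_taxonomy(1, 2, 2)
        genomes = simulate_genomes(t, CopyNumberModel(0.8, 2.0), seed=1)
        design = CommunityDesign(
            "S1", "A", {g.genome_id: 1 / len(genomes) for g in genomes},
            assembly_fraction=1.0, seed=4,
        )
        s = simulate_metagenome(genomes, design, emit_sequences=False)
        assert (s.proteins["fraction"] == "assembled").all()

    def test_depth_weighted_truth_single_genome(self):
        """One genome at exact coverage 5 with 2 assembled family copies:
        depth TSV reports 5 and the weighted family truth is 10."""
        t = build_taxonomy(1, 1, 1)
        genomes = simulate_genomes(t, CopyNumberModel(1.0, 1e-9), seed=1)
        g = genomes[0]
        g.family_copy_count = 2
        design = one_genome_design(
            g.genome_id, assembly_fraction=1.0, depth_scale=5.0,
            depth_sigma=0.0, context_rate=0.0, seed=9,
        )
        s = simulate_metagenome(genomes, design, emit_sequences=False)
        assert len(s.scaffolds) == 1
        assert s.scaffolds[0].read_depth == pytest.approx(5.0)
        assert s.truth_estimated_copies("family") == pytest.approx(10.0)
        assert s.truth_panel_copies()["rplB"] == pytest.approx(5.0)

    def test_bad_abundances_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CommunityDesign("S1", "A", {"g": 0.5})

    def test_truth_conservation_is_exact(self, study):
        for s in study.samples:
            fam = s.proteins[s.proteins["gene_class"] == "family"]
            assert s.truth_estimated_copies("family") == fam["weight"].sum()
            unasm = fam[fam["fraction"] == "unassembled"]
            assert (unasm["weight"] == 1.0).all()

    def test_determinism_byte_identical_files(self, tmp_path):
        outs = []
        for run in ("a", "b"):
            study = w.simulate_study(seed=17, n_phyla=2,
                                     n_samples_per_group=1)
            d = tmp_path / run
            write_sample(study.samples[0], d)
            outs.append(d)
        for name in ("proteins_assembled.faa", "proteins_unassembled.faa",
                     "genes.gff3", "depths.tsv", "truth_proteins.tsv",
                     "manifest.json"):
            assert filecmp.cmp(outs[0] / name, outs[1] / name, shallow=False), name


class TestStudyFixture:
    def test_groups_and_samples(self, study):
        assert len(study.samples) == 6
        assert sorted(set(study.groups.values())) == ["ANT", "ARG"]

    def test_reference_covers_all_species(self, study):
        ref = w.make_reference(study.tree, study.leaf_seqs)
        assert set(ref["taxon_id"]) == set(study.tree.leaves("species"))

    def test_protein_table_consistency(self, study):
        prot = study.all_proteins()
        assembled = prot[prot["fraction"] == "assembled"]
        depth_of = {s.scaffold_id: s.read_depth for s in study.all_scaffolds()}
        assert all(
            depth_of[r.scaffold_id] == r.weight for r in assembled.itertuples()
        )
        # protein naming convention: <scaffold>_<ordinal>
        assert all(
            r.protein_id.rsplit("_", 1)[0] == r.scaffold_id
            for r in assembled.itertuples()
        )
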