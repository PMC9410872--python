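import math

import numpy as np
import pandas as pd
import pytest

from ampmap.formats import PipelineConfig
from ampmap.linkage import haldane_rf
from ampmap.marker_design import build_kmer_blacklist
from ampmap.polymorphism import (
    call_all,
    interline_polymorphic_sites,
    line_fixed_sites,
    observations_from_table,
)
from ampmap.synthetic_data import (
    Cross,
    SimConfig,
    simulate_amplicon_depths,
    simulate_lines_and_cross,
    simulate_reference,
)


def recovered_fraction(sim_cfg: SimConfig) -> float:
    """Fraction of true founder differences the polymorphism screen finds."""
    ref = simulate_reference(sim_cfg)
    cross = simulate_lines_and_cross(sim_cfg, ref.truth)
    cfg = PipelineConfig()
    calls = call_all(observations_from_table(cross.variants), cfg)
    per_line = {
        ln: [c for c in calls if c.line_id == ln]
        for ln in ("parent1", "parent2")
    }
    fixed1 = line_fixed_sites(
        per_line["parent1"], "parent1", sim_cfg.n_parent1_individuals
    )
    fixed2 = line_fixed_sites(
        per_line["parent2"], "parent2", sim_cfg.n_parent2_individuals
    )
    sites = interline_polymorphic_sites(
        fixed1, per_line["parent2"], fixed2, per_line["parent1"]
    )
    found = {s.site_key for s in sites}
    truth_keys = {
        (l.unigene_id, l.transcript_pos, l.alt_allele)
        for l in ref.truth.founder_diff_loci()
    }
    return len(found & truth_keys) / len(truth_keys)


class TestReference:
    def test_bookkeeping(self, sim_cfg, reference):
        assert len(reference.unigenes) == sim_cfg.n_genes
        assert len(reference.alignments) == sim_cfg.n_genes
        assert len(reference.truth.genes) == sim_cfg.n_genes
        for gene in reference.truth.genes:
            assert len(gene.exons) == sim_cfg.exons_per_gene
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert s2 - e1 - 1 == sim_cfg.intron_length

    def test_unigene_is_spliced_exon_sequence(self, reference):
        genome = {r.id: r.seq for r in reference.genome}
        unigenes = {r.id: r.seq for r in reference.unigenes}
        comp = str.maketrans("ACGT", "TGCA")
        for gene in reference.truth.genes:
            spliced = "".join(
                genome[gene.scaffold][s - 1 : e] for s, e in gene.exons
            )
            if gene.strand == "-":
                spliced = spliced.translate(comp)[::-1]
            assert unigenes[gene.unigene_id] == spliced

    def test_anchor_fractions_echo_config(self):
        cfg = SimConfig(seed=3, n_genes=200, n_scaffolds=8,
                        anchored_fraction=0.3, chromosome_only_fraction=0.3)
        ref = simulate_reference(cfg)
        cats = [g.anchor_category for g in ref.truth.genes]
        frac_anchored = cats.count("anchored") / len(cats)
        assert frac_anchored == pytest.approx(0.3, abs=0.1)

    def test_planted_repeats_hit_blacklist(self, sim_cfg, reference):
        bl = build_kmer_blacklist(reference.genome, 16, 10)
        # each 200-bp family copy contributes 185 16-mers x 30 copies >> 10
        assert len(bl.kmers) >= 100

    def test_seed_determinism_byte_identical(self, sim_cfg):
        a = simulate_reference(sim_cfg)
        b = simulate_reference(sim_cfg)
        assert [r.seq for r in a.genome] == [r.seq for r in b.genome]
        assert a.truth.loci == b.truth.loci
        ca = simulate_lines_and_cross(sim_cfg, a.truth)
        cb = simulate_lines_and_cross(sim_cfg, b.truth)
        pd.testing.assert_frame_equal(ca.variants, cb.variants)
        assert ca.f2_genotypes == cb.f2_genotypes


class TestLinesAndCross:
    def test_full_fixation_recovers_everything(self):
        cfg = SimConfig(seed=11, fixation_rate=1.0, base_error_rate=0.0,
                        rnaseq_depth=60)
        assert recovered_fraction(cfg) == 1.0

    def test_recovery_monotone_in_fixation_rate(self):
        fracs = [
            recovered_fraction(
                SimConfig(seed=11, fixation_rate=f, n_genes=60,
                          n_scaffolds=6, rnaseq_depth=60)
            )
            for f in (0.5, 0.8, 1.0)
        ]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_f2_recombination_matches_haldane(self):
        """Empirical recombinant fraction between 10-cM-adjacent loci over
        many meioses approaches the inverse Haldane prediction."""
        cfg = SimConfig(seed=5, n_genes=2, n_scaffolds=1, n_chromosomes=1,
                        snps_per_gene=1, shared_variant_fraction=0.0,
                        fixation_rate=1.0, n_f2=2000)
        ref = simulate_reference(cfg)
        # force the two loci 10 cM apart on one chromosome
        loci = ref.truth.loci
        assert len(loci) == 2
        object.__setattr__(loci[0], "cm", 20.0)
        object.__setattr__(loci[1], "cm", 30.0)
        cross = simulate_lines_and_cross(cfg, ref.truth)
        ids = [l.locus_id for l in loci]
        g = np.array(
            [[geno[ids[0]], geno[ids[1]]]
             for geno in cross.f2_genotypes.values()]
        )
        from ampmap.linkage import estimate_rf_em, table_from_rows

        codes = {0: "A", 1: "H", 2: "B"}
        t = table_from_rows(
            [codes[x] for x in g[:, 0]], [codes[x] for x in g[:, 1]]
        )
        rf_hat = estimate_rf_em(t).rf_hat
        assert rf_hat == pytest.approx(haldane_rf(10.0), abs=0.02)


class FakeMarker:
    def __init__(self, marker_id, scaffold, hotspot_position):
        self.marker_id = marker_id
        self.scaffold = scaffold
        self.hotspot_position = hotspot_position


def markers_for(truth, kinds=("founder_diff",)):
    return [
        FakeMarker(f"mk_{l.locus_id}", l.scaffold, l.genome_pos)
        for l in truth.loci
        if l.kind in kinds
    ]


class TestAmpliconDepths:
    def test_noiseless_limit_calls_every_het(self, cfg):
        sim = SimConfig(seed=9, fixation_rate=1.0, allele_overdispersion=1e-9,
                        dropout_probability=0.0, base_error_rate=0.0)
        ref = simulate_reference(sim)
        cross = simulate_lines_and_cross(sim, ref.truth)
        depths, _ = simulate_amplicon_depths(
            markers_for(ref.truth), cross, ref.truth, sim, depth_override=100
        )
        from ampmap.amplicon_genotyping import call_genotype_frame

        called = call_genotype_frame(depths, cfg)
        f1 = called[called["sample_id"] == "F1_A"]
        assert (f1["call"] == "het").all()

    def test_dropout_flag_produces_class_four(self):
        sim = SimConfig(seed=9, fixation_rate=1.0, dropout_probability=1.0)
        ref = simulate_reference(sim)
        cross = simulate_lines_and_cross(sim, ref.truth)
        _, classes = simulate_amplicon_depths(
            markers_for(ref.truth), cross, ref.truth, sim, depth_override=100
        )
        assert set(classes.values()) == {3}  # both lines dropped
        sim2 = SimConfig(seed=9, fixation_rate=1.0, dropout_probability=0.5)
        _, classes2 = simulate_amplicon_depths(
            markers_for(ref.truth), cross, ref.truth, sim2, depth_override=100
        )
        assert {3, 4} & set(classes2.values())

    def test_lognormal_depth_spread_exceeds_tenfold(self):
        sim = SimConfig(seed=21, n_genes=60, n_scaffolds=6,
                        depth_log_sd=1.0, dropout_probability=0.0)
        ref = simulate_reference(sim)
        cross = simulate_lines_and_cross(sim, ref.truth)
        depths, _ = simulate_amplicon_depths(
            markers_for(ref.truth, kinds=("founder_diff", "shared_alt")),
            cross, ref.truth, sim,
        )
        per_marker = (
            depths.assign(total=depths.ref_count + depths.alt_count)
            .groupby("marker_id")["total"].mean()
        )
        q10, q90 = per_marker.quantile([0.1, 0.9])
        assert q90 / max(q10, 1e-9) > 10
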