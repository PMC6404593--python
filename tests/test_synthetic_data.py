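"""Generator correctness: determinism, composition targets, planted signals."""

import numpy as np
import pandas as pd
import pytest

from divscan import io as dio
from divscan.models import decode_seq
from divscan.synthetic_data import (
    SimConfig,
    SimConfigError,
    SweepRegion,
    derive_sweep_regions,
    plant_motif_sites,
    simulate_coverage,
    simulate_gene_models,
    simulate_genome,
    simulate_pwms,
    simulate_study,
    simulate_variants,
    write_study,
)


def _neutral_cfg(**kw):
    base = dict(
        n_genes=0,
        n_motifs=0,
        sweep_gene_fraction=0.0,
        planted_gene_fraction=0.0,
        bad_site_fraction=0.0,
        haploid_error_fraction=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_length_conservation_and_record_count(self):
        cfg = _neutral_cfg(seed=1, genome_length=100_000, n_scaffolds=2)
        genome = simulate_genome(cfg)
        assert len(genome) == 2
        assert sum(len(s) for s in genome.values()) == 100_000

    def test_seed_determinism_bytes(self, tmp_path):
        cfg = SimConfig(seed=5, genome_length=60_000, n_scaffolds=2, n_genes=10,
                        gene_length=1_000, min_gene_gap=200, n_motifs=2)
        a = write_study(simulate_study(cfg), tmp_path / "a")
        b = write_study(simulate_study(cfg), tmp_path / "b")
        for key in ("fasta", "vcf", "gff3", "bed", "coverage", "meme"):
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_gc_concentration(self):
        cfg = _neutral_cfg(seed=2, genome_length=50_000, n_scaffolds=1, gc_mean=0.5)
        (seq,) = simulate_genome(cfg).values()
        gc = np.isin(seq, (1, 2)).mean()
        assert 0.45 <= gc <= 0.55

    def test_zero_length_scaffold_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(genome_length=10_000, n_scaffolds=20_000).validate()


class TestGeneModels:
    def test_count_and_non_overlap(self):
        cfg = _neutral_cfg(seed=3, genome_length=100_000, n_scaffolds=1,
                           n_genes=10, gene_length=2_000, min_gene_gap=200)
        genes = simulate_gene_models(cfg, simulate_genome(cfg))
        assert len(genes) == 10
        spans = sorted((g.start, g.end) for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_minus_strand_tss_is_end(self):
        cfg = _neutral_cfg(seed=4, genome_length=100_000, n_scaffolds=1,
                           n_genes=20, gene_length=1_000, min_gene_gap=200)
        genes = simulate_gene_models(cfg, simulate_genome(cfg))
        minus = [g for g in genes if g.strand == "-"]
        assert minus and all(g.tss == g.end for g in minus)

    def test_gff3_roundtrip_preserves_tss(self, tmp_path, tiny_sim):
        path = tmp_path / "genes.gff3"
        dio.write_gff3(tiny_sim.genes, path)
        back = dio.read_gff3_genes(path)
        assert {(g.gene_id, g.scaffold, g.tss) for g in back} == {
            (g.gene_id, g.scaffold, g.tss) for g in tiny_sim.genes
        }
        bed_path = tmp_path / "genes.bed"
        dio.write_genes_bed(tiny_sim.genes, bed_path)
        bed = dio.read_genes_bed(bed_path)
        assert {(g.gene_id, g.start, g.end, g.strand) for g in bed} == {
            (g.gene_id, g.start, g.end, g.strand) for g in tiny_sim.genes
        }

    def test_genome_too_short_for_genes(self):
        cfg = _neutral_cfg(genome_length=10_000, n_scaffolds=1, n_genes=50,
                           gene_length=1_000, min_gene_gap=100)
        with pytest.raises(SimConfigError):
            simulate_gene_models(cfg, simulate_genome(cfg))


class TestVariants:
    def test_neutral_pi_matches_theta(self):
        cfg = _neutral_cfg(seed=11, genome_length=300_000, n_scaffolds=1)
        genome = simulate_genome(cfg)
        gm, _ = simulate_variants(cfg, genome)
        n_called, alt = gm.allele_counts()
        pi = (2.0 * alt * (n_called - alt) / (n_called * (n_called - 1))).sum()
        pi_per_bp = pi / 300_000
        assert 0.0012 <= pi_per_bp <= 0.0018

    def test_sweep_reduces_diversity(self):
        region = SweepRegion("scaffold_1", 50_000, 100_000, reduction=0.2, skew=2.0)
        cfg = _neutral_cfg(seed=12, genome_length=300_000, n_scaffolds=1,
                           sweep_regions=[region])
        genome = simulate_genome(cfg)
        gm, truth = simulate_variants(cfg, genome, sweep_regions=[region])
        n_called, alt = gm.allele_counts()
        site_pi = 2.0 * alt * (n_called - alt) / (n_called * (n_called - 1))
        in_sweep = truth["in_sweep"].to_numpy()
        sweep_pi = site_pi[in_sweep].sum() / 50_000
        neutral_pi = site_pi[~in_sweep].sum() / 250_000
        assert sweep_pi < 0.4 * neutral_pi

    def test_haploid_column_homozygous_without_errors(self):
        cfg = _neutral_cfg(seed=13, genome_length=100_000, n_scaffolds=1)
        genome = simulate_genome(cfg)
        gm, _ = simulate_variants(cfg, genome)
        hap = gm.dosage[:, gm.sample_index("MALE1")]
        assert not (hap == 1).any()

    def test_haploid_errors_written_heterozygous(self):
        cfg = _neutral_cfg(seed=13, genome_length=100_000, n_scaffolds=1,
                           haploid_error_fraction=0.5)
        genome = simulate_genome(cfg)
        gm, truth = simulate_variants(cfg, genome)
        hap = gm.dosage[:, gm.sample_index("MALE1")]
        assert ((hap == 1) == truth["haploid_error"].to_numpy()).all()

    def test_neutral_sfs_singleton_fraction(self):
        # the sample spectrum is drawn exactly proportional to 1/j
        cfg = _neutral_cfg(seed=14, genome_length=3_400_000, n_scaffolds=1)
        genome = simulate_genome(cfg)
        gm, truth = simulate_variants(cfg, genome)
        assert gm.n_sites >= 20_000
        j = truth["true_count"].to_numpy()
        expected = 1.0 / np.sum(1.0 / np.arange(1, 36))
        observed = (j == 1).mean()
        assert abs(observed - expected) / expected < 0.10

    def test_sweep_outside_genome_rejected(self):
        cfg = _neutral_cfg(genome_length=50_000, n_scaffolds=1)
        genome = simulate_genome(cfg)
        bad = SweepRegion("scaffold_1", 40_000, 60_000)
        with pytest.raises(SimConfigError):
            simulate_variants(cfg, genome, sweep_regions=[bad])

    def test_bad_annotation_sites_fail_some_predicate(self):
        cfg = _neutral_cfg(seed=15, genome_length=100_000, n_scaffolds=1,
                           bad_site_fraction=0.5)
        genome = simulate_genome(cfg)
        gm, truth = simulate_variants(cfg, genome)
        s = gm.sites
        fails = (
            (s["QD"] < 2.0) | (s["FS"] > 60.0) | (s["MQ"] < 40.0)
            | (s["ReadPosRankSum"] < -8.0)
        ).to_numpy()
        assert (fails == truth["bad_annotation"].to_numpy()).all()


class TestCoverage:
    def test_high_coverage_windows_nearly_complete(self):
        cfg = _neutral_cfg(seed=21, genome_length=50_000, n_scaffolds=1,
                           coverage_mean=30.0)
        cov = simulate_coverage(cfg, simulate_genome(cfg))
        assert (cov["frac_ge5"] >= 0.95).all()

    def test_dip_windows_underperform(self):
        cfg = _neutral_cfg(seed=22, genome_length=50_000, n_scaffolds=1,
                           coverage_mean=30.0, dip_mean=2.0,
                           coverage_dip_regions=[("scaffold_1", 10_000, 20_000)])
        cov = simulate_coverage(cfg, simulate_genome(cfg))
        in_dip = (cov["start"] >= 10_000) & (cov["end"] <= 20_000)
        assert (cov.loc[in_dip, "frac_ge5"] < 0.5).all()
        assert (cov.loc[~in_dip, "frac_ge5"] >= 0.95).all()

    def test_empty_genome_gives_empty_track(self):
        cfg = _neutral_cfg(seed=23)
        assert simulate_coverage(cfg, {}).empty


class TestPlantedMotifs:
    def test_deterministic_pwm_plants_consensus(self):
        cfg = SimConfig(seed=31, genome_length=100_000, n_scaffolds=1, n_genes=10,
                        gene_length=2_000, min_gene_gap=500, n_motifs=1,
                        motif_consensus_prob=1.0, planted_gene_fraction=0.5)
        genome = simulate_genome(cfg)
        genes = simulate_gene_models(cfg, genome)
        pwms = simulate_pwms(cfg)
        modified, planted = plant_motif_sites(cfg, genome, genes, pwms)
        consensus = decode_seq(pwms[0].consensus_codes().astype(np.int8))
        assert len(planted) == 5
        from divscan.models import revcomp_codes

        for row in planted.itertuples(index=False):
            w = pwms[0].width
            site = modified[row.scaffold][row.pos : row.pos + w]
            if row.strand == "-":
                site = revcomp_codes(site)
            assert decode_seq(site) == consensus

    def test_zero_fraction_leaves_genome_unchanged(self, tiny_sim):
        cfg = SimConfig(seed=32, genome_length=60_000, n_scaffolds=1, n_genes=5,
                        gene_length=1_000, min_gene_gap=200, n_motifs=2,
                        planted_gene_fraction=0.0)
        genome = simulate_genome(cfg)
        genes = simulate_gene_models(cfg, genome)
        modified, planted = plant_motif_sites(cfg, genome, genes, simulate_pwms(cfg))
        assert planted.empty
        assert all(
            np.array_equal(genome[k], modified[k]) for k in genome
        )

    def test_planted_sites_lie_in_declared_upstream_region(self, tiny_sim):
        genes = {g.gene_id: g for g in tiny_sim.genes}
        for row in tiny_sim.truth.planted_sites.itertuples(index=False):
            g = genes[row.gene_id]
            w = tiny_sim.pwms[0].width
            if g.strand == "+":
                assert g.tss - 1000 <= row.pos and row.pos + w <= g.tss
            else:
                assert g.tss <= row.pos and row.pos + w <= g.tss + 1000


class TestSweepTruth:
    def test_explicit_regions_select_overlapping_genes(self):
        cfg = _neutral_cfg(seed=41, genome_length=100_000, n_scaffolds=1,
                           n_genes=10, gene_length=2_000, min_gene_gap=500)
        genome = simulate_genome(cfg)
        genes = simulate_gene_models(cfg, genome)
        g = genes[3]
        cfg2 = _neutral_cfg(seed=41, genome_length=100_000, n_scaffolds=1,
                            n_genes=10, gene_length=2_000, min_gene_gap=500,
                            sweep_regions=[SweepRegion(g.scaffold, g.start, g.end)])
        regions, truth = derive_sweep_regions(cfg2, genes, genome)
        assert truth == {g.gene_id}

    def test_fraction_derived_regions_match_truth_count(self, tiny_sim):
        assert len(tiny_sim.truth.sweep_gene_ids) == 2  # 10% of 20 genes


class TestVcfRoundtrip:
    def test_write_read_preserves_genotypes_and_annotations(self, tmp_path, tiny_sim):
        path = tmp_path / "c.vcf"
        dio.write_vcf(tiny_sim.gm, path)
        back = dio.read_vcf(path, haploid_sample="MALE1")
        gm = tiny_sim.gm
        assert back.samples == gm.samples
        assert np.array_equal(back.dosage, gm.dosage)
        assert np.array_equal(back.dp, gm.dp)
        assert np.array_equal(back.gq, gm.gq)
        assert np.array_equal(back.sites["pos"].to_numpy(), gm.sites["pos"].to_numpy())
        np.testing.assert_allclose(
            back.sites["QD"].to_numpy(), gm.sites["QD"].to_numpy(), rtol=1e-3
        )

    def test_truth_tables_serialised(self, tmp_path, tiny_sim):
        paths = write_study(tiny_sim, tmp_path / "study")
        planted = pd.read_csv(paths["truth_planted"], sep="\t")
        assert set(planted.columns) == {"motif_id", "scaffold", "pos", "strand", "gene_id"}
        sweeps = paths["truth_sweep_genes"].read_text().split()
        assert set(sweeps) == tiny_sim.truth.sweep_gene_ids
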