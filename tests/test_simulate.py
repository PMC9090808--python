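"""Synthetic-data generators: determinism, invariants and closed forms."""

import math

import numpy as np
import pytest

from nmdase import (
    SimulationConfig,
    classify_nmd,
    gen_allele_counts,
    gen_deg_table,
    gen_haplotype_panel,
    gen_transcript_models,
    gen_variants,
    load_gtf,
    write_gtf,
)
from nmdase.simulate import ref_fraction_for_efficiency
from nmdase.vcfio import read_vcf, write_vcf


def small_config(**overrides):
    base = dict(seed=7, n_genes=50, n_targeted_ptv=5, n_escaping_ptv=5, n_other_het=40)
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(nmd_efficiency=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(frac_up=0.7, frac_down=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_targeted_ptv=-1)
        with pytest.raises(ValueError):
            SimulationConfig(mean_depth=0)


class TestTranscriptGenerator:
    def test_gtf_round_trip_and_byte_determinism(self, tmp_path):
        cfg = small_config()
        models = gen_transcript_models(cfg)
        assert len(models) == 50
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(models, p1)
        write_gtf(gen_transcript_models(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = {m.transcript_id: m for m in load_gtf(p1)}
        for m in models:
            assert back[m.transcript_id].exons == m.exons

    def test_cds_lengths_are_codon_multiples(self):
        """Independent audit: recompute each spliced CDS length from the
        exon/CDS intervals and check divisibility by 3."""
        for m in gen_transcript_models(small_config()):
            length = sum(
                max(0, min(e, m.cds_end) - max(s, m.cds_start)) for s, e in m.exons
            )
            assert length > 0 and length % 3 == 0

    def test_single_exon_fraction_controllable(self):
        cfg = small_config(n_genes=200)
        all_single = gen_transcript_models(cfg, frac_single_exon=1.0)
        assert all(m.n_exons == 1 for m in all_single)
        none_single = gen_transcript_models(cfg, frac_single_exon=0.0)
        assert all(m.n_exons >= 2 for m in none_single)
        mixed = gen_transcript_models(cfg, frac_single_exon=0.3)
        assert 0.15 < np.mean([m.n_exons == 1 for m in mixed]) < 0.45

    def test_exons_disjoint_and_sorted(self):
        for m in gen_transcript_models(small_config(seed=3)):
            assert all(a[1] <= b[0] for a, b in zip(m.exons, m.exons[1:]))
            assert all(m.n_exons <= 12 for m in [m])


class TestVariantGenerator:
    def test_truth_labels_recovered_by_classifier(self):
        cfg = small_config(n_targeted_ptv=12, n_escaping_ptv=8)
        models = gen_transcript_models(cfg)
        by_gene = {m.gene_id: m for m in models}
        variants = gen_variants(models, cfg)
        stop_gains = [v for v in variants if v.consequence == "stop_gain"]
        assert len(stop_gains) == 20
        for v in stop_gains:
            assert classify_nmd(v, by_gene[v.gene_id]).label == v.nmd_truth
        assert sum(v.nmd_truth == "targeted" for v in stop_gains) == 12

    def test_all_single_exon_cannot_host_targeted(self):
        cfg = small_config(n_targeted_ptv=1, n_escaping_ptv=0, n_other_het=0)
        models = gen_transcript_models(cfg, frac_single_exon=1.0)
        with pytest.raises(ValueError, match="single-exon"):
            gen_variants(models, cfg)

    def test_vcf_byte_determinism(self, tmp_path):
        cfg = small_config(n_other_het=100)
        models = gen_transcript_models(cfg)
        span = max(e for m in models for _, e in m.exons) + 1000
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(gen_variants(models, cfg), p1, {"chr1": span})
        write_vcf(gen_variants(models, cfg), p2, {"chr1": span})
        assert p1.read_bytes() == p2.read_bytes()
        back = read_vcf(p1)
        assert len(back) == 110
        assert all(v.nmd_truth in ("targeted", "escaping", "none") for v in back)


class TestAlleleCountGenerator:
    @staticmethod
    def targeted_ratios(e, seed=5, n_sites=220):
        cfg = SimulationConfig(
            seed=seed, n_genes=600, n_targeted_ptv=n_sites, n_escaping_ptv=0,
            n_other_het=10, nmd_efficiency=e, n_samples=1,
        )
        models = gen_transcript_models(cfg, frac_single_exon=0.0)
        variants = gen_variants(models, cfg)
        counts = gen_allele_counts(variants, cfg)
        vals = [
            r.refCount / (r.refCount + r.altCount)
            for r in counts
            if r.group == "targeted_ptv" and r.refCount + r.altCount > 0
        ]
        assert len(vals) >= 200
        return np.array(vals)

    @pytest.mark.parametrize("e", [0.0, 0.5])
    def test_mean_reference_fraction_matches_closed_form(self, e):
        """Pooled mean ref fraction converges to rho = 1/(2-e)."""
        vals = self.targeted_ratios(e)
        rho = ref_fraction_for_efficiency(e)
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean() - rho) < 3 * se + 1e-3

    def test_full_efficiency_without_overdispersion_is_monoallelic(self):
        cfg = SimulationConfig(
            seed=2, n_genes=80, n_targeted_ptv=30, n_escaping_ptv=0, n_other_het=5,
            nmd_efficiency=1.0, ase_overdispersion=math.inf, n_samples=2,
        )
        models = gen_transcript_models(cfg, frac_single_exon=0.0)
        counts = gen_allele_counts(gen_variants(models, cfg), cfg)
        assert all(r.altCount == 0 for r in counts if r.group == "targeted_ptv")

    def test_counts_sum_and_determinism(self):
        cfg = small_config()
        models = gen_transcript_models(cfg)
        variants = gen_variants(models, cfg)
        a = gen_allele_counts(variants, cfg)
        b = gen_allele_counts(variants, cfg)
        assert a == b
        assert all(r.refCount + r.altCount == r.totalCount for r in a)
        assert len(a) == len(variants) * cfg.n_samples

    def test_non_targeted_sites_balanced_even_at_full_efficiency(self):
        cfg = SimulationConfig(
            seed=4, n_genes=300, n_targeted_ptv=2, n_escaping_ptv=100, n_other_het=100,
            nmd_efficiency=1.0, n_samples=1,
        )
        models = gen_transcript_models(cfg, frac_single_exon=0.0)
        counts = gen_allele_counts(gen_variants(models, cfg), cfg)
        vals = np.array([
            r.refCount / (r.refCount + r.altCount)
            for r in counts if r.group != "targeted_ptv" and r.refCount + r.altCount > 0
        ])
        assert abs(vals.mean() - 0.5) < 3 * vals.std(ddof=1) / math.sqrt(vals.size) + 1e-3


class TestDegGenerator:
    def test_determinism_and_padj_range(self):
        cfg = SimulationConfig(seed=9, n_genes=400, frac_up=0.1, frac_down=0.05)
        a, b = gen_deg_table(cfg), gen_deg_table(cfg)
        assert a.equals(b)
        assert ((a["padj"] >= 0) & (a["padj"] <= 1)).all()
        assert len(a) == 400

    def test_effect_directions(self):
        cfg = SimulationConfig(seed=9, n_genes=400, frac_up=0.1, frac_down=0.05)
        df = gen_deg_table(cfg)
        assert (df.loc[df.truth == "up", "logFC"] > 0).all()
        assert (df.loc[df.truth == "down", "logFC"] < 0).all()
        assert (df.truth == "up").sum() == 40
        assert (df.truth == "down").sum() == 20

    def test_null_table_filter_symmetry(self):
        """With no true effects the significant up and down counts are
        both within binomial noise of their (small) expectation."""
        cfg = SimulationConfig(seed=1, n_genes=5000, frac_up=0.0, frac_down=0.0)
        df = gen_deg_table(cfg)
        sig = df[(df.padj < 0.05) & (df.logFC.abs() >= 0.25)]
        n_up, n_down = (sig.logFC > 0).sum(), (sig.logFC < 0).sum()
        assert n_up + n_down < 25  # false-positive mass only
        assert abs(n_up - n_down) <= 3 * math.sqrt(max(1, n_up + n_down))


class TestHaplotypeGenerator:
    def test_full_span_segment_boundary_case(self):
        panel = gen_haplotype_panel(2, 1e6, 1e-3, 1e6, seed=0)
        from nmdase import shared_haplotype_segments

        res = shared_haplotype_segments(panel)
        assert res["median_bp"] == panel.positions[-1] - panel.positions[0]

    def test_seed_determinism(self):
        a = gen_haplotype_panel(4, 2e6, 1e-3, 1e6, seed=5)
        b = gen_haplotype_panel(4, 2e6, 1e-3, 1e6, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_segment_larger_than_panel_rejected(self):
        with pytest.raises(ValueError):
            gen_haplotype_panel(2, 1e6, 1e-3, 2e6, seed=0)
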