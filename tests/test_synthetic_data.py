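"""Generator contracts: determinism, segregation structure, planted truth."""

import numpy as np
import pytest

from screenmap.expression_quant import compute_fpkm
from screenmap.genome_models import ValidationError
from screenmap.qpcr_and_stats import ddct
from screenmap.synthetic_data import (
    CrossConfig,
    ExpressionSimConfig,
    GeneClassSpec,
    random_gene_models,
    simulate_cross,
    simulate_counts,
    simulate_ct,
)

SMALL_CROSS = dict(
    n_chromosomes=2,
    chrom_length_bp=4_000_000,
    causal_chrom="chr1",
    causal_pos=2_000_000,
    genes_per_chromosome=6,
)


class TestSimulateCross:
    def test_deterministic_in_seed(self):
        a = simulate_cross(CrossConfig(seed=9, **SMALL_CROSS))
        b = simulate_cross(CrossConfig(seed=9, **SMALL_CROSS))
        assert a.variants == b.variants
        assert a.truth.mutant_pool == b.truth.mutant_pool
        assert a.genome.fetch("chr1", 1, 10_000) == b.genome.fetch("chr1", 1, 10_000)

    def test_causal_site_is_donor_g_to_a(self):
        res = simulate_cross(CrossConfig(seed=1, **SMALL_CROSS))
        causal = [
            v for v in res.variants
            if (v.chrom, v.pos) == (res.truth.causal_chrom, res.truth.causal_pos)
        ]
        assert len(causal) == 1
        assert (causal[0].ref_allele, causal[0].alt_allele) == ("G", "A")
        gene = {g.gene_id: g for g in res.genes}[res.truth.causal_gene_id]
        assert any(s == res.truth.causal_pos for s, _ in gene.introns)

    def test_mutant_pool_fixed_at_causal_site(self):
        """Every mutant-pool haplotype carries the lesion: true alt freq 1."""
        for seed in range(3):
            res = simulate_cross(CrossConfig(seed=seed, **SMALL_CROSS))
            key = (res.truth.causal_chrom, res.truth.causal_pos)
            wt_af, mut_af = res.truth.true_alt_freq[key]
            assert mut_af == 1.0
            assert wt_af < 1.0

    def test_sibling_pool_frequency_near_one_third(self):
        """Non-mutant sibs are het:hom-ref 2:1, so expected alt freq 1/3."""
        afs = [
            simulate_cross(CrossConfig(seed=s, **SMALL_CROSS)).truth.true_alt_freq[
                ("chr1", 2_000_000)
            ][0]
            for s in range(10)
        ]
        assert abs(np.mean(afs) - 1 / 3) < 0.06

    def test_no_recombination_gives_perfect_linkage(self):
        res = simulate_cross(CrossConfig(seed=4, recomb_rate=0.0, **SMALL_CROSS))
        truth = res.truth
        for (chrom, pos), strain in truth.alt_strain.items():
            if chrom != truth.causal_chrom or strain != 1:
                continue
            assert truth.true_alt_freq[(chrom, pos)][1] == 1.0

    def test_unlinked_chromosome_pools_balance(self):
        """Away from the lesion both pools see the same expected alt freq."""
        wt_means, mut_means = [], []
        for seed in range(5):
            truth = simulate_cross(CrossConfig(seed=seed, **SMALL_CROSS)).truth
            afs = [
                truth.true_alt_freq[k]
                for k in truth.true_alt_freq
                if k[0] == "chr2"
            ]
            wt_means.append(np.mean([a for a, _ in afs]))
            mut_means.append(np.mean([b for _, b in afs]))
        assert abs(np.mean(wt_means) - np.mean(mut_means)) < 0.02
        assert abs(np.mean(wt_means) - 0.5) < 0.02

    def test_fixed_family_size(self):
        cfg = CrossConfig(seed=7, n_f2_larvae=120, **SMALL_CROSS)
        res = simulate_cross(cfg)
        assert res.truth.n_simulated >= 120
        assert len(res.truth.mutant_pool) == cfg.n_mutant_larvae
        assert len(res.truth.wt_pool) == cfg.n_wt_larvae

    def test_pools_filled_exactly(self):
        res = simulate_cross(CrossConfig(seed=0, **SMALL_CROSS))
        truth = res.truth
        assert all(truth.larvae[i].is_mutant for i in truth.mutant_pool)
        assert not any(truth.larvae[i].is_mutant for i in truth.wt_pool)


class TestSimulateCounts:
    def test_zero_dispersion_recovers_fold_exactly(self):
        # the doubled gene carries a negligible share of the library so the
        # compositional correction to the FPKM ratio is < 0.1%
        cfg = ExpressionSimConfig(
            n_genes=200,
            classes=(GeneClassSpec("double", 1, 1.0, baseline=100.0),),
            causal_log2fc=0.0,
            dispersion=0.0,
            baseline_median=10_000.0,
            causal_baseline=10_000.0,
            retention_fraction=0.0,
            seed=0,
        )
        genes = random_gene_models(200, seed=0)
        result = simulate_counts(cfg, genes)
        fpkm = compute_fpkm(result.gene_counts, genes)
        doubled = [g for g, c in result.truth.class_of.items() if c == "double"]
        ratio = (
            fpkm.fpkm("mut").loc[doubled[0]] / fpkm.fpkm("wt").loc[doubled[0]]
        )
        assert ratio == pytest.approx(2.0, rel=1e-2)

    def test_zero_retention_plants_no_novel_junctions(self):
        cfg = ExpressionSimConfig(n_genes=30, retention_fraction=0.0, seed=1)
        genes = random_gene_models(30, seed=1)
        result = simulate_counts(cfg, genes)
        assert result.truth.novel_junction_ids == []
        annotated = {
            f"{g.chrom}:{s - 1}-{e + 1}" for g in genes for s, e in g.introns
        }
        assert set(result.junction_counts.feature_ids) == annotated

    def test_vision_class_has_zero_mutant_counts(self):
        cfg = ExpressionSimConfig(n_genes=50, seed=2)
        genes = random_gene_models(50, seed=2)
        result = simulate_counts(cfg, genes)
        vision = [g for g, c in result.truth.class_of.items() if c == "vision_down"]
        assert vision
        mut = result.gene_counts.sample("mut")
        for gid in vision:
            assert mut[result.gene_counts.feature_ids.index(gid)] == 0

    def test_deterministic_in_seed(self):
        cfg = ExpressionSimConfig(n_genes=40, seed=3)
        genes = random_gene_models(40, seed=3)
        a = simulate_counts(cfg, genes)
        b = simulate_counts(cfg, genes)
        assert np.array_equal(a.gene_counts.counts, b.gene_counts.counts)
        assert np.array_equal(a.junction_counts.counts, b.junction_counts.counts)

    def test_too_few_gene_models_rejected(self):
        with pytest.raises(ValidationError):
            simulate_counts(
                ExpressionSimConfig(n_genes=100), random_gene_models(10)
            )


class TestSimulateCt:
    def test_zero_noise_zero_ddct_gives_unit_fold(self):
        table = simulate_ct([("tp53", 0.0), ("crx", 0.0)], noise_sd=0.0, seed=0)
        for gene in ("tp53", "crx"):
            assert ddct(table, gene).fold == pytest.approx(1.0)

    def test_zero_noise_planted_minus_two_gives_fold_four(self):
        table = simulate_ct([("tp53", -2.0)], noise_sd=0.0, seed=0)
        result = ddct(table, "tp53")
        assert result.ddct == pytest.approx(-2.0)
        assert result.fold == pytest.approx(4.0)
        assert result.normalized == pytest.approx(3.0)

    def test_noisy_recovery_within_fifteen_percent_on_average(self):
        folds = []
        for seed in range(100):
            table = simulate_ct([("tp53", -2.0)], noise_sd=0.1, seed=seed)
            folds.append(ddct(table, "tp53").fold)
        assert abs(np.mean(folds) - 4.0) / 4.0 < 0.15

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ct([("tp53", 0.0)], noise_sd=-0.1)

    def test_replicate_structure(self):
        table = simulate_ct([("tp53", -1.0)], n_replicates=4, seed=1)
        assert len(table.ct("tp53", "wt")) == 4
        assert len(table.ct("actb1", "mut")) == 4
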