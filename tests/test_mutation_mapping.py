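"""Pool zygosity, windowed homozygosity mapping, effect classification."""

import numpy as np
import pytest

from screenmap.genome_models import GenomeSequence, PooledVariant, revcomp
from screenmap.mutation_mapping import (
    Peak,
    ReferenceMismatchError,
    ZygosityCall,
    call_zygosity,
    classify_effect,
    count_recombinants,
    find_peak,
    homozygosity_profile,
    retention_consequence,
    screen_candidates,
    select_mutant_pool_variants,
)
from screenmap.synthetic_data import CrossConfig, simulate_cross
from screenmap.synthetic_data import _materialize_gene, _plan_gene

SMALL_CROSS = dict(
    n_chromosomes=1,
    chrom_length_bp=4_000_000,
    causal_chrom="chr1",
    causal_pos=2_000_000,
    genes_per_chromosome=6,
)


def _variant(chrom="chr1", pos=100, wt=(20, 10), mut=(0, 30), ref="G", alt="A"):
    return PooledVariant(chrom, pos, ref, alt, wt, mut)


class TestCallZygosity:
    @pytest.mark.parametrize(
        "wt,mut,wt_state,mut_state,specific",
        [
            ((20, 10), (0, 30), "het", "hom_alt", True),
            ((0, 30), (0, 30), "hom_alt", "hom_alt", False),
            ((30, 0), (0, 30), "hom_ref", "hom_alt", True),
            ((20, 10), (0, 5), "het", "nocall", False),
            ((0, 5), (0, 30), "nocall", "hom_alt", False),
            ((28, 2), (3, 27), "hom_ref", "hom_alt", True),
        ],
    )
    def test_threshold_logic(self, wt, mut, wt_state, mut_state, specific):
        call = call_zygosity(_variant(wt=wt, mut=mut))
        assert call.wt_state == wt_state
        assert call.mut_state == mut_state
        assert call.mutant_specific_hom is specific

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            call_zygosity(_variant(), hom_alt_min_frac=0.4)
        with pytest.raises(ValueError):
            call_zygosity(_variant(), min_depth=0)

    def test_mutant_pool_variant_selection(self):
        calls = [
            call_zygosity(_variant(pos=1, mut=(0, 30))),  # hom_alt: kept
            call_zygosity(_variant(pos=2, mut=(15, 15))),  # het: kept
            call_zygosity(_variant(pos=3, mut=(30, 0))),  # hom_ref: dropped
            call_zygosity(_variant(pos=4, mut=(0, 5))),  # nocall: dropped
        ]
        kept = select_mutant_pool_variants(calls)
        assert [c.variant.pos for c in kept] == [1, 2]


def _call(pos, specific, chrom="chr1"):
    v = _variant(chrom=chrom, pos=pos, mut=(0, 30) if specific else (15, 15))
    return call_zygosity(v)


class TestHomozygosityProfile:
    def test_window_score_is_direct_fraction(self):
        calls = [_call(p, s) for p, s in [(10, True), (20, True), (30, False), (40, False)]]
        profiles = homozygosity_profile(calls, window_size=100, step=100, min_variants=1)
        assert profiles["chr1"].scores[0] == pytest.approx(50.0)

    def test_all_nonspecific_means_no_peak(self):
        calls = [_call(p, False) for p in range(1000, 9000, 500)]
        profiles = homozygosity_profile(calls, window_size=1000, step=1000, min_variants=1)
        assert all(s == 0 for s in profiles["chr1"].scores)
        assert find_peak(profiles) is None

    def test_empty_calls(self):
        assert homozygosity_profile([]) == {}
        assert find_peak({}) is None

    def test_sparse_windows_excluded(self):
        calls = [_call(10, True), _call(5000, True)]
        profiles = homozygosity_profile(
            calls, window_size=1000, step=1000, min_variants=2
        )
        assert np.all(np.isnan(profiles["chr1"].scores))
        assert find_peak(profiles) is None

    def test_score_permutation_invariant(self):
        rng = np.random.default_rng(0)
        calls = [_call(int(p), bool(s)) for p, s in zip(
            rng.integers(1, 50_000, 200), rng.random(200) < 0.4
        )]
        a = homozygosity_profile(calls, window_size=10_000, step=2_000, min_variants=1)
        rng.shuffle(calls)
        b = homozygosity_profile(calls, window_size=10_000, step=2_000, min_variants=1)
        np.testing.assert_allclose(a["chr1"].scores, b["chr1"].scores)

    def test_monotonicity_of_added_calls(self):
        base = [_call(100, True), _call(200, False)]
        profiles = homozygosity_profile(base, window_size=1000, step=1000, min_variants=1)
        s0 = profiles["chr1"].scores[0]
        with_specific = homozygosity_profile(
            base + [_call(300, True)], window_size=1000, step=1000, min_variants=1
        )["chr1"].scores[0]
        with_nonspecific = homozygosity_profile(
            base + [_call(300, False)], window_size=1000, step=1000, min_variants=1
        )["chr1"].scores[0]
        assert with_specific >= s0 >= with_nonspecific

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(42)
        positions = np.sort(rng.choice(np.arange(1, 200_000), 200, replace=False))
        flags = rng.random(200) < 0.3
        calls = [_call(int(p), bool(f)) for p, f in zip(positions, flags)]
        window, step = 20_000, 5_000
        profiles = homozygosity_profile(
            calls, window_size=window, step=step, min_variants=1,
            chrom_lengths={"chr1": 200_000},
        )
        p = profiles["chr1"]
        for start, score, n in zip(p.window_starts, p.scores, p.n_variants):
            in_win = [(pos, f) for pos, f in zip(positions, flags)
                      if start <= pos <= start + window - 1]
            assert n == len(in_win)
            if in_win:
                expected = 100.0 * sum(f for _, f in in_win) / len(in_win)
                assert score == pytest.approx(expected)
            else:
                assert np.isnan(score)

    def test_exact_ties_merge_into_one_interval(self):
        # two adjacent windows at 100%, the rest at 0
        calls = [_call(p, True) for p in (100, 1100)]
        calls += [_call(p, False) for p in (5100, 6100)]
        profiles = homozygosity_profile(calls, window_size=1000, step=1000, min_variants=1)
        peak = find_peak(profiles, tie_tolerance=1e-9)
        assert (peak.start, peak.end) == (1, 2000)
        assert peak.n_windows == 2


class TestClassifyEffect:
    def test_donor_site_g_to_a(self, toy_genome, gene_plus):
        v = _variant(chrom="chrT", pos=23, ref="G", alt="A")
        eff = classify_effect(v, [gene_plus], toy_genome)
        assert eff.category == "essential_splice"
        assert eff.detail == "intron1_donor_site_offset=1"

    def test_acceptor_site(self, toy_genome, gene_plus):
        v = _variant(chrom="chrT", pos=30, ref="G", alt="C")
        eff = classify_effect(v, [gene_plus], toy_genome)
        assert eff.category == "essential_splice"
        assert eff.detail == "intron1_acceptor_site_offset=1"

    def test_nonsense_tac_to_taa(self, toy_genome, gene_plus):
        # codon 3 (TAC) at 17-19; C>A makes TAA
        v = _variant(chrom="chrT", pos=19, ref="C", alt="A")
        eff = classify_effect(v, [gene_plus], toy_genome)
        assert eff.category == "nonsense"
        assert "TAC>TAA" in eff.detail

    def test_synonymous_and_missense(self, toy_genome, gene_plus):
        syn = classify_effect(
            _variant(chrom="chrT", pos=16, ref="T", alt="C"), [gene_plus], toy_genome
        )
        assert syn.category == "synonymous"  # GCT -> GCC, both Ala
        mis = classify_effect(
            _variant(chrom="chrT", pos=13, ref="G", alt="A"), [gene_plus], toy_genome
        )
        assert mis.category == "missense"  # ATG -> ATA, Met -> Ile

    def test_intronic_and_intergenic(self, toy_genome, gene_plus):
        intronic = classify_effect(
            _variant(chrom="chrT", pos=26, ref="C", alt="T"), [gene_plus], toy_genome
        )
        assert intronic.category == "intronic"
        intergenic = classify_effect(
            _variant(chrom="chrT", pos=50, ref="T", alt="C"), [gene_plus], toy_genome
        )
        assert intergenic.category == "intergenic"
        assert intergenic.gene_id is None

    def test_reference_mismatch(self, toy_genome, gene_plus):
        with pytest.raises(ReferenceMismatchError):
            classify_effect(
                _variant(chrom="chrT", pos=23, ref="T", alt="A"),
                [gene_plus],
                toy_genome,
            )

    def test_minus_strand_donor(self, toy_genome, gene_minus):
        # chrM donor = mirror of chrQ position 23 -> 60 - 23 + 1 = 38
        ref = toy_genome.base("chrM", 38)
        assert ref == "C"  # complement of the G donor base
        v = _variant(chrom="chrM", pos=38, ref="C", alt="T")
        eff = classify_effect(v, [gene_minus], toy_genome)
        assert eff.category == "essential_splice"
        assert eff.detail == "intron1_donor_site_offset=1"

    def test_agrees_with_bruteforce_on_random_genes(self):
        """Mutate the genome string, re-extract and translate the CDS."""
        rng = np.random.default_rng(11)
        from Bio.Seq import Seq

        for _ in range(15):
            arr = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, 20_000)
            ].copy()
            plan = _plan_gene(rng, int(rng.integers(2, 6)), (30, 90), (20, 60))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _materialize_gene(
                "g", "c", 2000, plan, strand, rng, arr
            )
            genome = GenomeSequence({"c": arr.tobytes().decode()}, validate=False)
            ref_protein = str(Seq(gene.coding_sequence(genome)).translate())
            span = gene.span
            for _ in range(30):
                pos = int(rng.integers(span[0] - 100, span[1] + 100))
                ref = genome.base("c", pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                eff = classify_effect(
                    _variant(chrom="c", pos=pos, ref=ref, alt=str(alt)),
                    [gene],
                    genome,
                )
                # independent oracle from first principles
                splice = any(
                    pos in (s, s + 1, e - 1, e) for s, e in gene.introns
                )
                in_coding = any(
                    s <= pos <= e for s, e in gene.coding_intervals()
                )
                if splice:
                    assert eff.category == "essential_splice"
                elif in_coding:
                    mutated = arr.copy()
                    mutated[pos - 1] = ord(alt)
                    mut_genome = GenomeSequence(
                        {"c": mutated.tobytes().decode()}, validate=False
                    )
                    alt_protein = str(
                        Seq(gene.coding_sequence(mut_genome)).translate()
                    )
                    changed = [
                        i for i, (a, b) in enumerate(zip(ref_protein, alt_protein))
                        if a != b
                    ]
                    if changed and alt_protein[changed[0]] == "*":
                        assert eff.category == "nonsense"
                    elif not changed:
                        assert eff.category == "synonymous"
                    else:
                        assert eff.category == "missense"
                elif any(s <= pos <= e for s, e in gene.introns):
                    assert eff.category == "intronic"
                elif not gene.contains(pos):
                    assert eff.category == "intergenic"


class TestScreenCandidates:
    def test_filters_to_nonsense_and_splice(self, toy_genome, gene_plus):
        peak = Peak("chrT", 1, 60, 100.0, 1)
        calls = [
            call_zygosity(_variant(chrom="chrT", pos=23, ref="G", alt="A")),  # splice
            call_zygosity(_variant(chrom="chrT", pos=16, ref="T", alt="C")),  # syn
            call_zygosity(_variant(chrom="chrT", pos=26, ref="C", alt="T")),  # intronic
            call_zygosity(
                _variant(chrom="chrT", pos=13, ref="G", alt="A", mut=(15, 15))
            ),  # missense, and not mutant-specific anyway
        ]
        out = screen_candidates(peak, calls, [gene_plus], toy_genome)
        assert [(e.variant.pos, e.category) for e in out] == [
            (23, "essential_splice")
        ]

    def test_no_peak_gives_empty_list(self, toy_genome, gene_plus):
        assert screen_candidates(None, [], [gene_plus], toy_genome) == []

    def test_outside_peak_excluded(self, toy_genome, gene_plus):
        peak = Peak("chrT", 40, 60, 100.0, 1)
        calls = [call_zygosity(_variant(chrom="chrT", pos=23, ref="G", alt="A"))]
        assert screen_candidates(peak, calls, [gene_plus], toy_genome) == []


class TestRetentionConsequence:
    def test_ptc_in_retained_intron(self, toy_genome, gene_ptc):
        rc = retention_consequence(gene_ptc, 0, toy_genome)
        assert rc.ptc_found
        assert rc.ptc_codon == "TAA"
        # intron GTCTAAAG at 23-30: TAA occupies 26-28
        assert rc.ptc_genomic_pos == 26
        # 4 exonic codons + GTC precede the stop
        assert rc.truncated_protein_length == 5

    def test_no_inframe_stop_runs_through(self, toy_genome, gene_plus):
        rc = retention_consequence(gene_plus, 0, toy_genome)
        assert not rc.ptc_found
        assert rc.ptc_codon is None

    def test_minus_strand_mirror_is_identical(self, toy_genome, gene_minus):
        rc = retention_consequence(gene_minus, 0, toy_genome)
        assert rc.ptc_found
        assert rc.ptc_codon == "TAA"
        assert rc.ptc_genomic_pos == 60 - 26 + 1  # mirrored coordinate
        assert rc.truncated_protein_length == 5

    def test_invalid_intron_index(self, toy_genome, gene_ptc):
        with pytest.raises(ValueError):
            retention_consequence(gene_ptc, 5, toy_genome)


class TestCountRecombinants:
    def test_marker_at_lesion_is_never_recombinant(self):
        res = simulate_cross(CrossConfig(seed=2, **SMALL_CROSS))
        n_rec, n_meioses = count_recombinants(res.truth, res.truth.causal_pos)
        assert n_rec == 0
        assert n_meioses == 2 * res.truth.n_simulated

    def test_zero_recomb_rate_has_no_recombinants(self):
        res = simulate_cross(CrossConfig(seed=3, recomb_rate=0.0, **SMALL_CROSS))
        for marker in (1, 1_000_000, 3_999_999):
            n_rec, _ = count_recombinants(res.truth, marker)
            assert n_rec == 0

    def test_marker_outside_chromosome_rejected(self):
        res = simulate_cross(CrossConfig(seed=2, **SMALL_CROSS))
        with pytest.raises(ValueError):
            count_recombinants(res.truth, 5_000_001)

    def test_recombination_fraction_matches_crossover_model(self):
        """Observed fraction ~ P(odd crossovers between marker and lesion)."""
        cfg = CrossConfig(
            seed=5,
            n_f2_larvae=500,
            recomb_rate=1.0,
            n_chromosomes=1,
            chrom_length_bp=5_000_000,
            causal_chrom="chr1",
            causal_pos=2_000_000,
            genes_per_chromosome=4,
        )
        res = simulate_cross(cfg)
        d = 1_000_000
        n_rec, n_meioses = count_recombinants(
            res.truth, cfg.causal_pos + d, n_larvae=500
        )
        expected = (1 - np.exp(-2 * cfg.recomb_rate * d / cfg.chrom_length_bp)) / 2
        se = np.sqrt(expected * (1 - expected) / n_meioses)
        assert abs(n_rec / n_meioses - expected) < 3 * se
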