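"""Seeded generators emulating the study designs the pipeline analyses.

Three independent generators, each a pure function of its config (seeded):

* :func:`simulate_cross` -- an F2 incross segregating a recessive lethal
  point mutation at a splice-donor site (G>A at the first intronic base).
  Two F1 parents are heterozygous genome-wide for a mutagenized-strain
  haplotype and a mapping-strain haplotype; each F2 larva receives one
  recombined gamete per parent (Poisson crossover count, uniform placement,
  no interference).  Strain-difference variants segregate 1:2:1 away from
  the lesion, while larvae homozygous for the causal allele are homozygous
  for the whole linked mutagenized haplotype -- the enrichment that bulked
  segregant analysis detects.  Pools of phenotypically mutant and wild-type
  sibling larvae are sequenced with Poisson site depth and binomial allele
  sampling.
* :func:`simulate_counts` -- RNA-seq gene and junction fragment counts for
  one wild-type and one mutant library, negative binomial around planted
  per-class fold changes, with intron-retention junction reads planted at
  the causal gene in the mutant library only.
* :func:`simulate_ct` -- qPCR Ct replicate tables with a planted ddCt
  structure around a reference gene.

Every generator also returns a truth record so recovery can be measured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_models import (
    CountMatrix,
    GeneModel,
    GenomeSequence,
    ValidationError,
)
from .junction_analysis import junction_id
from .qpcr_and_stats import CtTable

log = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# F2 mapping cross


@dataclass(frozen=True)
class CrossConfig:
    """Study-design parameters of the synthetic F2 mapping cross.

    Defaults mirror the pooled-exome design: pools of 20 phenotypically
    mutant and 20 wild-type sibling larvae at ~30x pooled depth, ~1 crossover
    per 25-Mb chromosome per meiosis, and a strain-difference variant every
    ~5 kb (zebrafish laboratory strains are highly polymorphic; exome variant
    lists run to thousands of sites per chromosome) with a much sparser load
    of mutagen-induced variants private to the mutagenized haplotype.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 25_000_000
    background_variant_density: float = 2e-4
    enu_variant_density: float = 1e-6
    causal_chrom: str = "chr2"
    causal_pos: int = 12_400_000
    n_mutant_larvae: int = 20
    n_wt_larvae: int = 20
    n_f2_larvae: int | None = None
    recomb_rate: float = 1.0
    mean_depth_per_pool: float = 30.0
    genes_per_chromosome: int = 40
    causal_n_exons: int = 13
    causal_retained_intron: int = 11  # 0-based; the 12th intron
    seed: int = 0

    def __post_init__(self):
        if not (self.background_variant_density > 0 and self.mean_depth_per_pool > 0):
            raise ValidationError("densities and depths must be > 0")
        if self.recomb_rate < 0 or self.enu_variant_density < 0:
            raise ValidationError("rates must be >= 0")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValidationError("causal_pos outside the causal chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class Gamete:
    """One transmitted haplotype: per-chromosome crossover mosaic.

    ``phase_at`` returns which parental haplotype (0 = mapping strain,
    1 = mutagenized strain) the gamete carries at a position.
    """

    starts: dict[str, int]
    breakpoints: dict[str, np.ndarray]

    def phase_at(self, chrom: str, pos) -> int | np.ndarray:
        bp = self.breakpoints[chrom]
        return (self.starts[chrom] + np.searchsorted(bp, pos)) % 2


@dataclass(frozen=True)
class LarvaTruth:
    gametes: tuple[Gamete, Gamete]
    is_mutant: bool


@dataclass
class CrossTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    causal_chrom: str
    causal_pos: int
    causal_ref: str
    causal_alt: str
    causal_gene_id: str
    chrom_lengths: dict[str, int]
    larvae: list[LarvaTruth]
    mutant_pool: list[int]
    wt_pool: list[int]
    alt_strain: dict[tuple[str, int], int]
    enu_sites: set[tuple[str, int]]
    true_alt_freq: dict[tuple[str, int], tuple[float, float]]  # (wt_af, mut_af)
    n_simulated: int = 0


@dataclass
class CrossResult:
    variants: list  # list[PooledVariant]
    truth: CrossTruth
    genome: GenomeSequence
    genes: list[GeneModel]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _intron_seq(rng: np.random.Generator, length: int) -> str:
    """Random intron on the coding strand with canonical GT...AG ends."""
    if length < 4:
        raise ValidationError("introns must be >= 4 bp for canonical ends")
    return "GT" + _random_bases(rng, length - 4) + "AG"


@dataclass(frozen=True)
class _GenePlan:
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]

    @property
    def total_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def _plan_gene(
    rng: np.random.Generator,
    n_exons: int,
    exon_len: tuple[int, int] = (100, 300),
    intron_len: tuple[int, int] = (500, 2000),
) -> _GenePlan:
    exons = list(rng.integers(exon_len[0], exon_len[1] + 1, n_exons))
    # CDS spans all exons; keep the spliced length a multiple of 3
    rem = sum(exons) % 3
    if rem:
        exons[-1] += 3 - rem
    introns = list(rng.integers(intron_len[0], intron_len[1] + 1, n_exons - 1))
    return _GenePlan(tuple(int(e) for e in exons), tuple(int(i) for i in introns))


def _materialize_gene(
    gene_id: str,
    chrom: str,
    start: int,
    plan: _GenePlan,
    strand: str,
    rng: np.random.Generator,
    chrom_array: np.ndarray,
    retained_intron: int | None = None,
) -> GeneModel:
    """Lay a gene's sequence into the chromosome byte array and model it.

    The coding sequence is random sense codons (no internal stop), introns
    carry canonical GT/AG ends on the coding strand.  When
    ``retained_intron`` is given (0-based, genomic order; plus strand only),
    that intron gets an early in-frame TAA so retention introduces a
    premature termination codon.
    """
    exon_ivs: list[tuple[int, int]] = []
    pos = start
    for i, elen in enumerate(plan.exon_lengths):
        exon_ivs.append((pos, pos + elen - 1))
        pos += elen
        if i < len(plan.intron_lengths):
            pos += plan.intron_lengths[i]
    end = pos - 1
    if end > len(chrom_array):
        raise ValidationError(f"gene {gene_id} runs past the chromosome end")

    cds_seq = _random_codons(rng, sum(plan.exon_lengths) // 3)

    # transcript-oriented exon pieces
    tx_exons = exon_ivs if strand == "+" else exon_ivs[::-1]
    offset = 0
    pieces: list[tuple[int, str]] = []  # (genomic start, genomic-strand seq)
    for s, e in tx_exons:
        piece = cds_seq[offset : offset + (e - s + 1)]
        offset += e - s + 1
        if strand == "-":
            from .genome_models import revcomp

            piece = revcomp(piece)
        pieces.append((s, piece))

    introns_genomic = [
        (e1 + 1, s2 - 1) for (s1, e1), (s2, e2) in zip(exon_ivs, exon_ivs[1:])
    ]
    for i, (istart, iend) in enumerate(introns_genomic):
        ilen = iend - istart + 1
        if retained_intron is not None and i == retained_intron:
            if strand != "+":
                raise ValidationError("retained-intron planting expects + strand")
            # frame offset of the coding sequence at the exon/intron junction
            coding_before = sum(plan.exon_lengths[: i + 1])
            pad = (3 - coding_before % 3) % 3  # intron bases completing the codon
            # place an in-frame TAA at the first codon boundary clear of the
            # fixed GT donor; the C filler cannot form an earlier stop
            n_fill = (pad - 2) % 3
            head = "GT" + "C" * n_fill + "TAA"
            tail_len = ilen - len(head) - 2
            if tail_len < 0:
                raise ValidationError("retained intron too short for PTC plant")
            seq = head + _random_bases(rng, tail_len) + "AG"
        else:
            seq = _intron_seq(rng, ilen)
        if strand == "-":
            from .genome_models import revcomp

            seq = revcomp(seq)
        pieces.append((istart, seq))

    for s, seq in pieces:
        chrom_array[s - 1 : s - 1 + len(seq)] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exon_ivs),
        cds=(exon_ivs[0][0], exon_ivs[-1][1]),
    )


def _simulate_reference(
    config: CrossConfig, rng: np.random.Generator
) -> tuple[GenomeSequence, list[GeneModel], str]:
    """Random genome plus gene models, causal gene anchored at causal_pos.

    The causal gene sits on the plus strand with the first base of its
    retained-to-be intron exactly at ``config.causal_pos`` (reference G of
    the canonical GT donor).
    """
    arrays = {
        chrom: _BASE_BYTES[
            rng.integers(0, 4, config.chrom_length_bp).astype(np.uint8)
        ].copy()
        for chrom in config.chrom_names
    }
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}

    # causal gene first, anchored so intron k starts at causal_pos
    k = config.causal_retained_intron
    if not 0 <= k < config.causal_n_exons - 1:
        raise ValidationError("causal_retained_intron out of range")
    plan = _plan_gene(rng, config.causal_n_exons)
    upstream = sum(plan.exon_lengths[: k + 1]) + sum(plan.intron_lengths[:k])
    causal_start = config.causal_pos - upstream
    if causal_start < 1 or causal_start + plan.total_length > config.chrom_length_bp:
        raise ValidationError(
            "causal_pos too close to a chromosome end for the causal gene"
        )
    causal_gene = _materialize_gene(
        "causal_gene",
        config.causal_chrom,
        causal_start,
        plan,
        "+",
        rng,
        arrays[config.causal_chrom],
        retained_intron=k,
    )
    genes.append(causal_gene)
    s, e = causal_gene.span
    occupied[config.causal_chrom].append((s - 1000, e + 1000))

    for chrom in config.chrom_names:
        n_target = config.genes_per_chromosome - (
            1 if chrom == config.causal_chrom else 0
        )
        placed = 0
        attempts = 0
        while placed < n_target and attempts < 50 * n_target:
            attempts += 1
            plan = _plan_gene(rng, int(rng.integers(3, 9)))
            start = int(rng.integers(1, config.chrom_length_bp - plan.total_length))
            end = start + plan.total_length - 1
            if any(
                not (end < s or start > e) for s, e in occupied[chrom]
            ):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _materialize_gene(
                f"{chrom}_g{placed + 1:03d}",
                chrom,
                start,
                plan,
                strand,
                rng,
                arrays[chrom],
            )
            genes.append(gene)
            occupied[chrom].append((start - 1000, end + 1000))
            placed += 1

    genome = GenomeSequence(
        {c: a.tobytes().decode("ascii") for c, a in arrays.items()},
        validate=False,
    )
    return genome, genes, causal_gene.gene_id


def _new_gamete(config: CrossConfig, rng: np.random.Generator) -> Gamete:
    starts = {}
    breakpoints = {}
    for chrom in config.chrom_names:
        n_x = rng.poisson(config.recomb_rate)
        breakpoints[chrom] = np.sort(
            rng.uniform(0, config.chrom_length_bp, n_x)
        )
        starts[chrom] = int(rng.integers(0, 2))
    return Gamete(starts=starts, breakpoints=breakpoints)


def simulate_cross(config: CrossConfig = CrossConfig()) -> CrossResult:
    """Simulate the pooled-exome mapping experiment end to end.

    Returns the pooled variant calls (sorted by position), the truth record,
    and the synthetic reference (genome + gene models) the calls refer to.
    """
    from .genome_models import PooledVariant

    rng = np.random.default_rng(config.seed)
    genome, genes, causal_gene_id = _simulate_reference(config, rng)

    # --- variant sites ---------------------------------------------------
    # alt_strain: which parental haplotype carries the alt allele
    sites: dict[str, dict[int, int]] = {c: {} for c in config.chrom_names}
    enu_sites: set[tuple[str, int]] = set()
    L = config.chrom_length_bp
    for chrom in config.chrom_names:
        n_bg = rng.poisson(config.background_variant_density * L)
        for pos in np.unique(rng.integers(1, L + 1, n_bg)):
            sites[chrom][int(pos)] = int(rng.integers(0, 2))
        n_enu = rng.poisson(config.enu_variant_density * L)
        for pos in np.unique(rng.integers(1, L + 1, n_enu)):
            if int(pos) not in sites[chrom]:
                sites[chrom][int(pos)] = 1
                enu_sites.add((chrom, int(pos)))
    # the causal lesion: G>A at the donor site, on the mutagenized haplotype
    causal_ref = genome.base(config.causal_chrom, config.causal_pos)
    assert causal_ref == "G", "causal donor site must start with G"
    sites[config.causal_chrom][config.causal_pos] = 1
    enu_sites.add((config.causal_chrom, config.causal_pos))

    # --- larvae -----------------------------------------------------------
    larvae: list[LarvaTruth] = []

    def add_larva():
        gametes = (_new_gamete(config, rng), _new_gamete(config, rng))
        is_mut = all(
            g.phase_at(config.causal_chrom, config.causal_pos) == 1
            for g in gametes
        )
        larvae.append(LarvaTruth(gametes=gametes, is_mutant=bool(is_mut)))

    if config.n_f2_larvae is not None:
        for _ in range(config.n_f2_larvae):
            add_larva()
    n_extra = 0
    while (
        sum(l.is_mutant for l in larvae) < config.n_mutant_larvae
        or sum(not l.is_mutant for l in larvae) < config.n_wt_larvae
    ):
        add_larva()
        n_extra += 1
    if config.n_f2_larvae is not None and n_extra:
        log.info(
            "%d extra larvae simulated beyond the requested %d to fill pools",
            n_extra,
            config.n_f2_larvae,
        )

    mutant_pool = [i for i, l in enumerate(larvae) if l.is_mutant][
        : config.n_mutant_larvae
    ]
    wt_pool = [i for i, l in enumerate(larvae) if not l.is_mutant][
        : config.n_wt_larvae
    ]

    # --- pooled sequencing ------------------------------------------------
    variants = []
    alt_strain_out: dict[tuple[str, int], int] = {}
    true_af: dict[tuple[str, int], tuple[float, float]] = {}
    other = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for chrom in config.chrom_names:
        positions = np.array(sorted(sites[chrom]))
        if positions.size == 0:
            continue
        strain = np.array([sites[chrom][int(p)] for p in positions])
        pool_alt = {}
        for name, pool in (("wt", wt_pool), ("mut", mutant_pool)):
            alt_copies = np.zeros(positions.size, dtype=np.int64)
            for i in pool:
                for gamete in larvae[i].gametes:
                    alt_copies += gamete.phase_at(chrom, positions) == strain
            pool_alt[name] = alt_copies / (2 * len(pool))
        depth_wt = rng.poisson(config.mean_depth_per_pool, positions.size)
        depth_mut = rng.poisson(config.mean_depth_per_pool, positions.size)
        alt_wt = rng.binomial(depth_wt, pool_alt["wt"])
        alt_mut = rng.binomial(depth_mut, pool_alt["mut"])
        for j, pos in enumerate(positions):
            pos = int(pos)
            if chrom == config.causal_chrom and pos == config.causal_pos:
                ref, alt = causal_ref, "A"
            else:
                ref = genome.base(chrom, pos)
                alt = other[ref][int(rng.integers(0, 3))]
            variants.append(
                PooledVariant(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    wt_pool_depths=(int(depth_wt[j] - alt_wt[j]), int(alt_wt[j])),
                    mut_pool_depths=(
                        int(depth_mut[j] - alt_mut[j]),
                        int(alt_mut[j]),
                    ),
                )
            )
            alt_strain_out[(chrom, pos)] = int(strain[j])
            true_af[(chrom, pos)] = (
                float(pool_alt["wt"][j]),
                float(pool_alt["mut"][j]),
            )

    truth = CrossTruth(
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
        causal_ref=causal_ref,
        causal_alt="A",
        causal_gene_id=causal_gene_id,
        chrom_lengths={c: L for c in config.chrom_names},
        larvae=larvae,
        mutant_pool=mutant_pool,
        wt_pool=wt_pool,
        alt_strain=alt_strain_out,
        enu_sites=enu_sites,
        true_alt_freq=true_af,
        n_simulated=len(larvae),
    )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return CrossResult(variants=variants, truth=truth, genome=genome, genes=genes)


# ---------------------------------------------------------------------------
# RNA-seq counts


@dataclass(frozen=True)
class GeneClassSpec:
    """A planted expression class: n genes at one log2 fold change.

    ``log2fc = -inf`` plants transcripts extinguished in the mutant (zero
    expected fragments), the behaviour of photoreceptor genes in a larva
    that has lost its photoreceptors.  ``baseline`` fixes the wild-type mean
    fragment count of the class (None draws it from the global lognormal);
    strongly induced stress/apoptotic genes are basally low, which also keeps
    the planted mass a small fraction of the library.
    """

    label: str
    n_genes: int
    log2fc: float
    baseline: float | None = None


DEFAULT_CLASSES = (
    GeneClassSpec("apoptotic_up", 10, 4.2, baseline=30.0),
    GeneClassSpec("splicing_up", 5, 3.7, baseline=30.0),
    GeneClassSpec("vision_down", 3, float("-inf"), baseline=150.0),
)


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Planted structure of the two-library RNA-seq simulation.

    Baselines are lognormal with a floor so every gene is moderately covered;
    the causal gene gets a fixed high baseline plus its own planted
    upregulation, and a fraction of its fragments in the mutant library is
    diverted to intron-retention junctions.
    """

    n_genes: int = 2000
    classes: tuple[GeneClassSpec, ...] = DEFAULT_CLASSES
    causal_gene_id: str | None = None  # default: first gene in the list
    causal_log2fc: float = 3.35
    dispersion: float = 0.05
    library_sizes: tuple[float, float] = (1.0, 1.0)
    baseline_median: float = 150.0
    baseline_sigma: float = 0.6
    min_mean: float = 30.0
    causal_baseline: float = 300.0
    retention_fraction: float = 0.2
    retained_intron_index: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.library_sizes) <= 0:
            raise ValidationError("library sizes must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.retention_fraction <= 1:
            raise ValidationError("retention_fraction must be in [0, 1]")


@dataclass
class ExpressionTruth:
    planted_log2fc: dict[str, float]
    class_of: dict[str, str]
    causal_gene_id: str
    novel_junction_ids: list[str]
    retained_intron: tuple[str, int, int] | None


@dataclass
class CountsResult:
    gene_counts: CountMatrix
    junction_counts: CountMatrix
    truth: ExpressionTruth


def planted_effects(
    config: ExpressionSimConfig, genes: Sequence[GeneModel]
) -> tuple[dict[str, float], dict[str, str], str]:
    """Deterministic assignment of planted classes to gene ids.

    The causal gene takes ``causal_log2fc``; class genes are assigned in the
    order the gene list is given; everything else is null (log2fc 0).
    """
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValidationError("gene ids are not unique")
    causal = config.causal_gene_id or ids[0]
    if causal not in ids:
        raise ValidationError(f"causal gene {causal!r} not among gene models")
    needed = sum(c.n_genes for c in config.classes)
    if needed + 1 > len(ids):
        raise ValidationError(
            f"{needed} class genes + causal exceed {len(ids)} genes"
        )
    log2fc = {gid: 0.0 for gid in ids}
    class_of = {gid: "null" for gid in ids}
    log2fc[causal] = config.causal_log2fc
    class_of[causal] = "causal"
    pool = iter(gid for gid in ids if gid != causal)
    for spec in config.classes:
        for _ in range(spec.n_genes):
            gid = next(pool)
            log2fc[gid] = spec.log2fc
            class_of[gid] = spec.label
    return log2fc, class_of, causal


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial draws (var = m + a m^2); a = 0 is the exact mean."""
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return np.rint(means).astype(np.int64)
    out = np.zeros(means.shape, dtype=np.int64)
    nonzero = means > 0
    n = 1.0 / dispersion
    p = n / (n + means[nonzero])
    out[nonzero] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    config: ExpressionSimConfig,
    genes: Sequence[GeneModel],
) -> CountsResult:
    """Gene and junction count matrices with planted differential structure.

    Junction fragments for every annotated intron are drawn around the
    gene-level mean of their sample; at the causal gene's retained intron the
    mutant library diverts ``retention_fraction`` of the junction mean to two
    novel exon-boundary/intron-interior junctions (absent from the wild-type
    library and from the annotation).
    """
    if len(genes) < config.n_genes:
        raise ValidationError(
            f"{config.n_genes} genes requested but only {len(genes)} models"
        )
    genes = list(genes)[: config.n_genes]
    rng = np.random.default_rng(config.seed)
    log2fc, class_of, causal = planted_effects(config, genes)

    ids = [g.gene_id for g in genes]
    baselines = np.maximum(
        rng.lognormal(math.log(config.baseline_median), config.baseline_sigma, len(ids)),
        config.min_mean,
    )
    class_baseline = {
        c.label: c.baseline for c in config.classes if c.baseline is not None
    }
    for i, gid in enumerate(ids):
        if class_of[gid] in class_baseline:
            baselines[i] = class_baseline[class_of[gid]]
    baselines[ids.index(causal)] = config.causal_baseline
    fold = np.array([2.0 ** log2fc[gid] if np.isfinite(log2fc[gid]) else 0.0 for gid in ids])
    # rescale mutant intensities to the wild-type total: the two libraries
    # are sequenced to comparable depth regardless of composition.  FPKM is
    # scale-invariant, so the expected FPKM ratio is the planted fold divided
    # by the planted-mass factor sum(b*f)/sum(b); the low-baseline defaults of
    # the planted classes keep that factor within a few percent of 1.
    raw_mut = baselines * fold
    wt_means = baselines * config.library_sizes[0]
    mut_means = raw_mut * (baselines.sum() / raw_mut.sum()) * config.library_sizes[1]

    gene_counts = CountMatrix(
        feature_ids=ids,
        sample_ids=["wt", "mut"],
        counts=np.column_stack(
            [
                _draw_counts(rng, wt_means, config.dispersion),
                _draw_counts(rng, mut_means, config.dispersion),
            ]
        ),
    )

    # --- junctions --------------------------------------------------------
    jids: list[str] = []
    j_wt_means: list[float] = []
    j_mut_means: list[float] = []
    novel_ids: list[str] = []
    retained: tuple[str, int, int] | None = None
    r = config.retention_fraction
    for gi, g in enumerate(genes):
        introns = g.introns
        if g.gene_id == causal:
            if not introns:
                raise ValidationError(
                    f"causal gene {causal!r} has no introns to retain"
                )
            retained_index = min(config.retained_intron_index, len(introns) - 1)
        for ii, (istart, iend) in enumerate(introns):
            donor_end, acceptor_start = istart - 1, iend + 1
            jid = junction_id(g.chrom, donor_end, acceptor_start)
            wt_m, mut_m = wt_means[gi], mut_means[gi]
            if g.gene_id == causal and ii == retained_index and r > 0:
                retained = (g.chrom, istart, iend)
                mut_m = mut_m * (1 - r)
                ilen = iend - istart + 1
                mid = istart + max(1, ilen // 2)
                novel = [
                    junction_id(g.chrom, donor_end, mid),
                    junction_id(g.chrom, min(mid + 1, iend), acceptor_start),
                ]
                # each retention boundary is crossed by ~r of the gene's reads
                for nid in novel:
                    jids.append(nid)
                    j_wt_means.append(0.0)
                    j_mut_means.append(mut_means[gi] * r)
                novel_ids.extend(novel)
            jids.append(jid)
            j_wt_means.append(wt_m)
            j_mut_means.append(mut_m)

    junction_counts = CountMatrix(
        feature_ids=jids,
        sample_ids=["wt", "mut"],
        counts=np.column_stack(
            [
                _draw_counts(rng, np.array(j_wt_means), config.dispersion),
                _draw_counts(rng, np.array(j_mut_means), config.dispersion),
            ]
        ),
    )
    truth = ExpressionTruth(
        planted_log2fc=log2fc,
        class_of=class_of,
        causal_gene_id=causal,
        novel_junction_ids=novel_ids,
        retained_intron=retained,
    )
    return CountsResult(gene_counts, junction_counts, truth)


def random_gene_models(
    n_genes: int,
    seed: int = 0,
    n_exon_range: tuple[int, int] = (2, 5),
    exon_len: tuple[int, int] = (100, 400),
    intron_len: tuple[int, int] = (200, 1000),
    genes_per_chrom: int = 200,
) -> list[GeneModel]:
    """Quick gene models (no genome) for count-level simulations."""
    rng = np.random.default_rng(seed)
    genes = []
    pos, chrom_i = 1, 1
    for i in range(n_genes):
        if i and i % genes_per_chrom == 0:
            chrom_i += 1
            pos = 1
        plan = _plan_gene(
            rng, int(rng.integers(n_exon_range[0], n_exon_range[1] + 1)),
            exon_len, intron_len,
        )
        exons = []
        p = pos
        for k, elen in enumerate(plan.exon_lengths):
            exons.append((p, p + elen - 1))
            p += elen
            if k < len(plan.intron_lengths):
                p += plan.intron_lengths[k]
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}",
                chrom=f"sim{chrom_i}",
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                cds=(exons[0][0], exons[-1][1]),
            )
        )
        pos = p + int(rng.integers(500, 2000))
    return genes


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct(
    targets: Sequence[tuple[str, float]],
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    reference_gene: str = "actb1",
    calibrator_sample: str = "wt",
    test_sample: str = "mut",
    seed: int = 0,
) -> CtTable:
    """Ct replicate table with a planted ddCt per target gene.

    The reference gene cycles at a fixed mean in both samples; each target's
    test-sample mean is shifted by its planted ddCt relative to its
    calibrator-sample mean, so the ddCt estimator recovers the planted value
    exactly at zero noise.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(gene: str, sample: str, mean: float):
        for rep in range(1, n_replicates + 1):
            ct = mean + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {"gene": gene, "sample": sample, "replicate": rep, "ct": ct}
            )

    for sample in (calibrator_sample, test_sample):
        emit(reference_gene, sample, 18.0)
    for gene, planted_ddct in targets:
        base = float(rng.uniform(22.0, 27.0))
        emit(gene, calibrator_sample, base)
        emit(gene, test_sample, base + planted_ddct)

    return CtTable(data=pd.DataFrame(rows), reference_gene=reference_gene)
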