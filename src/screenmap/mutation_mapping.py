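"""Causal-mutation identification from pooled exome variant calls.

The mapping strategy is bulked segregant analysis on an F2 incross: larvae
homozygous for a recessive lesion are pooled and sequenced alongside a pool of
their phenotypically wild-type siblings.  Near the lesion the mutant pool is
homozygous for the mutagenized haplotype while the sibling pool still
segregates, so the fraction of variant sites that are homozygous-alternate in
the mutant pool *only* rises sharply.  Scoring that fraction in 1-Mb windows
along each chromosome localizes the lesion; the peak interval is then screened
for nonsense and essential-splice variants, and a splice-donor hit can be
followed through to the premature stop codon an unspliced (retained) intron
would introduce.

Zygosity thresholds for pooled data default to: a pool is called
homozygous-alternate at observed alt fraction >= 0.9, homozygous-reference at
<= 0.1, heterozygous in between, and no-call below 10 reads.  All thresholds
are parameters and are logged by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_models import (
    GeneModel,
    GenomeSequence,
    PooledVariant,
    ValidationError,
    revcomp,
)

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    """One-letter amino acid (or '*') for a codon, standard nuclear code."""
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for b1 in "TCAG":
            for b2 in "TCAG":
                for b3 in "TCAG":
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


# ---------------------------------------------------------------------------
# zygosity calls


@dataclass(frozen=True)
class ZygosityCall:
    """Per-pool zygosity states for one variant site.

    ``mutant_specific_hom`` is the BSA signal: the mutant pool is
    homozygous-alternate while the sibling pool is anything else (a
    heterozygous sibling pool is *compatible* with mutant specificity, since
    wild-type siblings of a recessive mutant may carry the allele).
    """

    variant: PooledVariant
    wt_state: str
    mut_state: str
    mutant_specific_hom: bool


def call_zygosity(
    v: PooledVariant,
    hom_alt_min_frac: float = 0.9,
    min_depth: int = 10,
) -> ZygosityCall:
    """Call pool zygosity states from allele depths.

    A pool is ``hom_alt`` at alt fraction >= ``hom_alt_min_frac``, ``hom_ref``
    at <= 1 - hom_alt_min_frac, ``nocall`` below ``min_depth`` reads, and
    ``het`` otherwise.  The heterozygous band is the complement of the
    homozygous ones, so a single threshold controls both.
    """
    if not 0.5 < hom_alt_min_frac < 1:
        raise ValueError("hom_alt_min_frac must be in (0.5, 1)")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")

    def pool_state(pool: str) -> str:
        if v.depth(pool) < min_depth:
            return "nocall"
        af = v.alt_fraction(pool)
        if af >= hom_alt_min_frac:
            return "hom_alt"
        if af <= 1 - hom_alt_min_frac:
            return "hom_ref"
        return "het"

    wt_state = pool_state("wt")
    mut_state = pool_state("mut")
    specific = (
        mut_state == "hom_alt"
        and wt_state not in ("hom_alt", "nocall")
    )
    return ZygosityCall(v, wt_state, mut_state, specific)


def select_mutant_pool_variants(
    calls: Sequence[ZygosityCall],
) -> list[ZygosityCall]:
    """Restrict calls to sites that are variant in the mutant pool.

    A pooled caller reports, for the mutant pool, only sites where that pool
    shows the alternate allele; sites homozygous-reference in the mutant pool
    belong to the sibling pool's list alone.  Scoring windows over the mutant
    pool's list is what makes the linked block stand out at ~100%: within it
    every mutant-pool variant is homozygous, whereas scoring over the joint
    segregating-site list caps the signal near 50% and adds multi-Mb noise
    from the fraction of sites whose alternate allele happens to ride the
    mutagenized haplotype.
    """
    return [c for c in calls if c.mut_state in ("het", "hom_alt")]


# ---------------------------------------------------------------------------
# windowed homozygosity profile


@dataclass(frozen=True)
class Peak:
    """The mapping peak: contiguous run of windows at (or near) the maximum."""

    chrom: str
    start: int
    end: int
    score: float
    n_windows: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class HomozygosityProfile:
    """Per-window mutant-specific homozygosity scores on one chromosome.

    ``scores`` are percentages in [0, 100]; windows with fewer than
    ``min_variants`` calls carry NaN and are excluded from peak search.
    ``peak`` is the genome-wide peak, shared across chromosomes of one scan.
    """

    chrom: str
    window_starts: np.ndarray
    window_size: int
    scores: np.ndarray
    n_variants: np.ndarray
    peak: Peak | None = None


def homozygosity_profile(
    calls: Sequence[ZygosityCall],
    window_size: int = 1_000_000,
    step: int = 100_000,
    min_variants: int = 5,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, HomozygosityProfile]:
    """Sliding-window percentage of mutant-specific homozygous variants.

    For each window the score is ``100 * n_specific / n_calls`` over the calls
    whose position falls in the window; the per-window call count is the
    denominator, which keeps the score bounded and robust to depth and variant
    density.  The genome-wide peak (attached to every returned profile) is
    found by :func:`find_peak`.
    """
    if not (window_size >= step >= 1):
        raise ValueError("need window_size >= step >= 1")
    profiles: dict[str, HomozygosityProfile] = {}
    by_chrom: dict[str, list[ZygosityCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.variant.chrom, []).append(c)

    for chrom, chrom_calls in sorted(by_chrom.items()):
        pos = np.array([c.variant.pos for c in chrom_calls])
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        spec = np.array(
            [chrom_calls[i].mutant_specific_hom for i in order], dtype=float
        )
        spec_cum = np.concatenate([[0.0], np.cumsum(spec)])
        extent = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(pos[-1])
        )
        starts = np.arange(1, max(extent - window_size + 2, 2), step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size - 1, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = 100.0 * (spec_cum[hi] - spec_cum[lo]) / n
        scores[n < min_variants] = np.nan
        profiles[chrom] = HomozygosityProfile(
            chrom=chrom,
            window_starts=starts,
            window_size=window_size,
            scores=scores,
            n_variants=n,
        )

    peak = find_peak(profiles)
    for p in profiles.values():
        p.peak = peak
    return profiles


def find_peak(
    profiles: Mapping[str, HomozygosityProfile],
    tie_tolerance: float | None = None,
) -> Peak | None:
    """Genome-wide peak over a set of per-chromosome profiles.

    The peak is the contiguous run of windows, through the genome-wide
    maximum-score window, whose scores come within ``tie_tolerance``
    percentage points of the maximum.  The score of the best window is the
    percentage of a few hundred variant calls at most, so its location
    carries binomial sampling noise; the default tolerance (two binomial
    standard errors of the max window's score) merges the statistically
    indistinguishable plateau around the maximum into one interval instead
    of reporting an arbitrarily placed single window.  Exact ties always
    fall inside the run.  Returns None when no window is eligible or no
    window scores above zero.
    """
    best = -np.inf
    best_chrom: str | None = None
    best_idx = -1
    for chrom in sorted(profiles):
        p = profiles[chrom]
        if p.scores.size == 0 or np.all(np.isnan(p.scores)):
            continue
        idx = int(np.nanargmax(p.scores))
        if p.scores[idx] > best:
            best = float(p.scores[idx])
            best_chrom, best_idx = chrom, idx
    if best_chrom is None or best <= 0:
        return None

    p = profiles[best_chrom]
    if tie_tolerance is None:
        # binomial SE of the max window's score with an Agresti-Coull
        # adjustment so a 100% window still carries finite uncertainty
        n = max(int(p.n_variants[best_idx]), 1)
        s = (best / 100.0 * n + 2) / (n + 4)
        tie_tolerance = 2 * 100.0 * np.sqrt(s * (1 - s) / n)
    threshold = best - tie_tolerance

    def in_run(i: int) -> bool:
        return (
            0 <= i < p.scores.size
            and not np.isnan(p.scores[i])
            and p.scores[i] >= threshold
        )

    lo = hi = best_idx
    while in_run(lo - 1):
        lo -= 1
    while in_run(hi + 1):
        hi += 1
    return Peak(
        chrom=best_chrom,
        start=int(p.window_starts[lo]),
        end=int(p.window_starts[hi]) + p.window_size - 1,
        score=best,
        n_windows=hi - lo + 1,
    )


# ---------------------------------------------------------------------------
# variant effect classification


@dataclass(frozen=True)
class VariantEffect:
    """Predicted consequence of one SNV on (at most) one gene.

    ``category`` is one of nonsense, essential_splice, missense, synonymous,
    intronic, intergenic, assigned with precedence
    essential_splice > nonsense > missense > synonymous > intronic.
    ``detail`` carries site-specific context such as the donor-site offset or
    the affected codon.
    """

    variant: PooledVariant
    gene_id: str | None
    category: str
    detail: str = ""


class ReferenceMismatchError(ValidationError):
    """The variant's stated reference allele disagrees with the genome."""


_PRECEDENCE = {
    "essential_splice": 0,
    "nonsense": 1,
    "missense": 2,
    "synonymous": 3,
    "intronic": 4,
    "intergenic": 5,
}


def _splice_site_detail(gene: GeneModel, pos: int) -> str | None:
    """If pos is in the first/last 2 bases of an intron, describe the site.

    Donor and acceptor are named on the coding strand: the donor is the first
    two intronic bases 5' of the intron (canonical GT), the acceptor the last
    two (canonical AG).
    """
    for idx, (istart, iend) in enumerate(gene.introns):
        if iend - istart + 1 < 4:
            continue  # degenerate intron, no canonical sites
        if gene.strand == "+":
            donor = {istart: 1, istart + 1: 2}
            acceptor = {iend: 1, iend - 1: 2}
        else:
            donor = {iend: 1, iend - 1: 2}
            acceptor = {istart: 1, istart + 1: 2}
        if pos in donor:
            return f"intron{idx + 1}_donor_site_offset={donor[pos]}"
        if pos in acceptor:
            return f"intron{idx + 1}_acceptor_site_offset={acceptor[pos]}"
    return None


def _coding_index(gene: GeneModel, pos: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS, or None."""
    intervals = gene.coding_intervals()
    if gene.strand == "-":
        offset = 0
        for s, e in reversed(intervals):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
        return None
    offset = 0
    for s, e in intervals:
        if s <= pos <= e:
            return offset + (pos - s)
        offset += e - s + 1
    return None


def _effect_in_gene(
    v: PooledVariant, gene: GeneModel, genome: GenomeSequence
) -> VariantEffect:
    detail = _splice_site_detail(gene, v.pos)
    if detail is not None:
        return VariantEffect(v, gene.gene_id, "essential_splice", detail)

    idx = _coding_index(gene, v.pos)
    if idx is not None:
        cds = gene.coding_sequence(genome)
        codon_i = idx // 3
        within = idx % 3
        ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_base = v.alt_allele if gene.strand == "+" else revcomp(v.alt_allele)
        alt_codon = (
            ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        )
        detail = f"codon{codon_i + 1}:{ref_codon}>{alt_codon}"
        if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
            return VariantEffect(v, gene.gene_id, "nonsense", detail)
        if _translate_codon(alt_codon) == _translate_codon(ref_codon):
            return VariantEffect(v, gene.gene_id, "synonymous", detail)
        return VariantEffect(v, gene.gene_id, "missense", detail)

    for s, e in gene.introns:
        if s <= v.pos <= e:
            return VariantEffect(v, gene.gene_id, "intronic", "")
    # inside the gene span but neither coding nor intronic (noncoding exon)
    return VariantEffect(v, gene.gene_id, "intronic", "noncoding_exonic")


def classify_effect(
    v: PooledVariant,
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
) -> VariantEffect:
    """Classify one SNV against gene models, highest-impact category wins.

    Raises :class:`ReferenceMismatchError` if the variant's reference allele
    does not match the genome base at its position.
    """
    genome_base = genome.base(v.chrom, v.pos)
    if genome_base != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} ref allele {v.ref_allele} disagrees with "
            f"genome base {genome_base}"
        )
    effects = [
        _effect_in_gene(v, g, genome)
        for g in genes
        if g.chrom == v.chrom and g.contains(v.pos)
    ]
    if not effects:
        return VariantEffect(v, None, "intergenic", "")
    return min(effects, key=lambda e: _PRECEDENCE[e.category])


def screen_candidates(
    peak: Peak | None,
    calls: Iterable[ZygosityCall],
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
) -> list[VariantEffect]:
    """Nonsense / essential-splice candidates inside the mapping peak.

    Only mutant-specific homozygous variants within the peak interval are
    classified; the returned effects are sorted by position.
    """
    if peak is None:
        return []
    out = []
    for c in calls:
        if not c.mutant_specific_hom:
            continue
        if not peak.contains(c.variant.chrom, c.variant.pos):
            continue
        eff = classify_effect(c.variant, genes, genome)
        if eff.category in ("nonsense", "essential_splice"):
            out.append(eff)
    out.sort(key=lambda e: e.variant.pos)
    return out


# ---------------------------------------------------------------------------
# intron-retention consequence


@dataclass(frozen=True)
class RetentionConsequence:
    """First in-frame stop introduced by retaining one intron in the mRNA."""

    gene_id: str
    intron_index: int
    ptc_found: bool
    ptc_codon: str | None
    ptc_genomic_pos: int | None
    truncated_protein_length: int | None


def retention_consequence(
    gene: GeneModel,
    intron_index: int,
    genome: GenomeSequence,
) -> RetentionConsequence:
    """Translate through a retained intron and report the first stop codon.

    The transcript is rebuilt with intron ``intron_index`` (0-based, in
    transcript order) left unspliced, and translation proceeds in the CDS
    reading frame.  A premature termination codon is reported if the first
    stop encountered overlaps the retained intron; if translation runs through
    the intron without a stop, ``ptc_found`` is False.
    ``truncated_protein_length`` counts the codons preceding the stop.
    """
    if gene.cds is None:
        raise ValidationError(f"{gene.gene_id}: gene has no CDS")
    introns = gene.introns
    n_introns = len(introns)
    if not 0 <= intron_index < n_introns:
        raise ValueError(
            f"intron index {intron_index} invalid for {gene.gene_id} "
            f"({n_introns} introns)"
        )
    # transcript order: genomic order for +, reversed for -
    genomic_intron = (
        introns[intron_index]
        if gene.strand == "+"
        else introns[n_introns - 1 - intron_index]
    )

    # assemble transcript pieces (genomic order), marking the retained intron
    pieces: list[tuple[int, int, bool]] = []
    for i, (s, e) in enumerate(gene.exons):
        pieces.append((s, e, False))
        if i < n_introns and introns[i] == genomic_intron:
            pieces.append((genomic_intron[0], genomic_intron[1], True))
    if gene.strand == "-":
        pieces = pieces[::-1]

    tx_seq_parts: list[str] = []
    tx_pos_parts: list[np.ndarray] = []
    intron_tx: list[int] = []
    offset = 0
    for s, e, is_intron in pieces:
        seq = genome.fetch(gene.chrom, s, e)
        positions = np.arange(s, e + 1)
        if gene.strand == "-":
            seq = revcomp(seq)
            positions = positions[::-1]
        if is_intron:
            intron_tx = [offset, offset + len(seq) - 1]
        tx_seq_parts.append(seq)
        tx_pos_parts.append(positions)
        offset += len(seq)
    tx = "".join(tx_seq_parts)
    tx2genome = np.concatenate(tx_pos_parts)

    # CDS start in transcript coordinates: first coding base on coding strand
    cds_first_genomic = (
        gene.coding_intervals()[0][0]
        if gene.strand == "+"
        else gene.coding_intervals()[-1][1]
    )
    cds_start_tx = int(np.nonzero(tx2genome == cds_first_genomic)[0][0])
    if intron_tx[0] < cds_start_tx:
        # intron upstream of the CDS: retention cannot truncate the protein
        return RetentionConsequence(
            gene.gene_id, intron_index, False, None, None, None
        )

    i_lo, i_hi = intron_tx
    for codon_i in range((len(tx) - cds_start_tx) // 3):
        c_start = cds_start_tx + 3 * codon_i
        codon = tx[c_start : c_start + 3]
        if c_start > i_hi:
            break  # past the retained intron without a stop
        if c_start + 2 < i_lo:
            continue  # still fully exonic upstream of the intron
        if codon in STOP_CODONS:
            return RetentionConsequence(
                gene_id=gene.gene_id,
                intron_index=intron_index,
                ptc_found=True,
                ptc_codon=codon,
                ptc_genomic_pos=int(tx2genome[c_start]),
                truncated_protein_length=codon_i,
            )
    return RetentionConsequence(
        gene.gene_id, intron_index, False, None, None, None
    )


# ---------------------------------------------------------------------------
# recombinant counting against the simulated truth


def count_recombinants(
    truth,
    marker_pos: int,
    causal_pos: int | None = None,
    n_larvae: int | None = None,
) -> tuple[int, int]:
    """Count recombinant meioses between a marker and the causal lesion.

    ``truth`` is the :class:`~screenmap.synthetic_data.CrossTruth` from
    :func:`~screenmap.synthetic_data.simulate_cross`.  Each larva contributes
    two meioses (one gamete per parent); a meiosis is recombinant iff the
    transmitted haplotype derives the marker allele and the causal allele from
    different parental haplotypes.  Returns ``(n_recombinant, n_meioses)``.
    """
    chrom = truth.causal_chrom
    if causal_pos is None:
        causal_pos = truth.causal_pos
    length = truth.chrom_lengths[chrom]
    if not 1 <= marker_pos <= length:
        raise ValueError(
            f"marker position {marker_pos} outside {chrom} (length {length})"
        )
    larvae = truth.larvae if n_larvae is None else truth.larvae[:n_larvae]
    if n_larvae is not None and len(larvae) < n_larvae:
        raise ValueError(
            f"truth record holds {len(truth.larvae)} larvae, "
            f"{n_larvae} requested"
        )
    n_rec = 0
    for larva in larvae:
        for gamete in larva.gametes:
            if gamete.phase_at(chrom, marker_pos) != gamete.phase_at(
                chrom, causal_pos
            ):
                n_rec += 1
    return n_rec, 2 * len(larvae)


def plot_profile(
    profiles: Mapping[str, HomozygosityProfile],
    path: str | Path | None = None,
    highlight: tuple[str, int] | None = None,
):
    """Plot windowed homozygosity scores per chromosome (Fig-2B style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(profiles)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        p = profiles[chrom]
        centers = p.window_starts + p.window_size // 2
        ax.plot(centers / 1e6, p.scores, lw=1)
        if p.peak and p.peak.chrom == chrom:
            ax.axvspan(p.peak.start / 1e6, p.peak.end / 1e6, alpha=0.2)
        if highlight and highlight[0] == chrom:
            ax.axvline(highlight[1] / 1e6, color="red", lw=0.8, ls="--")
        ax.set_ylabel("% mutant-specific hom")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
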