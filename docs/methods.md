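# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know about.

## Coordinate and format conventions

All coordinates are 1-based closed intervals (the GFF3 convention); BED
export is the single conversion point to 0-based half-open, and the
conversion round-trips exactly. Variants are biallelic SNVs only —
multi-allelic and indel records are dropped (with a logged count) on input,
because the candidate screen targets point mutations; whether upstream
callers would have contributed indel candidates is unknowable from our
inputs, so the restriction is explicit rather than silent. VCF is read
through pysam, GFF3 through gffutils, FASTA through Biopython.

## The F2 cross model

Two F1 parents are heterozygous genome-wide for a mutagenized-strain
haplotype and a mapping-strain haplotype. Each gamete receives a Poisson
number of crossovers per chromosome (default 1.0, about right for a 25-Mb
zebrafish chromosome) placed uniformly, with no interference — at 1-Mb
window resolution interference is irrelevant. A larva is mutant iff both
gametes carry the mutagenized haplotype at the causal position, so mutants
arise at the Mendelian 25%.

Variant sites come in two flavours: strain-difference heterozygosities
(default density 1 per 5 kb; zebrafish laboratory strains are highly
polymorphic and exome variant lists run to thousands of sites per
chromosome), whose alternate allele rides either haplotype with equal
probability, and a sparser load of mutagen-induced variants (1 per Mb)
private to the mutagenized haplotype. The causal lesion is always a G→A at
the first base of a splice-donor GT; the synthetic causal gene is built with
13 exons and the lesion at the donor of intron 12, and the retained intron
carries an in-frame TAA a few bases in, so the splice-consequence stage has
a real premature stop to find.

Pooled sequencing draws per-site depth Poisson (default mean 30 per pool)
and allele counts binomially at the pool allele frequency of the 40 selected
haplotypes. Pools default to 20 mutant and 20 wild-type sibling larvae;
`n_f2_larvae` instead genotypes a fixed-size family (e.g. 225 larvae = 450
scorable meioses) with the pools drawn from it, which is what the
recombinant-counting check uses.

What the simulator does **not** emulate: read-level artefacts (mapping bias,
duplicates, base errors folded into depth sampling only), exome capture
geometry (variant positions are uniform, not exon-concentrated), crossover
interference, and segregation distortion. Passing the recovery suite
therefore says the *algorithmic* chain is sound under idealised sampling,
not that real exome noise is handled.

## Zygosity calls and the windowed score

A pool is homozygous-alternate at observed alt fraction ≥ 0.9,
homozygous-reference at ≤ 0.1, no-call below 10 reads, heterozygous in
between; the single `hom_alt_min_frac` threshold defines both homozygous
bands (its complement bounds the het band), and all thresholds are logged by
the CLI. A no-call in either pool vetoes mutant specificity. A heterozygous
sibling pool is *compatible* with mutant specificity: two-thirds of
phenotypically wild-type siblings of a recessive mutant carry the allele.

The window score is the percentage of mutant-specific homozygous variants
among the variants in the window — the per-window variant count as
denominator keeps the score in [0, 100] and robust to depth and density.
Windows are sliding (default 1 Mb wide, 100-kb step; both configurable,
tiled scoring is step = width) and windows with fewer than 5 variants are
excluded from peak search.

Two choices matter for peak quality:

* **Which calls are profiled.** The pipeline scores the *mutant pool's*
  variant list (sites het or hom-alt in the mutant pool) — a pooled caller
  reports for each pool only the sites where that pool shows the alternate
  allele. Inside the linked block every mutant-pool variant is homozygous,
  so the block scores ~100%. Profiling the joint segregating-site list
  instead caps the score near 50% (only sites whose alternate allele rides
  the mutagenized haplotype can be mutant-specific) and adds multi-Mb noise
  from the local fraction of such sites, which is enough to misplace a
  single-window argmax by 1–3 Mb.
* **Peak extent.** With 40 meioses the homozygous block has a flat top
  often >2 Mb wide, and the literal argmax window is an arbitrary point on
  it. The reported peak is therefore the contiguous window run, through the
  argmax, whose scores lie within a tolerance of the maximum; the default
  tolerance is two binomial standard errors of the max window's score, with
  an Agresti–Coull adjustment so a 100% window still carries finite
  uncertainty. Exact ties always fall inside the run. A profile whose best
  score is 0 has no peak.

Candidate screening classifies mutant-specific homozygous variants inside
the peak with precedence essential_splice > nonsense > missense >
synonymous > intronic, where essential-splice means the first/last two
intronic bases on the coding strand and coding consequences are computed by
splicing, substituting and translating the affected codon (standard nuclear
code; stops TAA/TAG/TGA). Exonic positions outside the CDS are reported
under `intronic` with detail `noncoding_exonic` — the category enum is
deliberately small and synthetic genes have CDS spanning all exons.
`retention_consequence` rebuilds the transcript with one intron unspliced
and translates the CDS frame through it; the premature stop is reported only
if the first stop encountered overlaps the retained intron (a run-through
translates into the downstream exons and is reported as no PTC).

## Expression quantification

FPKM follows the duplication-aware definition exactly: counts are accepted
as already collapsed per gene id (the multi-locus paralog collapse is a
counting-time rule that lives at the table boundary), `F_allexon` is the
column sum — identical by construction to "total exonic fragments" for
exon-union gene counts — and `L_g` is the unique exonic base count. The
identity Σ FPKM·L/10⁹ = 1 per sample holds to machine precision and is
asserted in the suite.

Fold changes use `log2((mut + ε)/(wt + ε))` with ε = 10⁻⁶ FPKM; records
with a zero count on either side are flagged so pseudocount-driven
magnitudes are interpretable. We do not attempt to reproduce any particular
extreme printed log-ratio for an extinguished transcript, since the
upstream handling of zeros (pseudocount, floor, or raw division) is not
recoverable; the flag plus the expressed filter carries the same
information. No p-values are emitted: with one library per condition there
is no replicate-based statistic to compute, and the method is pure fold
change by design. Rankings apply the strict FPKM > 0.1 in-both-samples
filter first and break ties by gene id.

The count generator plants per-class log2 fold changes (defaults: 10
apoptosis-class genes at +4.2, 5 spliceosome-class genes at +3.7, 3
vision-class genes extinguished in the mutant, the causal gene itself at
+3.35 over a fixed 300-fragment baseline) on negative-binomial counts with
dispersion 0.05 (var = m + 0.05 m²; dispersion 0 yields the rounded means
exactly). Baselines are lognormal (median 150, σ 0.6) floored at 30
fragments so every gene is moderately covered; the induced classes get a low
30-fragment basal level, which is both biologically sensible for
stress-response genes and keeps the planted mass ~3% of the library. That
matters because FPKM is compositional: expected FPKM ratios equal the
planted folds only up to the factor Σb·f/Σb, so all recovered log2 ratios
carry a shared ≈ −0.04 offset under the defaults — which is why recovery is
assessed as per-class means (pooled over 10 seeds) within ±0.3, not per-gene
maxima: at 30 fragments a single gene's log-ratio has sampling sd ≈ 0.4,
so a per-gene ±0.3 bound is unattainable under any honest noise model.
Mutant intensities are rescaled to the wild-type total (libraries are
sequenced to comparable depth regardless of composition).

## Junction screen

RPM is count × 10⁶ / total junction fragments of the sample. A junction is
known iff both boundaries exactly match an annotated intron. The candidate
filter is the conjunction of all four stated predicates (each independently
configurable): mean-of-log intensity (the alternative log-of-mean is
exposed via config, the choice between them being genuinely open),
absolute log2 ratio (so down-used junctions are candidates too; no
direction convention is imposed), fold change computed larger-over-smaller
with the pseudocount, and arithmetic mean RPM. The pseudocount is 0.5 RPM.
An upstream low-count/voom-style normalisation step is *not* reimplemented;
its role is taken by a ≥ 5 fragments in-at-least-one-sample prefilter, and
RPM is the normalisation actually used for candidate selection. The
generator plants retention as two novel junctions (exon boundary → intron
midpoint, intron interior → next exon start) carrying the retention
fraction (default 0.2) of the causal gene's mutant-library junction mean,
with the annotated junction reduced in proportion.

## qPCR

ddCt assumes ideal doubling (efficiency 2, no standard-curve correction).
ΔCt is the mean-over-replicates difference gene − reference per sample,
ΔΔCt = ΔCt(test) − ΔCt(calibrator), fold = 2^(−ΔΔCt). The standard error
treats each replicate index as one independent round of the *full*
statistic — per-round folds are computed and their SE reported — which is
the natural reading of "mean of n rounds with standard error"; rounds
missing any of the four Ct values are dropped with a warning (error if none
remain). `normalize_folds` shifts folds by the reference gene's fold so the
reference sits at zero; with self-calibration the reference fold is exactly
1 and normalized = fold − 1. Self-calibration fold 1 and reciprocal-fold
product 1 are exact identities asserted to 10⁻¹². The Ct generator places
the reference at 18 cycles, targets uniformly in 22–27 cycles, and adds
Gaussian replicate noise; it supports either a technical- or
biological-replicate reading of the rounds via its noise parameter.

Phenotype proportions (rescue scoring) report the percentage with a Wilson
95% interval (statsmodels); the interval is an addition for convenience —
the underlying scoring is a plain category count over larvae screened.

## Problem sizes in the validation suite

The default acceptance-scale runs use 3 × 25-Mb chromosomes (one genome in
miniature: enough for one linked and two unlinked chromosomes), 20-seed
sweeps for mapping and junction recovery, 10 seeds × 2000 genes for
expression recovery, and 100 random tables for the FPKM oracle. These sizes
give binomial noise well inside the asserted margins while the full suite
and the acceptance script each complete in well under a minute.

## Known limitations

* The mapping stage consumes variant calls, not reads; caller-specific
  artefacts (strand bias, clustered errors) are out of scope.
* Effect classification covers SNVs only and does not annotate UTR or
  regulatory consequences; protein-domain interpretation of truncations is
  out of scope.
* The junction screen does not extract junctions from alignments and does
  not reimplement voom; it operates on supplied junction counts.
* Fold-change DE with n = 1 per condition has no error control by
  construction; results are rankings, not inferences.
* Enrichment analysis (GO/KEGG) is out of scope — it depends on external
  databases.
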