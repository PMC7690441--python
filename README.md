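# screenmap

Computational pipeline for identifying a causal mutation from a zebrafish
forward-genetic screen and characterising its downstream effects — built for
the common situation where a recessive, larval-lethal ENU point mutation has
been isolated, pools of mutant and wild-type sibling F2 larvae have been
exome-sequenced, and RNA-seq plus qPCR follow-up data exist for one
wild-type and one mutant library.

It is aimed at genetics labs running mapping-by-sequencing (bulked segregant
analysis) crosses, and at anyone who needs a fully synthetic, seeded test bed
for such a pipeline: every input the analyses consume can be generated by the
built-in simulators, so the whole pipeline is testable without any sequencing
data.

## What it computes

**Homozygosity mapping.** For pooled variant calls (VCF with per-pool allele
depths), each site is given pool zygosity states from its observed alternate
allele fraction, and each 1-Mb sliding window is scored as

```
score = 100 x (# mutant-specific homozygous variants) / (# variants in window)
```

over the mutant pool's variant list. A variant is *mutant-specific
homozygous* when the mutant pool is homozygous-alternate and the sibling pool
is not (heterozygous siblings are expected — they carry the recessive
allele). Linkage to the lesion shows up as a window run scoring near 100%;
the peak interval is then screened for nonsense and essential-splice
(±2 bp intron-edge) variants, and a splice-donor hit can be followed through
`retention_consequence`, which translates the unspliced transcript and
reports the premature stop codon a retained intron introduces.

**Expression quantification.** A duplication-aware FPKM in which fragments
mapping to any exonic copy of a gene are collapsed into one count:

```
FPKM_g = F_g x 1000 x 1,000,000 / (F_allexon x L_g)
```

with `F_g` the gene's fragment count, `F_allexon` the sample's total exonic
fragments and `L_g` the gene's unique exonic length. With one library per
condition, differential expression is purely the mutant/wild-type fold change
(no p-values), with an `FPKM > 0.1` in-both-samples filter defining the
expressed set for top-N rankings.

**Splice-junction screen.** Junction counts are normalised to reads per
million, flagged novel when they do not exactly match an annotated intron,
and kept as candidates when all four predicates hold: mean log2(RPM + 0.5)
intensity > 2, |log2 ratio| > 2, fold change > 4, mean RPM > 4. Intron
retention appears as novel exon-boundary-to-intron-interior junctions in the
mutant library only.

**qPCR quantification.** Comparative-Ct (ddCt) with fold = 2^(−ΔΔCt)
against a reference gene, standard errors across replicate rounds, a
reference-zero normalisation (`normalized = fold − 1`), and a Wilson-CI
phenotype-proportion score for mRNA-rescue experiments.

**Synthetic data.** Seeded generators for (i) an F2 incross segregating a
recessive splice-donor G→A lesion — recombining gametes, strain-difference
and mutagen-private variants, pooled sequencing depth — together with the
synthetic reference genome and gene models the calls refer to; (ii) RNA-seq
gene/junction counts with planted per-class fold changes and intron-retention
junctions at the causal gene; (iii) Ct tables with planted ΔΔCt structure.
Each generator returns a truth record so recovery can be measured.

## Worked example

Simulate a small cross and map the lesion (the planted donor site is at
chr1:4,000,000):

```bash
$ cat cross.yaml
n_chromosomes: 2
chrom_length_bp: 8000000
causal_chrom: chr1
causal_pos: 4000000
genes_per_chromosome: 12

$ screenmap simulate cross --config cross.yaml --seed 42 --out sim/
wrote 3329 variants for 76 larvae to sim

$ screenmap map --vcf sim/pools.vcf --gff sim/genes.gff3 --fasta sim/genome.fa --out map/
peak chr1:3100001-4700000 (score 91.4), 1 candidate(s)

$ cat map/candidates.tsv
chrom   pos      ref  alt  gene         category          detail
chr1    4000000  G    A    causal_gene  essential_splice  intron12_donor_site_offset=1
```

The peak is a 1.6-Mb interval whose windows score 91% mutant-specific
homozygosity, and the single nonsense/essential-splice candidate inside it is
the planted G→A at the first base of intron 12 — the mapping outcome the
pipeline is designed to reach.

ddCt on a simulated Ct table (planted ΔΔCt of −1.65 for *tp53* and +4.32
for *crx*, replicate noise 0.05 cycles):

```bash
$ screenmap simulate ct --config ct.yaml --seed 7 --out ct.tsv
$ screenmap ddct --ct ct.tsv --out folds.tsv
$ cat folds.tsv
gene_id  ddct    fold    normalized  se      n_rounds
actb1    0.000   1.000    0.000      0.000   3
crx      4.310   0.050   -0.950      0.0015  3
tp53    -1.599   3.028    2.028      0.0525  3
```

`fold` is 2^(−ΔΔCt); `normalized` shifts folds so the reference gene sits at
zero, which is how confirmed up/down panels are usually reported — *crx*
lands at −0.95 (near-complete loss) and *tp53* at +2.0 (three-fold up).

The other stages run the same way: `screenmap simulate counts` →
`screenmap fpkm` → `screenmap de`, and `screenmap junctions` for the
splice-junction screen. Everything is also importable as a library; see the
module docstrings in `src/screenmap/`.

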