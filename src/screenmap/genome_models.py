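"""Shared domain types and text-format I/O.

Coordinates are 1-based closed intervals everywhere in this package, matching
GFF3 and the usual "position" language of variant tables.  BED export is the
single place where conversion to 0-based half-open coordinates happens, and
converting there and back is the identity (see :func:`interval_to_bed` /
:func:`bed_to_interval`).

The types here are the substrate for every analysis stage:

* :class:`GenomeSequence` -- chromosomes of uppercase DNA, any assembly real
  or synthetic.
* :class:`GeneModel` -- exon/intron/CDS structure of one gene.
* :class:`PooledVariant` -- one biallelic SNV with per-pool allele depths
  (wild-type-sibling pool and mutant pool of an F2 incross).
* :class:`CountMatrix` -- feature x sample fragment counts (genes or splice
  junctions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_VALID_DNA = re.compile(r"[^ACGTN]")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


class ParseError(ValueError):
    """An input file could not be parsed as the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coordinate conversion


def interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based closed interval -> 0-based half-open (BED) interval."""
    return start - 1, end


def bed_to_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (BED) interval -> 1-based closed interval."""
    return start + 1, end


# ---------------------------------------------------------------------------
# genome


class GenomeSequence:
    """Ordered chromosomes of uppercase DNA (alphabet ACGTN).

    Lookups are 1-based and closed; out-of-range access raises
    :class:`ValidationError`.
    """

    def __init__(self, sequences: Mapping[str, str], validate: bool = True):
        if not sequences:
            raise ValidationError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if len(seq) < 1:
                raise ValidationError(f"chromosome {name!r} has length 0")
            if validate and _VALID_DNA.search(seq):
                raise ValidationError(
                    f"chromosome {name!r} contains characters outside ACGTN"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def base(self, chrom: str, pos: int) -> str:
        """The single base at 1-based ``pos``."""
        seq = self._seq(chrom)
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"position {chrom}:{pos} outside chromosome (length {len(seq)})"
            )
        return seq[pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the closed interval [start, end]."""
        seq = self._seq(chrom)
        if not (1 <= start <= end <= len(seq)):
            raise ValidationError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    # -- FASTA I/O (Biopython) ------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ParseError(f"no FASTA records in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron/CDS structure of one gene on the genomic (+) axis.

    ``exons`` are 1-based closed intervals sorted by start and non-overlapping;
    ``cds`` is a single genomic interval whose intersection with the exons is
    the coding region (spliced coding length must be a positive multiple of 3).
    Introns are always derived as the gaps between consecutive exons.  Exons
    are stored in genomic order regardless of strand; minus-strand genes are
    reverse-complemented only when a transcript sequence is extracted.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene must have >= 1 exon")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = 0
        for start, end in self.exons:
            if start > end or start < 1:
                raise ValidationError(
                    f"{self.gene_id}: bad exon interval [{start}, {end}]"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted at "
                    f"[{start}, {end}]"
                )
            prev_end = end
        if self.cds is not None:
            cs, ce = self.cds
            if cs > ce:
                raise ValidationError(f"{self.gene_id}: bad CDS interval")
            if cs < self.exons[0][0] or ce > self.exons[-1][1]:
                raise ValidationError(
                    f"{self.gene_id}: CDS [{cs}, {ce}] outside exon span"
                )
            clen = self.coding_length
            if clen == 0:
                raise ValidationError(
                    f"{self.gene_id}: CDS does not intersect any exon"
                )
            if clen % 3 != 0:
                raise ValidationError(
                    f"{self.gene_id}: spliced CDS length {clen} is not a "
                    "multiple of 3"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS interval, genomic order."""
        if self.cds is None:
            return []
        cs, ce = self.cds
        out = []
        for s, e in self.exons:
            lo, hi = max(s, cs), min(e, ce)
            if lo <= hi:
                out.append((lo, hi))
        return out

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_intervals())

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def coding_sequence(self, genome: GenomeSequence) -> str:
        """Spliced CDS on the coding strand (5'->3')."""
        pieces = [genome.fetch(self.chrom, s, e) for s, e in self.coding_intervals()]
        seq = "".join(pieces)
        return seq if self.strand == "+" else revcomp(seq)


def unique_exonic_length(gene: GeneModel | Sequence[tuple[int, int]]) -> int:
    """Number of distinct genomic bases covered by >= 1 exon (L_gene).

    Accepts a :class:`GeneModel` or a raw interval list; duplicated or
    overlapping intervals are counted with set semantics.
    """
    exons = gene.exons if isinstance(gene, GeneModel) else gene
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s + 1 for s, e in merged)


# ---------------------------------------------------------------------------
# pooled variants


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNV with allele depths for the two sequencing pools.

    Depths are (ref_count, alt_count) pairs; ``wt`` is the wild-type-sibling
    pool and ``mut`` the phenotypically mutant pool.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    wt_pool_depths: tuple[int, int]
    mut_pool_depths: tuple[int, int]

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"variant position {self.pos} < 1")
        for allele, label in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if len(allele) != 1 or allele not in _BASES:
                raise ValidationError(
                    f"{label} allele {allele!r} is not a single ACGT base"
                )
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt alleles must differ")
        for depths in (self.wt_pool_depths, self.mut_pool_depths):
            if len(depths) != 2 or min(depths) < 0:
                raise ValidationError(f"bad depth pair {depths!r}")

    def alt_fraction(self, pool: str) -> float:
        """Observed alt-allele fraction in 'wt' or 'mut'; NaN at depth 0."""
        ref, alt = self.wt_pool_depths if pool == "wt" else self.mut_pool_depths
        total = ref + alt
        return alt / total if total else float("nan")

    def depth(self, pool: str) -> int:
        ref, alt = self.wt_pool_depths if pool == "wt" else self.mut_pool_depths
        return ref + alt


def read_variants(
    path: str | Path,
    wt_sample: str | None = None,
    mut_sample: str | None = None,
) -> list[PooledVariant]:
    """Read pooled variant calls from a VCF with per-sample AD fields.

    Exactly two samples are expected; by default the first sample is the
    wild-type-sibling pool and the second the mutant pool (override with
    ``wt_sample`` / ``mut_sample``).  Only biallelic SNVs are retained;
    multi-allelic and indel records are skipped with a logged count, since
    the mapping screen targets point mutations.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if len(samples) < 2:
        raise ParseError(
            f"{path}: expected two pool samples, found {len(samples)}"
        )
    wt = wt_sample or samples[0]
    mut = mut_sample or samples[1]
    for name in (wt, mut):
        if name not in samples:
            raise ParseError(f"{path}: sample {name!r} not present")

    variants: list[PooledVariant] = []
    n_skipped = 0
    try:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _BASES
                or alts[0] not in _BASES
            ):
                n_skipped += 1
                continue
            depths = {}
            for name in (wt, mut):
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) != 2 or any(v is None for v in ad):
                    raise ParseError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {name!r} "
                        "is missing a two-value AD field"
                    )
                depths[name] = (int(ad[0]), int(ad[1]))
            variants.append(
                PooledVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    wt_pool_depths=depths[wt],
                    mut_pool_depths=depths[mut],
                )
            )
    except ParseError:
        raise
    except Exception as exc:  # malformed body rows surface here from htslib
        raise ParseError(f"malformed VCF record in {path}: {exc}") from exc
    if n_skipped:
        log.info("%d record(s) skipped (multi-allelic or indel)", n_skipped)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def write_variants(
    variants: Iterable[PooledVariant],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write pooled variants as a two-sample VCF (samples ``wt``, ``mut``)."""
    variants = list(variants)
    if contig_lengths is None:
        contig_lengths = {}
        for v in variants:
            contig_lengths[v.chrom] = max(contig_lengths.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\twt\tmut\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            wt = f"./.:{v.wt_pool_depths[0]},{v.wt_pool_depths[1]}"
            mut = f"./.:{v.mut_pool_depths[0]},{v.mut_pool_depths[1]}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT:AD\t{wt}\t{mut}\n"
            )


# ---------------------------------------------------------------------------
# gene model I/O (GFF3 via gffutils)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene features with exon/CDS children)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            raise ParseError(f"gene {gene.id} has no exon features")
        cds_feats = list(db.children(gene, featuretype="CDS"))
        cds = None
        if cds_feats:
            cds = (min(f.start for f in cds_feats), max(f.end for f in cds_feats))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(exons),
                cds=cds,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene, exon and per-exon CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tscreenmap\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tscreenmap\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (cs, ce) in enumerate(g.coding_intervals(), 1):
                fh.write(
                    f"{g.chrom}\tscreenmap\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Non-negative integer fragment counts, features x samples.

    Features are genes or splice junctions (junction ids are formatted
    ``chrom:donor_end-acceptor_start``).  The default two samples are the
    wild-type and mutant libraries, but any number of samples is allowed.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids are not unique")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.rint(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = np.rint(self.counts).astype(np.int64)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def column_sums(self) -> dict[str, int]:
        return {
            s: int(self.counts[:, j].sum()) for j, s in enumerate(self.sample_ids)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            counts=frame.to_numpy(),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ParseError(f"cannot parse count table {path}: {exc}") from exc
        return cls.from_frame(frame)
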