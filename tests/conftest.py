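"""Shared fixtures: tiny hand-built genomes and gene models.

The toy genes are small enough that every expected value (codon positions,
splice sites, premature stops) is verifiable by eye:

* ``chrT`` carries a plus-strand two-exon gene whose intron contains no
  in-frame stop codon.
* ``chrQ`` carries the same gene except the intron reads GTCTAAAG, placing an
  in-frame TAA two codons into a retained intron.
* ``chrM`` is the reverse complement of ``chrQ`` with the mirrored gene on
  the minus strand (same transcript, mirrored coordinates).
"""

import pytest
from hypothesis import settings

from screenmap.genome_models import GeneModel, GenomeSequence, revcomp

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# positions 1-10 filler, 11-42 gene, 43-60 filler
_FILLER5 = "AAAAACCCCC"
_FILLER3 = "GGGGGTTTTTGGGGGTTT"
_EXON1 = "ATGGCTTACGAT"  # codons ATG GCT TAC GAT
_EXON2 = "GAATGGCTTTAA"  # codons GAA TGG CTT TAA (natural stop)
_INTRON_CLEAN = "GTCCATAG"  # no in-frame stop when retained (frame 0)
_INTRON_PTC = "GTCTAAAG"  # retained frame: GTC TAA -> stop 2 codons in

CHRT = _FILLER5 + _EXON1 + _INTRON_CLEAN + _EXON2 + _FILLER3
CHRQ = _FILLER5 + _EXON1 + _INTRON_PTC + _EXON2 + _FILLER3
CHRM = revcomp(CHRQ)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"chrT": CHRT, "chrQ": CHRQ, "chrM": CHRM})


@pytest.fixture(scope="session")
def gene_plus() -> GeneModel:
    """Plus-strand gene on chrT; retained intron has no in-frame stop."""
    return GeneModel(
        gene_id="toy_plus",
        chrom="chrT",
        strand="+",
        exons=((11, 22), (31, 42)),
        cds=(11, 42),
    )


@pytest.fixture(scope="session")
def gene_ptc() -> GeneModel:
    """Plus-strand gene on chrQ; retained intron reads GTC TAA ..."""
    return GeneModel(
        gene_id="toy_ptc",
        chrom="chrQ",
        strand="+",
        exons=((11, 22), (31, 42)),
        cds=(11, 42),
    )


@pytest.fixture(scope="session")
def gene_minus() -> GeneModel:
    """Minus-strand mirror of the chrQ gene on chrM (length 60)."""
    return GeneModel(
        gene_id="toy_minus",
        chrom="chrM",
        strand="-",
        exons=((19, 30), (39, 50)),
        cds=(19, 50),
    )
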