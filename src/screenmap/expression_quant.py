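"""Expression quantification and pure-fold-change differential calls.

Quantification uses a duplication-aware FPKM: fragments mapping to any exonic
copy of a gene are collapsed into a single per-gene count (the input contract
of :class:`~screenmap.genome_models.CountMatrix`), and

    FPKM = F_gene * 1000 * 1,000,000 / (F_allexon * L_gene)

where ``F_gene`` is the fragment count of the gene, ``F_allexon`` the total
exonic fragments of the sample (the column sum for exon-union gene counts) and
``L_gene`` the number of unique exonic bases of the gene.  With a single
library per condition there is no replicate-based statistic to compute:
differential expression is purely the fold change between mutant and
wild-type FPKM, with an ``FPKM > 0.1`` in-both-samples filter defining the
expressed set that top-N rankings are drawn from.  No p-values are emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_models import CountMatrix, GeneModel, ValidationError, unique_exonic_length

log = logging.getLogger(__name__)

EXPRESSED_FPKM_THRESHOLD = 0.1


@dataclass
class FpkmTable:
    """Per-gene fragment counts and FPKM for each sample.

    ``frame`` is indexed by gene id with columns ``<sample>_count`` and
    ``<sample>_fpkm`` plus ``length`` (unique exonic bases); ``f_allexon``
    maps sample id to its total exonic fragment count.
    """

    frame: pd.DataFrame
    sample_ids: list[str]
    f_allexon: dict[str, int]

    def fpkm(self, sample: str) -> pd.Series:
        return self.frame[f"{sample}_fpkm"]

    def counts(self, sample: str) -> pd.Series:
        return self.frame[f"{sample}_count"]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "FpkmTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        samples = [c[: -len("_fpkm")] for c in frame.columns if c.endswith("_fpkm")]
        return cls(
            frame=frame,
            sample_ids=samples,
            f_allexon={s: int(frame[f"{s}_count"].sum()) for s in samples},
        )


@dataclass(frozen=True)
class FoldChangeRecord:
    """Mutant-vs-wild-type fold change for one gene.

    ``log2fc = log2((mut_fpkm + eps) / (wt_fpkm + eps))`` is always finite for
    eps > 0; genes where either side is exactly zero are flagged so the
    pseudocount-driven magnitude is interpretable.  ``expressed_both`` applies
    the strict FPKM > 0.1 filter in both samples; ``detected_any`` requires at
    least one fragment in either sample.
    """

    gene_id: str
    wt_fpkm: float
    mut_fpkm: float
    log2fc: float
    expressed_both: bool
    detected_any: bool
    zero_in_wt: bool
    zero_in_mut: bool


def compute_fpkm(counts: CountMatrix, genes: Sequence[GeneModel]) -> FpkmTable:
    """Exon-union FPKM for every counted gene, per sample.

    Every feature id must have a gene model; a gene with zero unique exonic
    length or a sample with zero total fragments is an error.
    """
    models = {g.gene_id: g for g in genes}
    lengths = np.empty(counts.n_features)
    for i, gid in enumerate(counts.feature_ids):
        if gid not in models:
            raise ValidationError(f"no gene model for counted feature {gid!r}")
        L = unique_exonic_length(models[gid])
        if L < 1:
            raise ValidationError(f"gene {gid} has zero unique exonic length")
        lengths[i] = L

    f_allexon = counts.column_sums()
    data: dict[str, np.ndarray] = {}
    for sample in counts.sample_ids:
        total = f_allexon[sample]
        if total == 0:
            raise ValidationError(
                f"sample {sample!r} has zero exonic fragments (empty library)"
            )
        f_gene = counts.sample(sample).astype(float)
        data[f"{sample}_count"] = counts.sample(sample)
        data[f"{sample}_fpkm"] = f_gene * 1000 * 1_000_000 / (total * lengths)
    data["length"] = lengths.astype(int)
    frame = pd.DataFrame(
        data, index=pd.Index(counts.feature_ids, name="gene_id")
    )
    return FpkmTable(frame=frame, sample_ids=list(counts.sample_ids), f_allexon=f_allexon)


def fold_changes(
    fpkm: FpkmTable,
    epsilon: float = 1e-6,
    wt_sample: str = "wt",
    mut_sample: str = "mut",
) -> list[FoldChangeRecord]:
    """Pure fold-change records for every gene in the table."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    out = []
    for gid in fpkm.frame.index:
        wt = float(fpkm.frame.at[gid, f"{wt_sample}_fpkm"])
        mut = float(fpkm.frame.at[gid, f"{mut_sample}_fpkm"])
        wt_n = int(fpkm.frame.at[gid, f"{wt_sample}_count"])
        mut_n = int(fpkm.frame.at[gid, f"{mut_sample}_count"])
        out.append(
            FoldChangeRecord(
                gene_id=str(gid),
                wt_fpkm=wt,
                mut_fpkm=mut,
                log2fc=math.log2((mut + epsilon) / (wt + epsilon)),
                expressed_both=(
                    wt > EXPRESSED_FPKM_THRESHOLD and mut > EXPRESSED_FPKM_THRESHOLD
                ),
                detected_any=(wt_n >= 1 or mut_n >= 1),
                zero_in_wt=(wt_n == 0),
                zero_in_mut=(mut_n == 0),
            )
        )
    return out


def rank_top(
    records: Sequence[FoldChangeRecord],
    n: int = 10,
    require_expressed: bool = True,
) -> tuple[list[FoldChangeRecord], list[FoldChangeRecord]]:
    """Top-n upregulated and downregulated genes by log2 fold change.

    With ``require_expressed`` the FPKM > 0.1 in-both-samples filter is
    applied first (the inclusion rule for ranked tables).  Ties are broken
    deterministically by gene id; a shortfall against ``n`` is logged.
    """
    pool = [r for r in records if r.expressed_both] if require_expressed else list(records)
    if len(pool) < n:
        log.info("only %d qualifying records for top-%d ranking", len(pool), n)
    up = sorted(pool, key=lambda r: (-r.log2fc, r.gene_id))[:n]
    down = sorted(pool, key=lambda r: (r.log2fc, r.gene_id))[:n]
    return up, down


def records_to_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    """Tabular view (gene, wt_fpkm, mut_fpkm, log2fc, flags)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "wt_fpkm": r.wt_fpkm,
                "mut_fpkm": r.mut_fpkm,
                "log2fc": r.log2fc,
                "expressed_both": r.expressed_both,
                "detected_any": r.detected_any,
                "zero_in_wt": r.zero_in_wt,
                "zero_in_mut": r.zero_in_mut,
            }
            for r in records
        ]
    ).set_index("gene_id")
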