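"""ddCt relative quantification and phenotype-proportion scoring.

Relative expression is computed by the comparative-Ct (ddCt) method with an
ideal amplification efficiency of 2: for a gene g, a reference gene r, a
calibrator sample (wild-type) and a test sample (mutant),

    dCt(sample)  = mean Ct(g, sample) - mean Ct(r, sample)
    ddCt         = dCt(test) - dCt(calibrator)
    fold         = 2 ** (-ddCt)

Folds are additionally reported on a reference-zero scale
(``normalized = fold - reference_fold``), so the reference gene sits at 0 and
a completely extinguished transcript at -1.  Standard errors treat each
replicate index as one independent round of the full ddCt statistic.

The module also houses the phenotype-proportion score used for mRNA-rescue
quantification (percentage of larvae in a category, with a Wilson 95% CI).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_models import ParseError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CtTable:
    """Replicate Ct values per gene x sample, plus the reference gene.

    ``data`` has columns (gene, sample, replicate, ct); every gene needs at
    least one replicate per sample it appears in, and the reference gene must
    be present in every sample.
    """

    data: pd.DataFrame
    reference_gene: str

    REQUIRED = ("gene", "sample", "replicate", "ct")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table is missing columns {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive cycle counts")
        samples = set(self.data["sample"])
        ref_samples = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample"]
        )
        if samples - ref_samples:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing from "
                f"sample(s) {sorted(samples - ref_samples)}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample"]))

    def ct(self, gene: str, sample: str) -> pd.Series:
        """Replicate Ct values indexed by replicate number."""
        rows = self.data[
            (self.data["gene"] == gene) & (self.data["sample"] == sample)
        ]
        return rows.set_index("replicate")["ct"]

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, reference_gene: str) -> "CtTable":
        try:
            data = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ParseError(f"cannot parse Ct table {path}: {exc}") from exc
        return cls(data=data, reference_gene=reference_gene)


@dataclass(frozen=True)
class FoldResult:
    """ddCt result for one gene: fold = 2^(-ddCt), normalized = fold - 1."""

    gene_id: str
    ddct: float
    fold: float
    normalized: float
    se: float
    n_rounds: int


def ddct(
    table: CtTable,
    gene: str,
    calibrator_sample: str = "wt",
    test_sample: str = "mut",
) -> FoldResult:
    """Relative quantification of one gene by the ddCt method.

    Only replicate rounds with all four Ct measurements (gene and reference in
    both samples) enter the statistic; incomplete rounds are dropped with a
    warning.  ``se`` is the standard error of the per-round folds.
    """
    ref = table.reference_gene
    series = {
        (g, s): table.ct(g, s)
        for g in (gene, ref)
        for s in (calibrator_sample, test_sample)
    }
    for (g, s), values in series.items():
        if values.empty:
            raise ValidationError(f"no Ct values for gene {g!r} in sample {s!r}")

    rounds = sorted(
        set.intersection(*(set(v.index) for v in series.values()))
    )
    all_rounds = sorted(set().union(*(set(v.index) for v in series.values())))
    dropped = [r for r in all_rounds if r not in rounds]
    if dropped:
        log.warning(
            "gene %s: replicate round(s) %s dropped (incomplete Ct quartet)",
            gene,
            dropped,
        )
    if not rounds:
        raise ValidationError(
            f"gene {gene!r}: no replicate round has a complete Ct quartet"
        )

    def mean_ct(g: str, s: str) -> float:
        return float(series[(g, s)].loc[rounds].mean())

    dct_test = mean_ct(gene, test_sample) - mean_ct(ref, test_sample)
    dct_cal = mean_ct(gene, calibrator_sample) - mean_ct(ref, calibrator_sample)
    dd = dct_test - dct_cal
    fold = 2.0 ** (-dd)

    per_round_folds = np.array(
        [
            2.0
            ** -(
                (
                    series[(gene, test_sample)].loc[r]
                    - series[(ref, test_sample)].loc[r]
                )
                - (
                    series[(gene, calibrator_sample)].loc[r]
                    - series[(ref, calibrator_sample)].loc[r]
                )
            )
            for r in rounds
        ]
    )
    se = (
        float(per_round_folds.std(ddof=1) / math.sqrt(len(rounds)))
        if len(rounds) > 1
        else 0.0
    )
    return FoldResult(
        gene_id=gene,
        ddct=dd,
        fold=fold,
        normalized=fold - 1.0,
        se=se,
        n_rounds=len(rounds),
    )


def ddct_all(
    table: CtTable,
    calibrator_sample: str = "wt",
    test_sample: str = "mut",
) -> pd.DataFrame:
    """ddCt for every gene in the table (reference gene included, fold 1)."""
    results = [
        ddct(table, g, calibrator_sample, test_sample) for g in table.genes
    ]
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "ddct": r.ddct,
                "fold": r.fold,
                "normalized": r.normalized,
                "se": r.se,
                "n_rounds": r.n_rounds,
            }
            for r in results
        ]
    ).set_index("gene_id")


def normalize_folds(
    folds: list[tuple[str, float]],
    reference_gene: str,
) -> list[tuple[str, float]]:
    """Shift fold values so the reference gene sits at zero.

    ``normalized = fold - reference_fold`` where ``reference_fold`` is the
    reference gene's own fold (1.0 when it is its own calibrator).
    """
    by_gene = dict(folds)
    if reference_gene not in by_gene:
        raise ValidationError(
            f"reference gene {reference_gene!r} not among the fold values"
        )
    ref_fold = by_gene[reference_gene]
    return [(gene, fold - ref_fold) for gene, fold in folds]


def phenotype_proportion(
    n_category: int,
    n_total: int,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Percentage of individuals in a phenotype category with a Wilson CI.

    Returns ``(percentage, (lower, upper))``, all on the 0-100 scale.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_category <= n_total:
        raise ValueError("need 0 <= n_category <= n_total")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(
        n_category, n_total, alpha=1 - confidence, method="wilson"
    )
    return 100.0 * n_category / n_total, (100.0 * lo, 100.0 * hi)
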