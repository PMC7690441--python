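"""Novel / differential splice-junction screen.

Junction fragment counts (features formatted ``chrom:donor_end-acceptor_start``,
both coordinates 1-based: the last base of the upstream exon and the first
base of the downstream exon) are normalized per sample to reads per million
(RPM), flagged as known when they exactly match an annotated intron, and
passed through a four-predicate candidate filter:

* average intensity ``mean(log2(rpm + c))`` over the two samples > 2,
* ``|log2((mut_rpm + c) / (wt_rpm + c))|`` > 2,
* fold change ``(larger rpm + c) / (smaller rpm + c)`` > 4,
* arithmetic mean RPM of the two samples > 4.

The pseudocount ``c`` (default 0.5 RPM) keeps the log terms finite at zero
counts.  Intron-retention events show up here as novel junctions joining an
exon boundary to the interior of its intron, present in the mutant library
only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .genome_models import CountMatrix, GeneModel, ValidationError

_JUNCTION_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<donor>\d+)-(?P<acceptor>\d+)$")


def junction_id(chrom: str, donor_end: int, acceptor_start: int) -> str:
    return f"{chrom}:{donor_end}-{acceptor_start}"


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction with counts, RPM and screening metrics."""

    chrom: str
    donor_end: int
    acceptor_start: int
    wt_count: int
    mut_count: int
    wt_rpm: float
    mut_rpm: float
    log2_avg_intensity: float
    log2_ratio: float
    avg_rpm: float
    known: bool | None = None

    def __post_init__(self):
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction {self.chrom}:{self.donor_end}-{self.acceptor_start}: "
                "donor_end must be < acceptor_start"
            )

    @property
    def feature_id(self) -> str:
        return junction_id(self.chrom, self.donor_end, self.acceptor_start)

    @property
    def intron(self) -> tuple[int, int]:
        """The intron this junction would excise, as a closed interval."""
        return self.donor_end + 1, self.acceptor_start - 1


@dataclass(frozen=True)
class JunctionFilterConfig:
    """Thresholds of the candidate-junction screen (all strict >)."""

    min_log2_avg_intensity: float = 2.0
    min_log2_ratio: float = 2.0
    min_fold_change: float = 4.0
    min_avg_rpm: float = 4.0
    pseudocount: float = 0.5
    min_count: int = 5  # low-count prefilter: >= min_count in >= 1 sample

    def __post_init__(self):
        if min(
            self.min_log2_avg_intensity,
            self.min_log2_ratio,
            self.min_fold_change,
            self.min_avg_rpm,
            self.pseudocount,
        ) <= 0:
            raise ValidationError("all junction filter thresholds must be > 0")


def normalize_rpm(
    junctions: CountMatrix,
    pseudocount: float = 0.5,
    wt_sample: str = "wt",
    mut_sample: str = "mut",
    intensity: str = "mean_log",
) -> list[JunctionRecord]:
    """Per-sample RPM normalization of a junction count matrix.

    ``rpm = count * 1e6 / total junction fragments of the sample``, so RPM
    sums to 1e6 per sample.  ``intensity`` selects how the average intensity
    is formed: ``"mean_log"`` (default) averages ``log2(rpm + c)`` over the
    samples, ``"log_mean"`` takes ``log2(mean rpm + c)``.
    """
    if intensity not in ("mean_log", "log_mean"):
        raise ValueError("intensity must be 'mean_log' or 'log_mean'")
    totals = junctions.column_sums()
    for sample in (wt_sample, mut_sample):
        if totals[sample] == 0:
            raise ValidationError(
                f"sample {sample!r} has zero junction fragments"
            )
    wt_counts = junctions.sample(wt_sample)
    mut_counts = junctions.sample(mut_sample)
    c = pseudocount
    records = []
    for fid, wt_n, mut_n in zip(junctions.feature_ids, wt_counts, mut_counts):
        m = _JUNCTION_ID.match(fid)
        if not m:
            raise ValidationError(
                f"feature id {fid!r} is not 'chrom:donor_end-acceptor_start'"
            )
        wt_rpm = wt_n * 1e6 / totals[wt_sample]
        mut_rpm = mut_n * 1e6 / totals[mut_sample]
        if intensity == "mean_log":
            avg_int = (math.log2(wt_rpm + c) + math.log2(mut_rpm + c)) / 2
        else:
            avg_int = math.log2((wt_rpm + mut_rpm) / 2 + c)
        records.append(
            JunctionRecord(
                chrom=m["chrom"],
                donor_end=int(m["donor"]),
                acceptor_start=int(m["acceptor"]),
                wt_count=int(wt_n),
                mut_count=int(mut_n),
                wt_rpm=wt_rpm,
                mut_rpm=mut_rpm,
                log2_avg_intensity=avg_int,
                log2_ratio=math.log2((mut_rpm + c) / (wt_rpm + c)),
                avg_rpm=(wt_rpm + mut_rpm) / 2,
            )
        )
    return records


def flag_novel(
    junctions: Sequence[JunctionRecord],
    genes: Sequence[GeneModel],
) -> list[JunctionRecord]:
    """Mark each junction known/novel against the annotated introns.

    A junction is known iff its implied intron matches an annotated intron of
    some gene exactly on both boundaries; everything else -- including
    exon-boundary-to-intron-interior junctions characteristic of intron
    retention -- is novel.
    """
    annotated: set[tuple[str, int, int]] = set()
    for g in genes:
        for s, e in g.introns:
            annotated.add((g.chrom, s, e))
    out = []
    for j in junctions:
        intron = j.intron
        out.append(
            replace(j, known=(j.chrom, intron[0], intron[1]) in annotated)
        )
    return out


def filter_differential(
    junctions: Sequence[JunctionRecord],
    config: JunctionFilterConfig = JunctionFilterConfig(),
) -> list[JunctionRecord]:
    """Candidate junctions passing every screening predicate.

    The absolute log2 ratio is used, so junctions used less in the mutant are
    candidates too; output is sorted by |log2 ratio| descending (ties by
    position).
    """
    c = config.pseudocount
    out = []
    for j in junctions:
        if max(j.wt_count, j.mut_count) < config.min_count:
            continue
        lo, hi = sorted((j.wt_rpm, j.mut_rpm))
        fold = (hi + c) / (lo + c)
        if (
            j.log2_avg_intensity > config.min_log2_avg_intensity
            and abs(j.log2_ratio) > config.min_log2_ratio
            and fold > config.min_fold_change
            and j.avg_rpm > config.min_avg_rpm
        ):
            out.append(j)
    out.sort(key=lambda j: (-abs(j.log2_ratio), j.chrom, j.donor_end))
    return out


def records_to_frame(junctions: Sequence[JunctionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": j.feature_id,
                "chrom": j.chrom,
                "donor_end": j.donor_end,
                "acceptor_start": j.acceptor_start,
                "wt_count": j.wt_count,
                "mut_count": j.mut_count,
                "wt_rpm": j.wt_rpm,
                "mut_rpm": j.mut_rpm,
                "log2_avg_intensity": j.log2_avg_intensity,
                "log2_ratio": j.log2_ratio,
                "avg_rpm": j.avg_rpm,
                "known": j.known,
            }
            for j in junctions
        ]
    ).set_index("feature_id")


def candidates_to_bed(junctions: Sequence[JunctionRecord]) -> str:
    """BED track of candidate junctions; novel junctions colored red."""
    lines = []
    for j in junctions:
        start0 = j.donor_end - 1  # closed 1-based -> half-open 0-based
        name = "novel" if not j.known else "known"
        color = "255,0,0" if not j.known else "0,128,0"
        lines.append(
            f"{j.chrom}\t{start0}\t{j.acceptor_start}\t{name}\t0\t+"
            f"\t{start0}\t{j.acceptor_start}\t{color}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
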