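"""Genome-scale aggregation of per-read calls into per-site methylation frequencies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import pandas as pd

from .io import ReadPrediction


@dataclass(frozen=True)
class SiteSummary:
    """Per-site coverage and methylation frequency.

    ``frequency = methylated_count / coverage`` from hard calls (threshold
    0.5); ``mean_prob`` additionally reports the mean methylation
    probability over the covering reads as an auxiliary, soft estimate.
    """

    chrom: str
    pos: int
    strand: str
    coverage: int
    methylated_count: int
    mean_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0 <= self.methylated_count <= self.coverage:
            raise ValueError("methylated_count must lie in [0, coverage]")

    @property
    def frequency(self) -> float:
        return self.methylated_count / self.coverage


def summarize(
    predictions: Iterable[ReadPrediction], min_coverage: int = 1
) -> List[SiteSummary]:
    """Group per-read predictions by (chrom, pos, strand) into site summaries.

    Sites with coverage below ``min_coverage`` are dropped.  Output is
    sorted by (chrom, pos, strand) and invariant to input ordering; opposite
    strands of a palindromic CpG are reported separately.
    """
    preds = list(predictions)
    if not preds:
        return []
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in preds],
            "pos": [p.ref_pos for p in preds],
            "strand": [p.strand for p in preds],
            "call": [p.call for p in preds],
            "prob": [p.prob for p in preds],
        }
    )
    grouped = (
        df.groupby(["chrom", "pos", "strand"], sort=True)
        .agg(coverage=("call", "size"), methylated_count=("call", "sum"),
             mean_prob=("prob", "mean"))
        .reset_index()
    )
    out = []
    for row in grouped.itertuples(index=False):
        if row.coverage < min_coverage:
            continue
        out.append(
            SiteSummary(
                chrom=row.chrom,
                pos=int(row.pos),
                strand=row.strand,
                coverage=int(row.coverage),
                methylated_count=int(row.methylated_count),
                mean_prob=float(row.mean_prob),
            )
        )
    return out
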