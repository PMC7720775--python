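"""Selection of MSRE-PCR target regions from called DMRs.

A target region is a hypermethylated DMR whose mean methylation in the
normal group is below 2.5% (strict inequality): near-zero normal methylation
is what lets the restriction digest destroy essentially all normal template
while methylated tumor template survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dmr import CohortMatrix, DMRecord, region_group_mean
from .io import Cohort

__all__ = [
    "SelectorParams",
    "split_by_direction",
    "select_targets",
    "region_statistics",
    "region_methylation_matrix",
]


@dataclass
class SelectorParams:
    normal_max_meth: float = 0.025

    def __post_init__(self) -> None:
        if not 0.0 < self.normal_max_meth < 1.0:
            raise ValueError("normal_max_meth must lie in (0, 1)")


def split_by_direction(dmrs: Sequence[DMRecord]) -> tuple[list[DMRecord], list[DMRecord]]:
    """Partition DMRs into (hypermethylated, hypomethylated) by sign of
    mean_diff; zero-difference records belong to neither and are warned."""
    hyper = [d for d in dmrs if d.mean_diff > 0]
    hypo = [d for d in dmrs if d.mean_diff < 0]
    n_zero = len(dmrs) - len(hyper) - len(hypo)
    if n_zero:
        warnings.warn(f"{n_zero} regions with zero mean difference assigned to neither direction")
    return hyper, hypo


def select_targets(
    hyper_dmrs: Sequence[DMRecord],
    cohort: Cohort | CohortMatrix,
    params: SelectorParams | None = None,
) -> list[DMRecord]:
    """Retain hypermethylated DMRs with normal-group mean strictly below the
    threshold. The normal mean is recomputed from the cohort (single source
    of truth); regions lacking eligible CpGs are excluded with a warning.
    Input order is preserved.
    """
    params = params or SelectorParams()
    cm = cohort if isinstance(cohort, CohortMatrix) else CohortMatrix(cohort)
    out = []
    for rec in hyper_dmrs:
        if rec.mean_diff <= 0:
            raise ValueError(f"{rec.chrom}:{rec.start}-{rec.end} is not hypermethylated")
        try:
            mean_normal = region_group_mean(cm, (rec.chrom, rec.start, rec.end), "normal")
        except ValueError as exc:
            warnings.warn(f"excluding {rec.chrom}:{rec.start}-{rec.end}: {exc}")
            continue
        if mean_normal < params.normal_max_meth:
            out.append(rec)
    return out


def region_statistics(
    regions: Sequence[DMRecord], cohort: Cohort | CohortMatrix
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region length / CpG count / group means, plus cohort-level averages.

    Returns (per-region table, summary dict with mean_length_nt, mean_n_cpgs,
    mean_normal, mean_cancer).
    """
    if not regions:
        raise ValueError("empty region list")
    cm = cohort if isinstance(cohort, CohortMatrix) else CohortMatrix(cohort)
    rows = []
    for rec in regions:
        iv = (rec.chrom, rec.start, rec.end)
        rows.append(
            {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "length_nt": rec.length,
                "n_cpgs": rec.n_cpgs,
                "mean_normal": region_group_mean(cm, iv, "normal"),
                "mean_cancer": region_group_mean(cm, iv, "cancer"),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_regions": float(len(table)),
        "mean_length_nt": float(table["length_nt"].mean()),
        "mean_n_cpgs": float(table["n_cpgs"].mean()),
        "mean_normal": float(table["mean_normal"].mean()),
        "mean_cancer": float(table["mean_cancer"].mean()),
    }
    return table, summary


def region_methylation_matrix(
    regions: Sequence[DMRecord], cohort: Cohort | CohortMatrix
) -> pd.DataFrame:
    """Region x sample mean methylation matrix (per-sample mean of covered
    per-CpG ratios within the region); NaN where a sample covers no CpG in
    the region. Suitable for export and hierarchical clustering."""
    cm = cohort if isinstance(cohort, CohortMatrix) else CohortMatrix(cohort)
    data = np.full((len(regions), len(cm.sample_ids)), np.nan)
    names = []
    for i, rec in enumerate(regions):
        names.append(f"{rec.chrom}:{rec.start}-{rec.end}")
        if rec.chrom not in cm.positions:
            continue
        pos = cm.positions[rec.chrom]
        sel = (pos >= rec.start) & (pos < rec.end)
        if not sel.any():
            continue
        r = cm.ratios(rec.chrom)[sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            data[i] = np.nanmean(r, axis=0)
    return pd.DataFrame(data, index=names, columns=cm.sample_ids)
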