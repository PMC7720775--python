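"""Differentially methylated region (DMR) calling between two cohort groups.

Regions are found by recursive binary segmentation of per-CpG group
methylation differences: within each run of eligible CpGs (broken at large
genomic gaps) the window of consecutive CpGs maximizing the absolute group
mean difference is selected, the flanks are recursed, and candidate windows
are then filtered on effect size (|diff| >= 0.15 by default), genomic length
(>= 80 nt), CpG count, and Benjamini-Hochberg Q-value (< 0.01), the filter
set used for cancer-vs-normal WGBS discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, Methylome

__all__ = [
    "DMRecord",
    "DMRParams",
    "CohortMatrix",
    "global_methylation",
    "pairwise_correlation",
    "compare_group_methylation",
    "call_dmrs",
    "region_group_mean",
    "benjamini_hochberg",
]


@dataclass
class DMRecord:
    """One called region with its group means and statistics.

    ``mean_diff`` is cancer minus normal; direction is 'hyper' when positive
    (hypermethylated in cancer) and 'hypo' when negative.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_normal: float
    mean_cancer: float
    p_value: float = 1.0
    q_value: float = 1.0

    @property
    def mean_diff(self) -> float:
        return self.mean_cancer - self.mean_normal

    @property
    def direction(self) -> str:
        if self.mean_diff > 0:
            return "hyper"
        if self.mean_diff < 0:
            return "hypo"
        return "none"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DMRParams:
    """Segmentation and filter parameters.

    min_diff, min_length_nt and q_threshold are the published filter values;
    min_cpgs, max_cpg_gap_nt and min_sample_fraction follow common
    segmentation-tool conventions and are exposed for tuning. ``mwu_mode``
    selects the observations pooled into the region test: per-CpG per-sample
    ratios ('cpg_sample', default) or per-sample region means ('sample').
    """

    min_diff: float = 0.15
    min_length_nt: int = 80
    q_threshold: float = 0.01
    min_cpgs: int = 10
    max_cpg_gap_nt: int = 300
    min_sample_fraction: float = 0.8
    mwu_mode: str = "cpg_sample"
    segmentation_objective: str = "scan"

    def __post_init__(self) -> None:
        if not 0 < self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if min(self.min_diff, self.min_length_nt, self.q_threshold, self.min_cpgs) <= 0:
            raise ValueError("thresholds must be positive")
        if self.mwu_mode not in ("cpg_sample", "sample"):
            raise ValueError("mwu_mode must be 'cpg_sample' or 'sample'")
        if self.segmentation_objective not in ("scan", "mean"):
            raise ValueError("segmentation_objective must be 'scan' or 'mean'")


class CohortMatrix:
    """Dense per-chromosome CpG x sample methylation matrices for a cohort.

    Built once and reused by the caller and the region statistics; rows are
    the union of CpG positions observed in any sample.
    """

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.sample_ids = [s.sample_id for s in cohort.samples]
        self.groups = np.array([s.group for s in cohort.samples])
        self.normal_idx = np.where(self.groups == "normal")[0]
        self.cancer_idx = np.where(self.groups == "cancer")[0]
        self.positions: dict[str, np.ndarray] = {}
        self.meth: dict[str, np.ndarray] = {}
        self.cov: dict[str, np.ndarray] = {}
        chroms = sorted({c for s in cohort.samples for c in s.calls["chrom"].unique()})
        for chrom in chroms:
            per_sample = []
            for s in cohort.samples:
                sub = s.calls[s.calls["chrom"] == chrom]
                per_sample.append((sub["pos"].to_numpy(), sub))
            pos = np.unique(np.concatenate([p for p, _ in per_sample])) if per_sample else np.array([], int)
            n = len(pos)
            meth = np.zeros((n, len(cohort.samples)))
            cov = np.zeros((n, len(cohort.samples)))
            for j, (p, sub) in enumerate(per_sample):
                if len(p) == 0:
                    continue
                rows = np.searchsorted(pos, p)
                meth[rows, j] = sub["n_meth"].to_numpy()
                cov[rows, j] = sub["n_meth"].to_numpy() + sub["n_unmeth"].to_numpy()
            self.positions[chrom] = pos
            self.meth[chrom] = meth
            self.cov[chrom] = cov

    def ratios(self, chrom: str) -> np.ndarray:
        """Per-CpG per-sample methylation ratios; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.meth[chrom] / self.cov[chrom]
        r[self.cov[chrom] == 0] = np.nan
        return r

    def eligible_mask(self, chrom: str, min_sample_fraction: float) -> np.ndarray:
        cov = self.cov[chrom] > 0
        f_n = cov[:, self.normal_idx].mean(axis=1)
        f_c = cov[:, self.cancer_idx].mean(axis=1)
        return (f_n >= min_sample_fraction) & (f_c >= min_sample_fraction)


def global_methylation(methylome: Methylome) -> float:
    """Count-weighted global methylation: sum(meth) / sum(meth+unmeth)."""
    n_meth = int(methylome.calls["n_meth"].sum())
    total = n_meth + int(methylome.calls["n_unmeth"].sum())
    if total == 0:
        raise ValueError(f"{methylome.sample_id}: no covered CpGs")
    return n_meth / total


def pairwise_correlation(cohort: Cohort, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation of per-CpG ratios over jointly covered positions.

    Entries with fewer than ``min_shared`` shared CpGs are NaN. Symmetric
    with a unit diagonal.
    """
    cm = CohortMatrix(cohort)
    n = len(cohort.samples)
    ratios = {c: cm.ratios(c) for c in cm.positions}
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            xs, ys = [], []
            for chrom in ratios:
                r = ratios[chrom]
                both = ~np.isnan(r[:, i]) & ~np.isnan(r[:, j])
                xs.append(r[both, i])
                ys.append(r[both, j])
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            if len(x) >= min_shared and np.std(x) > 0 and np.std(y) > 0:
                out[i, j] = out[j, i] = float(np.corrcoef(x, y)[0, 1])
    return pd.DataFrame(out, index=cm.sample_ids, columns=cm.sample_ids)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided MWU: exact when both groups are small and tie-free,
    asymptotic with tie correction otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_group_methylation(cohort: Cohort) -> tuple[float, float]:
    """Mann-Whitney U test on per-sample global methylation, normal vs cancer."""
    normal = [global_methylation(s) for s in cohort.normal]
    cancer = [global_methylation(s) for s in cohort.cancer]
    if len(normal) < 2 or len(cancer) < 2:
        raise ValueError("need >=2 samples per group")
    return _mannwhitney(np.array(normal), np.array(cancer))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; returns q-values in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def region_group_mean(
    cohort: Cohort | CohortMatrix,
    interval: tuple[str, int, int],
    group: str,
    eligible_only: bool = False,
    min_sample_fraction: float = 0.8,
) -> float:
    """Mean methylation of a region in one group.

    Per CpG, the ratio is averaged over the group's covered samples; those
    per-CpG group means are then averaged unweighted across the region's
    CpGs. With ``eligible_only`` the CpGs are restricted to those covered in
    >= ``min_sample_fraction`` of both groups (the caller's eligibility
    rule).
    """
    cm = cohort if isinstance(cohort, CohortMatrix) else CohortMatrix(cohort)
    chrom, start, end = interval
    if chrom not in cm.positions:
        raise ValueError(f"no CpGs on {chrom}")
    pos = cm.positions[chrom]
    sel = (pos >= start) & (pos < end)
    if eligible_only:
        sel &= cm.eligible_mask(chrom, min_sample_fraction)
    if not sel.any():
        raise ValueError(f"no eligible CpGs in {chrom}:{start}-{end}")
    idx = cm.normal_idx if group == "normal" else cm.cancer_idx
    r = cm.ratios(chrom)[np.ix_(np.where(sel)[0], idx)]
    per_cpg = np.nanmean(r, axis=1)
    per_cpg = per_cpg[~np.isnan(per_cpg)]
    if per_cpg.size == 0:
        raise ValueError(f"no covered CpGs for group {group} in {chrom}:{start}-{end}")
    return float(per_cpg.mean())


def _best_window(
    d: np.ndarray, min_cpgs: int, objective: str, min_diff: float
) -> tuple[int, int, float] | None:
    """Best window [i, j) of length >= min_cpgs with |mean(d[i:j])| >= min_diff.

    Restricting the search to windows already past the effect-size filter
    keeps dilute mixtures (e.g. a hypomethylated block spanning an embedded
    hypermethylated island) from shadowing their differential sub-blocks.
    'scan' maximizes |sum(d[i:j])| / sqrt(j-i), the scan-statistic form with
    constant noise variance across window lengths, so signal blocks are
    captured at their full extent; 'mean' maximizes |mean(d[i:j])| (which,
    under noise, is biased toward the shortest admissible window). Ties are
    broken by leftmost start, then shortest window (scanned in ascending
    length, so an equally scoring longer window never replaces a shorter one
    at the same start). Returns None when no window qualifies.
    """
    n = d.size
    csum = np.concatenate([[0.0], np.cumsum(d)])
    best = None
    for length in range(min_cpgs, n + 1):
        sums = np.abs(csum[length:] - csum[:-length])
        scores = sums / (length if objective == "mean" else np.sqrt(length))
        scores = np.where(sums / length >= min_diff, scores, -np.inf)
        i = int(np.argmax(scores))
        val = float(scores[i])
        if not np.isfinite(val):
            continue
        if best is None or val > best[2] or (val == best[2] and i < best[0]):
            best = (i, i + length, val)
    return best


def _segment(
    d: np.ndarray,
    offset: int,
    min_cpgs: int,
    objective: str,
    min_diff: float,
    out: list[tuple[int, int]],
) -> None:
    if d.size < min_cpgs:
        return
    hit = _best_window(d, min_cpgs, objective, min_diff)
    if hit is None:
        return
    i, j, _ = hit
    out.append((offset + i, offset + j))
    _segment(d[:i], offset, min_cpgs, objective, min_diff, out)
    _segment(d[j:], offset + j, min_cpgs, objective, min_diff, out)


def call_dmrs(cohort: Cohort, params: DMRParams | None = None) -> list[DMRecord]:
    """Call DMRs between the cohort's normal and cancer groups.

    Pipeline: eligibility filter -> gap-based pre-segmentation -> recursive
    binary segmentation on per-CpG group differences -> effect/length/CpG
    filters -> Mann-Whitney U p-value per region -> Benjamini-Hochberg across
    candidates -> Q-value threshold. Output is coordinate-sorted and
    non-overlapping (region end = last CpG position + 2, covering the CG).
    """
    params = params or DMRParams()
    cm = CohortMatrix(cohort)
    candidates: list[DMRecord] = []
    pvals: list[float] = []
    for chrom in sorted(cm.positions):
        pos = cm.positions[chrom]
        if pos.size == 0:
            continue
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted CpG positions on {chrom}")
        eligible = cm.eligible_mask(chrom, params.min_sample_fraction)
        epos = pos[eligible]
        if epos.size < params.min_cpgs:
            continue
        r = cm.ratios(chrom)[eligible]
        mean_n = np.nanmean(r[:, cm.normal_idx], axis=1)
        mean_c = np.nanmean(r[:, cm.cancer_idx], axis=1)
        d = mean_c - mean_n
        # runs of eligible CpGs broken at genomic gaps
        breaks = np.where(np.diff(epos) > params.max_cpg_gap_nt)[0] + 1
        for run_lo, run_hi in zip(
            np.concatenate([[0], breaks]), np.concatenate([breaks, [epos.size]])
        ):
            windows: list[tuple[int, int]] = []
            _segment(
                d[run_lo:run_hi],
                run_lo,
                params.min_cpgs,
                params.segmentation_objective,
                params.min_diff,
                windows,
            )
            for i, j in windows:
                diff = float(np.mean(d[i:j]))
                start, end = int(epos[i]), int(epos[j - 1]) + 2
                if abs(diff) < params.min_diff:
                    continue
                if end - start < params.min_length_nt:
                    continue
                if params.mwu_mode == "cpg_sample":
                    xn = r[i:j, cm.normal_idx].ravel()
                    xc = r[i:j, cm.cancer_idx].ravel()
                else:
                    xn = np.nanmean(r[i:j, cm.normal_idx], axis=0)
                    xc = np.nanmean(r[i:j, cm.cancer_idx], axis=0)
                xn, xc = xn[~np.isnan(xn)], xc[~np.isnan(xc)]
                _, p = _mannwhitney(xn, xc)
                candidates.append(
                    DMRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_cpgs=j - i,
                        mean_normal=float(np.mean(mean_n[i:j])),
                        mean_cancer=float(np.mean(mean_c[i:j])),
                        p_value=p,
                    )
                )
                pvals.append(p)
    if not candidates:
        return []
    qvals = benjamini_hochberg(pvals)
    kept = []
    for rec, q in zip(candidates, qvals):
        rec.q_value = float(q)
        if q < params.q_threshold:
            kept.append(rec)
    kept.sort(key=lambda rec: (rec.chrom, rec.start))
    return kept
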