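"""QC, normalization and per-amplicon statistics for multiplex MSRE-PCR
count tables.

Samples are normalized to a non-differential internal control amplicon
(Control3); digestion completeness is checked with a consistently
unmethylated control (Control1) that should yield essentially no product.
Amplicons averaging fewer than 10 raw reads per sample are removed before
testing. Differential amplification is assessed per amplicon with a
two-sided Mann-Whitney U test, Benjamini-Hochberg corrected, and a
per-amplicon ROC AUC from the same U statistic (ties half-weighted).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dmr import _mannwhitney, benjamini_hochberg
from .io import AssayTable

__all__ = [
    "filter_low_count",
    "normalize",
    "digestion_qc",
    "amplicon_statistics",
    "export_heatmap_matrix",
    "rank_auc",
]


def filter_low_count(
    table: AssayTable, min_mean: float = 10.0
) -> tuple[AssayTable, list[str]]:
    """Drop amplicons with mean raw count strictly below ``min_mean``.

    Control amplicons are structural and exempt. Returns (filtered table,
    removed amplicon ids).
    """
    means = table.counts.mean(axis=1)
    controls = {table.control_norm, table.control_digest}
    removed = [
        a for a in table.counts.index if a not in controls and means[a] < min_mean
    ]
    kept = table.counts.drop(index=removed)
    return dataclasses.replace(table, counts=kept), removed


def normalize(table: AssayTable) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample division by the Control3 count.

    Samples in which Control3 is zero cannot be normalized; they are dropped
    and reported as QC failures rather than silently divided. The Control3
    row becomes all ones. Returns (normalized DataFrame, failed samples).
    """
    if table.control_norm not in table.counts.index:
        raise ValueError(f"normalization control {table.control_norm!r} missing")
    ctrl = table.counts.loc[table.control_norm]
    failed = list(ctrl.index[ctrl == 0])
    ok = [s for s in table.counts.columns if s not in failed]
    normalized = table.counts[ok] / ctrl[ok]
    return normalized, failed


def digestion_qc(
    normalized: pd.DataFrame, control_digest: str = "Control1", threshold: float = 0.05
) -> pd.DataFrame:
    """Per-sample digestion check: fail when the normalized digestion-control
    signal exceeds ``threshold`` (incomplete digestion leaves undigested
    unmethylated template to amplify)."""
    if control_digest not in normalized.index:
        raise ValueError(f"digestion control {control_digest!r} missing from table")
    vals = normalized.loc[control_digest]
    return pd.DataFrame(
        {"control1_normalized": vals, "pass": vals <= threshold}
    )


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney U statistic / (n1*n2), ties counted 1/2.

    Equals the fraction of (tumor, normal) pairs in which the tumor scores
    higher, plus half the tied pairs.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    allv = np.concatenate([pos, neg])
    from scipy.stats import rankdata

    ranks = rankdata(allv)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def amplicon_statistics(
    normalized: pd.DataFrame,
    table: AssayTable,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-amplicon differential statistics on normalized values.

    Fold change = (mean cancer + eps) / (mean normal + eps) — the
    pseudocount applies to the group means only, never to the per-sample
    values entering the rank test. MWU p-values are BH-corrected across
    amplicons; AUC treats cancer as the positive class.
    """
    samples = list(normalized.columns)
    groups = table.metadata.loc[samples, "group"]
    cancer_cols = [s for s in samples if groups[s] == "cancer"]
    normal_cols = [s for s in samples if groups[s] == "normal"]
    if len(cancer_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("need >=2 samples in each group")
    rows = []
    for amp in normalized.index:
        x_c = normalized.loc[amp, cancer_cols].to_numpy(float)
        x_n = normalized.loc[amp, normal_cols].to_numpy(float)
        fc = (x_c.mean() + eps) / (x_n.mean() + eps)
        if np.all(x_c == x_c[0]) and np.all(x_n == x_n[0]) and x_c[0] == x_n[0]:
            p, auc = 1.0, 0.5
        else:
            _, p = _mannwhitney(x_n, x_c)
            auc = rank_auc(x_c, x_n)
        rows.append(
            {
                "amplicon": amp,
                "mean_normal": x_n.mean(),
                "mean_cancer": x_c.mean(),
                "fold_change": fc,
                "log2_fold_change": np.log2(fc),
                "p": p,
                "auc": auc,
            }
        )
    stats_table = pd.DataFrame(rows).set_index("amplicon")
    stats_table["q"] = benjamini_hochberg(stats_table["p"].to_numpy())
    return stats_table


def export_heatmap_matrix(
    normalized: pd.DataFrame,
    table: AssayTable,
    selected: list[str],
    path: str | None = None,
) -> pd.DataFrame:
    """Matrix for heatmap rendering: samples ordered by tissue then id
    (supervised x), amplicons by complete-linkage correlation clustering
    (unsupervised y). Written as TSV when ``path`` is given."""
    if not selected:
        raise ValueError("no amplicons selected")
    sub = normalized.loc[selected]
    meta = table.metadata.loc[list(sub.columns)]
    sample_order = sorted(sub.columns, key=lambda s: (meta.loc[s, "group"], meta.loc[s, "tissue"], s))
    if len(selected) > 2:
        mat = sub.to_numpy(float)
        # correlation distance; degenerate (constant) rows fall back to 0 distance
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(mat, metric="correlation")
        d = np.nan_to_num(d, nan=0.0)
        link = hierarchy.linkage(d, method="complete")
        amp_order = [selected[i] for i in hierarchy.leaves_list(link)]
    else:
        amp_order = list(selected)
    out = sub.loc[amp_order, sample_order]
    if path is not None:
        out.to_csv(path, sep="\t", index_label="amplicon")
    return out
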