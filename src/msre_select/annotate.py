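"""Genomic-context annotation of regions: gene parts, CpG-island context,
TSS distance and gene-set over-representation.

Gene parts are assigned with the precedence promoter > exon > intron >
intergenic, with the promoter a fixed +/-1 kb window around the TSS; CpG
context is island if overlapping an island, shore within 2 kb of one, other
beyond. Distances to the TSS are measured from the nearest region edge (zero
on overlap), matching the convention under which "overlaps the TSS" means
distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import benjamini_hochberg
from .io import GenomeAssets

__all__ = [
    "AnnotationParams",
    "RegionAnnotation",
    "annotate_region",
    "annotate_regions",
    "summarize_annotations",
    "closest_gene_list",
    "gene_set_enrichment",
]

GENE_PARTS = ["promoter", "exon", "intron", "intergenic"]
CPG_CONTEXTS = ["island", "shore", "other"]


@dataclass
class AnnotationParams:
    promoter_flank_nt: int = 1000
    shore_flank_nt: int = 2000

    def __post_init__(self) -> None:
        if self.promoter_flank_nt <= 0 or self.shore_flank_nt <= 0:
            raise ValueError("flanks must be positive")


@dataclass
class RegionAnnotation:
    gene_part: str
    cpg_context: str
    distance_to_tss: int
    tss_overlap: bool
    closest_gene: str


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _edge_distance(start: int, end: int, point: int) -> int:
    """Distance from a half-open interval to a point: 0 inside, else the gap
    to the nearest interval boundary (start - point, or point - end)."""
    if point < start:
        return start - point
    if point >= end:
        return point - end
    return 0


def annotate_region(
    region, assets: GenomeAssets, params: AnnotationParams | None = None
) -> RegionAnnotation:
    """Annotate one region (any object with chrom/start/end)."""
    params = params or AnnotationParams()
    chrom, start, end = region.chrom, region.start, region.end
    genes = [g for g in assets.genes if g.chrom == chrom]

    gene_part = "intergenic"
    if not assets.genes:
        gene_part = "undefined"
    else:
        in_promoter = any(
            _overlaps(start, end, g.tss - params.promoter_flank_nt, g.tss + params.promoter_flank_nt)
            for g in genes
        )
        in_exon = any(
            _overlaps(start, end, es, ee) for g in genes for es, ee in g.exons
        )
        in_intron = any(
            _overlaps(start, end, g.start, g.end) for g in genes
        )
        if in_promoter:
            gene_part = "promoter"
        elif in_exon:
            gene_part = "exon"
        elif in_intron:
            gene_part = "intron"

    islands = [(s, e) for c, s, e in assets.cpg_islands if c == chrom]
    if any(_overlaps(start, end, s, e) for s, e in islands):
        cpg_context = "island"
    elif any(
        _overlaps(start, end, s - params.shore_flank_nt, e + params.shore_flank_nt)
        for s, e in islands
    ):
        cpg_context = "shore"
    else:
        cpg_context = "other"

    closest_gene, distance = "", -1
    if genes:
        ranked = sorted(
            genes, key=lambda g: (_edge_distance(start, end, g.tss), g.gene_id)
        )
        closest_gene = ranked[0].gene_id
        distance = _edge_distance(start, end, ranked[0].tss)
    return RegionAnnotation(
        gene_part=gene_part,
        cpg_context=cpg_context,
        distance_to_tss=distance,
        tss_overlap=distance == 0,
        closest_gene=closest_gene,
    )


def annotate_regions(
    regions: Sequence, assets: GenomeAssets, params: AnnotationParams | None = None
) -> list[RegionAnnotation]:
    return [annotate_region(r, assets, params) for r in regions]


def summarize_annotations(annotations: Sequence[RegionAnnotation]) -> dict:
    """Category fractions (each vocabulary sums to 1), mean TSS distance and
    TSS-overlap fraction."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    n = len(annotations)
    gene_part = {
        part: sum(a.gene_part == part for a in annotations) / n for part in GENE_PARTS
    }
    cpg_context = {
        ctx: sum(a.cpg_context == ctx for a in annotations) / n for ctx in CPG_CONTEXTS
    }
    dists = [a.distance_to_tss for a in annotations if a.distance_to_tss >= 0]
    return {
        "gene_part": gene_part,
        "cpg_context": cpg_context,
        "mean_distance_to_tss": float(np.mean(dists)) if dists else float("nan"),
        "tss_overlap_fraction": sum(a.tss_overlap for a in annotations) / n,
    }


def closest_gene_list(annotations: Sequence[RegionAnnotation]) -> list[str]:
    """Deduplicated, sorted closest-gene identifiers."""
    return sorted({a.closest_gene for a in annotations if a.closest_gene})


def gene_set_enrichment(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    p = P(overlap >= observed) under sampling len(gene_list) genes from the
    universe without replacement; q by Benjamini-Hochberg across the sets.
    """
    selected = set(gene_list)
    uni = set(universe)
    if not selected <= uni:
        raise ValueError(f"genes outside the universe: {sorted(selected - uni)[:5]}")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    rows = []
    for name, members in gene_sets.items():
        members_in = set(members) & uni
        overlap = len(selected & members_in)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(uni), len(members_in), len(selected))
        )
        rows.append({"set": name, "set_size": len(members_in), "overlap": overlap, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values("p", ignore_index=True)
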