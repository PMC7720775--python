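"""Readers and writers for every on-disk format the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). The coverage
reader is the single place where 1-based arithmetic occurs: Bismark-style
coverage files are 1-based inclusive and are shifted on read. CpGs are
represented once, at the forward-strand C; records on the opposite strand can
optionally be merged into the forward position at read time.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CALL_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

__all__ = [
    "Methylome",
    "Cohort",
    "Gene",
    "GenomeAssets",
    "read_coverage",
    "write_coverage",
    "write_regions_bed",
    "read_regions_bed",
    "read_count_table",
    "write_count_table",
    "read_fasta",
    "write_fasta",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_gene_models",
    "write_gene_models",
    "load_config",
]


class CoverageParseError(ValueError):
    """Raised for malformed coverage lines; carries the offending line number."""


@dataclass
class Methylome:
    """Per-CpG methylation calls for one sample.

    ``calls`` is a DataFrame with columns chrom, pos, n_meth, n_unmeth,
    sorted by (chrom, pos) with unique positions. ``pos`` is the 0-based
    coordinate of the C of the CpG on the forward strand.
    """

    sample_id: str
    group: str
    calls: pd.DataFrame
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("normal", "cancer"):
            raise ValueError(f"group must be 'normal' or 'cancer', got {self.group!r}")
        c = self.calls
        if list(c.columns) != CALL_COLUMNS:
            self.calls = c = c.loc[:, CALL_COLUMNS]
        if (c["n_meth"] < 0).any() or (c["n_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        dup = c.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in methylome calls")

    @property
    def coverage(self) -> np.ndarray:
        return (self.calls["n_meth"] + self.calls["n_unmeth"]).to_numpy()


@dataclass
class Cohort:
    """A labelled collection of methylomes with both groups non-empty."""

    samples: list[Methylome]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        if not self.normal or not self.cancer:
            raise ValueError("cohort must contain both normal and cancer samples")

    @property
    def normal(self) -> list[Methylome]:
        return [s for s in self.samples if s.group == "normal"]

    @property
    def cancer(self) -> list[Methylome]:
        return [s for s in self.samples if s.group == "cancer"]

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.group
        raise KeyError(sample_id)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class GenomeAssets:
    """Genome sequence plus the annotation intervals the pipeline needs.

    All intervals are 0-based half-open; the TSS is the transcript start
    respecting strand (strand '-' genes start at their rightmost base).
    """

    sequence: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    cpg_islands: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, s, e in self.cpg_islands:
            if chrom in self.sequence and not (0 <= s < e <= len(self.sequence[chrom])):
                raise ValueError(f"island {chrom}:{s}-{e} outside chromosome bounds")


# ---------------------------------------------------------------------------
# Coverage (Bismark-style) files
# ---------------------------------------------------------------------------

def read_coverage(
    path: str | os.PathLike,
    sample_id: str | None = None,
    group: str = "normal",
    tissue: str = "",
    merge_strands: bool = False,
    sequence: Mapping[str, str] | None = None,
) -> Methylome:
    """Read a Bismark-style coverage file into a :class:`Methylome`.

    Columns: chrom, start(1-based), end, percent methylation, count
    methylated, count unmethylated. Positions are converted to 0-based. With
    ``merge_strands`` and a reference ``sequence``, a record at position p+1
    whose reference context is a CG starting at p is folded into the
    forward-strand C at p and the counts summed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CoverageParseError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns"
                )
            try:
                chrom = parts[0]
                pos = int(parts[1]) - 1
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}: line {lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative counts")
            rows.append((chrom, pos, n_meth, n_unmeth))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if merge_strands and len(calls):
        calls = _merge_strands(calls, sequence)
    calls = (
        calls.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], ignore_index=True)
    )
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Methylome(sample_id=sample_id, group=group, tissue=tissue, calls=calls)


def _merge_strands(calls: pd.DataFrame, sequence: Mapping[str, str] | None) -> pd.DataFrame:
    """Fold reverse-strand G records (position p+1 of a CG at p) onto p.

    Without a reference sequence the CG context is inferred from the call
    positions themselves: a record at p+1 immediately following one at p is
    treated as the G of that CpG.
    """
    out = calls.copy()
    if sequence is not None:
        def shift(row):
            chrom, pos = row["chrom"], row["pos"]
            seq = sequence.get(chrom, "")
            if pos >= 1 and seq[pos - 1 : pos + 1].upper() == "CG":
                return pos - 1
            return pos
        out["pos"] = out.apply(shift, axis=1)
    else:
        keyed = {(c, p) for c, p in zip(out["chrom"], out["pos"])}
        out["pos"] = [
            p - 1 if (c, p - 1) in keyed else p for c, p in zip(out["chrom"], out["pos"])
        ]
    return out


def write_coverage(methylome: Methylome, path: str | os.PathLike) -> None:
    """Write calls back out in the 1-based coverage dialect."""
    c = methylome.calls
    cov = c["n_meth"] + c["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * c["n_meth"] / cov, 0.0)
    df = pd.DataFrame(
        {
            "chrom": c["chrom"],
            "start": c["pos"] + 1,
            "end": c["pos"] + 1,
            "pct": np.round(pct, 6),
            "n_meth": c["n_meth"],
            "n_unmeth": c["n_unmeth"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Region BED (6+ columns with statistics)
# ---------------------------------------------------------------------------

_REGION_EXTRA = [
    "n_cpgs", "mean_normal", "mean_cancer", "mean_diff", "p_value", "q_value",
]


def write_regions_bed(regions: Iterable, path: str | os.PathLike) -> None:
    """Write region records as BED6+ with statistics columns.

    Columns: chrom, start, end, name, score (=-10*log10 q clipped to 1000),
    strand '.', then n_cpgs, mean_normal, mean_cancer, mean_diff, p_value,
    q_value, direction. Round-trips through :func:`read_regions_bed`.
    """
    header = "#chrom\tstart\tend\tname\tscore\tstrand\t" + "\t".join(_REGION_EXTRA) + "\tdirection\n"
    with open(path, "w") as fh:
        fh.write(header)
        for i, r in enumerate(regions):
            q = getattr(r, "q_value", 1.0)
            score = 1000 if q <= 0 else min(1000, int(round(-10 * np.log10(max(q, 1e-300)))))
            name = getattr(r, "name", f"region_{i + 1}")
            extras = [repr(getattr(r, k)) for k in _REGION_EXTRA]
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\t"
                + "\t".join(extras)
                + f"\t{r.direction}\n"
            )


def read_regions_bed(path: str | os.PathLike):
    """Read a BED written by :func:`write_regions_bed` back into records."""
    from .dmr import DMRecord  # local import to avoid a cycle

    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            records.append(
                DMRecord(
                    chrom=p[0],
                    start=int(p[1]),
                    end=int(p[2]),
                    n_cpgs=int(p[6]),
                    mean_normal=float(p[7]),
                    mean_cancer=float(p[8]),
                    p_value=float(p[10]),
                    q_value=float(p[11]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class AssayTable:
    """Amplicon x sample read counts with aligned sample metadata.

    ``counts`` rows are amplicons, columns are samples. ``metadata`` is
    indexed by sample with at least a ``group`` column; ``tissue`` and
    ``split`` are carried when present.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    control_norm: str = "Control3"
    control_digest: str = "Control1"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated amplicon id in count table")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples lacking metadata: {missing}")
        self.metadata = self.metadata.loc[list(self.counts.columns)]
        groups = set(self.metadata["group"])
        if not {"normal", "cancer"} <= groups and len(groups) < 2:
            raise ValueError("metadata must contain two sample groups")

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])

    def subset_samples(self, samples: Sequence[str]) -> "AssayTable":
        return dataclasses.replace(
            self, counts=self.counts.loc[:, list(samples)], metadata=self.metadata.loc[list(samples)]
        )


def read_count_table(
    path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    control_norm: str = "Control3",
    control_digest: str = "Control1",
) -> AssayTable:
    """Read an amplicon x sample count TSV and its sample sheet.

    Metadata rows for samples absent from the count table are ignored;
    count-table samples missing from the metadata raise. Non-integer count
    cells raise a parse error.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = pd.to_numeric(vals, errors="coerce")
            if as_float.isna().any() or (as_float % 1 != 0).any():
                raise ValueError(f"non-integer count in column {col!r} of {path}")
            counts[col] = as_float.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"negative count in {path}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta = meta.loc[[s for s in meta.index if s in counts.columns]]
    return AssayTable(
        counts=counts, metadata=meta, control_norm=control_norm, control_digest=control_digest
    )


def write_count_table(
    table: AssayTable, path: str | os.PathLike, metadata_path: str | os.PathLike | None = None
) -> None:
    table.counts.to_csv(path, sep="\t", index_label="amplicon")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# FASTA / BED / gene models
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(os.fspath(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            p = line.split("\t")
            out.append((p[0], int(p[1]), int(p[2])))
    return out


def write_bed_intervals(
    intervals: Iterable[tuple], path: str | os.PathLike, names: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else (iv[3] if len(iv) > 3 else f"iv_{i + 1}")
            fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\t{name}\n")


def read_gene_models(path: str | os.PathLike) -> list[Gene]:
    """Read gene models from GFF3 (``gene``/``exon`` features) or BED12."""
    path = os.fspath(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.count("\t") >= 11 and not first.split("\t")[3].isdigit():
        return _read_bed12(path)
    return _read_gff3(path)


def _read_bed12(path: str) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            chrom, start, end, name, strand = p[0], int(p[1]), int(p[2]), p[3], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offs = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            tss = start if strand == "+" else end - 1
            genes.append(Gene(name, chrom, strand, tss, exons))
    return genes


def _read_gff3(path: str) -> list[Gene]:
    bounds: dict[str, list] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = p[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", ""))
                bounds[gid] = [chrom, strand, int(start) - 1, int(end)]
            elif ftype == "exon":
                gid = attr.get("Parent", attr.get("gene_id", ""))
                exons.setdefault(gid, []).append((int(start) - 1, int(end)))
    genes = []
    for gid, (chrom, strand, s, e) in bounds.items():
        ex = tuple(sorted(exons.get(gid, [(s, e)])))
        tss = s if strand == "+" else e - 1
        genes.append(Gene(gid, chrom, strand, tss, ex))
    return genes


def write_gene_models(genes: Sequence[Gene], path: str | os.PathLike) -> None:
    """Write genes as GFF3 with gene and exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmsre_select\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tmsre_select\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
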