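"""Amplicon and primer design for multiplex MSRE-PCR panels.

Design constraints follow the assay geometry: each amplicon must contain at
least 2 MSRE sites (so a normal-tissue molecule is cut with high
probability), be shorter than 150 bp (amplifiable from fragmented template),
and carry primers near a 61 degC melting temperature. Primers are CpG-free
by default so the primer annealing itself is methylation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import GenomeAssets
from .msre import DEFAULT_PANEL, EnzymePanel, count_cpgs_and_site_cpgs, scan_sites

__all__ = [
    "DesignConstraints",
    "Amplicon",
    "melting_temperature",
    "design_amplicons",
    "export_panel",
    "read_panel",
]

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class DesignConstraints:
    min_msre_sites: int = 2
    max_amplicon_len: int = 150  # exclusive upper bound
    target_tm_c: float = 61.0
    tm_tolerance_c: float = 2.0
    primer_len_range: tuple[int, int] = (18, 27)
    max_cpgs_in_primer: int = 0
    tm_method: str = "nn"

    def __post_init__(self) -> None:
        if self.max_amplicon_len <= 0 or self.primer_len_range[0] <= 0:
            raise ValueError("lengths must be positive")
        if self.tm_tolerance_c < 0:
            raise ValueError("tm tolerance must be non-negative")


@dataclass
class Amplicon:
    chrom: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    fwd_tm: float
    rev_tm: float
    n_cpgs: int
    n_msre_sites: int
    n_cpgs_in_sites: int
    parent_region: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


# SantaLucia (1998) unified nearest-neighbor parameters:
# dH in kcal/mol, dS in cal/(mol K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
_R = 1.987  # cal/(mol K)


def melting_temperature(
    primer: str,
    method: str = "nn",
    na_mM: float = 50.0,
    primer_nM: float = 250.0,
) -> float:
    """Primer melting temperature in degrees Celsius.

    'wallace': 2*(A+T) + 4*(G+C), the quick rule for short oligos (length
    >= 4). 'nn': nearest-neighbor thermodynamics with the SantaLucia (1998)
    unified parameter set, entropic salt correction 0.368*(N-1)*ln[Na+], and
    Tm = dH / (dS + R ln(CT/4)) for non-self-complementary duplexes (length
    >= 8).
    """
    seq = primer.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid primer sequence: {primer!r}")
    if method == "wallace":
        if len(seq) < 4:
            raise ValueError("wallace rule needs length >= 4")
        return float(
            2 * (seq.count("A") + seq.count("T")) + 4 * (seq.count("G") + seq.count("C"))
        )
    if method != "nn":
        raise ValueError(f"unknown Tm method {method!r}")
    if len(seq) < 8:
        raise ValueError("nearest-neighbor Tm needs length >= 8")
    import math

    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = primer_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + _R * math.log(ct / 4.0))
    return tm_k - 273.15


def _count_cpgs(seq: str) -> int:
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")


def design_amplicons(
    region,
    genome: GenomeAssets,
    panel: EnzymePanel = DEFAULT_PANEL,
    constraints: DesignConstraints | None = None,
) -> tuple[list[Amplicon], dict[str, int]]:
    """Exhaustively scan a target region for feasible amplicons.

    Every sub-interval shorter than ``max_amplicon_len`` with at least
    ``min_msre_sites`` fully contained MSRE sites is considered; its primer
    windows (forward at the 5' end, reverse = reverse complement of the 3'
    window) must reach the target Tm within tolerance and contain at most
    ``max_cpgs_in_primer`` CpGs. Candidates are emitted greedily
    non-overlapping, best score first, where score = (CpGs inside sites,
    site count, smaller mean |Tm - target|), ties to the leftmost start.

    Returns (amplicons, per-constraint failure tally).
    """
    constraints = constraints or DesignConstraints()
    chrom, rstart, rend = region.chrom, region.start, region.end
    seq = genome.sequence[chrom][rstart:rend].upper()
    n = len(seq)
    tally = {"min_msre_sites": 0, "primer_tm": 0, "primer_cpgs": 0}
    all_sites = scan_sites(seq, panel)
    site_starts = [s.start for s in all_sites]
    # cumulative count of CpG starts at positions <= i
    cpg_cum = []
    c = 0
    for i in range(n):
        if seq[i : i + 2] == "CG":
            c += 1
        cpg_cum.append(c)

    lo, hi = constraints.primer_len_range

    def primer_options(anchor: int, forward: bool):
        """Feasible primers anchored at one amplicon edge, as a cumulative
        best-by-|Tm deviation| table indexed by maximum allowed length."""
        per_len: list[tuple[str, float, float, int] | None] = []
        for plen in range(lo, hi + 1):
            sub = seq[anchor : anchor + plen] if forward else seq[anchor - plen : anchor]
            entry = None
            if len(sub) == plen and (not forward or anchor + plen <= n) and (forward or anchor - plen >= 0):
                if _count_cpgs(sub) > constraints.max_cpgs_in_primer:
                    tally["primer_cpgs"] += 1
                else:
                    primer = sub if forward else reverse_complement(sub)
                    try:
                        tm = melting_temperature(primer, constraints.tm_method)
                    except ValueError:
                        tm = None
                    if tm is not None:
                        dev = abs(tm - constraints.target_tm_c)
                        if dev <= constraints.tm_tolerance_c:
                            entry = (primer, tm, dev, plen)
            per_len.append(entry)
        best = None
        cumulative = []
        for entry in per_len:
            if entry is not None and (best is None or entry[2] < best[2]):
                best = entry
            cumulative.append(best)
        return cumulative  # cumulative[k] = best primer with plen <= lo+k

    fwd_table = [primer_options(p, forward=True) for p in range(n)]
    rev_table = [primer_options(p, forward=False) for p in range(n + 1)]

    def pick(table_entry, max_plen: int):
        k = min(max_plen, hi) - lo
        return table_entry[k] if k >= 0 else None

    candidates = []
    import bisect

    for start in range(n):
        for end in range(start + 2 * lo, min(n, start + constraints.max_amplicon_len - 1) + 1):
            # sites fully inside [start, end)
            i0 = bisect.bisect_left(site_starts, start)
            i1 = bisect.bisect_right(site_starts, end - 4)
            n_sites = i1 - i0
            if n_sites < constraints.min_msre_sites:
                tally["min_msre_sites"] += 1
                continue
            # primers must not overlap within the amplicon
            max_plen = (end - start) // 2
            fwd = pick(fwd_table[start], max_plen)
            rev = pick(rev_table[end], max_plen)
            if fwd is None or rev is None:
                tally["primer_tm"] += 1
                continue
            n_cpg = cpg_cum[end - 2] - (cpg_cum[start - 1] if start else 0)
            site_cpgs: set[int] = set()
            for s in all_sites[i0:i1]:
                site_cpgs.update(s.cpg_positions)
            n_cpg_sites = len(site_cpgs)
            mean_dev = (fwd[2] + rev[2]) / 2.0
            candidates.append(
                (
                    (-n_cpg_sites, -n_sites, mean_dev, start, end - start),
                    Amplicon(
                        chrom=chrom,
                        start=rstart + start,
                        end=rstart + end,
                        fwd_primer=fwd[0],
                        rev_primer=rev[0],
                        fwd_tm=fwd[1],
                        rev_tm=rev[1],
                        n_cpgs=n_cpg,
                        n_msre_sites=n_sites,
                        n_cpgs_in_sites=n_cpg_sites,
                        parent_region=f"{chrom}:{rstart}-{rend}",
                    ),
                )
            )
    candidates.sort(key=lambda c: c[0])
    chosen: list[Amplicon] = []
    for _, amp in candidates:
        if all(amp.end <= c.start or amp.start >= c.end for c in chosen):
            chosen.append(amp)
    chosen.sort(key=lambda a: a.start)
    return chosen, tally


def export_panel(amplicons: Sequence[Amplicon], tsv_path: str, fasta_path: str | None = None) -> None:
    """Write the panel as a descriptor TSV plus primer FASTA, deterministically
    ordered by coordinate."""
    if not amplicons:
        raise ValueError("empty panel")
    amps = sorted(amplicons, key=lambda a: (a.chrom, a.start))
    cols = [
        "name", "chrom", "start", "end", "length", "fwd_primer", "rev_primer",
        "fwd_tm", "rev_tm", "n_cpgs", "n_msre_sites", "n_cpgs_in_sites", "parent_region",
    ]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, a in enumerate(amps):
            name = f"amp_{i + 1:03d}"
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        name, a.chrom, a.start, a.end, a.length, a.fwd_primer,
                        a.rev_primer, repr(a.fwd_tm), repr(a.rev_tm), a.n_cpgs,
                        a.n_msre_sites, a.n_cpgs_in_sites, a.parent_region,
                    ]
                )
                + "\n"
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for i, a in enumerate(amps):
                fh.write(f">amp_{i + 1:03d}_F\n{a.fwd_primer}\n>amp_{i + 1:03d}_R\n{a.rev_primer}\n")


def read_panel(tsv_path: str) -> list[Amplicon]:
    out = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                Amplicon(
                    chrom=d["chrom"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    fwd_primer=d["fwd_primer"],
                    rev_primer=d["rev_primer"],
                    fwd_tm=float(d["fwd_tm"]),
                    rev_tm=float(d["rev_tm"]),
                    n_cpgs=int(d["n_cpgs"]),
                    n_msre_sites=int(d["n_msre_sites"]),
                    n_cpgs_in_sites=int(d["n_cpgs_in_sites"]),
                    parent_region=d["parent_region"],
                )
            )
    return out
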