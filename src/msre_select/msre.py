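"""Methylation-sensitive restriction enzyme (MSRE) site scanning and the
per-molecule digestion-survival model behind MSRE-PCR selectivity.

The five-enzyme panel (HhaI, HpaII, HpyCH4IV, AciI, BstUI) covers all the
commercially common 4-cutter MSREs whose recognition sequence contains a CpG.
Each enzyme cleaves its site only when every CpG inside the recognition
window is unmethylated; methylation of any in-site CpG protects the site. A
template molecule amplifies only if none of its sites is cleaved, which is
what makes multi-site amplicons strongly selective for methylated
(tumor-derived) DNA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Enzyme",
    "EnzymePanel",
    "MSRESite",
    "DEFAULT_PANEL",
    "scan_sites",
    "count_cpgs_and_site_cpgs",
    "sites_vs_cpgs_regression",
    "survival_probability",
    "simulate_digestion",
    "predicted_fold_change",
]


@dataclass(frozen=True)
class Enzyme:
    """One MSRE: name, forward recognition 4-mer, and whether the site is
    palindromic (palindromes occur once per duplex; non-palindromes such as
    AciI's CCGC also match as GCGG on the forward strand)."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        if len(self.recognition) != 4:
            raise ValueError("recognition sequence must be 4 bp")
        if "CG" not in self.recognition:
            raise ValueError("MSRE recognition sequence must contain a CpG")

    @property
    def reverse_complement(self) -> str:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return "".join(comp[b] for b in reversed(self.recognition))

    @property
    def palindromic(self) -> bool:
        return self.recognition == self.reverse_complement


@dataclass(frozen=True)
class EnzymePanel:
    enzymes: tuple[Enzyme, ...]

    def match_table(self) -> dict[str, tuple[str, str]]:
        """4-mer -> (enzyme name, orientation). Palindromes map once ('+');
        a non-palindrome contributes its forward word ('+') and its reverse
        complement ('-')."""
        table: dict[str, tuple[str, str]] = {}
        for e in self.enzymes:
            table[e.recognition] = (e.name, "+")
            if not e.palindromic:
                table[e.reverse_complement] = (e.name, "-")
        return table


DEFAULT_PANEL = EnzymePanel(
    enzymes=(
        Enzyme("HhaI", "GCGC"),
        Enzyme("HpaII", "CCGG"),
        Enzyme("HpyCH4IV", "ACGT"),
        Enzyme("AciI", "CCGC"),
        Enzyme("BstUI", "CGCG"),
    )
)


@dataclass(frozen=True)
class MSRESite:
    """A recognition-site occurrence on the forward strand.

    ``cpg_positions`` holds the position of the C of each CG dinucleotide
    inside the 4-bp window (1 or 2 CpGs)."""

    enzyme: str
    start: int
    end: int
    orientation: str
    cpg_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.end - self.start != 4:
            raise ValueError("MSRE site window must be 4 bp")
        if not 1 <= len(self.cpg_positions) <= 2:
            raise ValueError("site must contain 1 or 2 CpGs")


def scan_sites(sequence: str, panel: EnzymePanel = DEFAULT_PANEL) -> list[MSRESite]:
    """Enumerate all (possibly overlapping) MSRE sites on the forward strand.

    Windows containing N never match. Output is sorted by start, then enzyme
    name.
    """
    seq = sequence.upper()
    table = panel.match_table()
    sites = []
    for i in range(len(seq) - 3):
        word = seq[i : i + 4]
        hit = table.get(word)
        if hit is None:
            continue
        cpgs = tuple(i + j for j in range(3) if word[j : j + 2] == "CG")
        sites.append(MSRESite(hit[0], i, i + 4, hit[1], cpgs))
    sites.sort(key=lambda s: (s.start, s.enzyme))
    return sites


def count_cpgs_and_site_cpgs(
    sequence: str, panel: EnzymePanel = DEFAULT_PANEL
) -> tuple[int, int]:
    """Count CG dinucleotides and the distinct CpGs covered by >=1 MSRE site."""
    seq = sequence.upper()
    cpg_positions = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    in_sites = set()
    for site in scan_sites(seq, panel):
        in_sites.update(site.cpg_positions)
    return len(cpg_positions), len(in_sites & set(cpg_positions))


def sites_vs_cpgs_regression(
    n_cpgs: Sequence[int], n_sites: Sequence[int]
) -> tuple[float, float, float]:
    """OLS of site count on CpG count across regions: (slope, intercept, R^2)."""
    x = np.asarray(n_cpgs, dtype=float)
    y = np.asarray(n_sites, dtype=float)
    if x.size < 3:
        raise ValueError("need >=3 regions for the regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: CpG counts are constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _site_components(sites: Sequence[MSRESite]) -> list[list[MSRESite]]:
    """Group sites into connected components of shared CpG positions."""
    parent = list(range(len(sites)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_cpg: dict[int, int] = {}
    for idx, s in enumerate(sites):
        for c in s.cpg_positions:
            if c in by_cpg:
                ri, rj = find(by_cpg[c]), find(idx)
                parent[ri] = rj
            else:
                by_cpg[c] = idx
    comps: dict[int, list[MSRESite]] = {}
    for idx, s in enumerate(sites):
        comps.setdefault(find(idx), []).append(s)
    return list(comps.values())


def _check_profile(sites: Iterable[MSRESite], profile: Mapping[int, float]) -> None:
    for s in sites:
        for c in s.cpg_positions:
            if c not in profile:
                raise ValueError(f"CpG at {c} in site {s.enzyme}@{s.start} missing from profile")
            if not 0.0 <= profile[c] <= 1.0:
                raise ValueError(f"methylation probability at {c} out of [0,1]")


def survival_probability(
    sites: Sequence[MSRESite], profile: Mapping[int, float]
) -> float:
    """Probability that a single template molecule survives digestion.

    A site is cleaved iff every CpG in its window is unmethylated on the
    molecule; the molecule survives iff no site is cleaved. CpG states are
    independent Bernoulli(m). When no two sites share a CpG the closed form
    is prod_sites(1 - prod_{c in site}(1 - m_c)); components of CpG-sharing
    sites (common in GCGCGC runs) are handled by exact enumeration over the
    shared CpGs' states.
    """
    _check_profile(sites, profile)
    if not sites:
        return 1.0
    p = 1.0
    for comp in _site_components(sites):
        if len(comp) == 1:
            site = comp[0]
            p_cleave = float(np.prod([1.0 - profile[c] for c in site.cpg_positions]))
            p *= 1.0 - p_cleave
        else:
            cpgs = sorted({c for s in comp for c in s.cpg_positions})
            p_ok = 0.0
            for states in itertools.product((0, 1), repeat=len(cpgs)):
                state = dict(zip(cpgs, states))
                pr = float(
                    np.prod([profile[c] if st else 1.0 - profile[c] for c, st in state.items()])
                )
                if pr == 0.0:
                    continue
                cleaved = any(
                    all(state[c] == 0 for c in s.cpg_positions) for s in comp
                )
                if not cleaved:
                    p_ok += pr
            p *= p_ok
    return float(min(max(p, 0.0), 1.0))


def simulate_digestion(
    sites: Sequence[MSRESite],
    profile: Mapping[int, float],
    n_molecules: int,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo estimate of :func:`survival_probability`.

    Samples each CpG's methylation state once per molecule and applies the
    cleavage rule; unbiased for the closed form.
    """
    _check_profile(sites, profile)
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not sites:
        return 1.0
    cpgs = sorted({c for s in sites for c in s.cpg_positions})
    idx = {c: i for i, c in enumerate(cpgs)}
    probs = np.array([profile[c] for c in cpgs])
    states = rng.random((n_molecules, len(cpgs))) < probs  # True = methylated
    survived = np.ones(n_molecules, dtype=bool)
    for s in sites:
        cols = [idx[c] for c in s.cpg_positions]
        cleaved = ~states[:, cols].any(axis=1)
        survived &= ~cleaved
    return float(survived.mean())


def predicted_fold_change(
    sites: Sequence[MSRESite],
    tumor_profile: Mapping[int, float],
    normal_profile: Mapping[int, float],
    tumor_fraction: float = 1.0,
) -> float:
    """Expected tumor-sample / normal-sample ratio of surviving template.

    A tumor-containing sample is a mixture ``tumor_fraction`` of tumor
    molecules and the rest normal; the reference is pure normal. Returns
    ``inf`` when the normal survival probability is zero (perfect
    selectivity), never a division error.
    """
    if not 0.0 < tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in (0, 1]")
    s_t = survival_probability(sites, tumor_profile)
    s_n = survival_probability(sites, normal_profile)
    numer = tumor_fraction * s_t + (1.0 - tumor_fraction) * s_n
    if s_n == 0.0:
        return float("inf") if numer > 0 else 1.0
    return numer / s_n
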