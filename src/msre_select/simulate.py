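"""Synthetic genomes, WGBS-like methylomes and multiplex assay count tables.

The generator emulates the study conditions of a two-group WGBS discovery
cohort plus a downstream multiplex MSRE-PCR assay: 9 normal vs 9 cancer
methylomes at ~11x mean coverage; CpG islands nearly unmethylated in normal
tissue (~1.5%) against a ~75% methylated background, so the cohort-wide
global methylation lands near 67% in normals; cancers combine a global
background loss (factor 0.8, global mean near 55%) with planted island
hypermethylation conserved in a subset (default 60%) of tumors; and an
amplicon panel sequenced to 50,000 reads per sample in which informative
amplicons are ~10-fold elevated in tumors. Everything is reproducible from a
seed, with stage-tagged substreams so one stage's draws never perturb
another's.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AssayTable, Cohort, Gene, GenomeAssets, Methylome

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "stage_rng",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_assay_counts",
    "default_sample_sheet",
    "dmr_benchmark_config",
]

NORMAL_TISSUES = ["liver", "lung", "breast", "colon", "blood"]
CANCER_TISSUES = ["lung", "liver", "colon", "prostate", "breast"]


def stage_rng(seed: int, tag: str) -> np.random.Generator:
    """Seeded generator for a named pipeline stage."""
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence((int(seed), h)))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_islands: int = 30
    island_length_nt: int = 600
    island_length_jitter: float = 0.5  # island lengths uniform in (1 +/- jitter) x length
    island_cpg_rate: float = 0.10
    background_cpg_rate: float = 0.02
    # cohort
    n_normal: int = 9
    n_cancer: int = 9
    mean_coverage: float = 11.0
    beta_dispersion: float = 0.05
    normal_island_meth: float = 0.015
    normal_background_meth: float = 0.75
    cancer_global_factor: float = 0.80
    planted_hyper_fraction: float = 0.5
    planted_hyper_meth: float = 0.20
    hyper_sample_fraction: float = 0.6
    n_hypo_blocks: int = 0
    hypo_delta: float = 0.25
    hypo_block_cpgs: int = 20
    # assay
    n_amplicons: int = 50
    n_informative: int = 7
    fold_change: float = 10.0
    depth: int = 50_000
    assay_dispersion: float = 0.1
    n_low_count: int = 3
    control1_weight: float = 2e-5
    assay_hyper_sample_fraction: float = 0.6

    def __post_init__(self) -> None:
        probs = [
            self.island_cpg_rate, self.background_cpg_rate, self.normal_island_meth,
            self.normal_background_meth, self.planted_hyper_fraction,
            self.planted_hyper_meth, self.hyper_sample_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length, self.n_normal, self.n_cancer) <= 0:
            raise ValueError("counts must be positive")
        if self.mean_coverage <= 0 or self.beta_dispersion < 0:
            raise ValueError("coverage must be positive, dispersion non-negative")
        if self.n_islands and self.island_length_nt >= self.chrom_length:
            raise ValueError("island length exceeds chromosome length")
        if not 0 < self.cancer_global_factor <= 1:
            raise ValueError("cancer_global_factor must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each simulated artifact."""

    hyper_islands: list[tuple[str, int, int]] = field(default_factory=list)
    hypo_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    informative_amplicons: list[str] = field(default_factory=list)

    def planted_regions(self) -> list[tuple[str, int, int, str]]:
        return [(c, s, e, "hyper") for c, s, e in self.hyper_islands] + [
            (c, s, e, "hypo") for c, s, e in self.hypo_blocks
        ]


def dmr_benchmark_config(seed: int = 0, delta: float = 0.25, n_regions: int = 100) -> SimulationConfig:
    """Configuration of the planted-DMR recovery benchmark.

    ``n_regions`` hyper islands (~20 CpGs each) and as many hypo blocks of 20
    consecutive background CpGs are planted with a group-mean difference of
    ``delta`` (realized through the conserved-in-a-fraction tumor
    heterogeneity model). The cancer-wide background factor is 1 so the
    planted set is the exhaustive ground truth.
    """
    base = SimulationConfig(seed=seed)
    return replace(
        base,
        seed=seed,
        n_chromosomes=4,
        chrom_length=500_000,
        n_islands=n_regions,
        island_length_nt=220,
        island_length_jitter=0.0,
        planted_hyper_fraction=1.0,
        planted_hyper_meth=min(0.99, base.normal_island_meth + delta),
        cancer_global_factor=1.0,
        n_hypo_blocks=n_regions,
        hypo_delta=delta,
    )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, seed: int | None = None) -> GenomeAssets:
    """Random genome with CpGs planted densely inside islands.

    CpG dinucleotides start at each position with probability
    ``island_cpg_rate`` inside islands and ``background_cpg_rate`` elsewhere
    (overlapping starts are dropped left-to-right); accidental CGs are
    removed so observed CpG density tracks the configured rates. One gene is
    placed per island with its TSS at the island midpoint.
    """
    rng = stage_rng(config.seed if seed is None else seed, "genome")
    sequence: dict[str, str] = {}
    islands: list[tuple[str, int, int]] = []
    genes: list[Gene] = []
    per_chrom = _split_count(config.n_islands, config.n_chromosomes)
    bases = np.array(list("ACGT"))
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        seq = bases[rng.integers(0, 4, size=L)]
        # island placement: evenly spaced slots with jitter, never touching ends
        n_isl = per_chrom[ci]
        chrom_islands = []
        if n_isl:
            slot = L // n_isl
            max_len = int(config.island_length_nt * (1 + config.island_length_jitter))
            if slot <= max_len + 4000:
                raise ValueError("islands do not fit on chromosome")
            for k in range(n_isl):
                length = int(
                    round(
                        config.island_length_nt
                        * rng.uniform(1 - config.island_length_jitter, 1 + config.island_length_jitter)
                    )
                )
                lo = k * slot + 2000
                hi = (k + 1) * slot - 2000 - length
                start = int(rng.integers(lo, max(lo + 1, hi)))
                chrom_islands.append((chrom, start, start + length))
        # per-position CpG start rate
        rate = np.full(L, config.background_cpg_rate)
        for _, s, e in chrom_islands:
            rate[s:e] = config.island_cpg_rate
        starts = np.where(rng.random(L - 1) < rate[:-1])[0]
        keep = []
        last = -2
        for s in starts:
            if s >= last + 2:
                keep.append(s)
                last = s
        starts = np.array(keep, dtype=int)
        seq[starts] = "C"
        seq[starts + 1] = "G"
        # remove accidental CGs so CpG placement is exactly the planted set
        planted = np.zeros(L, dtype=bool)
        planted[starts] = True
        is_cg = (seq[:-1] == "C") & (seq[1:] == "G")
        accidental = np.where(is_cg & ~planted[:-1])[0]
        seq[accidental + 1] = "A"
        sequence[chrom] = "".join(seq)
        islands.extend(chrom_islands)
        for k, (_, s, e) in enumerate(chrom_islands):
            tss = (s + e) // 2
            exon1 = (tss, min(tss + 200, L))
            exon2 = (min(tss + 800, L - 1), min(tss + 1500, L))
            genes.append(Gene(f"gene_{chrom}_{k + 1:03d}", chrom, "+", tss, (exon1, exon2)))
    return GenomeAssets(sequence=sequence, genes=genes, cpg_islands=islands)


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def simulate_methylomes(
    genome: GenomeAssets, config: SimulationConfig, seed: int | None = None
) -> tuple[Cohort, GroundTruth]:
    """WGBS-like cohort with planted hyper islands and hypo blocks.

    Per CpG and sample, a true methylation level is drawn from a Beta
    distribution centred at the tier mean (island vs background; planted
    tiers in cancer only), coverage from Poisson(mean_coverage), and the
    methylated count from a Binomial. ``beta_dispersion`` is the phi
    parameterization (variance = m(1-m)*phi); zero gives the degenerate
    Beta. Planted hyper islands affect a fixed-size random subset of cancer
    samples (``hyper_sample_fraction``); hypo blocks lower all cancer
    samples by ``hypo_delta``.
    """
    base_seed = config.seed if seed is None else seed
    rng = stage_rng(base_seed, "methylomes")
    truth = GroundTruth()

    # choose planted hyper islands
    n_hyper = int(round(config.planted_hyper_fraction * len(genome.cpg_islands)))
    hyper_idx = set(
        rng.choice(len(genome.cpg_islands), size=n_hyper, replace=False).tolist()
    ) if n_hyper else set()

    n_c = config.n_cancer
    n_aff = int(round(config.hyper_sample_fraction * n_c))
    samples_meta = [("N%d" % (i + 1), "normal", NORMAL_TISSUES[i % len(NORMAL_TISSUES)]) for i in range(config.n_normal)]
    samples_meta += [("C%d" % (i + 1), "cancer", CANCER_TISSUES[i % len(CANCER_TISSUES)]) for i in range(n_c)]
    n_samples = len(samples_meta)
    is_cancer = np.array([g == "cancer" for _, g, _ in samples_meta])

    calls_per_sample: list[list[pd.DataFrame]] = [[] for _ in range(n_samples)]
    for chrom in sorted(genome.sequence):
        seq = genome.sequence[chrom]
        pos = _cpg_positions(seq)
        n_pos = pos.size
        chrom_islands = [
            (i, s, e) for i, (c, s, e) in enumerate(genome.cpg_islands) if c == chrom
        ]
        in_island = np.zeros(n_pos, dtype=bool)
        island_of = np.full(n_pos, -1)
        for i, s, e in chrom_islands:
            sel = (pos >= s) & (pos < e)
            in_island |= sel
            island_of[sel] = i

        # tier means: (n_pos, n_samples)
        m = np.full((n_pos, n_samples), config.normal_background_meth)
        m[:, is_cancer] = config.normal_background_meth * config.cancer_global_factor
        m[in_island, :] = config.normal_island_meth
        cancer_cols = np.where(is_cancer)[0]
        # planted_hyper_meth is the cancer-group mean; with hypermethylation
        # conserved in only a fraction of tumors, affected samples carry
        # proportionally more so the group mean realizes the configured value
        frac = n_aff / n_c if n_c else 1.0
        m_affected = min(
            0.99,
            config.normal_island_meth
            + (config.planted_hyper_meth - config.normal_island_meth) / max(frac, 1e-9),
        )
        for i, s, e in chrom_islands:
            if i not in hyper_idx:
                continue
            affected = rng.choice(cancer_cols, size=n_aff, replace=False)
            rows = np.where(island_of == i)[0]
            m[np.ix_(rows, affected)] = m_affected
            truth.hyper_islands.append((chrom, int(pos[rows][0]), int(pos[rows][-1]) + 2))

        # hypo blocks: runs of consecutive background CpGs, evenly spread
        bg_rows = np.where(~in_island)[0]
        blocks = _pick_hypo_blocks(bg_rows, pos, config, len(genome.sequence), chrom)
        hypo_mean = max(
            0.01, config.normal_background_meth * config.cancer_global_factor - config.hypo_delta
        )
        for rows in blocks:
            m[np.ix_(rows, cancer_cols)] = hypo_mean
            truth.hypo_blocks.append((chrom, int(pos[rows[0]]), int(pos[rows[-1]]) + 2))

        # beta-binomial draws
        if config.beta_dispersion > 0:
            s_conc = (1.0 - config.beta_dispersion) / config.beta_dispersion
            a = np.clip(m * s_conc, 1e-6, None)
            b = np.clip((1.0 - m) * s_conc, 1e-6, None)
            m_true = rng.beta(a, b)
            m_true[m == 0.0] = 0.0
            m_true[m == 1.0] = 1.0
        else:
            m_true = m
        cov = rng.poisson(config.mean_coverage, size=m.shape)
        n_meth = rng.binomial(cov, m_true)
        for j in range(n_samples):
            covered = cov[:, j] > 0
            calls_per_sample[j].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[covered],
                        "n_meth": n_meth[covered, j],
                        "n_unmeth": cov[covered, j] - n_meth[covered, j],
                    }
                )
            )

    methylomes = [
        Methylome(
            sample_id=sid,
            group=grp,
            tissue=tis,
            calls=pd.concat(frames, ignore_index=True),
        )
        for (sid, grp, tis), frames in zip(samples_meta, calls_per_sample)
    ]
    return Cohort(samples=methylomes), truth


def _pick_hypo_blocks(
    bg_rows: np.ndarray,
    pos: np.ndarray,
    config: SimulationConfig,
    n_chroms: int,
    chrom: str,
    max_gap_nt: int = 250,
) -> list[np.ndarray]:
    """Evenly spaced runs of ``hypo_block_cpgs`` consecutive background CpGs.

    A planted block must be one contiguous CpG run: not interrupted by an
    island and with no internal CpG gap larger than ``max_gap_nt``, so that
    it constitutes a single region rather than several.
    """
    per_chrom = _split_count(config.n_hypo_blocks, n_chroms)
    k = per_chrom[int(chrom.removeprefix("chr")) - 1]
    w = config.hypo_block_cpgs
    if k == 0 or bg_rows.size < w:
        return []
    # candidate window starts: w consecutive background rows, contiguous in
    # the genome-wide row index, with bounded internal gaps
    contiguous = np.ones(bg_rows.size - w + 1, dtype=bool)
    row_span = bg_rows[w - 1 :] - bg_rows[: bg_rows.size - w + 1]
    contiguous &= row_span == w - 1
    gaps = np.diff(pos[bg_rows])
    for off in range(w - 1):
        contiguous &= gaps[off : off + contiguous.size] <= max_gap_nt
    starts = np.where(contiguous)[0]
    if starts.size < k:
        raise ValueError("not enough contiguous background CpG runs for hypo blocks")
    blocks = []
    last_end = -w
    # evenly spaced picks, skipping windows that would touch the previous one
    targets = np.linspace(0, bg_rows.size - w, k).astype(int)
    for t in targets:
        cand = starts[np.searchsorted(starts, max(t, last_end + w))] if np.any(
            starts >= max(t, last_end + w)
        ) else None
        if cand is None:
            break
        blocks.append(bg_rows[cand : cand + w])
        last_end = cand
    return blocks


# ---------------------------------------------------------------------------
# Assay counts
# ---------------------------------------------------------------------------

def default_sample_sheet(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """100-sample assay cohort: 12 tumors + 8 normals for each of four solid
    tissues plus 20 normal blood samples, randomly split 50/50 train/test
    stratified by group."""
    rng = stage_rng(config.seed if seed is None else seed, "sample_sheet")
    rows = []
    i = 0
    for tissue in ["lung", "breast", "colon", "stomach"]:
        for _ in range(12):
            i += 1
            rows.append((f"S{i:03d}", "cancer", tissue))
        for _ in range(8):
            i += 1
            rows.append((f"S{i:03d}", "normal", tissue))
    for _ in range(20):
        i += 1
        rows.append((f"S{i:03d}", "normal", "blood"))
    meta = pd.DataFrame(rows, columns=["sample", "group", "tissue"]).set_index("sample")
    meta["split"] = ""
    for grp in ("normal", "cancer"):
        ids = list(meta.index[meta["group"] == grp])
        rng.shuffle(ids)
        half = len(ids) // 2
        meta.loc[ids[:half], "split"] = "train"
        meta.loc[ids[half:], "split"] = "test"
    return meta


def simulate_assay_counts(
    config: SimulationConfig,
    panel_size: int | None = None,
    sample_sheet: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[AssayTable, GroundTruth]:
    """Multiplex assay read counts with planted tumor-elevated amplicons.

    Counts are negative binomial (gamma-Poisson) around depth x weight.
    Informative amplicons' tumor-group mean weight is ``fold_change`` times
    their normal weight; "Control3" is non-differential and used for
    normalization; "Control1" models the fully digested control and sits
    near zero; a few amplicons are planted below the low-count filter.
    """
    base_seed = config.seed if seed is None else seed
    rng = stage_rng(base_seed, "assay")
    if sample_sheet is None:
        sample_sheet = default_sample_sheet(config, seed=base_seed)
    panel_size = panel_size or config.n_amplicons
    if panel_size < config.n_informative + 2:
        raise ValueError("panel must fit the informative amplicons plus 2 controls")

    n_bg = panel_size - config.n_informative - config.n_low_count - 2
    if n_bg < 0:
        raise ValueError("panel too small for the configured composition")
    names, kinds = [], []
    for i in range(config.n_informative):
        names.append(f"Amp{i + 1:02d}")
        kinds.append("informative")
    for i in range(n_bg):
        names.append(f"Amp{config.n_informative + i + 1:02d}")
        kinds.append("background")
    for i in range(config.n_low_count):
        names.append(f"Low{i + 1:02d}")
        kinds.append("low")
    names += ["Control1", "Control3"]
    kinds += ["control_digest", "control_norm"]

    is_cancer = (sample_sheet["group"] == "cancer").to_numpy()
    n_samples = len(sample_sheet)
    cancer_cols = np.where(is_cancer)[0]
    # per-sample weight matrix; tumor elevation of an informative amplicon is
    # conserved in a fixed-size subset of tumors, sized so the tumor-group
    # mean is exactly fold_change x the normal mean
    weights = np.empty((panel_size, n_samples))
    frac = config.assay_hyper_sample_fraction
    n_elev = max(1, int(round(frac * len(cancer_cols)))) if len(cancer_cols) else 0
    for i, kind in enumerate(kinds):
        if kind == "informative":
            w = 0.005 * rng.uniform(0.5, 1.5)
            weights[i, :] = w
            if n_elev:
                f_elev = (config.fold_change - (1 - n_elev / len(cancer_cols))) * len(
                    cancer_cols
                ) / n_elev
                elevated = rng.choice(cancer_cols, size=n_elev, replace=False)
                weights[i, elevated] = w * f_elev
        elif kind == "background":
            weights[i, :] = 0.02 * rng.uniform(0.5, 1.5)
        elif kind == "low":
            weights[i, :] = 1e-4
        elif kind == "control_digest":
            weights[i, :] = config.control1_weight
        else:
            weights[i, :] = 0.02
    mu = weights * config.depth
    if config.assay_dispersion > 0:
        shape = 1.0 / config.assay_dispersion
        lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) / shape * mu, 0.0)
    else:
        lam = mu
    counts = rng.poisson(lam)
    table = AssayTable(
        counts=pd.DataFrame(counts, index=names, columns=list(sample_sheet.index)),
        metadata=sample_sheet.copy(),
    )
    truth = GroundTruth(
        informative_amplicons=[n for n, k in zip(names, kinds) if k == "informative"]
    )
    return table, truth


def write_ground_truth(truth: GroundTruth, regions_bed: str | None = None, amplicons_tsv: str | None = None) -> None:
    """Emit the planted truth in machine-readable form."""
    if regions_bed is not None:
        with open(regions_bed, "w") as fh:
            for chrom, s, e, direction in truth.planted_regions():
                fh.write(f"{chrom}\t{s}\t{e}\t{direction}\n")
    if amplicons_tsv is not None:
        pd.DataFrame({"amplicon": truth.informative_amplicons}).to_csv(
            amplicons_tsv, sep="\t", index=False
        )
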