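# Methods

`msre_select` implements a discovery-to-assay workflow for DNA-methylation
cancer biomarkers built around methylation-sensitive restriction enzymes
(MSREs). This note documents the models, the synthetic data the package is
validated on, and the numerical and design choices a maintainer would want
to know about.

## The problem and the model

MSRE-PCR detects tumor-derived DNA by digesting a sample with restriction
enzymes that cut only unmethylated recognition sites, then amplifying target
regions by PCR. A molecule amplifies only if *every* MSRE site between its
primers was methylated and therefore protected. The ideal target region is
(i) essentially unmethylated in all normal tissues, so normal template is
destroyed; (ii) recurrently hypermethylated across tumor types, so tumor
template survives; and (iii) dense in MSRE sites, so the digestion is
multiply redundant.

The package covers the full chain:

1. **Cohort characterization** (`dmr`): per-sample global methylation
   (count-weighted), pairwise Pearson correlation on jointly covered CpGs,
   and a two-sided Mann–Whitney U comparison of the groups (exact for group
   sizes ≤ 8 without ties, normal approximation with tie correction
   otherwise).
2. **DMR calling** (`dmr.call_dmrs`): CpGs covered in ≥ 80% of each group
   are partitioned into runs broken at gaps > 300 nt; within each run,
   recursive binary segmentation selects windows of ≥ 10 consecutive CpGs;
   candidates are filtered on |group-mean difference| ≥ 0.15, genomic length
   ≥ 80 nt and CpG count, tested per region by Mann–Whitney U on pooled
   per-CpG per-sample methylation ratios, corrected by Benjamini–Hochberg
   genome-wide, and emitted at Q < 0.01. The effect-size, length and
   Q-value defaults are the filter set commonly used for cancer-vs-normal
   WGBS discovery; region ends cover the final CG dinucleotide (last CpG
   position + 2).
3. **Target selection** (`targets`): hypermethylated DMRs whose
   normal-group mean methylation, recomputed from the cohort, is strictly
   below 2.5%.
4. **MSRE modeling** (`msre`): exhaustive 4-mer scanning for HhaI (GCGC),
   HpaII (CCGG), HpyCH4IV (ACGT), AciI (CCGC, plus its reverse-complement
   reading GCGG) and BstUI (CGCG); a per-molecule digestion survival model;
   and the predicted tumor/normal amplification ratio.
5. **Amplicon design** (`design`): exhaustive sub-interval scan under the
   assay constraints (≥ 2 MSRE sites, < 150 bp, primer Tm ≈ 61 °C).
6. **Annotation** (`annotate`): gene parts with precedence promoter > exon >
   intron > intergenic, CpG island/shore/other context, TSS distances, and
   hypergeometric gene-set over-representation.
7. **Assay analysis** (`assay`) and **panel modeling** (`model`): control
   normalization, low-count filtering, per-amplicon Mann–Whitney U /
   Benjamini–Hochberg / ROC AUC, and an L1-penalized logistic panel chosen
   by cross-validation with the one-standard-error rule.

## Segmentation objective

The window search maximizes the scan statistic |Σ diff| / √L (L = CpGs in
the window) rather than the plain mean difference. Under per-CpG noise the
mean objective is maximized by the shortest admissible window almost surely,
which fragments true blocks; the scan form has length-invariant noise
variance and recovers signal blocks at full extent. The search is further
restricted to windows whose mean difference already passes the effect-size
threshold: without this, a long hypomethylated background window spanning an
embedded hypermethylated island can outscore the island, fail the filter,
and shadow it. The plain-mean objective remains available
(`DMRParams(segmentation_objective="mean")`). Ties are broken by leftmost
start, then shortest window, so calling is deterministic; it is also
invariant to sample order within groups because only group means enter the
objective.

## Digestion survival model

A site is cleaved iff every CpG in its 4-bp window is unmethylated on that
molecule; the molecule survives iff no site is cleaved. With CpG states
independent Bernoulli(m), disjoint sites give the closed form
Π_sites (1 − Π_{c∈site}(1 − m_c)). Sites sharing CpGs (GCGCGC-type runs,
common in islands) are grouped into connected components and handled by
exact enumeration over the shared CpGs' states — correctness over speed is
the right trade at 4-mer scale. `simulate_digestion` is the Monte-Carlo
counterpart used to cross-validate the closed form. Within-molecule CpG
independence is an assumption, not an observation; fully correlated
molecules ("all-or-none" methylation) would make multi-site amplicons less
selective than the independent model predicts, and the predicted fold
changes should be read as the independent-CpG limit.

## Melting temperature

`design.melting_temperature` implements the Wallace rule and
nearest-neighbor thermodynamics with the SantaLucia (1998) unified parameter
set, the entropic salt correction 0.368·(N−1)·ln[Na⁺] (default 50 mM), and
Tm = ΔH / (ΔS + R ln(CT/4)) with CT the total strand concentration (default
250 nM, equimolar convention). Agreement with an independent implementation
of the same parameter set is within fractions of a degree once the
concentration convention is matched. Primers are CpG-free by default so
primer annealing is methylation-independent; this and the primer length
range (18–27 nt) are declared defaults, exposed in `DesignConstraints`.

## Sparse panel model

Features are log2(normalized count + ε), ε = 10⁻³, standardized with
training statistics only (per CV fold inside cross-validation — no
leakage). The λ path starts at the smallest penalty that zeroes all
coefficients and descends four decades over 100 points; each point is fit
with liblinear (C = 1/(nλ), seeded). CV uses stratified 3-fold pooled
out-of-fold AUC with per-fold SD supplying the standard error for the
one-SE rule. One guard: on near-separable data, fold-level fits at the
full-data λ_max can already carry an informative coefficient, scoring the
head of the path perfectly while the full-data refit there is empty; the
selection therefore takes the largest qualifying λ whose full-data refit is
non-empty, falling back to the plain one-SE choice only when no such λ
exists (null data, where the intercept-only model is the honest answer).
Confidence intervals use the DeLong variance of the AUC U-statistic,
truncated to [0, 1].

## Synthetic cohorts: what they emulate and what they do not

`simulate` generates all validation data from a seed, with stage-tagged
substreams so adding a stage never shifts another stage's draws.

**Genome.** Random sequence with CpG dinucleotides planted at 0.10/nt inside
islands and 0.02/nt in background; accidental CGs are removed so density is
exactly controlled. Defaults: 2 chromosomes × 400 kb, 30 islands of
600 nt ± 50% (length jitter makes island CpG counts vary, as real islands
do). One gene per island with its TSS at the island midpoint, so island
targets are promoter/TSS-proximal by construction. Island CpGs are ~10% of
all CpGs, chosen so the cohort's global methylation matches the tiers below.

**Methylomes.** 9 normal vs 9 cancer samples. Per CpG and sample, a true
methylation level is drawn from a Beta centred on the tier mean with
dispersion φ = 0.05 (variance m(1−m)φ); coverage ~ Poisson(11); methylated
counts ~ Binomial. Tiers: normal islands 1.5%, normal background 75%
(global ≈ 67%); cancer background is scaled by 0.80 (global ≈ 55%,
reproducing both the global hypomethylation and the higher inter-sample
variability of tumors). A configurable fraction of islands (default 50%) is
hypermethylated in cancer: `planted_hyper_meth` (default 0.20) is the
planted *cancer-group mean*; hypermethylation is conserved in only 60% of
tumors (`hyper_sample_fraction`), with affected samples proportionally
higher so the group mean realizes the configured value. Hypomethylated
blocks (runs of 20 contiguous background CpGs) can additionally be planted;
they affect all cancer samples, since tumor hypomethylation is broad rather
than sample-sparse.

**DMR benchmark.** `dmr_benchmark_config` plants 100 hyper islands
(~20 CpGs, fixed 220 nt) and 100 hypo blocks at a group-mean difference of
0.25 on a 2-Mb genome, with the cancer-wide background factor set to 1 so
the planted set is the exhaustive ground truth (a genome-wide shift would
make every background CpG truly differential and undefine the
false-discovery proportion). Recall uses 50% reciprocal overlap; a call is
a false discovery when less than half of its own length lies in planted
regions, so a planted block recovered as two partial calls is not penalized
as a false positive.

**Assay counts.** 50 amplicons × 100 samples (4 tissues × 12 tumors + 8
normals, plus 20 normal blood), negative-binomial (gamma–Poisson,
dispersion 0.1) around depth × weight at 50,000 reads/sample. Seven
informative amplicons are elevated in a fixed-size 60% subset of tumors,
scaled so the tumor-group mean is exactly `fold_change` (default 10×) the
normal mean — single amplicons therefore discriminate imperfectly
(AUC ≈ 0.8), and the panel model is genuinely needed, matching how such
assays behave. "Control3" is a non-differential normalization control;
"Control1" models the fully digested control near zero; three amplicons are
planted below the 10-read filter.

**What passing these tests does not show.** The simulator has clean tier
structure, independent CpGs, no copy-number or purity variation, no
bisulfite conversion error, no mapping bias, and planted regions that
coincide with annotation units. Recovery rates on it bound the method's
behavior under its own assumptions; they do not predict performance on real
WGBS or assay data, where effect sizes, covariance and artifacts are less
favorable.

## Numerical and interface conventions

- All internal coordinates are 0-based half-open; the Bismark-style coverage
  reader is the only 1-based conversion point. CpGs live at the
  forward-strand C; opposite-strand records can be merged at read time.
- Zero-coverage calls are retained on read and ignored by statistics;
  coverage files round-trip losslessly.
- Benjamini–Hochberg is applied once genome-wide for DMRs and once across
  amplicons for the assay; q-values are clipped to [0, 1] and verified
  against an independent implementation in the tests.
- TSS distance is measured from the nearest region edge (`start − tss` or
  `tss − end`), 0 on overlap.
- The ε pseudocount in assay fold changes applies to group means only; the
  rank tests see raw normalized values.
- Problem sizes in the tests and the acceptance script (2-chromosome /
  2-Mb genomes, 9 + 9 methylomes, 100 assay samples, 10⁵ molecules for
  Monte-Carlo digestion, 100 permutations/seeds for null calibrations) are
  chosen so the full suite exercises every stage at statistical resolution
  comparable to its planted effects.

## Known limitations

- The DMR caller assumes exchangeable samples within groups; no covariates,
  pairing, or per-sample quality weights.
- Exact enumeration in the survival model is exponential in the CpGs of a
  shared-site component; components larger than ~20 shared CpGs (unseen in
  4-mer practice) would need a different algorithm.
- Amplicon design screens neither primer dimers/hairpins nor genome-wide
  primer specificity; it optimizes only the stated constraints.
- The enrichment module tests user-supplied gene sets; it ships no ontology.
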