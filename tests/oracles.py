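"""Independent brute-force oracles used by several test modules.

These deliberately share no code with the implementation: plain loops over
every possibility, written for clarity rather than speed.
"""

import itertools

RECOGNITION = {
    "GCGC": ("HhaI", "+"),
    "CCGG": ("HpaII", "+"),
    "ACGT": ("HpyCH4IV", "+"),
    "CCGC": ("AciI", "+"),
    "GCGG": ("AciI", "-"),
    "CGCG": ("BstUI", "+"),
}


def brute_scan(seq):
    """All 4-mer recognition matches: list of (enzyme, start, orientation)."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 3):
        word = seq[i : i + 4]
        if word in RECOGNITION:
            enzyme, orient = RECOGNITION[word]
            out.append((enzyme, i, orient))
    return sorted(out, key=lambda t: (t[1], t[0]))


def brute_cpg_inventory(seq):
    """(n_cpg, n_cpg_in_sites) by checking every CpG against every site."""
    seq = seq.upper()
    cpgs = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    covered = 0
    for c in cpgs:
        hit = False
        for _, start, _ in brute_scan(seq):
            if start <= c and c + 2 <= start + 4:
                hit = True
        covered += hit
    return len(cpgs), covered


def brute_survival(sites, profile):
    """Exact survival probability by enumerating every CpG state vector."""
    cpgs = sorted({c for s in sites for c in s.cpg_positions})
    total = 0.0
    for states in itertools.product([0, 1], repeat=len(cpgs)):
        state = dict(zip(cpgs, states))
        pr = 1.0
        for c, st in state.items():
            pr *= profile[c] if st else 1.0 - profile[c]
        cleaved = any(all(state[c] == 0 for c in s.cpg_positions) for s in sites)
        if not cleaved:
            total += pr
    return total if cpgs else 1.0


def brute_region_group_mean(cohort, chrom, start, end, group):
    """Mean over in-interval CpGs of (mean over covered group samples)."""
    positions = set()
    for s in cohort.samples:
        if s.group != group:
            continue
        for _, row in s.calls.iterrows():
            if row["chrom"] == chrom and start <= row["pos"] < end:
                positions.add(row["pos"])
    per_cpg = []
    for p in sorted(positions):
        ratios = []
        for s in cohort.samples:
            if s.group != group:
                continue
            sub = s.calls[(s.calls["chrom"] == chrom) & (s.calls["pos"] == p)]
            if len(sub):
                n_m = float(sub["n_meth"].iloc[0])
                n_u = float(sub["n_unmeth"].iloc[0])
                if n_m + n_u > 0:
                    ratios.append(n_m / (n_m + n_u))
        if ratios:
            per_cpg.append(sum(ratios) / len(ratios))
    if not per_cpg:
        raise ValueError("no covered CpGs")
    return sum(per_cpg) / len(per_cpg)


def brute_auc(pos, neg):
    """Concordant-pair fraction with half weight on ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
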