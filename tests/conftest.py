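import numpy as np
import pandas as pd
import pytest

from msre_select.io import Cohort, Methylome
from msre_select.simulate import SimulationConfig, simulate_genome, simulate_methylomes


def make_methylome(sample_id, group, records, tissue=""):
    """records: iterable of (chrom, pos, n_meth, n_unmeth)."""
    calls = pd.DataFrame(records, columns=["chrom", "pos", "n_meth", "n_unmeth"])
    calls = calls.sort_values(["chrom", "pos"], ignore_index=True)
    return Methylome(sample_id=sample_id, group=group, tissue=tissue, calls=calls)


def constant_cohort(ratios_by_sample, coverage=1000, chrom="chr1", positions=None):
    """Cohort where sample s has exact methylation ratio ratios_by_sample[s][i]
    at CpG i (realized with large integer counts)."""
    samples = []
    for sid, (group, ratios) in ratios_by_sample.items():
        pos = positions or [10 * (i + 1) for i in range(len(ratios))]
        recs = [
            (chrom, p, int(round(r * coverage)), coverage - int(round(r * coverage)))
            for p, r in zip(pos, ratios)
        ]
        samples.append(make_methylome(sid, group, recs))
    return Cohort(samples=samples)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def toy_genome(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def toy_cohort(toy_genome, default_config):
    cohort, truth = simulate_methylomes(toy_genome, default_config)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
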