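import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from psfarray.arrays import ProbeMatrix
from psfarray.pipeline import run_classification, run_discovery
from psfarray.psf import SamConfig
from psfarray.simulate import SimConfig, generate_experiment

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_matrix(array, n_probesets=1, scale="linear", samples=None):
    """ProbeMatrix from a 2-D array split evenly into probesets."""
    array = np.asarray(array, dtype=float)
    rows, n_samples = array.shape
    k = rows // n_probesets
    index = pd.MultiIndex.from_arrays(
        [
            np.repeat([f"PS{i}" for i in range(n_probesets)], k),
            np.tile(np.arange(1, k + 1), n_probesets),
        ],
        names=("probeset_id", "probe_index"),
    )
    columns = samples or [f"S{j}" for j in range(n_samples)]
    return ProbeMatrix(pd.DataFrame(array, index=index, columns=columns), scale=scale)


def make_sheet(genotypes, replicates):
    rows = [
        {"sample_id": f"{g}_{r}", "genotype": g, "replicate": r}
        for g in genotypes
        for r in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def recovery_sim():
    """Study-scale synthetic experiment under the recovery conditions
    (2,000 probesets, 11 probes, 4 replicates, mismatch penalties >= 1 log2)."""
    cfg = SimConfig(seed=17, mismatch_penalty_range=(1.0, 2.0))
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def recovery_discovery(recovery_sim):
    m, sheet, _ = recovery_sim
    return run_discovery(m, sheet, SamConfig(target_fdr=0.1, seed=17))


@pytest.fixture(scope="session")
def recovery_classification(recovery_sim, recovery_discovery):
    m, sheet, _ = recovery_sim
    return run_classification(m, sheet, recovery_discovery.psf_records)


@pytest.fixture(scope="session")
def small_sim():
    """Small experiment for sequence-validation and CLI round trips."""
    return generate_experiment(SimConfig(seed=5, n_probesets=120))
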