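import numpy as np
import pandas as pd
import pytest

from thermomark.containers import OmicsMatrix
from thermomark.simulate import SimulationConfig, generate_metabolome, generate_transcriptome


def toy_matrix(values: np.ndarray, genotypes, temperatures, replicates, role="metabolome"):
    """Build an OmicsMatrix from raw arrays and parallel metadata lists."""
    n = values.shape[1]
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "genotype": list(genotypes),
            "temperature_C": list(temperatures),
            "replicate": list(replicates),
        },
        index=sample_ids,
    )
    vals = pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=sample_ids
    )
    return OmicsMatrix(values=vals, metadata=meta, role=role)


def two_group_matrix(p=20, n_per=7, effect=0.0, n_signal=3, seed=0):
    """Two-temperature single-genotype matrix with optional planted effect."""
    rng = np.random.default_rng(seed)
    log2 = rng.normal(10.0, 1.0, size=(p, 2 * n_per)) * 0 + rng.normal(
        0.0, 1.0, size=(p, 2 * n_per)
    ) + 10.0
    log2[:n_signal, n_per:] += effect
    return toy_matrix(
        2.0 ** log2,
        genotypes=["tolerant"] * 2 * n_per,
        temperatures=[25] * n_per + [35] * n_per,
        replicates=list(range(1, n_per + 1)) * 2,
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def simulated(default_config):
    metab, truth = generate_metabolome(default_config)
    expr = generate_transcriptome(default_config, truth)
    return metab, expr, truth
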