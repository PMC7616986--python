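import logging

import numpy as np
import pandas as pd
import pytest

from hrcmap.config import SimulationConfig
from hrcmap import synthetic

logging.getLogger("hrcmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120, samples_per_dataset=80, n_datasets=3,
        n_epi_prognostic=15, n_tme_prognostic=15, n_msi_genes=10,
        log_hr_per_sd=0.3, n_patients_sc=4, cells_per_patient=300,
        n_hrc_program=30, n_stem_program=8, seed=11)


@pytest.fixture(scope="session")
def small_metacohort(small_config):
    return synthetic.simulate_metacohort(small_config)


@pytest.fixture(scope="session")
def small_sorted(small_config):
    return synthetic.simulate_sorted_populations(small_config)


@pytest.fixture(scope="session")
def small_scrna(small_config):
    return synthetic.simulate_scrna(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_clinical(n, dataset_id="DS1", seed=0):
    """Minimal clinical table for hand-built matrices."""
    r = np.random.default_rng(seed)
    idx = [f"{dataset_id}_S{i}" for i in range(n)]
    return pd.DataFrame({
        "gender": r.choice(["F", "M"], n),
        "age": r.uniform(40, 80, n),
        "stage": r.choice(["I", "II", "III", "IV"], n),
        "site": r.choice(["left", "right"], n),
        "msi": r.choice(["MSI", "MSS"], n),
        "dataset_id": dataset_id,
    }, index=idx)
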