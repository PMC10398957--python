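"""Shared fixtures: one small simulated cohort and one pipeline run,
generated once per session and reused by the module tests."""

import warnings

import numpy as np
import pytest

import astrotraj as at
from astrotraj.pipeline import recovery_report, run_pipeline_data


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    return at.SimulationConfig(
        nuclei_per_type={
            "protoplasmic": 430,
            "fibrous": 250,
            "doublet_neuron": 130,
            "doublet_oligo": 120,
        },
        n_genes=600,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return at.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_params():
    return at.PipelineParams(min_nuclei=5, max_genes=599, seed=42, gate_min_nuclei=100)


@pytest.fixture(scope="session")
def small_run(small_dataset, small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline_data(small_dataset.counts, small_dataset.meta, small_params)
    return small_dataset, result


@pytest.fixture(scope="session")
def small_report(small_run):
    dataset, result = small_run
    return recovery_report(result, dataset.truth)
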