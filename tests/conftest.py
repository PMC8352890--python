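"""Shared fixtures: generated datasets at the default study conditions and a
small fast configuration for unit tests."""

import pytest

from imcorr.diffexpr import call_degs, run_differential_expression
from imcorr.io import compute_rpkm
from imcorr.simulate import SimulationConfig, generate_dataset

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size dataset at the generator's default study conditions."""
    matrix, samples, truth = generate_dataset(SimulationConfig(seed=DEFAULT_SEED))
    return matrix, samples, truth


@pytest.fixture(scope="session")
def default_rpkm(default_dataset):
    matrix, _, _ = default_dataset
    return compute_rpkm(matrix)


@pytest.fixture(scope="session")
def default_de(default_dataset):
    """Differential-expression tables and DEG summary for the default dataset."""
    matrix, samples, _ = default_dataset
    results = run_differential_expression(matrix, samples)
    return results, call_degs(results)


@pytest.fixture(scope="session")
def small_config():
    """Reduced gene budget and shallow libraries for fast unit tests."""
    return SimulationConfig(
        n_background_genes=400,
        n_signal_up=3,
        n_signal_down=3,
        responders_per_signal=6,
        library_size_mean=500_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
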