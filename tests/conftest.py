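"""Shared fixtures: synthetic datasets, networks, and one cached UQ study."""

import numpy as np
import pytest
from hypothesis import settings

from vesseluq.aorta_surrogate import assemble_network, run_cycles
from vesseluq.synthetic_data import (
    SyntheticSpec,
    make_fixture_config,
    make_inflow_waveform,
    synthesize_qa_curves,
)
from vesseluq.uq_pipeline import StudyConfig, run_uq

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def aorta_config():
    return make_fixture_config("aorta_default")


@pytest.fixture(scope="session")
def aorta_network(aorta_config):
    return assemble_network(aorta_config)


@pytest.fixture(scope="session")
def default_inflow():
    return make_inflow_waveform(1.12, 8.0e-5, 0.35)


@pytest.fixture(scope="session")
def aorta_sim(aorta_network, default_inflow):
    """One converged 10-cycle run of the default aorta at 2 MPa walls."""
    return run_cycles(aorta_network, default_inflow, n_cycles=10, dt=0.005)


@pytest.fixture(scope="session")
def synthetic_noise_free():
    """Noise-free 30-frame QA dataset from a 2 MPa ground truth."""
    return synthesize_qa_curves(SyntheticSpec(ground_truth_modulus=2.0e6))


@pytest.fixture(scope="session")
def uq_result():
    """Full UQ study at the printed image-based estimate, 2.02 MPa."""
    config = StudyConfig(elastic_modulus=2.02e6, seed=7, pdf_samples=20_000)
    return run_uq(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260401)
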