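"""Shared fixtures: the miR-210/147a/147b trio and small simulation configs."""

import numpy as np
import pytest

from mirseed import MatureMiRNA, SimulationConfig

# mature sequences as deposited in miRBase release 16
MIR210 = MatureMiRNA(id="hsa-miR-210", sequence="CUGUGCGUGUGACAGCGGCUGA")
MIR147A = MatureMiRNA(id="hsa-miR-147", sequence="GUGUGUGGAAAUGCUUCUGC")
MIR147B = MatureMiRNA(id="hsa-miR-147b", sequence="GUGUGCGGAAAUGCUUCUGC")


@pytest.fixture
def trio():
    return [MIR210, MIR147A, MIR147B]


@pytest.fixture
def rng():
    return np.random.default_rng(20120922)


@pytest.fixture
def small_config():
    """A fast planted-signal configuration for unit tests."""
    return SimulationConfig(
        rng_seed=7,
        n_transcripts=400,
        utr3_mean=500.0,
        utr3_sd=100.0,
        utr3_min=60,
        target_fraction=0.1,
        effect_mu=2.0,
        noise_sigma=0.25,
    )
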