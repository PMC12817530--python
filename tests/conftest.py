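"""Shared fixtures: a small deterministic cohort and pre-simulated trials."""

from dataclasses import replace

import numpy as np
import pytest

from perturbalance.synthdata import (
    PerGroup,
    SimConfig,
    generate_cohort,
    reference_templates,
    simulate_trial,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42, n_cai=4, n_hc=4)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def participant(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def templates(participant, sim_config):
    return reference_templates(participant, sim_config, 1)


@pytest.fixture(scope="session")
def trial(participant, sim_config, templates):
    """One simulated trial (recording, ground truth)."""
    return simulate_trial(participant, sim_config, 1, 1, template=templates)


@pytest.fixture(scope="session")
def clean_config(sim_config):
    """Noise-free configuration for closed-form checks."""
    return replace(sim_config, emg_noise_rms=0.0, accel_noise_rms=0.0,
                   hip_coupling_trial_sd=0.0,
                   fail_probability=PerGroup(cai=(0.0,), hc=(0.0,)))
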