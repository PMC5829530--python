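"""Shared fixtures: synthetic sessions analyzed once per test run."""

import numpy as np
import pytest

from griplift import (
    SimulationConfig,
    TrialContext,
    analyze_trials,
    metrics_to_frame,
    simulate_session,
    simulate_trial,
)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(noise_sd=0.0, az_noise_sd=0.0, g_jitter_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_cfg):
    """Full 7-participant, 7-phase, 4-trial noiseless session (196 trials)."""
    return simulate_session(n_participants=7, config=noiseless_cfg, seed=7)


@pytest.fixture(scope="session")
def noiseless_metrics(noiseless_session):
    metrics, failures = analyze_trials(
        [(tr.recording, tr.context) for tr in noiseless_session]
    )
    assert not failures, f"noiseless trials must all segment: {failures[:3]}"
    return metrics


@pytest.fixture(scope="session")
def noiseless_metrics_df(noiseless_metrics):
    return metrics_to_frame(noiseless_metrics)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-condition session: sensor noise and gravity jitter on."""
    return simulate_session(n_participants=7, config=SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def noisy_metrics(noisy_session):
    metrics, _failures = analyze_trials(
        [(tr.recording, tr.context) for tr in noisy_session]
    )
    return metrics


@pytest.fixture(scope="session")
def noisy_metrics_df(noisy_metrics):
    return metrics_to_frame(noisy_metrics)


def make_context(g=1.5, trial_index=1, phase="ascending", mass=0.13, phase_index=1):
    return TrialContext(
        participant="P01",
        g_level=g,
        trial_index=trial_index,
        phase=phase,
        mass=mass,
        phase_index=phase_index,
    )
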