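"""Shared fixtures: the canonical task, scaled-down calibration designs, and
one simulated session reused across modules."""

import numpy as np
import pytest

from stopsig.race import SubjectParams, simulate_session
from stopsig.task import TaskConfig, build_trial_sequence


@pytest.fixture(scope="session")
def paper_config():
    """The canonical five-level parameterization of the task."""
    return TaskConfig()


@pytest.fixture(scope="session")
def paper_sequence(paper_config):
    return build_trial_sequence(paper_config, seed=1)


@pytest.fixture(scope="session")
def mini_config():
    """Three-level, 72-trial task for fast fMRI-side tests."""
    return TaskConfig(
        levels=(("green", 0.0), ("orange", 0.25), ("red", 1.0 / 3.0)),
        n_stop_per_level=(0, 6, 8),
        n_go_baseline=24,
        block_size_range=(12, 15),
        rest_blocks=((0.5, 16.0),),
    )


@pytest.fixture(scope="session")
def mini_sequence(mini_config):
    return build_trial_sequence(mini_config, seed=3)


@pytest.fixture(scope="session")
def mini_scans(mini_config):
    """Scan count covering the mini task plus a short HRF tail at TR 1.6 s."""
    return int(np.ceil((mini_config.total_trials() * 2 + 16 + 20) / 1.6))


@pytest.fixture(scope="session")
def default_subject():
    return SubjectParams()


@pytest.fixture(scope="session")
def mini_session(mini_sequence, default_subject):
    return simulate_session(mini_sequence, default_subject, seed=11)


@pytest.fixture(scope="session")
def paper_session(paper_sequence, default_subject):
    return simulate_session(paper_sequence, default_subject, seed=11)
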