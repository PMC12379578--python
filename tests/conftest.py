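"""Shared fixtures: small synthetic sessions sized for fast unit tests.

Desk-scale study parameters (203 channels, 4–5 s pacing, 80 reps) are only
exercised in the acceptance tests; unit tests use miniature sessions with
the same statistical structure.
"""

import numpy as np
import pytest

from megspeech import (
    SessionConfig, generate_session, lowpass_filter, notch_filter,
    detect_bad_channels, epoch_phases,
)


def small_config(**overrides) -> SessionConfig:
    defaults = dict(
        n_channels_grad=32,
        n_reps_per_word=10,
        inter_word_interval=(2.0, 2.5),
        seed=1,
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(small_config())


@pytest.fixture(scope="session")
def filtered_session(small_session):
    out = notch_filter(lowpass_filter(small_session))
    detect_bad_channels(out)
    return out


@pytest.fixture(scope="session")
def phase_epochs(filtered_session):
    """Ground-truth-event epochs of the small session (VAD bypassed)."""
    return epoch_phases(filtered_session, filtered_session.ground_truth_events)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
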