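"""Shared synthetic sessions and models for the test suite.

Session-scoped fixtures hold the expensive artifacts (simulated EEG,
trained models) so each is generated once per run.
"""

import numpy as np
import pytest

import hypnobci as hb


@pytest.fixture(scope="session")
def signatures():
    return hb.default_signatures(hb.STANDARD_1020)


def _two_state_script(seed: int) -> hb.SessionScript:
    return hb.SessionScript(
        segments=[
            hb.Segment(120, "WAKE"),
            hb.Segment(30, "MIX", (0.0, 1.0)),
            hb.Segment(120, "DEEP"),
        ],
        fs=250.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def calibration(signatures):
    """First-session recording with ground-truth labels (seed 11)."""
    wake, deep = signatures
    return hb.generate_session(_two_state_script(11), wake, deep)


@pytest.fixture(scope="session")
def second_session(signatures):
    """Same study conditions, independent noise (seed 22)."""
    wake, deep = signatures
    return hb.generate_session(_two_state_script(22), wake, deep)


@pytest.fixture(scope="session")
def config():
    return hb.RunConfig(seed=1)


@pytest.fixture(scope="session")
def trained(calibration, config):
    rec, track = calibration
    return hb.train_model(rec, track, config)


@pytest.fixture(scope="session")
def scripted_session(signatures):
    """Wake -> deepening ramp -> deep plateau -> awakening -> wake."""
    wake, deep = signatures
    script = hb.SessionScript(
        segments=[
            hb.Segment(120, "WAKE"),
            hb.Segment(60, "MIX", (0.0, 1.0)),
            hb.Segment(240, "DEEP"),
            hb.Segment(60, "MIX", (1.0, 0.0)),
            hb.Segment(120, "WAKE"),
        ],
        fs=250.0,
        seed=77,
    )
    return hb.generate_session(script, wake, deep)


@pytest.fixture(scope="session")
def small_recording():
    """4-channel white-noise recording for I/O and filter tests."""
    rng = np.random.default_rng(7)
    return hb.EEGRecording(
        samples=rng.standard_normal((4, 5000)) * 20.0,
        fs=250.0,
        montage=["C3", "C4", "O1", "O2"],
    )
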