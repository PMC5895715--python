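import numpy as np
import pytest

import ffsmvep as fm


@pytest.fixture(scope="session")
def geometry():
    return fm.StimulusGeometry()


@pytest.fixture(scope="session")
def speller_freqs():
    return fm.layout_frequencies()


@pytest.fixture(scope="session")
def noise_free_config():
    return fm.SyntheticSessionConfig(
        noise=fm.NoiseModel(pink_scale=0, alpha_amplitude=0, mains_amplitude=0, white_scale=0),
        trial_duration_s=3.0,
    )


@pytest.fixture(scope="session")
def default_config():
    return fm.SyntheticSessionConfig(trial_duration_s=3.0)


def decode_session(session, candidate_freqs, fs_hz, duration_s, latency_s=0.150, n_harmonics=1):
    """Decode every trial of a synthetic session; return accuracy."""
    correct = 0
    for rec, f_true in session:
        (epoch, _), = fm.extract_epochs(rec, duration_s, latency_s)
        out = fm.classify_epoch(epoch, candidate_freqs, fs_hz, n_harmonics)
        correct += abs(out.predicted_hz - f_true) < 1e-9
    return correct / len(session)
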