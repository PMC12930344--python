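"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from korosound.synth import GroundTruthParams, generate_recording


@pytest.fixture(scope="session")
def young_recording():
    """Mass-early (compliant-artery) recording with truth."""
    params = GroundTruthParams(envelope_skew=0.55, beat_center_freq=40.0, seed=11)
    rec, beats, window = generate_recording(params)
    return rec, beats, window, params


@pytest.fixture(scope="session")
def older_recording():
    """Mass-late (stiff-artery) recording with truth."""
    params = GroundTruthParams(envelope_skew=-0.55, beat_center_freq=29.0, seed=12)
    rec, beats, window = generate_recording(params)
    return rec, beats, window, params


@pytest.fixture(scope="session")
def clean_recording():
    """Noise- and drift-free recording for distortion oracles."""
    params = GroundTruthParams(
        envelope_skew=0.2, noise_sd=0.0, drift_amp=0.0, seed=21
    )
    rec, beats, window = generate_recording(params)
    return rec, beats, window, params
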