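import numpy as np
import pytest

from neuromuse import (
    BandPowerFrame,
    EEGRecording,
    Note,
    QuadrantModelSet,
    Score,
    generate_corpus,
    train,
)
from neuromuse.synth import CorpusSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_frame(alpha, beta, t=0.0):
    """BandPowerFrame from per-channel (AF3, F3, F4, AF4) power tuples."""
    chans = ("AF3", "F3", "F4", "AF4")
    return BandPowerFrame(
        t_center=t,
        power={
            "alpha": dict(zip(chans, alpha)),
            "beta": dict(zip(chans, beta)),
        },
    )


def sinusoid_recording(freq_amps, duration_s=4.0, rate=128.0,
                       channels=("AF3", "F3", "F4", "AF4"), phase=0.0):
    """Recording where every channel is the same sum of sinusoids
    [(freq, amplitude), ...]."""
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    sig = sum(a * np.sin(2 * np.pi * f * t + phase) for f, a in freq_amps)
    data = np.tile(sig, (len(channels), 1))
    return EEGRecording(data=data, rate=rate, channels=channels)


@pytest.fixture
def five_note_score():
    return Score(
        notes=[
            Note(pitch=60, onset=0.0, duration=1.0, velocity=70),
            Note(pitch=62, onset=1.0, duration=0.5, velocity=75),
            Note(pitch=64, onset=1.5, duration=0.5, velocity=80),
            Note(pitch=67, onset=2.0, duration=1.0, velocity=85),
            Note(pitch=65, onset=3.0, duration=1.0, velocity=60),
        ],
        meter=(4, 4),
        tempo_bpm=120.0,
    )


@pytest.fixture(scope="session")
def trained_model_set() -> QuadrantModelSet:
    """Quadrant models fitted on a small synthetic corpus (shared, read-only)."""
    corpora = generate_corpus(CorpusSpec(n_notes=250, noise_sd=0.02, seed=5))
    models = {
        emo: (
            train(c.X, c.duration_ratio, "duration_ratio"),
            train(c.X, c.energy_ratio, "energy_ratio"),
        )
        for emo, c in corpora.items()
    }
    return QuadrantModelSet(models=models)
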