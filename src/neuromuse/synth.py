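"""Synthetic data with known ground truth for every pipeline stage.

* EEG: each channel is a 10 Hz (alpha-band centre) sinusoid plus a 20 Hz
  (beta-band centre) sinusoid with per-channel, piecewise-constant or
  linearly ramped amplitude trajectories, plus white Gaussian noise. The
  ground-truth affect series follows analytically from the amplitudes
  (band power of a sinusoid of amplitude A is A^2/2).
* Scores: monophonic melodies with random-walk pitches and durations from
  {0.25, 0.5, 1, 2} beats.
* Corpora: note-feature matrices whose duration/energy ratio targets are
  exact linear combinations of the features with known coefficients plus
  noise — so model fitting has a known answer.
* Responder: a stochastic participant stand-in whose valence drifts with
  the delivered tempo and whose arousal drifts with the delivered loudness,
  closing the feedback loop in simulation.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .affect import AffectSample, AffectSeries
from .eeg import EEGRecording
from .errors import ParameterError
from .score import FEATURE_NAMES, Note, Score, design_matrix, extract_features

ALPHA_CARRIER_HZ = 10.0  # alpha band centre
BETA_CARRIER_HZ = 20.0  # beta band centre
EEG_CHANNELS_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


def _as_segments(traj, duration_s: float):
    """Normalize an amplitude trajectory to [(t0, t1, a0, a1), ...].

    Accepts a scalar (constant), or a list of (t_start, amplitude) break
    points (piecewise constant), or (t_start, a_start, a_end) ramps.
    """
    if np.isscalar(traj):
        return [(0.0, duration_s, float(traj), float(traj))]
    segs = []
    traj = list(traj)
    for i, piece in enumerate(traj):
        t0 = float(piece[0])
        t1 = float(traj[i + 1][0]) if i + 1 < len(traj) else duration_s
        if len(piece) == 2:
            a0 = a1 = float(piece[1])
        elif len(piece) == 3:
            a0, a1 = float(piece[1]), float(piece[2])
        else:
            raise ParameterError(f"bad trajectory piece {piece!r}")
        if a0 < 0 or a1 < 0:
            raise ParameterError("amplitudes must be >= 0")
        segs.append((t0, t1, a0, a1))
    return segs


def _amplitude_at(segs, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for t0, t1, a0, a1 in segs:
        m = (t >= t0) & (t < t1)
        if t1 > t0:
            out[m] = a0 + (a1 - a0) * (t[m] - t0) / (t1 - t0)
        else:
            out[m] = a0
    # samples at/after the last break hold the final value
    if segs:
        out[t >= segs[-1][1]] = segs[-1][3]
    return out


@dataclass
class AffectScenario:
    """Recipe for a synthetic EEG recording with known affect.

    ``alpha`` and ``beta`` map channel label -> amplitude trajectory
    (microvolts); channels not named get the ``default_alpha`` /
    ``default_beta`` trajectory. ``noise_sd`` is white-noise sd in uV.
    """

    duration_s: float = 60.0
    rate: float = 128.0
    channels: tuple[str, ...] = EEG_CHANNELS_14
    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    default_alpha: object = 10.0
    default_beta: object = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @classmethod
    def from_json(cls, path) -> "AffectScenario":
        with open(path) as fh:
            d = json.load(fh)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


def generate_eeg(scn: AffectScenario) -> tuple[EEGRecording, AffectSeries]:
    """Synthesize a recording and its analytic ground-truth affect series.

    Ground truth (one sample per second) applies the arousal/valence
    formulas to the analytic band powers A(t)^2/2 of the per-channel
    amplitude trajectories; deterministic given the scenario seed.
    """
    rng = np.random.default_rng(scn.seed)
    n = int(round(scn.duration_s * scn.rate))
    t = np.arange(n) / scn.rate
    data = np.empty((len(scn.channels), n))
    alpha_segs = {}
    beta_segs = {}
    for i, ch in enumerate(scn.channels):
        a_segs = _as_segments(scn.alpha.get(ch, scn.default_alpha), scn.duration_s)
        b_segs = _as_segments(scn.beta.get(ch, scn.default_beta), scn.duration_s)
        alpha_segs[ch] = a_segs
        beta_segs[ch] = b_segs
        phase_a = rng.uniform(0, 2 * np.pi)
        phase_b = rng.uniform(0, 2 * np.pi)
        sig = _amplitude_at(a_segs, t) * np.sin(2 * np.pi * ALPHA_CARRIER_HZ * t + phase_a)
        sig += _amplitude_at(b_segs, t) * np.sin(2 * np.pi * BETA_CARRIER_HZ * t + phase_b)
        if scn.noise_sd > 0:
            sig = sig + rng.normal(0.0, scn.noise_sd, size=n)
        data[i] = sig
    rec = EEGRecording(data=data, rate=scn.rate, channels=scn.channels)

    tt = np.arange(0.0, scn.duration_s, 1.0)
    samples = []
    for ti in tt:
        tarr = np.array([ti])
        a_pow = {ch: float(_amplitude_at(alpha_segs[ch], tarr)[0] ** 2 / 2)
                 for ch in ("AF3", "F3", "F4", "AF4") if ch in scn.channels}
        b_pow = {ch: float(_amplitude_at(beta_segs[ch], tarr)[0] ** 2 / 2)
                 for ch in ("AF3", "F3", "F4", "AF4") if ch in scn.channels}
        if len(a_pow) < 4:
            continue
        alpha_sum = sum(a_pow.values())
        if alpha_sum == 0:
            continue
        samples.append(
            AffectSample(
                t=float(ti),
                arousal=sum(b_pow.values()) / alpha_sum,
                valence=a_pow["F4"] - a_pow["F3"],
            )
        )
    truth = AffectSeries(samples=samples, window_s=1.0, hop_s=1.0,
                         meta={"source": "analytic ground truth"})
    return rec, truth


def generate_score(
    n_notes: int,
    meter: tuple[int, int] = (4, 4),
    seed: int = 0,
    tempo_bpm: float = 100.0,
) -> Score:
    """Random monophonic melody: random-walk pitches in MIDI 48-84,
    durations from {0.25, 0.5, 1, 2} beats, contiguous onsets."""
    if n_notes < 1:
        raise ParameterError("need at least one note")
    rng = np.random.default_rng(seed)
    steps = np.array([-12, -9, -7, -5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, 7, 9, 12])
    weights = np.array([4, 5, 7, 6, 6, 7, 8, 7, 18, 7, 8, 7, 6, 6, 7, 5, 4], dtype=float)
    weights /= weights.sum()
    pitches = [int(rng.integers(55, 78))]
    for _ in range(n_notes - 1):
        step = int(rng.choice(steps, p=weights))
        pitches.append(int(np.clip(pitches[-1] + step, 48, 84)))
    durations = rng.choice([0.25, 0.5, 1.0, 2.0], size=n_notes, p=[0.2, 0.35, 0.35, 0.1])
    velocities = np.clip(np.round(rng.normal(72, 10, size=n_notes)), 30, 110).astype(int)
    onset = 0.0
    notes = []
    for p, d, v in zip(pitches, durations, velocities):
        notes.append(Note(pitch=p, onset=onset, duration=float(d), velocity=int(v)))
        onset += float(d)
    return Score(notes=notes, meter=meter, tempo_bpm=tempo_bpm)


def _articulated(score: Score, rng) -> Score:
    """Performed-like copy: durations scaled by a random articulation factor
    in [0.5, 1.5] of the inter-onset interval, giving a mix of detached and
    overlapping (legato) notes. Overlap is capped below the next note's IOI
    so the melody never spans past its immediate successor (monophonic)."""
    ns = score.notes
    out = []
    for i, n in enumerate(ns):
        ioi = ns[i + 1].onset - n.onset if i + 1 < len(ns) else n.duration
        factor = float(rng.uniform(0.5, 1.5))
        dur = factor * ioi
        if i + 2 < len(ns):
            next_ioi = ns[i + 2].onset - ns[i + 1].onset
            dur = min(dur, ioi + 0.9 * next_ioi)
        elif i + 1 < len(ns):
            dur = min(dur, ioi + 0.9 * ns[i + 1].duration)
        out.append(replace(n, duration=max(1e-3, dur)))
    return Score(notes=out, meter=score.meter, tempo_bpm=score.tempo_bpm)


@dataclass
class CorpusSpec:
    """Recipe for a labelled training corpus with known regression structure.

    ``true_coefficients`` maps emotion -> {"duration_ratio": (weights,
    intercept), "energy_ratio": (weights, intercept)} with one weight per
    entry of ``FEATURE_NAMES``. Targets are the exact linear form plus
    Gaussian noise, clipped to (0.25, 4).
    """

    n_notes: int = 500
    true_coefficients: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    notes_per_piece: int = 25

    def __post_init__(self) -> None:
        if self.n_notes < 10:
            raise ParameterError("corpus needs >= 10 notes")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


#: Typical span of each feature, used to express effect sizes per
#: normalized unit so random true models keep targets in a musical range.
_FEATURE_SPANS = {
    "pitch": 36.0,
    "dur": 2.0,
    "metr_str": 1.0,
    "prev_pitch": 24.0,
    "prev_dur": 8.0,
    "next_pitch": 24.0,
    "next_dur": 8.0,
}


def default_true_coefficients(seed: int = 0, scale: float = 0.05) -> dict:
    """Plausible per-emotion ground-truth coefficients.

    Weights are drawn as effects of ``scale`` ratio units per feature
    *span* (so a note at the top vs bottom of a feature's range shifts the
    target by about one ``scale``); intercepts are quadrant-typical
    (happy/angry faster and louder, sad/relaxed slower and softer).
    """
    rng = np.random.default_rng(seed)
    intercepts = {
        "happy": {"duration_ratio": 0.92, "energy_ratio": 1.10},
        "angry": {"duration_ratio": 0.88, "energy_ratio": 1.18},
        "sad": {"duration_ratio": 1.15, "energy_ratio": 0.85},
        "relaxed": {"duration_ratio": 1.05, "energy_ratio": 0.95},
    }
    spans = np.array([_FEATURE_SPANS.get(name, 1.0) for name in FEATURE_NAMES])
    out = {}
    for emo in intercepts:
        out[emo] = {}
        for target in ("duration_ratio", "energy_ratio"):
            w = rng.normal(0.0, scale, size=len(FEATURE_NAMES)) / spans
            out[emo][target] = (w, intercepts[emo][target])
    return out


@dataclass
class Corpus:
    """Training data for one emotion: features + ratio targets."""

    emotion: str
    X: np.ndarray
    duration_ratio: np.ndarray
    energy_ratio: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


def generate_corpus(spec: CorpusSpec) -> dict[str, Corpus]:
    """Per-emotion corpora with targets built from known coefficients."""
    coeffs = spec.true_coefficients or default_true_coefficients(spec.seed)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for emo in sorted(coeffs):
        blocks = []
        n_done = 0
        piece_seed = int(rng.integers(0, 2**31 - 1))
        piece_rng = np.random.default_rng(piece_seed)
        while n_done < spec.n_notes:
            n_piece = min(spec.notes_per_piece, spec.n_notes - n_done)
            sc = generate_score(n_piece, seed=int(piece_rng.integers(0, 2**31 - 1)))
            sc = _articulated(sc, piece_rng)
            blocks.append(design_matrix(extract_features(sc)))
            n_done += n_piece
        X = np.vstack(blocks)
        corpus = {}
        for target in ("duration_ratio", "energy_ratio"):
            w, b = coeffs[emo][target]
            y = X @ np.asarray(w, dtype=float) + b
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
            corpus[target] = np.clip(y, 0.25, 4.0)
        out[emo] = Corpus(
            emotion=emo,
            X=X,
            duration_ratio=corpus["duration_ratio"],
            energy_ratio=corpus["energy_ratio"],
        )
    return out


@dataclass(frozen=True)
class ResponderState:
    """Simulated participant affect: raw arousal ratio and valence (uV^2)."""

    arousal: float = 1.0
    valence: float = 0.0


#: Intrinsic upward drive of the simulated participant, in the same units
#: as the normalized feedback terms. Participants in a neurofeedback
#: protocol are *instructed* to raise tempo and loudness, so the stand-in
#: combines that intent with the reinforcement delivered by the feedback;
#: 0.3 outweighs the strongest opposing feedback (tempo_factor - 1 >= -0.2,
#: loudness/6 >= -1 is scaled the same way), so an engaged responder
#: trends upward rather than amplifying whichever way baseline noise broke.
DEFAULT_INTENT = 0.3


def simulate_responder(
    state: ResponderState,
    tempo_factor: float,
    loudness_gain_db: float,
    gain: float = 0.02,
    noise_sd: float = 0.05,
    intent: float = DEFAULT_INTENT,
    rng: np.random.Generator | None = None,
) -> ResponderState:
    """One step of the participant stand-in.

    Valence drifts by ``gain x (tempo_factor - 1 + intent)`` per step plus
    noise; log-arousal drifts the same way from the normalized loudness
    gain, damped by a factor 0.01 so the arousal ratio stays in a
    physiological range over a 15-minute session. With gain = 0 the state
    is a pure random walk (unchanged
    when noise is also 0). Positive feedback (tempo above 1, positive
    gain) accelerates the drift, closing the loop.
    """
    if gain < 0:
        raise ParameterError("gain must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    dv = gain * (tempo_factor - 1.0 + intent)
    da = gain * (loudness_gain_db / 6.0 + intent) * 0.01
    if noise_sd > 0:
        dv += noise_sd * rng.normal()
        da += noise_sd * 0.01 * rng.normal()
    return ResponderState(
        arousal=float(max(state.arousal * np.exp(da), 1e-6)),
        valence=float(state.valence + dv),
    )
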