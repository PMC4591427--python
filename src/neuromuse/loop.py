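"""Affect-to-music feedback: control mapping, expressive rendering and the
simulated closed-loop session.

The mapping is the neurofeedback contract: increased arousal raises
loudness, increased valence raises tempo. A session iterates a playlist of
pieces for a fixed length (default 15 min) with 1 s pauses between pieces;
controls update at the affect hop (default 0.25 s) and are held between
updates. The participant is either a decoded affect series (open loop) or
a simulated responder (closed loop).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .affect import (
    AffectSample,
    AffectSeries,
    BaselineCalibration,
    PlaneCoordinate,
    to_plane,
)
from .errors import ConfigError, ModelError, ParameterError
from .model import ExpressiveAction, QuadrantModelSet, predict
from .score import Note, Score, extract_features
from .synth import ResponderState, simulate_responder

TEMPO_RANGE = (0.8, 1.25)
GAIN_RANGE_DB = (-6.0, 6.0)


@dataclass(frozen=True)
class ControlSignal:
    """Playback controls at time ``t``: tempo multiplier and loudness gain."""

    t: float
    tempo_factor: float = 1.0
    loudness_gain_db: float = 0.0

    def __post_init__(self) -> None:
        if not TEMPO_RANGE[0] <= self.tempo_factor <= TEMPO_RANGE[1]:
            raise ParameterError(
                f"tempo_factor {self.tempo_factor} outside {TEMPO_RANGE}"
            )
        if not GAIN_RANGE_DB[0] <= self.loudness_gain_db <= GAIN_RANGE_DB[1]:
            raise ParameterError(
                f"loudness gain {self.loudness_gain_db} dB outside {GAIN_RANGE_DB}"
            )


def map_controls(
    coord: PlaneCoordinate,
    t: float = 0.0,
    tempo_range: tuple[float, float] = TEMPO_RANGE,
    gain_range_db: tuple[float, float] = GAIN_RANGE_DB,
) -> ControlSignal:
    """Map a plane coordinate to playback controls.

    Piecewise-linear and strictly increasing: valence_n -1/0/+1 map to the
    tempo range minimum / 1.0 / maximum, and arousal_n -1/0/+1 to the gain
    range minimum / 0 dB / maximum.
    """
    v, a = coord.valence_n, coord.arousal_n
    tempo = 1.0 + v * ((tempo_range[1] - 1.0) if v >= 0 else (1.0 - tempo_range[0]))
    gain = a * (gain_range_db[1] if a >= 0 else -gain_range_db[0])
    return ControlSignal(t=t, tempo_factor=float(tempo), loudness_gain_db=float(gain))


def render(
    score: Score,
    actions: list[ExpressiveAction],
    control: ControlSignal,
) -> Score:
    """Apply expressive actions and global controls to a score.

    Inter-onset intervals and durations are scaled per note by
    ``duration_ratio / tempo_factor`` (so onsets stay contiguous);
    velocities by ``energy_ratio`` and the dB gain, clipped to 1-127.
    Pitches are never changed.
    """
    if len(actions) != len(score.notes):
        raise ModelError(
            f"{len(actions)} actions for {len(score.notes)} notes"
        )
    tf = control.tempo_factor
    amp = 10.0 ** (control.loudness_gain_db / 20.0)
    out: list[Note] = []
    onset = score.notes[0].onset / tf if score.notes else 0.0
    for i, (note, act) in enumerate(zip(score.notes, actions)):
        scale = act.duration_ratio / tf
        vel = int(np.clip(round(note.velocity * act.energy_ratio * amp), 1, 127))
        out.append(Note(pitch=note.pitch, onset=onset,
                        duration=note.duration * scale, velocity=vel))
        if i + 1 < len(score.notes):
            ioi = score.notes[i + 1].onset - note.onset
            onset += ioi * scale
    return Score(notes=out, meter=score.meter, tempo_bpm=score.tempo_bpm)


@dataclass
class SessionRecord:
    """One log frame: affect, plane coordinate and the applied controls."""

    t: float
    arousal: float
    valence: float
    arousal_n: float | None
    valence_n: float | None
    tempo_factor: float
    loudness_gain_db: float
    piece_id: int


@dataclass
class SessionLog:
    session_id: str
    subject_id: str
    records: list[SessionRecord] = field(default_factory=list)
    playlist: list[str] = field(default_factory=list)
    pause_s: float = 1.0
    hop_s: float = 0.25

    def __post_init__(self) -> None:
        t = [r.t for r in self.records]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ParameterError("session record times must be strictly increasing")

    def affect_series(self) -> AffectSeries:
        return AffectSeries(
            samples=[
                AffectSample(t=r.t, arousal=r.arousal, valence=r.valence)
                for r in self.records
            ],
            hop_s=self.hop_s,
        )


def write_session_jsonl(log: SessionLog, path) -> None:
    with open(path, "w") as fh:
        header = {
            "session_id": log.session_id,
            "subject_id": log.subject_id,
            "playlist": log.playlist,
            "pause_s": log.pause_s,
            "hop_s": log.hop_s,
        }
        fh.write(json.dumps({"header": header}) + "\n")
        for r in log.records:
            fh.write(json.dumps(vars(r)) + "\n")


def read_session_jsonl(path) -> SessionLog:
    with open(path) as fh:
        lines = [json.loads(x) for x in fh if x.strip()]
    if not lines or "header" not in lines[0]:
        raise ConfigError(f"{path}: not a session log (missing header line)")
    h = lines[0]["header"]
    return SessionLog(
        session_id=h["session_id"],
        subject_id=h["subject_id"],
        playlist=list(h["playlist"]),
        pause_s=h["pause_s"],
        hop_s=h["hop_s"],
        records=[SessionRecord(**d) for d in lines[1:]],
    )


@dataclass
class SessionConfig:
    """Session protocol parameters: 15 min of music with 1 s pauses."""

    length_s: float = 900.0
    pause_s: float = 1.0
    hop_s: float = 0.25
    baseline_s: float = 30.0
    responder_gain: float = 0.02
    responder_noise_sd: float = 0.05
    seed: int = 0


class _SeriesSource:
    """Zero-order-hold affect lookup over a precomputed series."""

    def __init__(self, series: AffectSeries):
        if not len(series):
            raise ConfigError("empty affect series")
        self._t = series.t
        self._samples = series.samples

    def step(self, t: float, control: ControlSignal, rng) -> AffectSample:
        i = int(np.searchsorted(self._t, t, side="right")) - 1
        i = max(0, min(i, len(self._samples) - 1))
        s = self._samples[i]
        return AffectSample(t=t, arousal=s.arousal, valence=s.valence)


class _ResponderSource:
    """Closed-loop participant stand-in driven by the delivered controls."""

    def __init__(self, cfg: SessionConfig, state: ResponderState | None = None):
        self._state = state or ResponderState()
        self._gain = cfg.responder_gain
        self._noise = cfg.responder_noise_sd

    def step(self, t: float, control: ControlSignal, rng) -> AffectSample:
        self._state = simulate_responder(
            self._state,
            tempo_factor=control.tempo_factor,
            loudness_gain_db=control.loudness_gain_db,
            gain=self._gain,
            noise_sd=self._noise,
            rng=rng,
        )
        return AffectSample(t=t, arousal=self._state.arousal, valence=self._state.valence)


def run_session(
    affect_source,
    playlist: list[Score],
    model_set: QuadrantModelSet | None = None,
    cfg: SessionConfig | None = None,
    session_id: str = "s01",
    subject_id: str = "sub01",
    playlist_ids: list[str] | None = None,
) -> SessionLog:
    """Simulate one neurofeedback session.

    Pieces play in playlist order with wraparound, separated by silent
    pauses (no control records) until the session length elapses; the final
    piece is truncated. ``affect_source`` is an :class:`AffectSeries`
    (open loop) or a :class:`~neuromuse.synth.ResponderState` /
    ``None`` for the closed-loop responder. The first ``baseline_s``
    seconds run at neutral controls while the per-subject plane calibration
    accumulates; thereafter controls follow the mapped affect coordinate.
    """
    cfg = cfg or SessionConfig()
    if not playlist:
        raise ConfigError("playlist must contain at least one piece")
    if cfg.length_s <= 0:
        raise ConfigError("session length must be positive")

    rng = np.random.default_rng(cfg.seed)
    if isinstance(affect_source, AffectSeries):
        source = _SeriesSource(affect_source)
    elif isinstance(affect_source, ResponderState) or affect_source is None:
        source = _ResponderSource(cfg, affect_source)
    else:
        source = affect_source  # duck-typed: needs .step(t, control, rng)

    piece_durs = [max(sc.duration_s, cfg.hop_s) for sc in playlist]
    ids = playlist_ids or [f"piece{i:02d}" for i in range(len(playlist))]

    records: list[SessionRecord] = []
    baseline: list[AffectSample] = []
    calib: BaselineCalibration | None = None
    control = ControlSignal(t=0.0)

    t = 0.0
    piece_idx = 0
    piece_no = 0  # running index including wraparound
    while t < cfg.length_s:
        piece_end = min(t + piece_durs[piece_idx], cfg.length_s)
        ft = t
        while ft < piece_end - 1e-9:
            sample = source.step(ft, control, rng)
            if calib is None:
                baseline.append(sample)
                if ft >= cfg.baseline_s and len(baseline) >= BaselineCalibration.MIN_SAMPLES:
                    calib = BaselineCalibration.from_series(AffectSeries(samples=baseline))
            coord = to_plane(sample, calib) if calib is not None else None
            if coord is not None:
                control = map_controls(coord, t=ft)
            else:
                control = ControlSignal(t=ft)
            records.append(
                SessionRecord(
                    t=round(ft, 6),
                    arousal=sample.arousal,
                    valence=sample.valence,
                    arousal_n=coord.arousal_n if coord else None,
                    valence_n=coord.valence_n if coord else None,
                    tempo_factor=control.tempo_factor,
                    loudness_gain_db=control.loudness_gain_db,
                    piece_id=piece_no,
                )
            )
            ft += cfg.hop_s
        t = piece_end + cfg.pause_s  # silent pause: no control records
        piece_idx = (piece_idx + 1) % len(playlist)
        piece_no += 1

    return SessionLog(
        session_id=session_id,
        subject_id=subject_id,
        records=records,
        playlist=ids,
        pause_s=cfg.pause_s,
        hop_s=cfg.hop_s,
    )


def render_at_coord(
    score: Score,
    coord: PlaneCoordinate,
    model_set: QuadrantModelSet,
) -> Score:
    """Convenience: interpolate models at ``coord``, predict actions for the
    score, map the coordinate to controls, and render."""
    models = model_set.interpolate(coord)
    actions = predict(models, extract_features(score))
    return render(score, actions, map_controls(coord))
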