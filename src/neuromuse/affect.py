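"""Arousal/valence decoding from frontal band powers.

Arousal is the summed beta over summed alpha power ratio across the four
prefrontal electrodes AF3, AF4, F3, F4:

    arousal = (bF3 + bF4 + bAF3 + bAF4) / (aF3 + aF4 + aAF3 + aAF4)

Valence is the frontal alpha asymmetry, alpha power at F4 minus F3:

    valence = aF4 - aF3

Higher alpha indicates cortical *in*activation, so relatively less
left-frontal (F3) alpha — a positive difference — indicates relatively
greater left-frontal activation, the classic marker of positive affect.

The module also provides trajectory extraction over a windowed band-power
sequence, optional exponential smoothing, min-max / z-score normalization
for reporting, and a per-subject baseline calibration mapping raw values
onto the [-1, 1]^2 arousal-valence plane used for model interpolation and
feedback control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import eeg
from .eeg import AFFECT_CHANNELS, BandPowerFrame, EEGRecording
from .errors import DegenerateInputError, InsufficientDataError, ParameterError


@dataclass(frozen=True)
class AffectSample:
    """One time-stamped affect estimate.

    ``arousal`` is a dimensionless power ratio >= 0; ``valence`` is a signed
    alpha-power difference in uV^2.
    """

    t: float
    arousal: float
    valence: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.arousal) and math.isfinite(self.valence)):
            raise DegenerateInputError(f"non-finite affect sample at t={self.t}")
        if self.arousal < 0:
            raise DegenerateInputError(f"negative arousal at t={self.t}")


@dataclass
class AffectSeries:
    """Time-ordered affect samples plus the window/hop metadata that made them."""

    samples: list[AffectSample]
    window_s: float = eeg.DEFAULT_WINDOW_S
    hop_s: float = eeg.DEFAULT_HOP_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.t
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("affect sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    @property
    def arousal(self) -> np.ndarray:
        return np.array([s.arousal for s in self.samples])

    @property
    def valence(self) -> np.ndarray:
        return np.array([s.valence for s in self.samples])


@dataclass(frozen=True)
class PlaneCoordinate:
    """Normalized (valence, arousal) coordinate on the emotion plane.

    Quadrants: happy (+v, +a), angry (-v, +a), sad (-v, -a), relaxed (+v, -a).
    """

    valence_n: float
    arousal_n: float

    def __post_init__(self) -> None:
        for name in ("valence_n", "arousal_n"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [-1, 1]")


def arousal_from_powers(frame: BandPowerFrame) -> float:
    """Summed-beta over summed-alpha ratio over AF3, AF4, F3, F4."""
    beta = sum(frame.get("beta", c) for c in AFFECT_CHANNELS)
    alpha = sum(frame.get("alpha", c) for c in AFFECT_CHANNELS)
    if alpha == 0:
        raise DegenerateInputError(
            f"alpha power sum is zero at t={frame.t_center}; arousal undefined"
        )
    return beta / alpha


def valence_from_powers(frame: BandPowerFrame) -> float:
    """Frontal alpha asymmetry: alpha power at F4 minus alpha power at F3."""
    return frame.get("alpha", "F4") - frame.get("alpha", "F3")


def affect_trajectory(
    rec: EEGRecording,
    bands: list[eeg.BandDefinition] | None = None,
    window_s: float = eeg.DEFAULT_WINDOW_S,
    hop_s: float = eeg.DEFAULT_HOP_S,
    mode: str = "zero_phase",
) -> AffectSeries:
    """Decode an affect time series from a recording.

    One :class:`AffectSample` per band-power frame; deterministic given the
    input and configuration. Raises a montage error if any of AF3, AF4, F3,
    F4 is absent, and a degenerate-input error (tagged with the frame time)
    if a frame has zero total alpha power.
    """
    rec.require_channels(AFFECT_CHANNELS)
    if bands is None:
        bands = [eeg.alpha_band(), eeg.beta_band()]
    frames = eeg.band_power(
        rec, bands, window_s=window_s, hop_s=hop_s, channels=AFFECT_CHANNELS, mode=mode
    )
    samples = [
        AffectSample(
            t=f.t_center,
            arousal=arousal_from_powers(f),
            valence=valence_from_powers(f),
        )
        for f in frames
    ]
    return AffectSeries(samples=samples, window_s=window_s, hop_s=hop_s)


def smooth_series(series: AffectSeries, half_life_s: float = 2.0) -> AffectSeries:
    """Exponential moving average of arousal and valence.

    ``half_life_s`` is the time over which an observation's weight halves;
    0 or negative disables smoothing.
    """
    if half_life_s <= 0 or len(series) < 2:
        return series
    t = series.t
    a = series.arousal.copy()
    v = series.valence.copy()
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        w = 0.5 ** (dt / half_life_s)
        a[i] = w * a[i - 1] + (1 - w) * a[i]
        v[i] = w * v[i - 1] + (1 - w) * v[i]
    samples = [
        AffectSample(t=float(ti), arousal=float(ai), valence=float(vi))
        for ti, ai, vi in zip(t, a, v)
    ]
    return AffectSeries(samples=samples, window_s=series.window_s, hop_s=series.hop_s,
                        meta={**series.meta, "smoothed_half_life_s": half_life_s})


def _normalize(x: np.ndarray, method: str) -> np.ndarray:
    if method == "minmax":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise DegenerateInputError("constant series cannot be min-max normalized")
        return (x - lo) / (hi - lo)
    if method == "zscore":
        sd = float(np.std(x, ddof=0))
        if sd == 0:
            raise DegenerateInputError("constant series cannot be z-scored")
        return (x - float(np.mean(x))) / sd
    raise ParameterError(f"unknown normalization method {method!r}")


def normalize_series(series: AffectSeries, method: str = "minmax") -> AffectSeries:
    """Normalize arousal and valence independently for reporting.

    ``minmax`` maps each dimension onto [0, 1]; ``zscore`` onto mean 0,
    sd 1. Both are strictly monotone, so rank order is preserved. Because
    z-scored/centred valence may be negative and arousal is stored as a
    ratio >= 0, normalized values are returned in ``meta['normalized']``
    arrays rather than re-wrapped as raw samples.
    """
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 samples to normalize")
    a_n = _normalize(series.arousal, method)
    v_n = _normalize(series.valence, method)
    if method == "zscore":
        # z-scores are signed; shift is not meaningful as a raw arousal ratio,
        # so keep raw samples and attach the normalized arrays.
        out = AffectSeries(samples=list(series.samples), window_s=series.window_s,
                           hop_s=series.hop_s, meta=dict(series.meta))
    else:
        samples = [
            AffectSample(t=s.t, arousal=float(ai), valence=float(vi))
            for s, ai, vi in zip(series.samples, a_n, v_n)
        ]
        out = AffectSeries(samples=samples, window_s=series.window_s,
                           hop_s=series.hop_s, meta=dict(series.meta))
    out.meta["normalization"] = method
    out.meta["arousal_n"] = a_n
    out.meta["valence_n"] = v_n
    return out


@dataclass(frozen=True)
class BaselineCalibration:
    """Per-subject baseline statistics for plane mapping.

    Raw arousal ratios and valence differences are in subject-dependent
    units, so the plane coordinate is a saturating (tanh) deviation from
    the subject's own baseline: the median of log-arousal and of valence
    over the calibration window, scaled by a robust spread estimate
    (1.4826 x MAD, floored to avoid division by ~0 on very clean baselines).
    """

    log_arousal_median: float
    log_arousal_scale: float
    valence_median: float
    valence_scale: float
    n_samples: int

    MIN_SAMPLES = 30

    @classmethod
    def from_series(cls, series: AffectSeries) -> "BaselineCalibration":
        if len(series) < cls.MIN_SAMPLES:
            raise InsufficientDataError(
                f"baseline calibration needs >= {cls.MIN_SAMPLES} samples, got {len(series)}"
            )
        a = series.arousal
        if np.any(a <= 0):
            raise DegenerateInputError("baseline contains non-positive arousal")
        la = np.log(a)
        v = series.valence
        mad = lambda x: float(np.median(np.abs(x - np.median(x))))  # noqa: E731
        return cls(
            log_arousal_median=float(np.median(la)),
            log_arousal_scale=max(1.4826 * mad(la), 1e-3),
            valence_median=float(np.median(v)),
            valence_scale=max(1.4826 * mad(v), 1e-3),
            n_samples=len(series),
        )


def to_plane(sample: AffectSample, calib: BaselineCalibration) -> PlaneCoordinate:
    """Map a raw affect sample onto the [-1, 1]^2 arousal-valence plane.

    A sample exactly at the baseline medians maps to (0, 0); deviations
    saturate smoothly toward +/-1. Monotone in both raw dimensions.
    """
    if calib is None:
        raise ParameterError("plane mapping requires a baseline calibration")
    if sample.arousal <= 0:
        raise DegenerateInputError(f"non-positive arousal at t={sample.t}")
    a_dev = (math.log(sample.arousal) - calib.log_arousal_median) / calib.log_arousal_scale
    v_dev = (sample.valence - calib.valence_median) / calib.valence_scale
    return PlaneCoordinate(
        valence_n=float(np.clip(math.tanh(v_dev / 2), -1.0, 1.0)),
        arousal_n=float(np.clip(math.tanh(a_dev / 2), -1.0, 1.0)),
    )


def write_affect_jsonl(series: AffectSeries, path, calib: BaselineCalibration | None = None) -> None:
    """Write an affect stream as JSON lines: {t, arousal, valence[, *_n]}."""
    with open(path, "w") as fh:
        for s in series.samples:
            rec = {"t": s.t, "arousal": s.arousal, "valence": s.valence}
            if calib is not None:
                coord = to_plane(s, calib)
                rec["arousal_n"] = coord.arousal_n
                rec["valence_n"] = coord.valence_n
            fh.write(json.dumps(rec) + "\n")


def read_affect_jsonl(path) -> AffectSeries:
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            samples.append(AffectSample(t=d["t"], arousal=d["arousal"], valence=d["valence"]))
    return AffectSeries(samples=samples)
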