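"""EEG data model, CSV I/O, Butterworth band-pass filtering and band power.

The signal chain mirrors a frontal-asymmetry neurofeedback setup: a
multichannel recording sampled at 128 Hz with 10-20 labels is band-pass
filtered into the alpha (8-12 Hz) and beta (12-28 Hz) bands with Butterworth
filters, and band power is measured as the mean squared amplitude of the
filtered signal over a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateInputError, FormatError, MontageError, ParameterError

#: Electrode labels required for affect decoding (prefrontal 10-20 sites).
AFFECT_CHANNELS = ("AF3", "F3", "F4", "AF4")

#: Default band edges in Hz.
ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (12.0, 28.0)

DEFAULT_FILTER_ORDER = 4
DEFAULT_WINDOW_S = 1.0
DEFAULT_HOP_S = 0.25


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band realised as a Butterworth band-pass filter.

    Parameters
    ----------
    name : str
        Band label, conventionally ``"alpha"`` or ``"beta"``.
    low_hz, high_hz : float
        Band edges in Hz; ``0 < low_hz < high_hz`` required.
    filter_order : int
        Butterworth order (default 4, standard for alpha/beta separation
        at a 128 Hz sampling rate).
    """

    name: str
    low_hz: float
    high_hz: float
    filter_order: int = DEFAULT_FILTER_ORDER

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"band {self.name!r}: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )
        if self.filter_order < 1:
            raise ParameterError(f"band {self.name!r}: filter order must be >= 1")

    def validate_for_rate(self, rate: float) -> None:
        if self.high_hz >= rate / 2:
            raise ParameterError(
                f"band {self.name!r}: high edge {self.high_hz} Hz >= Nyquist "
                f"({rate / 2} Hz at rate {rate} Hz)"
            )

    def sos(self, rate: float) -> np.ndarray:
        """Second-order-sections coefficients for this band at ``rate``."""
        self.validate_for_rate(rate)
        return signal.butter(
            self.filter_order,
            (self.low_hz, self.high_hz),
            btype="bandpass",
            fs=rate,
            output="sos",
        )


def alpha_band(order: int = DEFAULT_FILTER_ORDER) -> BandDefinition:
    return BandDefinition("alpha", *ALPHA_BAND, filter_order=order)


def beta_band(order: int = DEFAULT_FILTER_ORDER) -> BandDefinition:
    return BandDefinition("beta", *BETA_BAND, filter_order=order)


@dataclass
class EEGRecording:
    """Multichannel EEG: a channels x samples matrix in microvolts.

    ``channels`` are ordered 10-20 labels; all channels share ``rate``
    (samples/second) and length. ``start_time`` is the timestamp of the
    first sample in seconds.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise FormatError("EEG data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channels):
            raise FormatError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise MontageError("channel labels must be unique")
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise MontageError(
                f"channel {label!r} not present (have {', '.join(self.channels)})"
            ) from None

    def require_channels(self, labels=AFFECT_CHANNELS) -> None:
        missing = [c for c in labels if c not in self.channels]
        if missing:
            raise MontageError(
                f"required channel(s) missing: {', '.join(missing)} "
                f"(have {', '.join(self.channels)})"
            )


@dataclass
class BandPowerFrame:
    """Band power (uV^2) per channel per band, centred at ``t_center`` seconds."""

    t_center: float
    power: dict[str, dict[str, float]] = field(default_factory=dict)

    def get(self, band: str, channel: str) -> float:
        try:
            return self.power[band][channel]
        except KeyError:
            raise MontageError(
                f"no {band} power for channel {channel!r} in frame at t={self.t_center}"
            ) from None


def read_eeg_csv(path, rate: float) -> EEGRecording:
    """Read an EEG recording from CSV.

    Expected dialect: comma-separated, header row, first column ``time``
    (seconds), remaining columns one electrode each, values in microvolts.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse EEG CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus >= 1 channel column")
    time_col = df.columns[0]
    chan_cols = list(df.columns[1:])
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and not df[col].isna().any():
            bad = df[col][numeric.isna()].iloc[0]
            raise FormatError(f"{path}: non-numeric value {bad!r} in column {col!r}")
        if numeric.isna().any():
            raise FormatError(f"{path}: missing value in column {col!r}")
        df[col] = numeric
    start = float(df[time_col].iloc[0]) if len(df) else 0.0
    data = df[chan_cols].to_numpy(dtype=float).T
    return EEGRecording(data=data, rate=rate, channels=tuple(chan_cols), start_time=start)


def write_eeg_csv(rec: EEGRecording, path) -> None:
    """Write a recording in the dialect :func:`read_eeg_csv` expects."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.insert(0, "time", rec.times())
    df.to_csv(path, index=False, float_format="%.9g")


def bandpass(rec: EEGRecording, band: BandDefinition, mode: str = "zero_phase") -> EEGRecording:
    """Band-pass filter every channel of ``rec``.

    ``mode="zero_phase"`` applies the filter forward and backward
    (no phase distortion; acausal, for offline analysis).
    ``mode="causal"`` applies a single forward pass, as a real-time loop
    would. Output has the same shape and rate as the input.
    """
    sos = band.sos(rec.rate)
    if mode == "zero_phase":
        if rec.n_samples <= 1:
            filtered = np.zeros_like(rec.data)
        else:
            filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    elif mode == "causal":
        filtered = signal.sosfilt(sos, rec.data, axis=1)
    else:
        raise ParameterError(f"unknown filter mode {mode!r}")
    return EEGRecording(
        data=filtered, rate=rec.rate, channels=rec.channels, start_time=rec.start_time
    )


def band_power(
    rec: EEGRecording,
    bands: list[BandDefinition],
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    channels: tuple[str, ...] | None = None,
    mode: str = "zero_phase",
) -> list[BandPowerFrame]:
    """Windowed band power: mean squared amplitude of the filtered signal.

    For a sinusoid of amplitude A inside the band this converges to A^2/2
    for windows of a cycle or more. A recording shorter than one window
    yields an empty list. Frames are spaced ``hop_s`` apart and ordered by
    ``t_center``.
    """
    if channels is None:
        channels = rec.channels
    else:
        rec.require_channels(channels)
    win = int(round(window_s * rec.rate))
    hop = int(round(hop_s * rec.rate))
    if win < 1:
        raise ParameterError(f"window of {window_s} s is shorter than one sample")
    if hop < 1:
        raise ParameterError("hop must be at least one sample")
    if rec.n_samples < win:
        return []

    idx = [rec.channels.index(c) for c in channels]
    filtered = {b.name: bandpass(rec, b, mode=mode).data[idx] for b in bands}

    frames: list[BandPowerFrame] = []
    for start in range(0, rec.n_samples - win + 1, hop):
        t_center = rec.start_time + (start + win / 2) / rec.rate
        power: dict[str, dict[str, float]] = {}
        for bname, sig_f in filtered.items():
            seg = sig_f[:, start : start + win]
            power[bname] = {c: float(np.mean(seg[i] ** 2)) for i, c in enumerate(channels)}
        frames.append(BandPowerFrame(t_center=t_center, power=power))
    return frames


def check_nonzero(value: float, what: str) -> float:
    if value == 0:
        raise DegenerateInputError(f"{what} is zero")
    return value
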