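"""Run configuration: one validated object shared by all CLI subcommands.

Defaults encode the signal chain (alpha 8-12 Hz, beta 12-28 Hz, 4th-order
Butterworth, 1 s window / 0.25 s hop), the control ranges (tempo 0.8-1.25,
loudness -6..+6 dB), the prediction clip range [0.5, 2.0], and the session
protocol (900 s with 1 s pauses, 30 s baseline).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .errors import ConfigError


@dataclass
class RunConfig:
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (12.0, 28.0)
    filter_order: int = 4
    window_s: float = 1.0
    hop_s: float = 0.25
    rate: float = 128.0
    smoothing_half_life_s: float = 2.0
    tempo_range: tuple[float, float] = (0.8, 1.25)
    gain_range_db: tuple[float, float] = (-6.0, 6.0)
    ratio_clip: tuple[float, float] = (0.5, 2.0)
    anchor_magnitude: float = 0.5
    session_length_s: float = 900.0
    pause_s: float = 1.0
    baseline_s: float = 30.0
    responder_gain: float = 0.02
    responder_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_band = tuple(self.alpha_band)
        self.beta_band = tuple(self.beta_band)
        self.tempo_range = tuple(self.tempo_range)
        self.gain_range_db = tuple(self.gain_range_db)
        self.ratio_clip = tuple(self.ratio_clip)
        self.validate()

    def validate(self) -> None:
        checks = [
            (0 < self.alpha_band[0] < self.alpha_band[1], "alpha_band must satisfy 0 < low < high"),
            (0 < self.beta_band[0] < self.beta_band[1], "beta_band must satisfy 0 < low < high"),
            (self.beta_band[1] < self.rate / 2, "beta high edge must be below Nyquist"),
            (self.filter_order >= 1, "filter_order must be >= 1"),
            (self.window_s > 0 and self.hop_s > 0, "window_s and hop_s must be positive"),
            (self.rate > 0, "rate must be positive"),
            (self.tempo_range[0] < 1.0 < self.tempo_range[1], "tempo_range must bracket 1.0"),
            (self.gain_range_db[0] < 0.0 < self.gain_range_db[1], "gain_range_db must bracket 0"),
            (self.ratio_clip[0] < 1.0 < self.ratio_clip[1], "ratio_clip must bracket 1.0"),
            (0 < self.anchor_magnitude <= 1.0, "anchor_magnitude must be in (0, 1]"),
            (self.session_length_s > 0, "session_length_s must be positive"),
            (self.pause_s >= 0, "pause_s must be >= 0"),
            (self.baseline_s >= 0, "baseline_s must be >= 0"),
            (self.responder_gain >= 0, "responder_gain must be >= 0"),
            (self.responder_noise_sd >= 0, "responder_noise_sd must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def digest(self) -> str:
        """Short hash of the full configuration, for run logging."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
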