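"""Per-emotion expressive-performance regressions and plane interpolation.

For each of the four emotions — happy, relaxed, sad, angry, one per
quadrant of the arousal-valence plane — two linear models are trained on
note features: one predicting the note's performed/score *duration ratio*
and one its *energy ratio* (e.g. a predicted duration ratio of 1.14 means
the note is lengthened by 14% with respect to the score; an energy ratio
of 1.14 means it is played 14% louder than the piece's average energy).
An affect coordinate anywhere on the plane selects an intermediate model
by bilinear interpolation of the four coefficient vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .affect import PlaneCoordinate
from .errors import ModelError, ParameterError
from .score import FEATURE_NAMES, NoteFeatureVector, design_matrix

EMOTIONS = ("happy", "relaxed", "sad", "angry")
#: Quadrant of each emotion as (sign of valence, sign of arousal).
QUADRANT_SIGNS = {
    "happy": (1, 1),
    "relaxed": (1, -1),
    "sad": (-1, -1),
    "angry": (-1, 1),
}
DEFAULT_ANCHORS = {
    e: PlaneCoordinate(valence_n=0.5 * sv, arousal_n=0.5 * sa)
    for e, (sv, sa) in QUADRANT_SIGNS.items()
}

TARGETS = ("duration_ratio", "energy_ratio")
#: Predicted ratios are clipped to this range to keep the rendered
#: performance musically plausible.
RATIO_CLIP = (0.5, 2.0)


@dataclass
class LinearModel:
    """OLS model: ``ratio = X @ coefficients + intercept``."""

    target: str
    coefficients: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.target not in TARGETS:
            raise ParameterError(f"unknown target {self.target!r}")
        if self.coefficients.shape != (len(self.feature_names),):
            raise ModelError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.feature_names)} features"
            )
        if not (np.all(np.isfinite(self.coefficients)) and np.isfinite(self.intercept)):
            raise ModelError("non-finite model coefficients")

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.coefficients):
            raise ModelError(
                f"design matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {len(self.coefficients)}"
            )
        return X @ self.coefficients + self.intercept


def train(
    X: np.ndarray,
    y: np.ndarray,
    target: str,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    ridge_fallback: bool = False,
    ridge_penalty: float = 1e-6,
) -> LinearModel:
    """Ordinary least squares with an intercept.

    Requires n >= p + 1 and a full-rank augmented design; a rank-deficient
    design raises unless ``ridge_fallback`` enables a tiny ridge penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p != len(feature_names):
        raise ModelError(f"{p} design columns vs {len(feature_names)} feature names")
    if n < p + 1:
        raise ModelError(f"need >= {p + 1} notes to fit {p} coefficients, got {n}")
    A = np.hstack([X, np.ones((n, 1))])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        if not ridge_fallback:
            raise ModelError(
                f"design matrix is rank-deficient (rank {rank} < {p + 1}); "
                "enable ridge_fallback or enrich the corpus"
            )
        beta = np.linalg.solve(A.T @ A + ridge_penalty * np.eye(p + 1), A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(
        target=target,
        coefficients=beta[:p],
        intercept=float(beta[p]),
        feature_names=feature_names,
    )


@dataclass(frozen=True)
class ExpressiveAction:
    """Per-note performance deviation: duration and energy multipliers."""

    duration_ratio: float
    energy_ratio: float


@dataclass
class QuadrantModelSet:
    """Four (duration, energy) model pairs anchored in the four quadrants."""

    models: dict[str, tuple[LinearModel, LinearModel]]
    anchors: dict[str, PlaneCoordinate] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )

    def __post_init__(self) -> None:
        missing = set(EMOTIONS) - set(self.models)
        if missing:
            raise ModelError(f"missing emotion model(s): {', '.join(sorted(missing))}")
        for emo, anchor in self.anchors.items():
            sv, sa = QUADRANT_SIGNS[emo]
            if anchor.valence_n * sv <= 0 or anchor.arousal_n * sa <= 0:
                raise ModelError(
                    f"{emo} anchor ({anchor.valence_n}, {anchor.arousal_n}) "
                    "is not strictly inside its quadrant"
                )

    def interpolation_weights(self, coord: PlaneCoordinate) -> dict[str, float]:
        """Bilinear weights; non-negative, sum to 1, exact at anchors.

        The coordinate is clamped to the anchor rectangle, so anchors are
        reproduced exactly and extrapolation is flat.
        """
        v_pos = np.mean([self.anchors[e].valence_n for e in ("happy", "relaxed")])
        v_neg = np.mean([self.anchors[e].valence_n for e in ("angry", "sad")])
        a_pos = np.mean([self.anchors[e].arousal_n for e in ("happy", "angry")])
        a_neg = np.mean([self.anchors[e].arousal_n for e in ("relaxed", "sad")])
        fv = float(np.clip((coord.valence_n - v_neg) / (v_pos - v_neg), 0.0, 1.0))
        fa = float(np.clip((coord.arousal_n - a_neg) / (a_pos - a_neg), 0.0, 1.0))
        return {
            "happy": fv * fa,
            "angry": (1 - fv) * fa,
            "relaxed": fv * (1 - fa),
            "sad": (1 - fv) * (1 - fa),
        }

    def interpolate(self, coord: PlaneCoordinate) -> tuple[LinearModel, LinearModel]:
        """Coefficient-wise blend of the four quadrant models at ``coord``."""
        w = self.interpolation_weights(coord)
        out = []
        for ti, target in enumerate(TARGETS):
            coefs = sum(w[e] * self.models[e][ti].coefficients for e in EMOTIONS)
            intercept = sum(w[e] * self.models[e][ti].intercept for e in EMOTIONS)
            names = self.models["happy"][ti].feature_names
            out.append(
                LinearModel(
                    target=target,
                    coefficients=coefs,
                    intercept=float(intercept),
                    feature_names=names,
                )
            )
        return out[0], out[1]


def predict(
    models: tuple[LinearModel, LinearModel],
    features: list[NoteFeatureVector],
    clip: tuple[float, float] = RATIO_CLIP,
) -> list[ExpressiveAction]:
    """Per-note expressive actions, clipped to the plausible ratio range."""
    dur_model, en_model = models
    if dur_model.target != "duration_ratio" or en_model.target != "energy_ratio":
        raise ModelError("predict expects (duration_ratio, energy_ratio) models")
    X = design_matrix(features)
    dur = np.clip(dur_model.predict_raw(X), *clip)
    en = np.clip(en_model.predict_raw(X), *clip)
    return [
        ExpressiveAction(duration_ratio=float(d), energy_ratio=float(e))
        for d, e in zip(dur, en)
    ]


def identity_models(feature_names: tuple[str, ...] = FEATURE_NAMES) -> tuple[LinearModel, LinearModel]:
    """Models that predict ratio 1 for every note (identity performance)."""
    z = np.zeros(len(feature_names))
    return (
        LinearModel("duration_ratio", z, 1.0, feature_names),
        LinearModel("energy_ratio", z.copy(), 1.0, feature_names),
    )


# --- JSON model files -----------------------------------------------------

def save_model_set(ms: QuadrantModelSet, path) -> None:
    doc = {
        "emotions": {
            emo: {
                "anchor": [ms.anchors[emo].valence_n, ms.anchors[emo].arousal_n],
                "models": [
                    {
                        "target": m.target,
                        "feature_names": list(m.feature_names),
                        "coefficients": m.coefficients.tolist(),
                        "intercept": m.intercept,
                    }
                    for m in ms.models[emo]
                ],
            }
            for emo in EMOTIONS
        }
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model_set(path) -> QuadrantModelSet:
    with open(path) as fh:
        doc = json.load(fh)
    models = {}
    anchors = {}
    for emo, entry in doc["emotions"].items():
        anchors[emo] = PlaneCoordinate(valence_n=entry["anchor"][0], arousal_n=entry["anchor"][1])
        pair = tuple(
            LinearModel(
                target=m["target"],
                coefficients=np.array(m["coefficients"]),
                intercept=m["intercept"],
                feature_names=tuple(m["feature_names"]),
            )
            for m in entry["models"]
        )
        models[emo] = pair
    return QuadrantModelSet(models=models, anchors=anchors)
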