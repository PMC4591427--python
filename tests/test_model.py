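"""Expressive models: OLS training, plane interpolation, prediction clip."""

import numpy as np
import pytest

from neuromuse import (
    LinearModel,
    PlaneCoordinate,
    QuadrantModelSet,
    extract_features,
    generate_score,
    load_model_set,
    predict,
    save_model_set,
    train,
)
from neuromuse.errors import ModelError
from neuromuse.model import EMOTIONS, identity_models
from neuromuse.score import FEATURE_NAMES, design_matrix
from neuromuse.synth import CorpusSpec, default_true_coefficients, generate_corpus

N_FEAT = len(FEATURE_NAMES)


def _intercept_only_set(intercepts):
    """Model set with zero weights and given per-emotion intercepts."""
    models = {}
    for emo, b in intercepts.items():
        models[emo] = (
            LinearModel("duration_ratio", np.zeros(N_FEAT), b),
            LinearModel("energy_ratio", np.zeros(N_FEAT), b),
        )
    return QuadrantModelSet(models=models)


class TestTrain:
    def test_noiseless_recovery_exact(self):
        corpora = generate_corpus(CorpusSpec(n_notes=200, noise_sd=0.0, seed=21))
        truth = default_true_coefficients(21)
        c = corpora["sad"]
        m = train(c.X, c.energy_ratio, "energy_ratio")
        w, b = truth["sad"]["energy_ratio"]
        np.testing.assert_allclose(m.coefficients, w, atol=1e-6)
        assert m.intercept == pytest.approx(b, abs=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        corpora = generate_corpus(CorpusSpec(n_notes=500, noise_sd=0.05, seed=1234))
        truth = default_true_coefficients(1234)
        for emo, c in corpora.items():
            m = train(c.X, c.duration_ratio, "duration_ratio")
            w, b = truth[emo]["duration_ratio"]
            assert np.max(np.abs(m.coefficients - w)) < 0.05
            assert abs(m.intercept - b) < 0.05

    def test_constant_target_gives_pure_intercept(self):
        X = generate_corpus(CorpusSpec(n_notes=300, noise_sd=0.0, seed=3))["happy"].X
        y = np.full(len(X), 1.14)
        m = train(X, y, "duration_ratio")
        assert m.intercept == pytest.approx(1.14, abs=1e-8)
        np.testing.assert_allclose(m.coefficients, 0.0, atol=1e-8)

    def test_rank_deficient_raises_without_fallback(self):
        X = np.zeros((50, N_FEAT))  # all-constant columns
        y = np.ones(50)
        with pytest.raises(ModelError, match="rank"):
            train(X, y, "duration_ratio")
        m = train(X, y, "duration_ratio", ridge_fallback=True)
        assert np.isfinite(m.intercept)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ModelError, match="need >="):
            train(np.zeros((5, N_FEAT)), np.ones(5), "duration_ratio")


class TestInterpolation:
    def test_anchor_reproduces_quadrant_model_exactly(self, trained_model_set):
        ms = trained_model_set
        for emo in EMOTIONS:
            dur, en = ms.interpolate(ms.anchors[emo])
            np.testing.assert_array_equal(dur.coefficients, ms.models[emo][0].coefficients)
            assert dur.intercept == ms.models[emo][0].intercept
            np.testing.assert_array_equal(en.coefficients, ms.models[emo][1].coefficients)

    def test_center_is_unweighted_mean_with_symmetric_anchors(self):
        ms = _intercept_only_set(
            {"happy": 1.0, "relaxed": 1.1, "sad": 1.2, "angry": 1.3}
        )
        dur, _ = ms.interpolate(PlaneCoordinate(0.0, 0.0))
        assert dur.intercept == pytest.approx((1.0 + 1.1 + 1.2 + 1.3) / 4)

    def test_weights_nonnegative_and_sum_to_one(self, trained_model_set, rng):
        for _ in range(200):
            coord = PlaneCoordinate(*rng.uniform(-1, 1, size=2))
            w = trained_model_set.interpolation_weights(coord)
            assert all(v >= 0 for v in w.values())
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_interpolated_intercept_within_convex_hull(self, rng):
        ms = _intercept_only_set(
            {"happy": 1.0, "relaxed": 1.1, "sad": 1.2, "angry": 1.3}
        )
        for _ in range(300):
            coord = PlaneCoordinate(*rng.uniform(-1, 1, size=2))
            dur, _ = ms.interpolate(coord)
            assert 1.0 - 1e-12 <= dur.intercept <= 1.3 + 1e-12

    def test_predictions_bounded_by_quadrant_models(self, trained_model_set, rng):
        feats = extract_features(generate_score(15, seed=13))
        X = design_matrix(feats)
        raw = {
            emo: trained_model_set.models[emo][0].predict_raw(X)
            for emo in EMOTIONS
        }
        lo = np.min(list(raw.values()), axis=0)
        hi = np.max(list(raw.values()), axis=0)
        for _ in range(50):
            coord = PlaneCoordinate(*rng.uniform(-1, 1, size=2))
            dur, _ = trained_model_set.interpolate(coord)
            pred = dur.predict_raw(X)
            assert np.all(pred >= lo - 1e-9)
            assert np.all(pred <= hi + 1e-9)

    def test_misplaced_anchor_rejected(self):
        with pytest.raises(ModelError, match="quadrant"):
            _intercept_only_set({"happy": 1.0, "relaxed": 1.0, "sad": 1.0,
                                 "angry": 1.0}).anchors
            QuadrantModelSet(
                models=_intercept_only_set(
                    {"happy": 1.0, "relaxed": 1.0, "sad": 1.0, "angry": 1.0}
                ).models,
                anchors={
                    "happy": PlaneCoordinate(-0.5, 0.5),  # wrong quadrant
                    "relaxed": PlaneCoordinate(0.5, -0.5),
                    "sad": PlaneCoordinate(-0.5, -0.5),
                    "angry": PlaneCoordinate(-0.5, 0.5),
                },
            )


class TestPredict:
    def test_lengthening_semantics(self):
        """A duration ratio of 1.14 means 14% lengthening versus the score."""
        feats = extract_features(generate_score(10, seed=1))
        models = (
            LinearModel("duration_ratio", np.zeros(N_FEAT), 1.14),
            LinearModel("energy_ratio", np.zeros(N_FEAT), 1.0),
        )
        actions = predict(models, feats)
        for act in actions:
            assert act.duration_ratio == pytest.approx(1.14)
            assert (act.duration_ratio - 1.0) * 100 == pytest.approx(14.0)

    def test_identity_models_predict_unity(self):
        feats = extract_features(generate_score(10, seed=1))
        for act in predict(identity_models(), feats):
            assert act.duration_ratio == 1.0
            assert act.energy_ratio == 1.0

    def test_adversarial_predictions_clipped(self):
        feats = extract_features(generate_score(30, seed=2))
        wild = (
            LinearModel("duration_ratio", np.full(N_FEAT, 5.0), -3.0),
            LinearModel("energy_ratio", np.full(N_FEAT, -5.0), 3.0),
        )
        for act in predict(wild, feats):
            assert 0.5 <= act.duration_ratio <= 2.0
            assert 0.5 <= act.energy_ratio <= 2.0

    def test_dimension_mismatch_rejected(self):
        m = LinearModel("duration_ratio", np.zeros(N_FEAT), 1.0)
        with pytest.raises(ModelError):
            m.predict_raw(np.zeros((3, N_FEAT + 2)))


class TestModelIO:
    def test_json_round_trip(self, trained_model_set, tmp_path):
        p = tmp_path / "models.json"
        save_model_set(trained_model_set, p)
        back = load_model_set(p)
        for emo in EMOTIONS:
            for i in (0, 1):
                a = trained_model_set.models[emo][i]
                b = back.models[emo][i]
                np.testing.assert_array_equal(a.coefficients, b.coefficients)
                assert a.intercept == b.intercept
                assert a.feature_names == b.feature_names
            assert back.anchors[emo] == trained_model_set.anchors[emo]
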