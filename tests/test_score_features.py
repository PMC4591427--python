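"""Score model, MIDI round trips and note-feature extraction."""

import numpy as np
import pytest

from neuromuse import (
    Note,
    Score,
    design_matrix,
    extract_features,
    generate_score,
    legato_amount,
    metrical_strength,
    narmour_labels,
    read_midi,
    write_midi,
)
from neuromuse.errors import DegenerateInputError, ParameterError, StructureError


class TestMidiRoundTrip:
    def test_generated_score_round_trips_exactly(self, tmp_path):
        sc = generate_score(20, seed=4)
        p = tmp_path / "melody.mid"
        write_midi(sc, p)
        back = read_midi(p)
        assert len(back) == 20
        assert back.meter == sc.meter
        assert back.tempo_bpm == pytest.approx(sc.tempo_bpm, rel=1e-4)
        for a, b in zip(sc.notes, back.notes):
            assert a.pitch == b.pitch
            assert a.velocity == b.velocity
            # onsets/durations exact at 480 ticks/beat for these durations
            assert b.onset == pytest.approx(a.onset, abs=1 / 480)
            assert b.duration == pytest.approx(a.duration, abs=1 / 480)

    def test_empty_score_round_trips(self, tmp_path):
        p = tmp_path / "empty.mid"
        write_midi(Score(notes=[]), p)
        assert read_midi(p).notes == []

    def test_overlapping_notes_flagged_polyphonic(self, tmp_path):
        chord = Score(notes=[
            Note(pitch=60, onset=0.0, duration=1.0),
            Note(pitch=64, onset=0.0, duration=1.0),
        ])
        p = tmp_path / "chord.mid"
        write_midi(chord, p)
        back = read_midi(p)
        assert back.is_polyphonic()
        with pytest.raises(StructureError):
            extract_features(back)


class TestMetricalStrength:
    @pytest.mark.parametrize(
        "onset,meter,expected",
        [
            (0.0, (4, 4), 1.0),    # downbeat
            (4.0, (4, 4), 1.0),    # downbeat of bar 2
            (2.0, (4, 4), 0.5),    # beat 3, mid-bar strong beat
            (1.0, (4, 4), 0.25),   # weak beat
            (3.0, (4, 4), 0.25),
            (1.5, (4, 4), 0.125),  # off-beat subdivision
            (0.25, (4, 4), 0.125),
            (0.0, (3, 4), 1.0),
            (1.0, (3, 4), 0.25),   # no mid-bar level in odd meters
            (2.0, (3, 4), 0.25),
            (0.0, (6, 8), 1.0),
            (1.5, (6, 8), 0.5),    # second dotted-quarter group
            (0.5, (6, 8), 0.25),   # grid eighth
        ],
    )
    def test_hierarchy_table(self, onset, meter, expected):
        assert metrical_strength(onset, meter) == expected

    def test_invalid_meter_rejected(self):
        with pytest.raises(ParameterError):
            metrical_strength(0.0, (0, 4))


class TestNarmour:
    @pytest.mark.parametrize(
        "pitches,expected",
        [
            ((60, 62, 64), "P"),    # small + small, same direction, similar
            ((60, 60, 60), "D"),    # duplication
            ((60, 67, 64), "IR"),   # large then reversal with smaller interval
            ((60, 64, 60), "ID"),   # exact mirror of a small interval
            ((60, 62, 59), "IP"),   # small, reversed, similar size
            ((60, 62, 71), "VP"),   # small then large, same direction
            ((60, 69, 71), "R"),    # large then smaller, same direction
            ((60, 67, 59), "VR"),   # large then larger, reversed
        ],
    )
    def test_rule_table(self, pitches, expected):
        labels = narmour_labels(pitches)
        assert labels == ["boundary", expected, "boundary"]

    def test_boundary_labels_on_short_melodies(self):
        assert narmour_labels([60]) == ["boundary"]
        assert narmour_labels([60, 62]) == ["boundary", "boundary"]


class TestLegato:
    def test_contiguous_notes_have_zero_legato(self):
        a = Note(pitch=60, onset=0.0, duration=1.0)
        b = Note(pitch=62, onset=1.0, duration=1.0)
        assert legato_amount(a, b) == 0.0

    def test_half_overlap(self):
        # prev sounds 1.5 beats, next starts after 1 beat: overlap 0.5 of IOI
        a = Note(pitch=60, onset=0.0, duration=1.5)
        b = Note(pitch=62, onset=1.0, duration=1.0)
        assert legato_amount(a, b) == pytest.approx(0.5)

    def test_staccato_gap_clips_to_zero(self):
        a = Note(pitch=60, onset=0.0, duration=0.25)
        b = Note(pitch=62, onset=1.0, duration=1.0)
        assert legato_amount(a, b) == 0.0

    def test_zero_ioi_degenerate(self):
        a = Note(pitch=60, onset=0.0, duration=1.0)
        b = Note(pitch=62, onset=0.0, duration=1.0)
        with pytest.raises(DegenerateInputError):
            legato_amount(a, b)


class TestExtractFeatures:
    def test_single_note_gets_boundary_sentinels(self):
        sc = Score(notes=[Note(pitch=70, onset=2.0, duration=1.0, velocity=90)])
        (f,) = extract_features(sc)
        assert (f.prev_pitch, f.next_pitch) == (0.0, 0.0)
        assert (f.has_prev, f.has_next) == (0.0, 0.0)
        assert f.metr_str == 0.5  # beat 3 of 4/4
        assert f.mean_energy == 90.0

    def test_uniform_piece_symmetry(self):
        notes = [Note(pitch=60, onset=float(i), duration=1.0, velocity=64)
                 for i in range(6)]
        feats = extract_features(Score(notes=notes))
        inner = feats[1:-1]
        assert all(f.prev_pitch == 0.0 and f.next_pitch == 0.0 for f in inner)
        assert all(f.prev_dur == 1.0 and f.next_dur == 1.0 for f in inner)
        assert all(f.mean_energy == 64.0 for f in feats)

    def test_matches_independent_hand_extractor(self):
        """Spot-check 3 interior notes against a from-scratch extractor."""
        sc = generate_score(20, seed=8)
        feats = extract_features(sc)
        ns = sc.notes
        mean_vel = sum(n.velocity for n in ns) / len(ns)
        for i in (5, 10, 14):
            f = feats[i]
            assert f.pitch == ns[i].pitch
            assert f.dur == ns[i].duration
            assert f.prev_pitch == ns[i - 1].pitch - ns[i].pitch
            assert f.next_pitch == ns[i + 1].pitch - ns[i].pitch
            assert f.prev_dur == pytest.approx(ns[i - 1].duration / ns[i].duration)
            assert f.next_dur == pytest.approx(ns[i + 1].duration / ns[i].duration)
            assert f.mean_energy == pytest.approx(mean_vel)
            # legato by the definition: overlap fraction of the IOI
            ioi_prev = ns[i].onset - ns[i - 1].onset
            overlap = max(0.0, ns[i - 1].onset + ns[i - 1].duration - ns[i].onset)
            assert f.legato_prev == pytest.approx(min(1.0, overlap / ioi_prev))

    def test_transposition_invariance(self):
        sc = generate_score(30, seed=2)
        shifted = Score(
            notes=[Note(n.pitch + 3, n.onset, n.duration, n.velocity) for n in sc.notes],
            meter=sc.meter, tempo_bpm=sc.tempo_bpm,
        )
        f0, f1 = extract_features(sc), extract_features(shifted)
        for a, b in zip(f0, f1):
            assert b.pitch == a.pitch + 3
            assert b.prev_pitch == a.prev_pitch
            assert b.next_pitch == a.next_pitch
            assert b.narmour_primary == a.narmour_primary
            assert b.dur == a.dur

    def test_time_scale_invariance_of_duration_ratios(self):
        sc = generate_score(30, seed=2)
        doubled = Score(
            notes=[Note(n.pitch, 2 * n.onset, 2 * n.duration, n.velocity)
                   for n in sc.notes],
            meter=sc.meter, tempo_bpm=sc.tempo_bpm,
        )
        f0, f1 = extract_features(sc), extract_features(doubled)
        for a, b in zip(f0, f1):
            assert b.prev_dur == pytest.approx(a.prev_dur)
            assert b.next_dur == pytest.approx(a.next_dur)
            assert b.legato_prev == pytest.approx(a.legato_prev)

    def test_design_matrix_shape_and_determinism(self):
        sc = generate_score(25, seed=6)
        X1 = design_matrix(extract_features(sc))
        X2 = design_matrix(extract_features(sc))
        assert X1.shape == (25, 19)
        assert np.array_equal(X1, X2)
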