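"""Score representation, MIDI I/O and per-note feature extraction.

Each note of a monophonic melody is described by features of the note
itself (pitch, duration in beats, metrical strength), of its melodic
context (signed pitch intervals and duration ratios to the previous and
next note, Narmour implication-realization group of the triplet centred on
the note), articulation (legato overlap with the previous and next note)
and the piece-level mean energy (MIDI velocity is the energy proxy; the
reference "score value" for energy is the average velocity of all notes in
the piece). These feature vectors are the regressors of the expressive
performance models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import midi
from .errors import DegenerateInputError, ParameterError, StructureError

_EPS = 1e-9


@dataclass(frozen=True)
class Note:
    """One score note: pitch (MIDI number), onset and duration in beats."""

    pitch: int
    onset: float
    duration: float
    velocity: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ParameterError(f"pitch {self.pitch} outside MIDI 0-127")
        if self.duration <= 0:
            raise ParameterError(f"non-positive duration at onset {self.onset}")
        if not 0 <= self.velocity <= 127:
            raise ParameterError(f"velocity {self.velocity} outside 0-127")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Score:
    """A melody: ordered notes, meter (numerator, denominator), tempo."""

    notes: list[Note]
    meter: tuple[int, int] = (4, 4)
    tempo_bpm: float = 120.0

    def __post_init__(self) -> None:
        if self.meter[0] < 1 or self.meter[1] < 1:
            raise ParameterError(f"invalid meter {self.meter}")
        if self.tempo_bpm <= 0:
            raise ParameterError("tempo must be positive")
        onsets = [n.onset for n in self.notes]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise StructureError("note onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def bar_beats(self) -> float:
        """Bar length in quarter-note beats."""
        num, den = self.meter
        return num * 4.0 / den

    @property
    def total_beats(self) -> float:
        return max((n.offset for n in self.notes), default=0.0)

    @property
    def duration_s(self) -> float:
        return self.total_beats * 60.0 / self.tempo_bpm

    def is_polyphonic(self) -> bool:
        """True if any two notes start together or a note spans a later onset.

        Simultaneous onsets (chords) and overlap reaching past the immediate
        successor count as polyphony; partial overlap with the very next note
        is legato articulation, not polyphony.
        """
        ns = self.notes
        for a, b in zip(ns, ns[1:]):
            if b.onset - a.onset <= _EPS:
                return True
        for i, n in enumerate(ns[:-2]):
            if n.offset > ns[i + 2].onset + _EPS:
                return True
        return False

    def check_monophonic(self) -> None:
        if self.is_polyphonic():
            raise StructureError("score is polyphonic; feature extraction needs a melody")


def read_midi(path) -> Score:
    md = midi.read_midi_file(path)
    notes = [
        Note(pitch=n.pitch, onset=n.onset_beats, duration=n.duration_beats, velocity=n.velocity)
        for n in md.notes
    ]
    return Score(notes=notes, meter=(md.numerator, md.denominator), tempo_bpm=md.tempo_bpm)


def write_midi(score: Score, path, ticks_per_beat: int = midi.DEFAULT_TICKS_PER_BEAT) -> None:
    md = midi.MidiData(
        notes=[
            midi.MidiNote(
                pitch=n.pitch,
                onset_beats=n.onset,
                duration_beats=n.duration,
                velocity=n.velocity,
            )
            for n in score.notes
        ],
        tempo_bpm=score.tempo_bpm,
        numerator=score.meter[0],
        denominator=score.meter[1],
        ticks_per_beat=ticks_per_beat,
    )
    midi.write_midi_file(md, path)


def metrical_strength(onset: float, meter: tuple[int, int]) -> float:
    """Metrical prominence of an onset in (0, 1].

    Four-level power-of-two hierarchy: downbeat 1.0; the mid-bar strong
    beat of even-numerator meters (beat 3 in 4/4, the second group of 6/8)
    0.5; other beats of the meter's grid 0.25; off-beat subdivisions 0.125.
    Odd-numerator meters (3/4) have no mid-bar level: non-downbeat beats
    score 0.25.
    """
    num, den = meter
    if num < 1 or den < 1:
        raise ParameterError(f"invalid meter {meter}")
    if onset < 0:
        raise ParameterError("onset must be >= 0")
    bar = num * 4.0 / den
    beat_unit = 4.0 / den
    pos = onset % bar

    def _is(x: float, y: float) -> bool:
        return abs(x - y) < _EPS or abs(x - y - bar) < _EPS

    if _is(pos, 0.0):
        return 1.0
    if num % 2 == 0 and _is(pos, bar / 2):
        return 0.5
    if abs(pos / beat_unit - round(pos / beat_unit)) < _EPS:
        return 0.25
    return 0.125


# --- Narmour implication-realization groups -------------------------------

NARMOUR_GROUPS = ("P", "D", "R", "ID", "IP", "VP", "IR", "VR", "none")
_SMALL_MAX = 6  # intervals of 6 semitones are ambiguous; treated as small
_LARGE_MIN = 7
_SIMILAR = 2  # "similar size" = within 2 semitones


def _classify_triplet(p1: int, p2: int, p3: int) -> str:
    """Classify one melodic triplet into a basic implication-realization group.

    With i1 = p2-p1 (implicative) and i2 = p3-p2 (realized), absolute sizes
    a1, a2, "small" <= 6 semitones, "large" >= 7, "similar" within 2:

    ==========  =========================================================
    group       rule
    ==========  =========================================================
    D           a1 = a2 = 0 (duplication)
    P           small a1, small similar a2, same direction (process)
    ID          small a1 > 0, a2 = a1, direction reversed (intervallic dup.)
    IP          small a1, small similar a2, direction reversed
    VP          small a1, large a2, same direction (process violated in
                interval)
    R           large a1, smaller a2, same direction (reversal of interval)
    IR          large a1, smaller a2, direction reversed
    VR          large a1, large a2 >= a1, direction reversed
    none        anything else
    ==========  =========================================================
    """
    i1, i2 = p2 - p1, p3 - p2
    a1, a2 = abs(i1), abs(i2)
    same_dir = i1 * i2 > 0
    reversed_dir = i1 * i2 < 0

    if a1 == 0 and a2 == 0:
        return "D"
    if a1 <= _SMALL_MAX:
        if a2 <= _SMALL_MAX:
            if a1 > 0 and a2 == a1 and reversed_dir:
                return "ID"
            if abs(a1 - a2) <= _SIMILAR:
                if same_dir:
                    return "P"
                if reversed_dir:
                    return "IP"
            return "none"
        return "VP" if same_dir else "none"
    # large implicative interval
    if a2 < a1:
        if reversed_dir:
            return "IR"
        if same_dir:
            return "R"
        return "none"
    if a2 >= _LARGE_MIN and reversed_dir:
        return "VR"
    return "none"


def narmour_labels(pitches) -> list[str]:
    """Per-note group labels: the triplet centred on each interior note.

    The first and last notes have no centred triplet and are labelled
    ``"boundary"``.
    """
    pitches = list(pitches)
    labels = ["boundary"] * len(pitches)
    for i in range(1, len(pitches) - 1):
        labels[i] = _classify_triplet(pitches[i - 1], pitches[i], pitches[i + 1])
    return labels


def narmour_memberships(pitches) -> list[tuple[str, ...]]:
    """All triplet memberships of each note (as last, centre and first
    element of a triplet), up to three labels per note."""
    pitches = list(pitches)
    n = len(pitches)
    trips = [_classify_triplet(*pitches[i : i + 3]) for i in range(n - 2)]
    out = []
    for i in range(n):
        # note i appears in triplets starting at i-2, i-1 and i
        member = tuple(trips[j] for j in (i - 2, i - 1, i) if 0 <= j < len(trips))
        out.append(member)
    return out


def legato_amount(prev_note: Note, note: Note) -> float:
    """Fraction of the inter-onset interval over which ``prev_note`` still
    sounds after ``note`` starts; 0 for contiguous or detached notes."""
    ioi = note.onset - prev_note.onset
    if ioi <= 0:
        raise DegenerateInputError("zero inter-onset interval; legato undefined")
    return float(np.clip((prev_note.offset - note.onset) / ioi, 0.0, 1.0))


@dataclass(frozen=True)
class NoteFeatureVector:
    """Features of one note; sentinel 0 plus a presence flag for absent
    neighbors (duration *ratios* use sentinel 0 as well)."""

    pitch: int
    dur: float
    metr_str: float
    prev_pitch: float
    prev_dur: float
    next_pitch: float
    next_dur: float
    has_prev: float
    has_next: float
    legato_prev: float
    legato_next: float
    narmour: tuple[str, ...]
    narmour_primary: str
    mean_energy: float


#: Column order of the numeric design matrix. Narmour membership enters as
#: one-hot indicators of the *centred* triplet label; "none" and "boundary"
#: are the joint reference category (boundary position is already encoded by
#: has_prev/has_next, so a separate indicator would be collinear).
NARMOUR_ONEHOT = ("P", "D", "R", "ID", "IP", "VP", "IR", "VR")
FEATURE_NAMES = (
    "pitch",
    "dur",
    "metr_str",
    "prev_pitch",
    "prev_dur",
    "next_pitch",
    "next_dur",
    "has_prev",
    "has_next",
    "legato_prev",
    "legato_next",
) + tuple(f"narmour_{g}" for g in NARMOUR_ONEHOT)


def extract_features(score: Score) -> list[NoteFeatureVector]:
    """Per-note feature vectors for a monophonic score (>= 1 note)."""
    score.check_monophonic()
    ns = score.notes
    if not ns:
        raise StructureError("cannot extract features from an empty score")
    labels = narmour_labels([n.pitch for n in ns])
    members = narmour_memberships([n.pitch for n in ns])
    mean_energy = float(np.mean([n.velocity for n in ns]))
    out = []
    for i, n in enumerate(ns):
        prev_n = ns[i - 1] if i > 0 else None
        next_n = ns[i + 1] if i < len(ns) - 1 else None
        out.append(
            NoteFeatureVector(
                pitch=n.pitch,
                dur=n.duration,
                metr_str=metrical_strength(n.onset, score.meter),
                prev_pitch=float(prev_n.pitch - n.pitch) if prev_n else 0.0,
                prev_dur=float(prev_n.duration / n.duration) if prev_n else 0.0,
                next_pitch=float(next_n.pitch - n.pitch) if next_n else 0.0,
                next_dur=float(next_n.duration / n.duration) if next_n else 0.0,
                has_prev=1.0 if prev_n else 0.0,
                has_next=1.0 if next_n else 0.0,
                legato_prev=legato_amount(prev_n, n) if prev_n else 0.0,
                legato_next=legato_amount(n, next_n) if next_n else 0.0,
                narmour=members[i],
                narmour_primary=labels[i],
                mean_energy=mean_energy,
            )
        )
    return out


def design_matrix(features: list[NoteFeatureVector]) -> np.ndarray:
    """Numeric regressor matrix, one row per note, columns ``FEATURE_NAMES``."""
    rows = []
    for f in features:
        onehot = [1.0 if f.narmour_primary == g else 0.0 for g in NARMOUR_ONEHOT]
        rows.append(
            [
                f.pitch,
                f.dur,
                f.metr_str,
                f.prev_pitch,
                f.prev_dur,
                f.next_pitch,
                f.next_dur,
                f.has_prev,
                f.has_next,
                f.legato_prev,
                f.legato_next,
            ]
            + onehot
        )
    return np.asarray(rows, dtype=float)


def features_to_csv(features: list[NoteFeatureVector], path) -> None:
    """Write the numeric feature matrix (plus labels) as CSV."""
    import pandas as pd

    X = design_matrix(features)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "narmour_primary", [f.narmour_primary for f in features])
    df["mean_energy"] = [f.mean_energy for f in features]
    df.to_csv(path, index=False)
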