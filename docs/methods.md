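# Methods

## Signal chain

An `EEGRecording` is a channels × samples matrix in microvolts with 10–20
labels, sampled at 128 Hz by default. The alpha (8–12 Hz) and beta
(12–28 Hz) bands are realised as 4th-order Butterworth band-pass filters;
the band edges are standard for these rhythms and the order is standard
EEG practice — steep enough to separate alpha from beta at 128 Hz without
severe ringing. Two filtering contracts are exposed: zero-phase
(forward–backward, for offline analysis; no phase distortion, acausal)
and causal (single forward pass, as a real-time loop would apply).

Band power is the **mean squared amplitude of the filtered signal** over
a sliding window (default 1.0 s window, 0.25 s hop). This time-domain
filter-then-measure estimator matches the architecture of a live
neurofeedback chain; a periodogram-sum estimator appears in the tests as
an independent oracle, never in the pipeline. For an in-band sinusoid of
amplitude A the estimator converges to A²/2 once the window covers a few
cycles; the 1-s window at 8 Hz and above keeps the ripple below a few
percent. The 1 s / 0.25 s epoching balances responsiveness (4 control
updates per second) against estimator variance; there is no universally
standard choice and both are configurable.

EEG CSV dialect: header row, first column `time` in seconds, one column
per electrode, microvolts. No re-referencing is applied and no artifact
detection is performed; the decoder consumes the montage as recorded.

## Affect decoding

Arousal is the summed beta over summed alpha power across AF3, AF4, F3,
F4; valence is alpha power at F4 minus F3 (frontal alpha asymmetry).
Both follow directly from the band-power frames; frames with zero total
alpha raise a degenerate-input error rather than emitting infinities, so
downstream consumers never see non-finite affect.

Raw arousal (a dimensionless ratio near 1) and valence (a signed power
difference in µV²) are in subject-dependent units, so mapping onto the
[−1, 1]² arousal–valence plane is **baseline-calibrated per subject**: the
median and robust spread (1.4826 × MAD, floored at 10⁻³ to survive very
clean baselines) of log-arousal and valence over a calibration window
(default: the first 30 s of a session, ≥ 30 samples) define a tanh-scaled
deviation score per dimension. The map is monotone, centred (baseline
medians → origin) and saturating (±1 are approached, never exceeded).
Log-arousal is used because the ratio is positive and right-skewed.

Optional smoothing is an exponential moving average with 2 s half-life —
long enough to suppress frame-to-frame estimator jitter, short enough to
track affect changes on the timescale of a musical phrase. Reporting
normalization offers min-max (to [0, 1]) and z-score; both are strictly
monotone, and correlation-based analyses are invariant to them.

## Synthetic EEG

Each channel is a 10 Hz sinusoid (alpha-band centre) plus a 20 Hz
sinusoid (beta-band centre) with per-channel amplitude trajectories
(constant, piecewise-constant, or linear ramps) plus white Gaussian
noise; phases are random per channel. Ground-truth affect follows
analytically from the amplitudes via power = A²/2. White noise (default
2 µV against default 10 µV carriers, i.e. comfortably above 10 dB SNR)
keeps the ground truth exact; pink noise, ocular/muscular artifacts,
non-sinusoidal rhythms and volume conduction are *not* emulated, so
passing recovery tests demonstrates the decoder's correctness on its own
signal model, not robustness to real-world EEG contamination.

## Note features

Each note of a monophonic melody carries: MIDI pitch; duration in beats;
metrical strength from a four-level power-of-two hierarchy (downbeat 1.0;
mid-bar strong beat of even-numerator meters 0.5; other grid beats 0.25;
off-beat subdivisions 0.125 — odd meters like 3/4 have no mid-bar level);
signed semitone intervals and duration ratios to the previous and next
note (sentinel 0 plus a presence flag at boundaries); the Narmour
implication-realization group of the triplet centred on the note; legato
with the previous/next note as the overlap fraction of the inter-onset
interval, clipped to [0, 1]; and mean energy, the piece-average MIDI
velocity (velocity is the energy proxy throughout — audio energy
estimation is out of scope). Legato is defined on symbolic timing.

Narmour classification uses interval-size thresholds: "small" ≤ 5
semitones (6, the ambiguous tritone, is treated small), "large" ≥ 7,
"similar" within 2. The rule table (D, P, ID, IP, VP, R, IR, VR, none) is
documented in `score.py`; only the basic groups are implemented. Chords
(simultaneous onsets) and overlap reaching past the immediate successor
are rejected as polyphony; partial overlap with the very next note is
legato articulation, not polyphony.

The numeric design matrix one-hot encodes the centred triplet label over
the eight groups, with "none"/"boundary" as the joint reference category:
a separate boundary indicator would be exactly collinear with the
intercept and the two presence flags. Mean energy is the reference value
for the energy-ratio target, not a regressor (it is constant within a
piece and would be collinear with the intercept on single-piece corpora).

## Expressive models and interpolation

Per emotion (happy, relaxed, sad, angry) and per target (duration ratio,
energy ratio), models are ordinary least squares with an intercept,
requiring n ≥ p + 1 and a full-rank augmented design; a tiny ridge
penalty (10⁻⁶, off by default, logged when used) is available for
rank-deficient designs. Predictions are clipped to [0.5, 2.0] — halving
to doubling — to keep feedback musically plausible under adversarial
inputs.

Anchors default to (±0.5, ±0.5), strictly inside each emotion's quadrant.
Interpolation at a plane coordinate is a coefficient-wise **bilinear
blend**: the coordinate is clamped to the anchor rectangle and split into
a valence fraction and an arousal fraction; products of these give four
non-negative weights summing to 1. This gives exactness at anchors,
continuity, and convexity (every interpolated coefficient and prediction
lies within the range spanned by the four quadrant models) — all of which
are contract-tested. Inverse-distance weighting was the alternative; it
lacks anchor exactness for smooth exponents and has no convexity
guarantee on predictions.

Because no recorded emotional performances are bundled, the shipped
training path fits on **synthetic corpora with known coefficients**:
targets are exact linear combinations of the implemented feature vector
plus Gaussian noise, clipped to (0.25, 4). The true-coefficient generator
scales each weight by its feature's typical span so targets stay within
the clip range (the noiseless recovery contract requires the clip to be
inactive), and corpora are built from many short (25-note) melodies with
randomized articulation (0.5–1.5 × IOI, overlap capped below the next
IOI) so that boundary flags, legato and all Narmour indicator columns
have usable variance. These synthetic corpora are stand-ins: recovering
known coefficients validates the training/prediction machinery, not any
claim about real expressive performance.

## Feedback loop and session simulation

Controls are piecewise-linear and strictly monotone: valence −1/0/+1 →
tempo factor 0.8/1.0/1.25, arousal −1/0/+1 → loudness gain −6/0/+6 dB.
The ranges bound the feedback to musically tolerable transformations; the
direction (valence→tempo, arousal→loudness) is the neurofeedback
contract. Controls update at the affect hop (0.25 s) with zero-order
hold.

Rendering is symbolic: per-note inter-onset intervals and durations are
scaled by `duration_ratio / tempo_factor` (preserving contiguity),
velocities by the energy ratio and the dB gain (clipped to 1–127),
pitches never change. Only timing and loudness are transformed;
articulation transformations are out of scope.

A session plays the playlist in order with wraparound, separated by 1 s
silent pauses (no control records), for 15 minutes (900 s) by default,
truncating the final piece. The first 30 s run at neutral controls while
the baseline calibration accumulates. The affect source is either a
precomputed series (open loop) or the **simulated responder**: its
valence drifts by `gain × (tempo_factor − 1 + intent)` per step plus
noise, its log-arousal analogously from the normalized loudness gain
(damped ×0.01 so the ratio stays physiological over a session). The
`intent` term (default 0.3) models the instructed participant — people in
such a protocol are explicitly encouraged to drive the music faster and
louder — and outweighs the strongest opposing feedback, so an engaged
responder trends upward instead of amplifying whichever way its baseline
noise happened to break; feedback then modulates the rate. Defaults
(gain 0.02, noise sd 0.05 per 0.25 s step) give a drift that clearly
dominates the accumulated random walk over 15 minutes, emulating a
clearly-responding participant. With gain 0 the responder is a pure
random walk (a non-responder control).

## Session analyses

Minute means average one affect dimension over contiguous 60 s periods of
the *active* (music-playing) timeline — pauses are excluded by
construction since frames only exist during pieces. The affect–time
correlation is Pearson's r of the ten period means against period index,
with the two-sided p from the t-transform on n − 2 degrees of freedom.
Begin/end-of-study comparisons use a paired two-sided t-test (differences
constant to float precision are flagged zero-variance: p = 1 when the
difference is zero, p = 0 otherwise, instead of an unstable t). BDI
percent improvement is (pre − post)/pre × 100 per subject, mean and n−1
SD across subjects; subjects with pre = 0 are excluded and listed (a
non-depressed participant has no meaningful percent change). When
aggregating across sessions, period means are averaged across sessions
per subject, then across subjects.

The package does not claim to reproduce any published clinical values:
those depend on participant EEG and BDI data that are not available. The
analyses here are validated against brute-force statistical oracles and
simulated sessions.

## Numerical and scope notes

- Zero-phase filtering of a ≤ 1-sample recording returns zeros (filtfilt
  needs padding); recordings shorter than one window yield an empty frame
  sequence, not an error.
- MIDI I/O is a purpose-built Standard MIDI File (type 0/1) reader/writer
  covering note events plus tempo/time-signature meta; round-trip error is
  bounded by the tick resolution (480 ticks/beat by default). EDF input is
  not implemented; EEG enters as CSV.
- All generators are pure functions of (specification, seed); the CLI
  threads one seed through every source of randomness.
- Problem sizes used by the test suite and acceptance script (60 s
  recordings, 300–500-note corpora, single 900 s sessions) are the
  package's default demonstration scale; all complete in seconds.
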