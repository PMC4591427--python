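# neuromuse

Offline, fully testable implementation of an **emotion-driven musical
neurofeedback** pipeline: multichannel EEG is decoded into a continuous
arousal/valence estimate, the estimate selects an *expressive performance
model* by interpolating between four emotion-specific regression models,
and the selected model drives tempo and loudness feedback on symbolic
(MIDI) music. The package also reproduces the session-level analyses such
a study reports: within-session affect–time correlations over ten 1-minute
periods, begin/end-of-study comparisons, and Beck Depression Inventory
(BDI) percent change.

Everything runs on synthetic data with known ground truth — a 14-channel
EEG generator with controllable alpha/beta amplitude trajectories, a
melody generator, regression corpora with known coefficients, and a
simulated closed-loop participant — so every stage is testable with no
recordings or participant data.

## The model

From band powers at the four prefrontal 10–20 sites AF3, AF4, F3, F4
(Butterworth band-pass 8–12 Hz for alpha, 12–28 Hz for beta, 4th order,
128 Hz sampling; power = windowed mean squared amplitude):

```
arousal = (βF3 + βF4 + βAF3 + βAF4) / (αF3 + αF4 + αAF3 + αAF4)
valence = αF4 − αF3
```

Arousal is the beta/alpha activation ratio of the frontal cortex; valence
is frontal alpha asymmetry (less left-frontal alpha ⇒ relatively greater
left activation ⇒ more positive affect). A per-subject baseline
calibration maps both onto the [−1, 1]² arousal–valence plane, whose
quadrants carry the four emotions: happy (+v, +a), angry (−v, +a),
sad (−v, −a), relaxed (+v, −a).

For each emotion, two linear regressions over per-note score features
(pitch, duration, metrical strength, neighbor intervals and duration
ratios, Narmour implication-realization group, legato, mean energy)
predict the note's performed/score **duration ratio** and **energy
ratio** — a predicted duration ratio of 1.14 means the note is lengthened
by 14% with respect to the score. An affect coordinate anywhere on the
plane gets an intermediate model by bilinear interpolation of the four
coefficient vectors. The feedback mapping is monotone: higher valence →
faster tempo (0.8–1.25×), higher arousal → louder playback (−6…+6 dB).

## Worked example

```sh
neuromuse --seed 2 synth eeg --out eeg.csv --truth-out truth.jsonl
neuromuse decode --eeg eeg.csv --out affect.jsonl
neuromuse --seed 5 train --n-notes 300 --out models.json
neuromuse --seed 5 synth score --n-notes 30 --out melody.mid
neuromuse render --score melody.mid --coord 0.5,0.5 --models models.json --out happy.mid
neuromuse --seed 7 simulate --responder --models models.json --out session.jsonl
neuromuse analyze --sessions session.jsonl --out report.json
```

which prints, in order:

```
wrote 7680 samples x 14 channels to eeg.csv
wrote 237 affect frames to affect.jsonl
trained 4 x 2 models on 300 notes/emotion -> models.json
wrote 30-note score to melody.mid
rendered 30 notes at (0.5, 0.5) -> happy.mid
logged 3543 frames to session.jsonl
wrote report for 1 session(s) to report.json
```

The decode step emits one `{t, arousal, valence, arousal_n, valence_n}`
record per 1-s window (0.25-s hop) of the 60-s synthetic recording.
`happy.mid` is the melody rendered with the model interpolated at the
happy-quadrant coordinate (faster, louder than the score). The simulated
session runs the full closed loop for 15 minutes: the synthetic
responder's valence rises as the feedback rewards it, and `report.json`
contains the ten 1-minute period means with their Pearson correlation
against time — `r ≈ 0.998` for valence in this run, i.e. a strongly
rising within-session valence trend.

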