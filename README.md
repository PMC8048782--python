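# runsync

Auditory–motor entrainment analysis for running: a tested, reusable
pipeline from raw-ish sensor signals (ankle gyroscopes, a backpack sonar,
a musical beat schedule) to the statistics that describe whether and how
a runner's steps lock to the music.

## The problem

When people run with music whose tempo is close to their step rate, some
of them *entrain*: their steps adopt the period of the beat, and
sometimes a stable phase relation. Quantifying this in the field takes
four ingredients:

1. **Gait events.** Each reversal of the leg's angular velocity, seen as
   a negative-to-positive zero crossing of an ankle gyroscope trace, is
   a step. Cadence (steps per minute, SPM) is a moving average over
   windows of 8 consecutive same-leg steps; step length is the distance
   between successive heel prints; speed comes from a sonar that sees a
   distance minimum each time the runner passes one of 29 marker rods
   spaced 9.97 m along a 289 m track.
2. **Tempo entrainment (%).** A step is tempo-entrained when its
   instantaneous cadence is within 1 % of the concurrent music tempo
   (BPM); the score is the percentage of such steps.
3. **Relative phase angle (rPA).** Each step at time *St* bracketed by
   beats *B1*, *B2* gets the angle φ = 360·(St − B1)/(B2 − B1), wrapped
   to (−180°, 180°]: 0° is a footfall exactly on the beat, 180° exactly
   between beats, negative angles are footfalls ahead of the beat. The
   circular mean of the φ summarizes the phase relation.
4. **Resultant vector length (RVL).** The norm of the mean unit vector
   of the angles, in [0, 1]: 1 means perfectly repeatable phase, ≈0 no
   phase relation. A session with RVL ≥ 0.75 marks an *entrainer*, and
   the mean rPA is only reported above that cutoff. For a von Mises
   phase distribution with concentration κ the expected RVL is the
   Bessel ratio I₁(κ)/I₀(κ).

Sessions follow a repeated-measures protocol: a silent run, then two
runs with music whose tempo is matched to the cadence of the last 120
steps of the silent run — once without instructions, once with the
instruction to match the beat. Features are compared across conditions
with a 3 × 2 mixed-design ANOVA (condition within subjects, sex
between), plus Friedman/Wilcoxon tests for ordinal ratings and subgroup
tests for musical training and listening habits. The first 60 s and
final 30 s of every 4-minute run are discarded before any computation.

Because raw data of this kind are rarely public, the package ships a
first-class synthetic cohort generator that emulates the assumed data
structure — phase-coupled (von Mises) footfalls for entrainers, renewal
stepping for nonentrainers, gyroscope-like and sonar-like traces — so
every stage of the analysis can be validated by parameter recovery.

## Worked example

```python
import runsync as rs

study = rs.EntrainmentStudy.from_simulation(n_runners=33, seed=1)
res = study.fit()          # detection -> kinematics -> entrainment -> ANOVA
print(res.summary())
print(res.entrainer_fraction("uninstructed"), res.entrainer_fraction("instructed"))
```

prints (excerpt of the actual output):

```
Running-to-music entrainment study
  runners: 33, sessions: 99

Condition means (mean +/- SE):
  cadence            no_music 168.37+/-1.32; uninstructed 169.86+/-1.30; instructed 168.92+/-1.30
  step_length        no_music 1.08+/-0.03; uninstructed 1.11+/-0.03; instructed 1.08+/-0.03
  speed              no_music 10.92+/-0.27; uninstructed 11.27+/-0.26; instructed 10.88+/-0.28
  tempo_entrainment  uninstructed 44.29+/-7.04; instructed 74.29+/-4.92
  mean_rpa           uninstructed -40.76+/-3.18; instructed -37.96+/-3.56
  rvl                uninstructed 0.34+/-0.07; instructed 0.61+/-0.07

Effects (mixed-design ANOVA, condition within / sex between):
  cadence:
    sex: F(1,31) = 13.09, P = 0.00104, eta2 = 0.297
    condition: F(2,62) = 25.27, P = 9.42e-09, eta2 = 0.449
    condition x sex: F(2,62) = 0.99, P = 0.379, eta2 = 0.031
    ...
```

with entrainer fractions 0.333 (uninstructed) and 0.636 (instructed).
Read it as: cadence rises under music relative to silence; the mean
relative phase is negative (footfalls anticipate the beat); phase
coherence (RVL) and tempo entrainment are higher when runners are
instructed to match the beat; and about a third of the cohort entrains
spontaneously while instruction roughly doubles that fraction. All of
these are properties the simulator plants and the pipeline recovers —
per-session cadence within 0.5 SPM, speed within 1 %, mean rPA within
3°, RVL within 0.02 of I₁(κ)/I₀(κ) (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```bash
runsync all --out study_dir --seed 7 --n 33        # simulate+detect+entrain+stats
runsync entrain --config my.yml --out study_dir    # rerun one stage
```

Every stage consumes and produces plain CSV, so measured (non-simulated)
step events, beat schedules, and traces can be dropped into the same
layout and analyzed with `runsync entrain` + `runsync stats`, or with
`EntrainmentStudy.from_directory(...)`.

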