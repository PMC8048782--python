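# Methods

This note documents the models, algorithms, and numerical choices behind
`runsync`, and what its synthetic validation does and does not show.

## Measurement model

**Step detection.** A step is a movement-direction reversal of the leg.
On the angular-velocity trace this is taken as a negative-to-positive
zero crossing, located by linear interpolation between the two bracketing
samples, with a 0.4 s refractory interval (no physiological stride is
faster; at running cadences of 130–200 SPM the same-leg period is
0.6–0.92 s). The crossing direction and the refractory length are
implementation choices; any consistent direction convention yields the
same cadence because only inter-event intervals matter downstream.

**Cadence.** Over each window of 8 consecutive same-leg steps (7 stride
intervals), cadence = 2·60 / mean(stride interval) SPM, timestamped at
the window's last step (causal: the value is available in real time).
The windows of the two feet are interleaved. "8 consecutive steps" is
read as 8 events → 7 intervals; the window size is a parameter
(`cadence_window`), and for steady running both readings converge. The
telescoping of the window mean (span / 7) makes the estimate robust to
step-to-step jitter.

**Step length** is the heel-to-heel distance between successive steps of
opposite feet, using 1-D along-track heel coordinates. Positions wrap at
the track length (289 m); a negative difference is corrected by one lap,
and a corrected length outside (0 m, 3 m] is rejected as corrupt rather
than silently absorbed.

**Speed.** The sonar sees a distance dip at each marker rod (spacing
9.97 m). Each below-threshold excursion (< 3 m) contributes the time of
its minimum sample; minima closer than 1 s are merged. Speed between
consecutive passages is 3.6 · spacing / interval (km/h). Note one
geometric caveat: 29 rods on a 289 m circuit leave one inter-rod gap of
9.84 m per lap, so one of every 29 intervals overestimates speed by
~1.3 %; averaged over a session the bias is below 0.05 %.

**Analysis window.** The first 60 s (start-up) and last 30 s
(anticipated ending) of each 240 s run are discarded — a closed interval
[60, 210] s — before any feature is computed.

## Entrainment statistics

Per step at time St with bracketing beats B1 ≤ St < B2:
φ = 360·(St − B1)/(B2 − B1), wrapped from [0°, 360°) to (−180°, 180°]
so that a footfall just ahead of its nearest beat is negative; +180° is
the canonical antipode (−180° does not occur). The raw angle is snapped
to nanodegree resolution before wrapping so that floating-point jitter
at the exact landmarks (on-beat, antipode) cannot flip the convention;
1 nanodegree of phase is ~10⁻¹⁵ s of step timing, far below any
measurement resolution. Steps of both feet are pooled (the music tempo
is set in SPM — one beat per step); steps before the first or after the
last beat are dropped and counted.

The circular mean is atan2 of the mean sine and cosine; it is undefined
(an error, not a number) when the resultant norm is below 1e-12. RVL is
the norm of the mean unit vector. A session is an *entrainer* when
RVL ≥ 0.75 (inclusive), and the mean rPA is reported only then — the
gate is applied at the summary level, while raw per-step angles remain
available for diagnostics.

Tempo entrainment holds the most recent cadence value at or before each
step (causal hold) and interpolates BPM linearly between beats; a step
is entrained when |SPM − BPM| ≤ 0.01·BPM, boundary inclusive. Steps
taken before the first cadence window fills are not scored. Whether the
original study used the instantaneous series or per-step intervals is
not documented; the causal hold is this package's choice.

## Protocol

The adaptive music tempo is the mean step rate over the final 120
inter-step intervals of the silent run, both feet pooled, unrounded:
BPM = 60·120/(t_last − t_last−120). The tempo-stretching stage is
modeled symbolically: an isochronous schedule at the target BPM, with
the stretch factor relative to the 168 BPM original recorded and bounded
to (0, 2], and the target bounded to the recreational cadence range
[130, 200] SPM. Both music conditions reuse the identical schedule (the
same stimulus is presented twice). Training, familiarization, and
control runs exist as protocol entries but never generate analyzed data.

## Synthetic cohort generator

The generator's defaults encode the study conditions the analysis
expects:

| parameter | default | rationale |
|---|---|---|
| cohort size | 33 (17 F / 16 M) | balanced to within one |
| baseline cadence | N(169, 8) SPM, truncated [130, 200]; F − M gap 7.4 SPM | typical recreational means by sex |
| step length | N(1.21, 0.12) m male, N(1.00, 0.12) m female | typical sex difference |
| condition shifts (cadence) | 0 / +2.11 / +1.52 SPM + N(0, 0.8) per runner | music raises cadence; silent baseline |
| condition shifts (step length) | 0 / +0.03 / −0.01 m + N(0, 0.015) | uninstructed music lengthens steps |
| entrainer probability | 1/3 uninstructed, 0.58 instructed | spontaneous vs instructed entrainment rates |
| trained-entrainment boost | ×2 relative odds, marginal preserved | musically trained runners entrain more |
| phase offset μ | N(−40°, 15°) | footfalls anticipate the beat |
| concentration κ | U(4, 8) | entrainers comfortably above RVL 0.75 (I₁/I₀: 0.86–0.94) |
| step-to-step tempo jitter | U(1, 2) SPM sd | short-term cadence variability |
| musical training / habit | 36.4 %; 51.5/39.4/9.1 % without/with/both | cohort composition |

Entrainers place one step per beat, offset by von Mises(μ, κ) phase
noise (κ = 0 gives uniform phase; κ is capped at 10⁶ for the degenerate
"locked" case). Von Mises is the maximum-entropy circular distribution
and makes RVL analytically predictable via the Bessel ratio, which the
tests exploit. Nonentrainers follow a renewal process at their own
condition-adjusted tempo, independent of the beat — the simplest null;
intermittent or partial coupling regimes are deliberately not modeled.
Entrainer flags are drawn independently per music condition.

Sensor synthesis is contractual only at the event level: the gyroscope
waveform is one sine cycle per stride (clamped clear of zero outside the
stepping interval) plus Gaussian noise — only its upward zero-crossing
times matter; the sonar is a 6 m plateau with a V-shaped dip to 1 m of
±0.15 s half-width at each rod crossing, computed by integrating the
true speed profile along the circular track.

What passing tests show: the analysis pipeline recovers the parameters
of data that satisfy its own assumptions (stationary phase coupling or
none, constant per-condition tempo, clean periodic sensor waveforms).
What they do not show: robustness to real-world phenomena the generator
omits — fatigue drift, intermittent coupling, asymmetric gait, sensor
dropouts, soft-tissue artifacts, 2-D foot placement.

## Statistics

The 3 × 2 mixed-design ANOVA (condition within, sex between) is
computed via `pingouin.mixed_anova` on complete cases (runners observed
in every compared condition); a direct sums-of-squares decomposition
serves as fallback for degenerate inputs (zero within-subject variance,
where 0/0 F ratios are reported as 0) and as the independent oracle in
the tests. Music-dependent features use the two music conditions.
Uncorrected F tests are reported (sphericity assumed, as is conventional
with three within levels when ε is near 1); partial eta squared
SS_eff/(SS_eff + SS_err) is the labeled effect size. Pairwise condition
contrasts are 1-df mixed ANOVAs on the level pairs, giving the familiar
F(1, n−2) form. Mean rPA analyses listwise-delete runners gated by the
RVL cutoff in any compared condition, so their error dfs are small by
construction.

Ratings use Friedman's ANOVA with pairwise two-sided Wilcoxon
signed-rank follow-ups (normal approximation, no continuity correction),
Bonferroni-multiplied by the 3 condition pairs and capped at 1, with
z²/(2n) as the effect-size estimate. Subgroup comparisons use a
pooled-variance two-sample t (the conventional t(n−2) form) and a
one-way fixed-effects ANOVA, both in closed form so that zero-variance
inputs yield t = 0 / F = 0 rather than NaN.

Calibration is tested empirically: on 1000 simulated null cohorts of 33
runners the condition test rejects at 5 % ± 2 %, and a condition effect
sized for 90 % nominal power (noncentral-F arithmetic) is detected in at
least 80 % of 200 replicates.

## Problem sizes and determinism

Every stochastic component takes a seed (or a shared
`numpy.random.Generator`), making cohorts, sessions, traces, and the
full CLI bit-for-bit reproducible. The validation suite uses 4-minute
sessions (~670 steps), cohorts of 33 for end-to-end recovery and
calibration, 10,000 draws per κ for the Bessel-ratio checks, and
2-minute sessions with 4 runners for CLI round trips — sizes at which
the statistical tolerances (mean rPA ± 3°, RVL ± 0.02, cadence
± 0.5 SPM, speed ± 1 %) are comfortably resolvable.

## Known limitations

- Heel positions are 1-D along-track; true foot placement is not modeled.
- Beat schedules are isochronous; musical structure (and beat-tracking
  error) is out of scope, as is audio I/O.
- The renewal null can transiently mimic coherence when a nonentrainer's
  tempo sits very close to the music tempo with little jitter; the
  trimmed-window RVL then fluctuates, which is a property of the
  statistic, not a bug in the generator.
- Group means of the simulator are plausibility defaults, not empirical
  claims; only parameter-recovery statements are validated.
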