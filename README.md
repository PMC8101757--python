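# groovetap

Quantitative analysis of sensorimotor coupling from paced finger tapping,
built for studies of rhythm-based interventions in Parkinson's disease (PD).
Movement-to-music entrainment is a candidate mechanism for why dance and
rhythmic-auditory-cueing programmes help parkinsonian motor symptoms; this
package turns raw tapping recordings into a per-trial coupling statistic and
runs the cohort-level models that link that statistic to beat perception and
clinical change.

## What it computes

**Tapping entropy.** Tap onsets (detected from a mono WAV click track, or
read from event tables) are converted to inter-onset intervals (IOIs). The
first three IOIs of each trial are discarded as task warm-up and any IOI
> 3 s is discarded as a device dropout. Each kept IOI is mapped to a phase
angle on the beat cycle, θ = 2π·((IOI mod T)/T) for reference period T, the
angles are binned into a 400-bin circular histogram, and the trial is scored
by Shannon entropy (log base 10):

    H(x) = −Σᵢ P(xᵢ) · log₁₀ P(xᵢ)

H = 0 for perfectly periodic ("robotic") tapping; the 400-bin maximum,
reached by phase-uniform tapping, is log₁₀(400) = 2.602. Lower entropy =
tighter sensorimotor coupling.

**Beat Alignment Test (BAT) scoring.** Respondents judge whether a beep
track overlaid on music is on or off the beat (standard battery: 5 on-beat,
7 off-beat stimuli). Off-beat is the signal class; sensitivity is
d′ = Φ⁻¹(HR) − Φ⁻¹(FAR), with a log-linear correction so 12-item batteries
with perfect hit rates stay finite.

**Cohort statistics.** UPDRS change scores (post − pre, z-normalized across
completers), paired and Welch t-tests with Cohen's d, one-way ANOVA with
Tukey HSD, Pearson/Spearman correlations, and random-intercept linear
mixed-effects models of log(Entropy) fitted by maximum likelihood and
compared with likelihood-ratio tests (Groove, Group, Time-Point, dance
experience as fixed effects; participant as random intercept).

**Synthetic cohorts.** Because tapping studies rarely publish raw
recordings, `groovetap.synthetic_data` generates complete cohorts with
known ground truth: a phase-coupled tapper model (per-tap Gaussian phase
jitter, period drift, misses, extra taps, registration dropouts), Gaussian
signal-detection BAT responders, and UPDRS trajectories whose improvement
is coupled to baseline tapping entropy. Every encoded effect direction is
recoverable by the pipeline, and a null configuration supports type-I-error
calibration.

## Worked example

```
$ python examples/single_trial_entropy.py
 jitter (frac of period)  n taps  H (log10)
                     0.0      61      0.000
                    0.01      60      1.270
                    0.05      60      1.637
                     0.2      60      1.705
                     0.8      60      1.727
```

A noiseless tapper scores exactly 0; increasing phase jitter drives H up
towards the ceiling for a ~60-event trial (log₁₀ 60 ≈ 1.78). The full
cohort demo (`python examples/cohort_analysis.py`) simulates 552 trials
(30 PD tappers, 20 with follow-up, 19 controls, 8 songs split by groove)
and prints, among other things:

```
likelihood-ratio tests on log(Entropy), random intercept per participant:
  time_point  chi2(1) =  12.07, p = 5.11e-04, coef = +0.018
  groove      chi2(1) =  72.16, p = 1.98e-17, coef = +0.041
  de          chi2(1) =   8.34, p = 3.88e-03, coef = -0.054
baseline entropy vs UPDRS change z (high-groove): r = +0.425, p = 8.53e-05
```

i.e. entropy is lower post-intervention than pre, lower for high-groove
songs than low-groove, lower for dance-experienced participants, and lower
baseline entropy predicts more UPDRS improvement — the four relationships
the generator encodes.

Other examples: `onset_detection.py` (audio → onsets → filtered IOIs) and
`bat_scoring.py` (response tables → d′). A thin CLI mirrors the stages:
`groovetap simulate cohort`, `groovetap onsets`, `groovetap ioi`,
`groovetap entropy`, `groovetap bat`, `groovetap analyze`.

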