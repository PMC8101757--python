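# Methods

## The coupling statistic

A tapping trial is a sequence of onset times for one participant tapping
along to one 30 s music excerpt. The pipeline is:

1. **IOIs.** Differences of consecutive onsets.
2. **Exclusion rules.** The first three IOIs are dropped (task warm-up:
   three IOIs consume the first four taps), then any remaining IOI strictly
   greater than 3 s is dropped (gaps that long reflect a failure of the
   tapping device to register events or a misunderstanding of the task, not
   tempo). The warm-up rule is positional and is applied first; the
   boundary value 3.0 s is kept. The audit counts always reconcile:
   kept + warm-up-dropped + long-dropped = raw.
3. **Phase angles.** Each kept IOI maps to θ = 2π·((IOI mod T)/T) with
   reference period T. By default T is the song's nominal beat period from
   metadata; without metadata it falls back to the trial median of the kept
   IOIs, which is self-contained and robust to dropouts. An alternative
   `onset_phase` mode maps onset times (relative to the first tap) onto the
   beat cycle — the classical sensorimotor-synchronization asynchrony
   phase. Both modes are first-class and every output records which was
   used; the IOI mode is the default because the histogram is built from
   interval durations, making consecutive-tap timing (not absolute drift)
   the object of analysis.
4. **Polar histogram.** 400 equal half-open bins over [0, 2π); bin i covers
   [2πi/400, 2π(i+1)/400). Bin count is configurable; 400 is the default
   everywhere and all bounds are recomputed from it, never hard-coded.
5. **Shannon entropy.** H = −Σ P·log₁₀P over occupied bins, with
   0·log 0 := 0. Log base 10 is forced by the statistic's published ceiling
   at 400 bins, 2.602 = log₁₀ 400. H ∈ [0, log₁₀ n_bins] is asserted on
   every evaluation.

Two numerical choices deserve note. First, with noiseless periodic input,
IOI mod T sits an ulp below T for some tempos, which would split all mass
across the 0/2π seam; phase fractions are therefore rounded at 10⁻¹² of a
cycle before binning, which affects representation-level error only.
Second, downstream mixed models use log(Entropy) (natural log); H = 0
trials would give −∞, so H is floored at 10⁻⁶ before logging and such
trials carry a `floored` flag. Real tapping never reaches the floor; only
synthetic robotic tappers do.

An important property of the statistic: a trial with n events can occupy at
most n bins, so its entropy ceiling is log₁₀ n (≈ 1.78 for a 60-tap trial),
well below the 400-bin bound. H saturates quickly as phase noise grows —
the statistic is most sensitive in the tight-coupling regime.

## Onset detection

The upstream device registers discrete pad hits, so detection from audio is
deliberately simple: the absolute amplitude is smoothed with a 5 ms moving
average, the stationary noise floor (median of the envelope) is subtracted,
and an onset is the first sample of each excursion above 20% of the trial's
peak envelope, with a 100 ms refractory period suppressing ringing from the
same physical tap. All three parameters are exposed in `OnsetConfig`. On
rendered click tracks at 20 dB SNR the detector recovers ≥ 99% of generated
onsets within one smoothing window (property-tested).

## BAT scoring

"Off the beat" is the signal class: HR is the proportion of off-beat
stimuli called "off", FAR the proportion of on-beat stimuli called "off",
and d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) — the inverse-normal reading of "z-scores" of
the rates, which is the standard signal-detection sensitivity and the only
reading under which the statistic measures sensitivity at all. Because a
12-item battery frequently produces HR = 1 or FAR = 0, the default is the
log-linear correction, (hits+0.5)/(n+1); the uncorrected route is available
and raises on extreme rates rather than returning ±∞. Confidence ratings
are carried through but not modelled.

## Cohort statistics

* **Change scores**: post − pre UPDRS totals over completers (negative =
  improvement), z-normalized across completers (mean 0, sd 1 by
  construction). Non-completers are excluded and counted — complete-case
  analysis, mirroring loss to follow-up in longitudinal cohorts.
* **t-tests**: paired t with Cohen's d on change scores; independent
  comparisons default to Welch with Satterthwaite fractional df (reduces to
  pooled 2n−2 under equal variance and n). A summary-statistic Welch
  variant supports comparisons against printed group means/SDs.
* **ANOVA/Tukey**: standard decompositions via scipy/statsmodels;
  Tukey intervals come from the studentized-range distribution.
* **Mixed models**: random-intercept LMEs via statsmodels `MixedLM`,
  always fitted by maximum likelihood (never REML) so nested fits are
  LRT-comparable. The LRT statistic is 2·Δlog-likelihood on the difference
  in fixed-effect parameter count; negativity beyond 10⁻⁸ (non-nested or
  unconverged input) raises. Singular fixed-effect designs are rejected
  naming the aliased columns. Kenward–Roger/Satterthwaite F-tests for
  mixed models are not implemented; the LRT is the model-comparison route.

Under the null cohort configuration the Groove LRT's empirical size at
α = 0.05 is ≈ 0.04 over 1000 scaled-down replicates (12 participants × 8
trials), i.e. the χ²(1) reference is adequately calibrated at this scale.

## The synthetic cohort

`simulate_tapper` is a phase-coupled jitter/drift process: nominal beats at
multiples of the period (with a small random walk on the period and a
−20 ms mean anticipatory asynchrony, the human norm), per-tap Gaussian
phase noise, Bernoulli misses, uniform extra taps, and an occasional
3.2–5 s blanked window emulating the registration dropouts that motivate
the > 3 s IOI rule. A two-level timekeeper/motor-delay model was
deliberately not used: the single jitter parameter maps one-to-one onto
every contrast the analysis tests, and spans the full entropy range.

`simulate_cohort` reproduces the study design shape: 30 PD participants
(20 completing follow-up), 19 controls, 8 songs per session split 4
high-/4 low-groove — 552 trials. The two groove sets share the same tempo
distribution so event counts are balanced across groove and any recovered
groove effect comes from the encoded coupling gain, not trial length.
Effects are multiplicative on phase jitter:

| parameter | default | meaning |
|---|---|---|
| `base_jitter_median` | 0.025 of period | PD baseline phase jitter (≈ 12 ms at 0.5 s period), placing trials on the steep part of the entropy–noise curve |
| `jitter_lognorm_sd` | 0.35 | between-participant spread (log scale) |
| `control_jitter_gain` | 0.75 | controls couple more tightly than PD |
| `groove_coupling_gain` | 0.80 | high-groove songs couple more tightly |
| `de_jitter_advantage` | 0.60 | dance experience tightens coupling |
| `intervention_jitter_reduction` | 0.85 | pre → post tightening |
| `updrs_change_entropy_slope` | 60 pts per log-entropy unit | UPDRS change rises with baseline log-entropy (the cohort spans ≈ 0.25 units, so ≈ ±7 points across its range) |

UPDRS totals are drawn around 29.9 ± 15.4 and decomposed into the four
sections (maxima 16/52/108/23) in fixed proportions typical of a PD
profile, with integer rounding kept within section ranges and sections
always summing to the total. The UPDRS change of each completer is tied to
their *realized* baseline tapping entropy (computed by the package's own
entropy pipeline inside the generator), so the encoded tapping–clinical
association is exactly the quantity the analysis later estimates. BAT
sensitivities are drawn per group (PD 1.70 ± 0.96, control 2.29 ± 0.80)
and responses generated from the equal-variance Gaussian model.
`CohortParams.null()` switches every multiplier to 1 and the slope to 0.

What the generator does **not** emulate: real music (groove is a label, as
in the analysis), tempo changes within songs, serial correlation of tap
errors (e.g. lag-1 negative correlation of a two-level timing model),
learning within a trial, enjoyment/familiarity effects, or non-normal
UPDRS measurement error. Passing tests therefore demonstrate that the
pipeline recovers structure of this idealized form at realistic sizes and
noise levels — not that any particular clinical dataset would show these
effects.

## Problem sizes in the test suite

The suite favours the smallest sizes at which each property is
informative: calibration uses 1000 replicates of a 12-participant null
cohort; variance-component recovery averages 10 replicate fits of 50 × 16
observations (a single fit estimates a variance with ≈ 20% sampling error,
so replicate averaging tests the estimator, not one draw); monotonicity
uses 5 jitter levels × 200 trials; d′ recovery uses 10⁴ batteries;
end-to-end direction recovery uses 20 full-size (552-trial) cohorts.

## Known limitations

* The IOI-phase construction is one of two defensible phase definitions;
  per-trial entropy values are not comparable across modes, and neither
  mode is claimed to reproduce any particular published per-trial value.
* Entropy depends on event count through its log₁₀ n ceiling; comparisons
  across trials of very different lengths should use the metadata
  reference period and equal trial durations, as the cohort design does.
* The LRT relies on χ² asymptotics; with very few participants it can be
  mildly conservative (empirically so at 16 participants here).
* `read_audio` accepts PCM WAV only; compressed audio is out of scope.
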