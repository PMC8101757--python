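"""Synthetic tapping trials, BAT respondents and whole cohorts.

No participant recordings accompany the study design this package
implements, so every stage is exercised against generated data with known
ground truth.  The tapper is a phase-coupled jitter/drift process: nominal
beats at multiples of the beat period (plus a mean anticipatory
asynchrony), per-tap Gaussian phase noise, a random walk on the period,
Bernoulli missed taps, uniformly placed extra taps, and an occasional long
pause emulating a failure of the tapping device to register events.  This
is deliberately simpler than a two-level timekeeper/motor model; its
parameters map one-to-one onto the contrasts the analysis tests.

The cohort generator encodes the effect structure the analysis is designed
to detect, each as a multiplicative change in phase jitter:

* high-groove songs couple more tightly than low-groove songs
  (``groove_coupling_gain`` < 1),
* dance-experienced tappers couple more tightly (``de_jitter_advantage``),
* coupling tightens from pre- to post-intervention
  (``intervention_jitter_reduction``),
* UPDRS improvement increases with tighter baseline coupling
  (``updrs_change_entropy_slope`` > 0: UPDRS change, negative =
  improvement, rises with baseline log-entropy).

Setting all multipliers to 1 and the slope to 0 yields a null cohort for
type-I-error calibration.  Default cohort shape follows the study design:
30 PD participants (20 completing follow-up) and 19 controls, each tapping
to 8 songs (4 high-, 4 low-groove), giving 30*8 + 20*8 + 19*8 = 552 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from groovetap.io_formats import (
    AudioTrack,
    BATResponseTable,
    TapTrial,
    UPDRSRecord,
    UPDRS_SECTION_MAX,
    write_bat,
    write_tap_events,
    write_updrs,
)
from groovetap import entropy as _entropy


@dataclass(frozen=True)
class TapperParams:
    """One simulated tapping trial.

    phase_jitter_sd and period_drift_sd are fractions of the beat period;
    anticipation is the mean tap-before-beat asynchrony in seconds
    (negative mean asynchrony is the human norm, so the default is
    slightly negative).
    """

    beat_period: float = 0.5
    phase_jitter_sd: float = 0.05
    period_drift_sd: float = 0.0
    miss_prob: float = 0.0
    extra_prob: float = 0.0
    anticipation: float = -0.02
    trial_duration: float = 30.0
    pause_prob: float = 0.0  # chance of one long (>3 s) registration dropout
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.beat_period <= 0:
            raise ValueError("beat_period must be positive")
        for name in ("miss_prob", "extra_prob", "pause_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.phase_jitter_sd < 0 or self.period_drift_sd < 0:
            raise ValueError("jitter and drift must be non-negative")
        expected = (1 - self.miss_prob) * self.trial_duration / self.beat_period
        if expected < 1:
            raise ValueError(
                f"parameters yield {expected:.2f} expected taps (need >= 1)"
            )


def simulate_tapper(
    params: TapperParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Generate ground-truth onset times (seconds) for one trial."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    T = params.beat_period
    # random walk on the period, then cumulative beat times
    n_beats = int(np.ceil(params.trial_duration / T)) + 2
    periods = T * (1 + np.cumsum(rng.normal(0, params.period_drift_sd, n_beats)))
    periods = np.clip(periods, 0.2 * T, 5 * T)
    beats = np.concatenate(([0.0], np.cumsum(periods)))
    taps = beats + params.anticipation + rng.normal(0, params.phase_jitter_sd * T, len(beats))
    keep = rng.random(len(taps)) >= params.miss_prob
    taps = taps[keep]
    n_extra = rng.binomial(len(beats), params.extra_prob)
    if n_extra:
        taps = np.concatenate([taps, rng.uniform(0, params.trial_duration, n_extra)])
    taps = np.sort(taps)
    taps = taps[(taps >= 0) & (taps <= params.trial_duration)]
    if params.pause_prob and rng.random() < params.pause_prob:
        # emulate a registration dropout: blank out a 3.2-5 s window
        start = rng.uniform(3.0, max(3.1, params.trial_duration - 6))
        width = rng.uniform(3.2, 5.0)
        taps = taps[(taps < start) | (taps >= start + width)]
    # enforce strict monotonicity (collapse coincident taps)
    if taps.size > 1:
        taps = taps[np.concatenate(([True], np.diff(taps) > 1e-4))]
    return taps


def render_audio(
    onsets: Sequence[float],
    duration: float,
    sample_rate: int = 8000,
    click_duration: float = 0.005,
    click_amplitude: float = 0.9,
    snr_db: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> AudioTrack:
    """Render onsets as raised-cosine clicks on silence (optionally noisy).

    ``snr_db`` adds white Gaussian noise at the given peak-signal-to-noise
    ratio; None keeps the track noiseless.
    """
    n = int(round(duration * sample_rate))
    samples = np.zeros(n)
    click_n = max(2, int(round(click_duration * sample_rate)))
    click = click_amplitude * 0.5 * (1 - np.cos(2 * np.pi * np.arange(click_n) / click_n))
    for t in onsets:
        i = int(round(t * sample_rate))
        j = min(i + click_n, n)
        if i < n:
            samples[i:j] += click[: j - i]
    if snr_db is not None:
        rng = rng if rng is not None else np.random.default_rng()
        noise_sd = click_amplitude * 10 ** (-snr_db / 20)
        samples = samples + rng.normal(0, noise_sd, n)
    return AudioTrack(samples=np.clip(samples, -1, 1), sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# BAT respondents

def simulate_bat_respondent(
    sensitivity: float,
    criterion: float = 0.0,
    n_on: int = 5,
    n_off: int = 7,
    n_batteries: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    respondent_id: str = "sim",
) -> BATResponseTable:
    """Equal-variance Gaussian signal-detection responder.

    Off-beat (signal) stimuli draw evidence from N(sensitivity, 1), on-beat
    from N(0, 1); the response is "off" when evidence exceeds the decision
    criterion placed at sensitivity/2 + criterion (criterion 0 = unbiased).
    Each battery presents 5 on-beat and 7 off-beat stimuli; ``n_batteries``
    repeats support large-sample recovery checks.  Confidence is a 1-3
    rating increasing with distance from the criterion.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    truth = np.tile(["on"] * n_on + ["off"] * n_off, n_batteries)
    evidence = np.where(
        truth == "off",
        rng.normal(sensitivity, 1, truth.size),
        rng.normal(0, 1, truth.size),
    )
    c = sensitivity / 2 + criterion
    response = np.where(evidence > c, "off", "on")
    conf = np.minimum(3, 1 + np.floor(np.abs(evidence - c)).astype(int))
    rows = pd.DataFrame(
        {
            "stimulus_id": [f"s{i:05d}" for i in range(truth.size)],
            "truth": truth,
            "response": response,
            "confidence": conf,
        }
    )
    return BATResponseTable(respondent_id=respondent_id, rows=rows)


# ---------------------------------------------------------------------------
# cohorts

#: 8 tapping songs: 4 high-groove, 4 low-groove, with nominal beat periods
#: (seconds) spanning typical popular-song tempi (~100-125 BPM).  The two
#: groove sets share the same tempo distribution so that trial length and
#: event count are balanced across groove: any groove difference the
#: analysis finds comes from the encoded coupling gain, not from tempo.
DEFAULT_SONGS = (
    ("song_h1", "high", 0.48),
    ("song_h2", "high", 0.52),
    ("song_h3", "high", 0.56),
    ("song_h4", "high", 0.60),
    ("song_l1", "low", 0.48),
    ("song_l2", "low", 0.52),
    ("song_l3", "low", 0.56),
    ("song_l4", "low", 0.60),
)

#: UPDRS section shares of the total score, matching the typical PD profile
#: (Activities of Daily Life and Motor Examination dominate).
UPDRS_SECTION_PROPS = (2.80 / 29.9, 12.2 / 29.9, 11.1 / 29.9, 3.80 / 29.9)


@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters for a full synthetic cohort."""

    n_pd: int = 30
    n_control: int = 19
    n_completers: int = 20  # PD participants with post-intervention data
    p_dance_experience: float = 0.65
    p_music_experience: float = 0.60
    # tapping coupling structure (multipliers apply to phase jitter)
    base_jitter_median: float = 0.025  # PD baseline jitter, fraction of period
    jitter_lognorm_sd: float = 0.35  # between-participant spread (log scale)
    control_jitter_gain: float = 0.75  # controls couple more tightly than PD
    groove_coupling_gain: float = 0.80
    de_jitter_advantage: float = 0.60
    intervention_jitter_reduction: float = 0.85
    trial_jitter_sd: float = 0.10  # within-participant trial-to-trial (log scale)
    miss_prob: float = 0.05
    extra_prob: float = 0.02
    pause_prob: float = 0.10
    # UPDRS structure
    updrs_pre_mean: float = 29.9
    updrs_pre_sd: float = 15.4
    updrs_change_mean: float = -8.7  # mean improvement over the intervention
    # UPDRS-change points per unit of baseline participant-mean log-entropy;
    # the default cohort spans ~0.25 such units, so this contributes ~+-7
    # points across the cohort range, comparable to the change-noise SD.
    updrs_change_entropy_slope: float = 60.0
    updrs_change_noise_sd: float = 5.0
    # BAT structure
    bat_dprime_pd_mean: float = 1.70
    bat_dprime_pd_sd: float = 0.96
    bat_dprime_control_mean: float = 2.29
    bat_dprime_control_sd: float = 0.80
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "groove_coupling_gain", "de_jitter_advantage",
            "intervention_jitter_reduction", "control_jitter_gain",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_pd < 1 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 1 PD")
        if not 0 <= self.n_completers <= self.n_pd:
            raise ValueError("n_completers must be between 0 and n_pd")

    def null(self) -> "CohortParams":
        """The no-effect configuration (all multipliers 1, slope 0)."""
        return replace(
            self,
            groove_coupling_gain=1.0,
            de_jitter_advantage=1.0,
            intervention_jitter_reduction=1.0,
            control_jitter_gain=1.0,
            updrs_change_entropy_slope=0.0,
        )


@dataclass
class CohortBundle:
    """Everything simulate_cohort produces, ready for the pipeline or disk."""

    tap_trials: list[TapTrial]
    updrs: list[UPDRSRecord]
    bat: list[BATResponseTable]
    participants: pd.DataFrame  # participant_id, group, de, me, years_de, years_me
    songs: pd.DataFrame  # song_id, groove, beat_period_s

    @property
    def reference_periods(self) -> dict[str, float]:
        return dict(zip(self.songs["song_id"], self.songs["beat_period_s"]))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tap_events": out / "tap_events.csv",
            "updrs": out / "updrs.csv",
            "bat": out / "bat_responses.csv",
            "participants": out / "participants.csv",
            "songs": out / "songs.csv",
        }
        write_tap_events(paths["tap_events"], self.tap_trials)
        write_updrs(paths["updrs"], self.updrs)
        write_bat(paths["bat"], self.bat)
        self.participants.to_csv(paths["participants"], index=False)
        self.songs.to_csv(paths["songs"], index=False)
        return paths


def _decompose_updrs_total(total: int) -> tuple[int, int, int, int]:
    """Split a total into four section scores within their printed ranges."""
    maxima = list(UPDRS_SECTION_MAX.values())
    raw = [p * total for p in UPDRS_SECTION_PROPS]
    sections = [min(int(round(v)), m) for v, m in zip(raw, maxima)]
    # distribute the rounding remainder, respecting section maxima
    remainder = total - sum(sections)
    order = [2, 1, 3, 0]  # prefer motor & ADL sections for the slack
    while remainder != 0:
        moved = False
        for i in order:
            if remainder > 0 and sections[i] < maxima[i]:
                sections[i] += 1
                remainder -= 1
                moved = True
            elif remainder < 0 and sections[i] > 0:
                sections[i] -= 1
                remainder += 1
                moved = True
            if remainder == 0:
                break
        if not moved:
            raise ValueError(f"cannot decompose total {total}")
    return tuple(sections)


def simulate_cohort(params: CohortParams | None = None,
                    seed: Optional[int] = None) -> CohortBundle:
    """Generate a full cohort bundle under the given study conditions.

    ``seed`` overrides ``params.seed``; identical seeds give identical
    bundles.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed if seed is not None else params.seed)

    songs = pd.DataFrame(DEFAULT_SONGS, columns=["song_id", "groove", "beat_period_s"])

    # -- participants -------------------------------------------------------
    rows = []
    pids_pd = [f"pd{i:02d}" for i in range(1, params.n_pd + 1)]
    pids_ctl = [f"ct{i:02d}" for i in range(1, params.n_control + 1)]
    for pid, group in [(p, "pd") for p in pids_pd] + [(p, "control") for p in pids_ctl]:
        de = bool(rng.random() < params.p_dance_experience)
        me = bool(rng.random() < params.p_music_experience)
        years_de = float(np.round(max(1.0, rng.gamma(2.0, 5.0)), 1)) if de else 0.0
        years_me = float(np.round(max(1.0, rng.gamma(2.0, 10.0)), 1)) if me else 0.0
        rows.append({"participant_id": pid, "group": group, "de": de, "me": me,
                     "years_de": years_de, "years_me": years_me})
    participants = pd.DataFrame(rows)
    completers = set(pids_pd[: params.n_completers])
    participants["completer"] = [
        (pid in completers) if grp == "pd" else False
        for pid, grp in zip(participants["participant_id"], participants["group"])
    ]

    # -- tapping trials -----------------------------------------------------
    tap_trials: list[TapTrial] = []
    base_jitter = {}
    for _, person in participants.iterrows():
        pid = person["participant_id"]
        jit = params.base_jitter_median * np.exp(rng.normal(0, params.jitter_lognorm_sd))
        if person["group"] == "control":
            jit *= params.control_jitter_gain
        if person["de"]:
            jit *= params.de_jitter_advantage
        base_jitter[pid] = jit
        time_points = ["pre"]
        if person["group"] == "pd" and person["completer"]:
            time_points.append("post")
        for tp in time_points:
            for _, song in songs.iterrows():
                trial_jit = jit * np.exp(rng.normal(0, params.trial_jitter_sd))
                if song["groove"] == "high":
                    trial_jit *= params.groove_coupling_gain
                if tp == "post":
                    trial_jit *= params.intervention_jitter_reduction
                onsets = simulate_tapper(
                    TapperParams(
                        beat_period=float(song["beat_period_s"]),
                        phase_jitter_sd=trial_jit,
                        period_drift_sd=0.002,
                        miss_prob=params.miss_prob,
                        extra_prob=params.extra_prob,
                        pause_prob=params.pause_prob,
                    ),
                    rng=rng,
                )
                tap_trials.append(
                    TapTrial(
                        participant_id=pid,
                        song_id=str(song["song_id"]),
                        groove=str(song["groove"]),
                        time_point=tp,
                        onsets=onsets,
                        source="provided",
                    )
                )

    # -- UPDRS --------------------------------------------------------------
    # Baseline totals for all PD participants; change scores for completers
    # are tied to realized baseline tapping entropy through the slope.
    ref_periods = dict(zip(songs["song_id"], songs["beat_period_s"]))
    pre_pd = [t for t in tap_trials
              if t.time_point == "pre" and t.participant_id in set(pids_pd)]
    ent = _entropy.entropy_table(pre_pd, reference_periods=ref_periods)
    mean_logH = ent.groupby("participant_id")["log_H"].mean()

    updrs: list[UPDRSRecord] = []
    for pid in pids_pd:
        pre_total = int(np.clip(round(rng.normal(params.updrs_pre_mean,
                                                 params.updrs_pre_sd)), 6, 150))
        s = _decompose_updrs_total(pre_total)
        updrs.append(UPDRSRecord(pid, "pre", *s))
        if pid in completers:
            logh = mean_logH.get(pid, float(mean_logH.mean()))
            delta = (
                params.updrs_change_mean
                + params.updrs_change_entropy_slope * (logh - float(mean_logH.mean()))
                + rng.normal(0, params.updrs_change_noise_sd)
            )
            post_total = int(np.clip(round(pre_total + delta), 0, 199))
            updrs.append(UPDRSRecord(pid, "post", *_decompose_updrs_total(post_total)))

    # -- BAT ----------------------------------------------------------------
    bat: list[BATResponseTable] = []
    for _, person in participants.iterrows():
        if person["group"] == "pd":
            sens = rng.normal(params.bat_dprime_pd_mean, params.bat_dprime_pd_sd)
        else:
            sens = rng.normal(params.bat_dprime_control_mean, params.bat_dprime_control_sd)
        bat.append(
            simulate_bat_respondent(
                sensitivity=max(0.0, sens),
                rng=rng,
                respondent_id=str(person["participant_id"]),
            )
        )

    return CohortBundle(
        tap_trials=tap_trials,
        updrs=updrs,
        bat=bat,
        participants=participants,
        songs=songs,
    )
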