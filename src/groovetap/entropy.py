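"""Phase angles, 400-bin polar histograms, and the Shannon-entropy statistic.

The coupling statistic for one tapping trial is the Shannon entropy (log
base 10) of the distribution of tap phases around the beat cycle, binned
into a 400-bin circular histogram:

    H(x) = -sum_i P(x_i) * log10 P(x_i)

with 0 * log 0 := 0.  A perfectly periodic tapper puts all mass in one bin
and scores H = 0; a tapper whose phases are uniform on the cycle approaches
the maximum H = log10(400) = 2.602 (3 d.p.).  Lower entropy means tighter
sensorimotor coupling.

Two phase constructions are offered.  ``ioi_phase`` (default) maps each
kept inter-onset interval to the angle 2*pi*((IOI mod T)/T) for a reference
period T; ``onset_phase`` maps each onset time (relative to the first) to
its position in the beat cycle, the standard sensorimotor-synchronization
asynchrony phase.  The reference period is the song's nominal beat period
when supplied, otherwise the trial median of the kept IOIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from groovetap.io_formats import TapTrial
from groovetap.onset_ioi import IOISeries, N_WARMUP_IOIS, compute_iois, filter_iois

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 400
#: Floor applied to H before taking log(Entropy) for downstream models, so
#: perfectly periodic (H = 0) trials stay finite; floored trials are flagged.
LOG_ENTROPY_FLOOR = 1e-6

PHASE_MODES = ("ioi_phase", "onset_phase")


@dataclass(frozen=True)
class PhaseAngleSeries:
    """Tap phases in radians on [0, 2*pi), with their reference period."""

    angles: np.ndarray
    reference_period: float
    mode: str

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if self.reference_period <= 0:
            raise ValueError("reference_period must be positive")
        if self.mode not in PHASE_MODES:
            raise ValueError(f"mode must be one of {PHASE_MODES}")
        if angles.size and (angles.min() < 0 or angles.max() >= 2 * np.pi):
            raise ValueError("angles must lie in [0, 2*pi)")


@dataclass(frozen=True)
class PhaseHistogram:
    """Equal-width circular histogram; bin i covers [2*pi*i/n, 2*pi*(i+1)/n)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or len(counts) < 2:
            raise ValueError("histogram needs at least 2 bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram has no probabilities")
        return self.counts / total

    @classmethod
    def from_probabilities(cls, probs: Iterable[float], n_events: int = 1) -> "PhaseHistogram":
        """Build a histogram carrying fractional mass directly (for analytic
        cases such as the uniform maximum-entropy reference)."""
        probs = np.asarray(list(probs), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")
        return cls(counts=probs * n_events)


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of one trial, in log10 units, with its bounds."""

    H: float
    n_events: int
    n_bins: int

    @property
    def bounds(self) -> tuple[float, float]:
        return (0.0, float(np.log10(self.n_bins)))

    @property
    def log_H(self) -> float:
        """Natural log of H with a 1e-6 floor (finite for robotic tapping)."""
        return float(np.log(max(self.H, LOG_ENTROPY_FLOOR)))

    @property
    def floored(self) -> bool:
        return self.H < LOG_ENTROPY_FLOOR


def phase_angles(
    data: IOISeries | TapTrial | np.ndarray,
    reference_period: Optional[float] = None,
    mode: str = "ioi_phase",
) -> PhaseAngleSeries:
    """Map a trial's kept IOIs (or its onsets) to phases on the beat cycle.

    With ``mode='ioi_phase'`` each kept IOI maps to 2*pi*((IOI mod T)/T).
    With ``mode='onset_phase'`` each onset after warm-up maps to
    2*pi*(((t - t0) mod T)/T).  If ``reference_period`` is None the trial
    median of the kept IOIs is used.
    """
    if mode not in PHASE_MODES:
        raise ValueError(f"mode must be one of {PHASE_MODES}")

    if isinstance(data, IOISeries):
        iois = data.kept_iois
        onsets = None
    elif isinstance(data, TapTrial):
        series = filter_iois(compute_iois(data.onsets))
        iois = series.kept_iois
        onsets = data.onsets
    else:
        iois = np.asarray(data, dtype=float)
        onsets = None

    if reference_period is None:
        if iois.size == 0:
            raise ValueError("cannot infer reference period from an empty trial")
        reference_period = float(np.median(iois))
    if reference_period <= 0:
        raise ValueError("reference_period must be positive")

    if mode == "ioi_phase":
        frac = np.mod(iois, reference_period) / reference_period
    else:
        if onsets is None:
            raise ValueError("onset_phase mode requires a TapTrial with onsets")
        # skip the onsets consumed by the warm-up IOIs (3 IOIs = 4 onsets)
        post_warmup = onsets[min(N_WARMUP_IOIS + 1, len(onsets)):] if len(onsets) else onsets
        if post_warmup.size == 0:
            frac = np.empty(0)
        else:
            frac = np.mod(post_warmup - onsets[0], reference_period) / reference_period
    # Values an ulp short of a full period would otherwise land just below
    # 2*pi and split a noiseless periodic trial across the circular seam:
    # snap representation-level error (<= 1e-12 of a cycle) to the bin edge.
    frac = np.round(frac, 12) % 1.0
    angles = 2 * np.pi * frac
    angles = np.where(angles >= 2 * np.pi, 0.0, angles)
    return PhaseAngleSeries(angles=angles, reference_period=reference_period, mode=mode)


def polar_histogram(series: PhaseAngleSeries, n_bins: int = DEFAULT_N_BINS) -> PhaseHistogram:
    """Bin phases into ``n_bins`` equal half-open bins over [0, 2*pi)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if series.angles.size == 0:
        raise ValueError("histogram undefined for zero angles")
    idx = np.floor(series.angles / (2 * np.pi) * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # roundoff guard at the upper edge
    counts = np.bincount(idx, minlength=n_bins)
    return PhaseHistogram(counts=counts)


def shannon_entropy(hist: PhaseHistogram) -> EntropyResult:
    """H = -sum over occupied bins of P * log10 P, with 0*log0 := 0.

    The result always lies in [0, log10(n_bins)].
    """
    probs = hist.probabilities
    occupied = probs[probs > 0]
    H = float(-np.sum(occupied * np.log10(occupied)))
    H = max(0.0, H)  # clip -0.0 and roundoff below zero
    upper = np.log10(hist.n_bins)
    if H > upper + 1e-9:
        raise AssertionError(f"entropy {H} exceeds log10({hist.n_bins})")
    return EntropyResult(H=min(H, upper), n_events=hist.total, n_bins=hist.n_bins)


def trial_entropy(
    trial: TapTrial,
    reference_period: Optional[float] = None,
    n_bins: int = DEFAULT_N_BINS,
    mode: str = "ioi_phase",
) -> Optional[EntropyResult]:
    """Full per-trial pipeline: IOIs -> filtering -> phases -> histogram -> H.

    Returns None (with a logged reason) when the trial retains no IOIs after
    filtering, so degenerate trials can be excluded from downstream tables.
    """
    series = filter_iois(compute_iois(trial.onsets),
                         trial_ref=f"{trial.participant_id}/{trial.song_id}/{trial.time_point}")
    if series.kept_iois.size == 0:
        logger.info(
            "trial (%s, %s, %s): no IOIs kept after filtering "
            "(%d raw, %d warm-up, %d long) - entropy undefined",
            trial.participant_id, trial.song_id, trial.time_point,
            len(series.raw_iois), series.n_dropped_warmup, series.n_dropped_long,
        )
        return None
    source = trial if mode == "onset_phase" else series
    angles = phase_angles(source, reference_period=reference_period, mode=mode)
    hist = polar_histogram(angles, n_bins=n_bins)
    return shannon_entropy(hist)


def entropy_table(
    trials: Iterable[TapTrial],
    reference_periods: Optional[dict[str, float]] = None,
    n_bins: int = DEFAULT_N_BINS,
    mode: str = "ioi_phase",
) -> pd.DataFrame:
    """Per-trial entropy table for a collection of trials.

    ``reference_periods`` maps song_id to a nominal beat period in seconds;
    songs not listed fall back to the trial-median IOI.  Trials with no kept
    IOIs are excluded (counted in the log).  Columns: participant_id,
    song_id, groove, time_point, n_events, H, log_H, floored, mode.
    """
    reference_periods = reference_periods or {}
    rows = []
    n_excluded = 0
    for trial in trials:
        result = trial_entropy(
            trial,
            reference_period=reference_periods.get(trial.song_id),
            n_bins=n_bins,
            mode=mode,
        )
        if result is None:
            n_excluded += 1
            continue
        rows.append(
            {
                "participant_id": trial.participant_id,
                "song_id": trial.song_id,
                "groove": trial.groove,
                "time_point": trial.time_point,
                "n_events": result.n_events,
                "H": result.H,
                "log_H": result.log_H,
                "floored": result.floored,
                "mode": mode,
            }
        )
    if n_excluded:
        logger.info("%d trials excluded: no IOIs kept after filtering", n_excluded)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "song_id", "groove", "time_point",
                 "n_events", "H", "log_H", "floored", "mode"],
    )
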