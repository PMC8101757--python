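"""Tap-onset detection from audio, inter-onset intervals, and exclusion rules.

Onset detection is a smoothed-envelope threshold crossing with a refractory
period: tap transients are impulsive, so an onset is taken as the first
sample of a supra-threshold excursion of the smoothed absolute amplitude,
and any further crossing within the refractory window is treated as ringing
from the same physical tap.

Two exclusion rules are applied to each trial's IOI sequence:
the first three IOIs are dropped as task warm-up, and any remaining IOI
strictly greater than 3 seconds is dropped (such gaps reflect missed device
registrations or task misunderstanding, not tapping tempo).  The warm-up
drop is positional and is applied first; the boundary value of exactly
3.0 s is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from groovetap.io_formats import AudioTrack

logger = logging.getLogger(__name__)

#: Maximum credible inter-tap gap; longer gaps are treated as dropouts.
LONG_IOI_CUTOFF_S = 3.0
#: Number of leading IOIs discarded while the tapper settles into the task.
N_WARMUP_IOIS = 3


@dataclass(frozen=True)
class OnsetConfig:
    """Detection parameters.

    amplitude_threshold is a fraction of the trial's peak smoothed envelope;
    refractory is the minimum spacing between detected onsets in seconds;
    smoothing_window is the moving-average width applied to the absolute
    amplitude before thresholding.
    """

    amplitude_threshold: float = 0.2
    refractory: float = 0.100
    smoothing_window: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_threshold < 1:
            raise ValueError("amplitude_threshold must be in (0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")
        if self.smoothing_window <= 0:
            raise ValueError("smoothing_window must be positive")


@dataclass(frozen=True)
class IOISeries:
    """Raw and filtered IOIs for one trial, with an audit of what was dropped."""

    trial_ref: str
    raw_iois: np.ndarray
    kept_iois: np.ndarray
    n_dropped_warmup: int
    n_dropped_long: int

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_iois, dtype=float)
        kept = np.asarray(self.kept_iois, dtype=float)
        object.__setattr__(self, "raw_iois", raw)
        object.__setattr__(self, "kept_iois", kept)
        if len(kept) + self.n_dropped_warmup + self.n_dropped_long != len(raw):
            raise ValueError("IOI accounting does not reconcile")
        if kept.size and (np.any(kept <= 0) or np.any(kept > LONG_IOI_CUTOFF_S)):
            raise ValueError("kept IOIs must be in (0, 3.0] s")


def detect_onsets(track: AudioTrack, cfg: OnsetConfig | None = None) -> np.ndarray:
    """Detect tap onsets in a mono track.

    Returns onset times in seconds, strictly increasing, separated by at
    least ``cfg.refractory``.  An all-silent track yields an empty array.
    """
    cfg = cfg or OnsetConfig()
    win = max(1, int(round(cfg.smoothing_window * track.sample_rate)))
    env = np.convolve(np.abs(track.samples), np.ones(win) / win, mode="same")
    # subtract the stationary noise floor so the threshold tracks the tap
    # transients, not the recording's background level
    env = np.maximum(env - np.median(env), 0.0)
    peak = env.max()
    if peak <= 0:
        logger.info("all-silent track: no onsets")
        return np.empty(0)
    above = env >= cfg.amplitude_threshold * peak
    # first samples of supra-threshold excursions
    starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    refractory_n = cfg.refractory * track.sample_rate
    onsets = []
    last = -np.inf
    for s in starts:
        if s - last >= refractory_n:
            onsets.append(s)
            last = s
    return np.asarray(onsets, dtype=float) / track.sample_rate


def compute_iois(onsets: np.ndarray) -> np.ndarray:
    """Differences of consecutive onsets; empty for fewer than 2 onsets."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        return np.empty(0)
    iois = np.diff(onsets)
    if np.any(iois <= 0):
        raise ValueError("onsets must be strictly increasing")
    return iois


def filter_iois(raw: np.ndarray, trial_ref: str = "") -> IOISeries:
    """Apply the warm-up and long-gap exclusion rules to a raw IOI sequence.

    The first ``min(3, len(raw))`` entries are dropped as warm-up; of the
    remainder, entries strictly greater than 3.0 s are dropped.  Order of the
    kept values is preserved and the counts always reconcile:
    ``len(kept) + n_dropped_warmup + n_dropped_long == len(raw)``.
    """
    raw = np.asarray(raw, dtype=float)
    n_warm = min(N_WARMUP_IOIS, len(raw))
    after_warmup = raw[n_warm:]
    long_mask = after_warmup > LONG_IOI_CUTOFF_S
    kept = after_warmup[~long_mask]
    return IOISeries(
        trial_ref=trial_ref,
        raw_iois=raw,
        kept_iois=kept,
        n_dropped_warmup=n_warm,
        n_dropped_long=int(long_mask.sum()),
    )
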