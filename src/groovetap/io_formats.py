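"""Readers, writers and validated domain types for all external formats.

Interchange formats are deliberately plain: PCM WAV for audio, UTF-8 CSV
with a header row for tap events, BAT responses and UPDRS records, JSON for
result bundles.  Times are seconds as decimal numbers; columns snake_case.
Every reader validates into a domain type and rejects out-of-enumeration
values rather than coercing them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

GROOVE_LEVELS = ("high", "low")
TIME_POINTS = ("pre", "post")
BAT_LABELS = ("on", "off")

#: UPDRS section maxima: I Mentation/Behavior/Mood, II Activities of Daily
#: Life, III Motor Examination, IV Complications of Therapy.  Total 0-199.
UPDRS_SECTION_MAX = {"section_1": 16, "section_2": 52, "section_3": 108, "section_4": 23}


class FormatError(ValueError):
    """File could not be parsed in the expected format."""


class SchemaError(ValueError):
    """Tabular file is missing required columns."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class AudioTrack:
    """Mono audio, samples scaled to [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValidationError("AudioTrack is mono: samples must be 1-D")
        if len(self.samples) == 0:
            raise ValidationError("zero-length audio")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class TapTrial:
    """One participant x song x time-point tapping record."""

    participant_id: str
    song_id: str
    groove: str
    time_point: str
    onsets: np.ndarray  # strictly increasing, seconds
    source: str = "provided"  # {detected, provided}

    def __post_init__(self) -> None:
        if self.groove not in GROOVE_LEVELS:
            raise ValidationError(
                f"groove must be one of {GROOVE_LEVELS}, got {self.groove!r}"
            )
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"time_point must be one of {TIME_POINTS}, got {self.time_point!r}"
            )
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and onsets[0] < 0:
            raise ValidationError("onsets must be non-negative")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError(
                f"onsets must be strictly increasing in trial "
                f"({self.participant_id}, {self.song_id}, {self.time_point})"
            )


@dataclass(frozen=True)
class UPDRSRecord:
    """UPDRS section scores for one participant at one time-point.

    The four sections are scored out of 16, 52, 108 and 23 points; the total
    out of 199, higher = more severe.
    """

    participant_id: str
    time_point: str
    section_1: int
    section_2: int
    section_3: int
    section_4: int

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(f"time_point must be one of {TIME_POINTS}")
        for name, mx in UPDRS_SECTION_MAX.items():
            val = getattr(self, name)
            if not (0 <= val <= mx):
                raise ValidationError(
                    f"participant {self.participant_id}: {name}={val} "
                    f"out of range 0-{mx}"
                )

    @property
    def total(self) -> int:
        return self.section_1 + self.section_2 + self.section_3 + self.section_4


@dataclass
class BATResponseTable:
    """All Beat Alignment Test responses for one respondent.

    ``truth`` is whether the overlaid beep track was on or off the musical
    beat; ``response`` is the respondent's judgement; ``confidence`` an
    optional 1-3 rating.
    """

    respondent_id: str
    rows: pd.DataFrame = field(repr=False)  # stimulus_id, truth, response, confidence

    def __post_init__(self) -> None:
        for col in ("stimulus_id", "truth", "response"):
            if col not in self.rows.columns:
                raise SchemaError(f"BAT table missing column {col!r}")
        for col in ("truth", "response"):
            bad = set(self.rows[col]) - set(BAT_LABELS)
            if bad:
                raise ValidationError(
                    f"respondent {self.respondent_id}: {col} values {sorted(bad)} "
                    f"not in {BAT_LABELS}"
                )
        if self.rows["stimulus_id"].duplicated().any():
            raise ValidationError(
                f"respondent {self.respondent_id}: duplicate stimulus ids"
            )


# ---------------------------------------------------------------------------
# audio

def read_audio(path: str | Path) -> AudioTrack:
    """Read a PCM WAV file into a mono :class:`AudioTrack`.

    Stereo input is mean-down-mixed with a logged warning.  Integer PCM is
    rescaled to [-1, 1] by its dtype's full-scale value.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # wavfile chunk warnings
            rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")
    if data.ndim == 2:
        logger.warning("stereo file %s down-mixed to mono", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioTrack(samples=data, sample_rate=int(rate))


def write_audio(path: str | Path, track: AudioTrack) -> None:
    """Write an :class:`AudioTrack` as 16-bit PCM WAV."""
    scaled = np.clip(track.samples, -1.0, 1.0)
    wavfile.write(Path(path), track.sample_rate, (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# tap events

_TAP_COLUMNS = ["participant_id", "song_id", "groove", "time_point", "onset_s"]


def read_tap_events(path: str | Path) -> list[TapTrial]:
    """Read a tap-event CSV into one :class:`TapTrial` per trial.

    Rows may arrive in any time order; onsets are sorted within each
    (participant, song, time_point) group.  Duplicate onset times within a
    trial are a validation error naming the trial.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "song_id": str})
    missing = [c for c in _TAP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    trials = []
    keys = ["participant_id", "song_id", "time_point"]
    for (pid, song, tp), grp in df.groupby(keys, sort=True):
        groove_vals = grp["groove"].unique()
        if len(groove_vals) != 1:
            raise ValidationError(
                f"trial ({pid}, {song}, {tp}): inconsistent groove labels {groove_vals}"
            )
        onsets = np.sort(grp["onset_s"].to_numpy(dtype=float))
        trials.append(
            TapTrial(
                participant_id=str(pid),
                song_id=str(song),
                groove=str(groove_vals[0]),
                time_point=str(tp),
                onsets=onsets,
                source="provided",
            )
        )
    return trials


def write_tap_events(path: str | Path, trials: Sequence[TapTrial]) -> None:
    """Write trials to the tap-event CSV schema (round-trips to 1e-9 s)."""
    records = [
        {
            "participant_id": t.participant_id,
            "song_id": t.song_id,
            "groove": t.groove,
            "time_point": t.time_point,
            "onset_s": onset,
        }
        for t in trials
        for onset in t.onsets
    ]
    pd.DataFrame(records, columns=_TAP_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


# ---------------------------------------------------------------------------
# UPDRS

def read_updrs(path: str | Path) -> list[UPDRSRecord]:
    """Read UPDRS section scores; any provided total column is cross-checked,
    never trusted."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ["participant_id", "time_point"] + list(UPDRS_SECTION_MAX)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        rec = UPDRSRecord(
            participant_id=str(row["participant_id"]),
            time_point=str(row["time_point"]),
            **{k: int(row[k]) for k in UPDRS_SECTION_MAX},
        )
        if "total" in df.columns and not pd.isna(row["total"]):
            if int(row["total"]) != rec.total:
                raise ValidationError(
                    f"participant {rec.participant_id} ({rec.time_point}): "
                    f"provided total {int(row['total'])} != recomputed {rec.total}"
                )
        records.append(rec)
    return records


def write_updrs(path: str | Path, records: Sequence[UPDRSRecord]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "time_point": r.time_point,
                **{k: getattr(r, k) for k in UPDRS_SECTION_MAX},
                "total": r.total,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BAT

def read_bat(path: str | Path) -> list[BATResponseTable]:
    """Read a BAT response CSV into one table per respondent."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "stimulus_id": str})
    required = ["respondent_id", "stimulus_id", "truth", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "confidence" not in df.columns:
        df["confidence"] = pd.NA
    tables = []
    for rid, grp in df.groupby("respondent_id", sort=True):
        tables.append(
            BATResponseTable(
                respondent_id=str(rid),
                rows=grp[["stimulus_id", "truth", "response", "confidence"]]
                .reset_index(drop=True),
            )
        )
    return tables


def write_bat(path: str | Path, tables: Sequence[BATResponseTable]) -> None:
    frames = []
    for t in tables:
        frame = t.rows.copy()
        frame.insert(0, "respondent_id", t.respondent_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
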