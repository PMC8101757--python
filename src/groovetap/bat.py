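"""Beat Alignment Test scoring: hit rate, false-alarm rate and d'.

Respondents hear music with an overlaid beep track and judge whether the
beeps are on or off the beat.  "Off the beat" is the signal class: the hit
rate is the proportion of off-beat stimuli correctly called "off", the
false-alarm rate the proportion of on-beat stimuli incorrectly called
"off".  Sensitivity is the classical equal-variance signal-detection
statistic d' = Phi^-1(HR) - Phi^-1(FAR).

Because a 12-item battery frequently yields HR = 1 or FAR = 0, the default
extreme-rate handling is the log-linear correction (add 0.5 to each count
and 1 to each denominator), which keeps d' finite without materially
biasing interior rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from groovetap.io_formats import BATResponseTable

CORRECTIONS = ("none", "loglinear")


@dataclass(frozen=True)
class BATScore:
    respondent_id: str
    n_off: int  # signal (off-beat) stimulus count
    n_on: int  # noise (on-beat) stimulus count
    HR: float
    FAR: float
    zHR: float
    zFAR: float

    @property
    def d_prime(self) -> float:
        return self.zHR - self.zFAR


def rates(table: BATResponseTable) -> tuple[float, float]:
    """Raw hit and false-alarm rates from a response table.

    Both truth classes must be present, otherwise the rates are undefined.
    """
    truth = table.rows["truth"].to_numpy()
    resp = table.rows["response"].to_numpy()
    n_off = int((truth == "off").sum())
    n_on = int((truth == "on").sum())
    if n_off == 0 or n_on == 0:
        raise ValueError(
            f"respondent {table.respondent_id}: both on- and off-beat stimuli "
            f"are required (got {n_on} on, {n_off} off)"
        )
    hits = int(((truth == "off") & (resp == "off")).sum())
    fas = int(((truth == "on") & (resp == "off")).sum())
    return hits / n_off, fas / n_on


def d_prime(
    hits: int,
    fas: int,
    n_off: int,
    n_on: int,
    correction: str = "loglinear",
    respondent_id: str = "",
) -> BATScore:
    """Compute z-transformed rates and d' from raw counts.

    With ``correction='loglinear'`` the adjusted rates are
    (hits + 0.5)/(n_off + 1) and (fas + 0.5)/(n_on + 1); with ``'none'``,
    extreme rates (0 or 1) raise, since the quantile transform diverges.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    HR, FAR = hits / n_off, fas / n_on
    if correction == "loglinear":
        hr_adj = (hits + 0.5) / (n_off + 1)
        far_adj = (fas + 0.5) / (n_on + 1)
    else:
        if HR in (0.0, 1.0) or FAR in (0.0, 1.0):
            raise ValueError(
                f"respondent {respondent_id}: rate at 0 or 1 gives infinite d' "
                f"(HR={HR}, FAR={FAR}); use correction='loglinear'"
            )
        hr_adj, far_adj = HR, FAR
    return BATScore(
        respondent_id=respondent_id,
        n_off=n_off,
        n_on=n_on,
        HR=HR,
        FAR=FAR,
        zHR=float(norm.ppf(hr_adj)),
        zFAR=float(norm.ppf(far_adj)),
    )


def score_table(table: BATResponseTable, correction: str = "loglinear") -> BATScore:
    """Score a single respondent's table into a :class:`BATScore`."""
    truth = table.rows["truth"].to_numpy()
    resp = table.rows["response"].to_numpy()
    n_off = int((truth == "off").sum())
    n_on = int((truth == "on").sum())
    rates(table)  # validates both classes present
    hits = int(((truth == "off") & (resp == "off")).sum())
    fas = int(((truth == "on") & (resp == "off")).sum())
    return d_prime(hits, fas, n_off, n_on, correction=correction,
                   respondent_id=table.respondent_id)


def score_bat(tables: list[BATResponseTable], correction: str = "loglinear") -> pd.DataFrame:
    """Score a list of respondents into a tidy per-respondent table."""
    scores = [score_table(t, correction=correction) for t in tables]
    return pd.DataFrame(
        {
            "respondent_id": [s.respondent_id for s in scores],
            "n_off": [s.n_off for s in scores],
            "n_on": [s.n_on for s in scores],
            "HR": [s.HR for s in scores],
            "FAR": [s.FAR for s in scores],
            "zHR": [s.zHR for s in scores],
            "zFAR": [s.zFAR for s in scores],
            "d_prime": [s.d_prime for s in scores],
        }
    )
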