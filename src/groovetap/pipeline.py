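"""End-to-end cohort analysis: tapping entropy, BAT, UPDRS and the models.

``analyze_cohort`` ties the modules together the way the study analysis
does: per-trial entropies are computed, log(Entropy) is modelled with
random-intercept LMEs compared by likelihood-ratio tests (Time-Point and
Groove within PD; Group between pre-intervention PD and controls; presence
of dance experience within PD), UPDRS change z-scores are correlated with
baseline entropy separately for high- and low-groove trials, and BAT d'
is compared between groups with a Welch t-test.

The result is a plain nested dict (JSON-serializable) so it can be dumped
by the CLI or consumed programmatically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from groovetap import bat as _bat
from groovetap import cohort_stats as cs
from groovetap import entropy as _entropy
from groovetap.io_formats import (
    BATResponseTable,
    TapTrial,
    UPDRSRecord,
    read_bat,
    read_tap_events,
    read_updrs,
)
from groovetap.onset_ioi import compute_iois, filter_iois


def _lrt_effect(table: pd.DataFrame, base_terms: list[str], term: str,
                coef_prefix: str) -> dict:
    """LRT for adding ``term`` to the base fixed effects, plus the sign of
    its first coefficient in the extended fit."""
    base = cs.fit_lme(table, cs.LMESpec("log_H", tuple(base_terms)))
    ext = cs.fit_lme(table, cs.LMESpec("log_H", tuple(base_terms + [term])))
    res = cs.lrt(base, ext)
    coef = next(
        (v for k, v in ext.fe_params.items() if k.startswith(coef_prefix)), np.nan
    )
    return {"chi_sq": res.chi_sq, "df": res.df, "p": res.p, "coef": float(coef)}


def exclusion_report(trials: list[TapTrial]) -> dict:
    """Per-cohort audit of the IOI exclusion rules: how many IOIs were
    dropped, and how many trials had at least one long (>3 s) gap."""
    n_trials = len(trials)
    n_long_iois = 0
    n_affected_trials = 0
    n_warmup = 0
    for t in trials:
        s = filter_iois(compute_iois(t.onsets))
        n_long_iois += s.n_dropped_long
        n_warmup += s.n_dropped_warmup
        if s.n_dropped_long:
            n_affected_trials += 1
    return {
        "n_trials": n_trials,
        "n_trials_with_long_ioi": n_affected_trials,
        "n_long_iois_dropped": n_long_iois,
        "n_warmup_iois_dropped": n_warmup,
    }


def analyze_cohort(
    tap_trials: list[TapTrial],
    updrs: list[UPDRSRecord],
    bat_tables: list[BATResponseTable],
    participants: pd.DataFrame,
    reference_periods: Optional[dict[str, float]] = None,
    n_bins: int = 400,
    mode: str = "ioi_phase",
) -> dict:
    """Run the full cohort analysis and return a JSON-serializable bundle.

    ``participants`` needs columns participant_id, group ({pd, control}),
    de, me (booleans).  Returns entropy summaries, LRT tables, change-score
    correlations, and BAT group comparison.
    """
    ent = _entropy.entropy_table(tap_trials, reference_periods=reference_periods,
                                 n_bins=n_bins, mode=mode)
    meta = participants.set_index("participant_id")
    ent = ent.join(meta[["group", "de", "me"]], on="participant_id")

    results: dict = {"exclusions": exclusion_report(tap_trials)}

    results["entropy_summary"] = {
        f"{grp}_{tp}": {
            "mean_H": float(sub["H"].mean()),
            "sd_H": float(sub["H"].std(ddof=1)),
            "n_trials": int(len(sub)),
        }
        for (grp, tp), sub in ent.groupby(["group", "time_point"])
    }

    # --- within-PD LMEs: time-point, groove, dance experience --------------
    pd_ent = ent[ent["group"] == "pd"].copy()
    pd_ent["de"] = pd_ent["de"].astype(int)
    lme: dict = {}
    if pd_ent["time_point"].nunique() == 2:
        lme["time_point"] = _lrt_effect(pd_ent, ["groove"], "time_point",
                                        "time_point[T.pre]")
        lme["groove"] = _lrt_effect(pd_ent, ["time_point"], "groove",
                                    "groove[T.low]")
        lme["de"] = _lrt_effect(pd_ent, ["time_point", "groove"], "de", "de")
    else:
        lme["groove"] = _lrt_effect(pd_ent, [], "groove", "groove[T.low]")
        lme["de"] = _lrt_effect(pd_ent, ["groove"], "de", "de")

    # --- pre-intervention PD vs control ------------------------------------
    pre = ent[ent["time_point"] == "pre"].copy()
    if pre["group"].nunique() == 2:
        lme["group_pre"] = _lrt_effect(pre, ["groove"], "group", "group[T.pd]")
    results["entropy_lme"] = lme

    # --- UPDRS change scores and correlations ------------------------------
    updrs_res: dict = {}
    pids_with_post = {r.participant_id for r in updrs if r.time_point == "post"}
    if len(pids_with_post) >= 3:
        changes = cs.change_scores(updrs)
        pre_tot = changes["pre_total"].to_numpy()
        post_tot = changes["post_total"].to_numpy()
        updrs_res["paired_t_pre_vs_post"] = cs.paired_t(pre_tot, post_tot)
        updrs_res["mean_delta"] = float(changes["delta"].mean())
        # baseline (pre) trial entropy vs change z-score, by groove
        zmap = changes.set_index("participant_id")["z_delta"]
        base = ent[(ent["time_point"] == "pre")
                   & ent["participant_id"].isin(zmap.index)].copy()
        base["z_delta"] = base["participant_id"].map(zmap)
        corr = {}
        for groove, sub in base.groupby("groove"):
            corr[groove] = cs.correlations(sub["log_H"].to_numpy(),
                                           sub["z_delta"].to_numpy())
        updrs_res["baseline_entropy_vs_change_z"] = corr
    results["updrs"] = updrs_res

    # --- BAT ---------------------------------------------------------------
    bat_res: dict = {}
    if bat_tables:
        scores = _bat.score_bat(bat_tables)
        scores = scores.join(meta[["group"]], on="respondent_id")
        bat_res["group_means"] = {
            grp: {
                "d_prime": float(sub["d_prime"].mean()),
                "HR": float(sub["HR"].mean()),
                "FAR": float(sub["FAR"].mean()),
                "n": int(len(sub)),
            }
            for grp, sub in scores.groupby("group")
        }
        if scores["group"].nunique() == 2:
            bat_res["welch_t_pd_vs_control"] = cs.welch_t(
                scores.loc[scores["group"] == "pd", "d_prime"].to_numpy(),
                scores.loc[scores["group"] == "control", "d_prime"].to_numpy(),
            )
    results["bat"] = bat_res
    return results


def effect_directions(results: dict) -> dict[str, bool]:
    """Extract the four encoded effect directions from an analysis bundle.

    Returns booleans: high-groove entropy below low-groove, dance-experienced
    below inexperienced, post-intervention below pre, and positive
    correlation of baseline entropy with the UPDRS change z-score.
    """
    lme = results["entropy_lme"]
    corr = results["updrs"]["baseline_entropy_vs_change_z"]
    mean_r = np.mean([corr[g]["r"] for g in corr])
    return {
        "high_groove_below_low": bool(lme["groove"]["coef"] > 0),  # low-level coef > 0
        "de_below_no_de": bool(lme["de"]["coef"] < 0),
        "post_below_pre": bool(lme["time_point"]["coef"] > 0),  # pre-level coef > 0
        "updrs_change_correlated_with_baseline_entropy": bool(mean_r > 0),
    }


def analyze_files(
    tap_events_csv: str | Path,
    updrs_csv: str | Path,
    bat_csv: str | Path,
    participants_csv: str | Path,
    songs_csv: Optional[str | Path] = None,
    **kwargs,
) -> dict:
    """File-based wrapper around :func:`analyze_cohort` (used by the CLI)."""
    trials = read_tap_events(tap_events_csv)
    updrs = read_updrs(updrs_csv)
    bat_tables = read_bat(bat_csv)
    participants = pd.read_csv(participants_csv, dtype={"participant_id": str})
    ref = None
    if songs_csv is not None:
        songs = pd.read_csv(songs_csv, dtype={"song_id": str})
        ref = dict(zip(songs["song_id"], songs["beat_period_s"]))
    return analyze_cohort(trials, updrs, bat_tables, participants,
                          reference_periods=ref, **kwargs)
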