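"""Cohort-level statistics.

Covers the analyses applied to a tapping/UPDRS/BAT cohort: UPDRS change
scores and their z-normalization, paired and Welch t-tests with Cohen's d,
one-way ANOVA with Tukey HSD post-hocs, Pearson/Spearman correlations, and
random-intercept linear mixed-effects models fitted by maximum likelihood
and compared with likelihood-ratio tests.

Mixed models are always fitted by ML (never REML) so that nested models can
be compared by LRT: the statistic is twice the log-likelihood difference,
referred to a chi-squared distribution with df equal to the difference in
fixed-effect parameter counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMResults
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from groovetap.io_formats import UPDRSRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# change scores

def change_scores(records: Sequence[UPDRSRecord]) -> pd.DataFrame:
    """Per-participant UPDRS change (post - pre) and its cohort z-score.

    Only completers (participants with both time-points) contribute; the
    number excluded is logged.  Negative delta = improvement.  The z-scores
    have mean 0 and sd 1 (ddof=1) across completers by construction.
    """
    by_pid: dict[str, dict[str, int]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, {})[r.time_point] = r.total
    completers = {pid: tp for pid, tp in by_pid.items() if {"pre", "post"} <= tp.keys()}
    n_lost = len(by_pid) - len(completers)
    if n_lost:
        logger.info("%d participants without both time-points excluded", n_lost)
    if len(completers) < 2:
        raise ValueError("need at least 2 completers to form change z-scores")
    pids = sorted(completers)
    delta = np.array([completers[p]["post"] - completers[p]["pre"] for p in pids], dtype=float)
    sd = delta.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in change scores: z-scores undefined")
    return pd.DataFrame(
        {
            "participant_id": pids,
            "pre_total": [completers[p]["pre"] for p in pids],
            "post_total": [completers[p]["post"] for p in pids],
            "delta": delta,
            "z_delta": (delta - delta.mean()) / sd,
        }
    )


# ---------------------------------------------------------------------------
# t-tests

def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Paired t-test of x vs y with Cohen's d on the change scores.

    d = mean(x - y) / sd(x - y).  Identical inputs give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    diff = x - y
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0 else 0.0
        d = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
    else:
        t = diff.mean() / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
        d = diff.mean() / sd
    return {"t": float(t), "df": n - 1, "p": float(p), "cohen_d": float(d)}


def welch_t(a: np.ndarray, b: np.ndarray) -> dict:
    """Welch two-sample t-test with Satterthwaite fractional df.

    Cohen's d uses the pooled standard deviation.  With equal variances and
    equal n, the df reduces to the pooled 2n - 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    pooled_sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else np.nan
    return {"t": float(t), "df": float(df), "p": float(p), "cohen_d": float(d)}


def welch_t_from_summaries(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> dict:
    """Welch t from printed summary statistics (means, SDs, ns)."""
    va, vb = sd_a**2, sd_b**2
    se2 = va / n_a + vb / n_b
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


# ---------------------------------------------------------------------------
# ANOVA and post-hocs

def one_way_anova(groups: Sequence[np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA across two or more groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    F, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons; columns group1, group2, diff, lwr,
    upr, p_adj (studentized-range adjusted)."""
    values = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    pairs = [(a, b) for i, a in enumerate(res.groupsunique)
             for b in res.groupsunique[i + 1:]]
    return pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "diff": res.meandiffs,
            "lwr": res.confint[:, 0],
            "upr": res.confint[:, 1],
            "p_adj": res.pvalues,
        }
    )


# ---------------------------------------------------------------------------
# correlations

def correlations(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> dict:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p), "n": int(x.size)}


# ---------------------------------------------------------------------------
# mixed models

@dataclass(frozen=True)
class LMESpec:
    """A random-intercept mixed-model specification.

    ``fixed_effects`` are patsy terms (e.g. ``["groove", "time_point"]`` or
    ``["groove * group"]``); the random structure is always an intercept per
    ``group_col`` participant; fitting is by ML so LRT comparison is valid.
    """

    response: str
    fixed_effects: tuple[str, ...] = ()
    group_col: str = "participant_id"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.response} ~ {rhs}"


@dataclass(frozen=True)
class LRTResult:
    chi_sq: float
    df: int
    p: float


def fit_lme(table: pd.DataFrame, spec: LMESpec) -> MixedLMResults:
    """Fit a random-intercept linear mixed model by maximum likelihood.

    Raises on singular (aliased) fixed-effect designs, naming the columns.
    """
    needed = {spec.response, spec.group_col}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    if table[spec.group_col].nunique() < 2:
        raise ValueError("need >= 2 participants for a random intercept")
    model = smf.mixedlm(spec.formula, table, groups=table[spec.group_col])
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            f"singular fixed-effect design: {model.exog_names} has rank {rank}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        result = model.fit(reml=False)
    return result


def lrt(base: MixedLMResults, extended: MixedLMResults) -> LRTResult:
    """Likelihood-ratio test of nested ML-fitted mixed models.

    chi_sq = 2 (llf_ext - llf_base); df = difference in fixed-effect
    parameter count; p is the upper chi-squared tail.
    """
    for fit in (base, extended):
        if fit.model.reml:
            raise ValueError("LRT requires ML (reml=False) fits")
    if base.nobs != extended.nobs:
        raise ValueError("models fitted on different numbers of rows")
    df = len(extended.fe_params) - len(base.fe_params)
    if df < 1:
        raise ValueError("extended model must add at least one parameter")
    if not set(base.model.exog_names) <= set(extended.model.exog_names):
        raise ValueError("base model is not nested in extended model")
    chi_sq = 2 * (extended.llf - base.llf)
    if chi_sq < -1e-8:
        raise ValueError(f"negative LRT statistic {chi_sq}: fits not nested/converged")
    chi_sq = max(chi_sq, 0.0)
    return LRTResult(chi_sq=float(chi_sq), df=df, p=float(stats.chi2.sf(chi_sq, df)))
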