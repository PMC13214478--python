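"""Validation statistics for a completed (or simulated) SRT study.

Four analyses mirror the standard validation of a speech-in-noise test:

* list equivalence — per-list mean SRT and SD across participants, with
  list deviations from the grand average;
* within-subject variability — the SD of each participant's test SRTs
  and the cohort average of those SDs;
* post hoc psychometric slopes — a logistic refit to every track's own
  trial log, summarized by the grand-average slope;
* training effect — a linear mixed-effects model of SRT on presentation
  order with a random per-participant intercept, tested with a marginal
  F-test at alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .psychometrics import fit_psychometric
from .simulation import N_KEYWORDS, StudyResult

__all__ = [
    "ListEquivalenceReport",
    "TrainingEffectFit",
    "list_equivalence",
    "within_subject_stats",
    "training_effect",
    "posthoc_slopes",
]


@dataclass
class ListEquivalenceReport:
    """Across-list dispersion of mean SRTs (test measurements only)."""

    per_list: pd.DataFrame  # list_id, n, mean_srt_db, sd_db, normalized_db
    grand_mean_db: float  # mean of list means
    grand_sd_db: float  # SD of list means
    max_pairwise_diff_db: float


@dataclass
class TrainingEffectFit:
    """Mixed-model estimate of the per-measurement SRT drift.

    ``order_slope_db`` is the fixed presentation-order coefficient in dB
    per measurement (negative = improvement with practice); the F-test
    uses 1 numerator df and residual denominator df (n_obs - 2).
    """

    intercept_db: float
    order_slope_db: float
    order_slope_ci: tuple[float, float]
    random_intercept_var: float
    residual_var: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_obs: int
    include_training: bool
    converged: bool

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _test_rows(results: pd.DataFrame) -> pd.DataFrame:
    if "is_training" in results.columns:
        return results.loc[~results["is_training"].astype(bool)]
    return results


def list_equivalence(results: pd.DataFrame,
                     expected_lists: Optional[Sequence[int]] = None
                     ) -> ListEquivalenceReport:
    """Per-list SRT summary over participants; training rows excluded.

    ``expected_lists`` forces lists with no data to appear with n = 0 and
    NaN statistics instead of being silently dropped.  The grand mean is
    the unweighted mean of list means, and ``normalized_db`` is each
    list's deviation from it.
    """
    df = _test_rows(results)
    grouped = df.groupby("list_id")["srt_db"]
    per = grouped.agg(n="count", mean_srt_db="mean", sd_db="std").reset_index()
    if expected_lists is not None:
        per = (
            per.set_index("list_id")
            .reindex(sorted(expected_lists))
            .reset_index()
        )
        per["n"] = per["n"].fillna(0).astype(int)
    if (per["n"] >= 1).sum() < 2:
        raise ValueError("list equivalence needs at least 2 lists with data")
    grand_mean = float(per["mean_srt_db"].mean())
    per["normalized_db"] = per["mean_srt_db"] - grand_mean
    means = per["mean_srt_db"].dropna()
    return ListEquivalenceReport(
        per_list=per,
        grand_mean_db=grand_mean,
        grand_sd_db=float(means.std(ddof=1)),
        max_pairwise_diff_db=float(means.max() - means.min()),
    )


def within_subject_stats(results: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-participant mean/SD of test SRTs and the cohort-average SD."""
    df = _test_rows(results)
    grouped = df.groupby("participant_id")["srt_db"]
    per = grouped.agg(n="count", mean_srt_db="mean", sd_db="std").reset_index()
    if (per["n"] < 2).any():
        bad = per.loc[per["n"] < 2, "participant_id"].tolist()
        raise ValueError(f"participants with < 2 test SRTs: {bad}")
    return per, float(per["sd_db"].mean())


def training_effect(results: pd.DataFrame,
                    include_training: bool = True) -> TrainingEffectFit:
    """Fit SRT ~ 1 + order + (1 | participant) by REML and test the order
    term.

    With ``include_training=False`` the training rows are dropped and the
    original order coding (3, 4, ...) is kept — the slope is invariant to
    a linear recoding, only the intercept's meaning changes.  The marginal
    F statistic is the squared Wald t of the order coefficient with
    residual denominator df (n_obs - 2), and the 95% CI uses the matching
    t quantile.
    """
    df = results if include_training else _test_rows(results)
    df = df.dropna(subset=["srt_db"])
    if df["participant_id"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    if df["presentation_order"].nunique() < 3:
        raise ValueError("need >= 3 presentation orders")

    endog = df["srt_db"].to_numpy(dtype=float)
    order = df["presentation_order"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(order), order])
    model = MixedLM(endog, exog, groups=df["participant_id"].to_numpy())

    # variance estimation can degenerate when the true random variance is 0;
    # try successively more forgiving optimizers before flagging a fallback
    fit = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method)
                usable = bool(np.isfinite(candidate.bse_fe[1]))
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not usable:
            continue
        fit = candidate
        if getattr(candidate, "converged", True):
            break
    n = len(df)
    df_den = n - exog.shape[1]
    if fit is None:
        # flagged fallback: ordinary least squares, no variance decomposition
        beta, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        resid = endog - exog @ beta
        sigma2 = float(resid @ resid / df_den)
        xtx_inv = np.linalg.inv(exog.T @ exog)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        f_stat = float((beta[1] / se) ** 2)
        p = float(stats.f.sf(f_stat, 1, df_den))
        t_crit = float(stats.t.ppf(0.975, df_den))
        return TrainingEffectFit(
            intercept_db=float(beta[0]),
            order_slope_db=float(beta[1]),
            order_slope_ci=(float(beta[1] - t_crit * se),
                            float(beta[1] + t_crit * se)),
            random_intercept_var=float("nan"),
            residual_var=sigma2,
            f_stat=f_stat,
            df_num=1,
            df_den=int(df_den),
            p_value=p,
            n_obs=n,
            include_training=include_training,
            converged=False,
        )

    beta = fit.fe_params
    se = fit.bse_fe[1]
    f_stat = float((beta[1] / se) ** 2)
    p = float(stats.f.sf(f_stat, 1, df_den))
    t_crit = float(stats.t.ppf(0.975, df_den))
    converged = bool(getattr(fit, "converged", True))
    return TrainingEffectFit(
        intercept_db=float(beta[0]),
        order_slope_db=float(beta[1]),
        order_slope_ci=(float(beta[1] - t_crit * se), float(beta[1] + t_crit * se)),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        f_stat=f_stat,
        df_num=1,
        df_den=int(df_den),
        p_value=p,
        n_obs=n,
        include_training=include_training,
        converged=converged,
    )


def posthoc_slopes(study: StudyResult) -> tuple[pd.DataFrame, float, int]:
    """Refit a logistic curve to every track's trial log.

    Returns (per-track table, grand-average slope over convergent fits,
    number of excluded non-convergent tracks).  Tracks whose logs cannot
    support a fit (e.g. constant SNR) are excluded and counted, never
    imputed.
    """
    if not study.trial_logs:
        raise ValueError("study carries no trial logs (simulate with keep_logs=True)")
    rows = []
    n_excluded = 0
    for (pid, order), log in study.trial_logs.items():
        scored = log.loc[~log["is_escalation_replay"].astype(bool)]
        trials = [
            (r.nominal_snr_db, N_KEYWORDS, int(r.k_correct))
            for r in scored.itertuples()
        ]
        try:
            fit = fit_psychometric(trials)
        except ValueError:
            fit = None
        ok = fit is not None and fit.converged
        if not ok:
            n_excluded += 1
        rows.append(
            {
                "participant_id": pid,
                "presentation_order": order,
                "slope_pct_per_db": fit.slope if ok else float("nan"),
                "midpoint_db": fit.midpoint_db if ok else float("nan"),
                "converged": ok,
            }
        )
    per = pd.DataFrame(rows)
    good = per.loc[per["converged"], "slope_pct_per_db"]
    if good.empty:
        raise ValueError("every post hoc fit was non-convergent")
    return per, float(good.mean()), n_excluded
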