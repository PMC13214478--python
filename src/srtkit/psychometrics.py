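"""Logistic psychometric functions: the model, the fit, and level offsets.

The intelligibility of a sentence in stationary noise is modelled as a
logistic function of the signal-to-noise ratio (SNR).  The curve is
parameterized directly by the two quantities reported in speech-in-noise
work: the *midpoint* (inflection point, the SNR in dB at which 50% of
keywords are repeated correctly) and the *slope* at the midpoint in
percentage points per dB,

    p(x) = 1 / (1 + exp(-4 * (s / 100) * (x - m)))

so that dp/dx at x = m equals s/100 exactly (p in [0, 1]) and the curve is
strictly increasing for s > 0.  No guess or lapse rate is modelled: the
sentence material is open-set, so chance performance is effectively zero,
and fits operate on averaged keyword proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PsychometricFunction",
    "TrialObservation",
    "logistic_p",
    "fit_psychometric",
    "compute_offsets",
]


@dataclass(frozen=True)
class PsychometricFunction:
    """A fitted (or assumed) logistic intelligibility curve.

    Attributes
    ----------
    midpoint_db : float
        SNR in dB at which the probability of a correct keyword is 0.5.
    slope : float
        Derivative of the curve at the midpoint, in %/dB.
    mse : float
        Mean squared error of the fit on the percent-correct (0-100) scale,
        hence in units of %^2.  NaN for curves that were not fitted.
    converged : bool
        False for degenerate fits (all-correct / all-wrong responses or an
        optimizer failure); parameter values are then not meaningful.
    """

    midpoint_db: float
    slope: float
    mse: float = float("nan")
    converged: bool = True

    def p(self, snr_db):
        """Probability of a correct keyword at ``snr_db`` (vectorized)."""
        return logistic_p(snr_db, self.midpoint_db, self.slope)


@dataclass(frozen=True)
class TrialObservation:
    """One scored sentence presentation: SNR and keywords repeated."""

    snr_db: float
    n_keywords: int = 3
    k_correct: int = 0

    def __post_init__(self):
        if not (0 <= self.k_correct <= self.n_keywords):
            raise ValueError(
                f"k_correct={self.k_correct} outside 0..{self.n_keywords}"
            )


def logistic_p(snr_db, midpoint_db: float, slope: float):
    """Logistic probability of a correct response at ``snr_db``.

    ``slope`` is the derivative at the midpoint in %/dB and must be > 0.
    Accepts scalars or arrays; raises on non-finite SNR input.
    """
    x = np.asarray(snr_db, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite SNR value")
    if not math.isfinite(midpoint_db) or not math.isfinite(slope):
        raise ValueError("non-finite psychometric parameters")
    if slope <= 0:
        raise ValueError("slope must be positive")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-4.0 * (slope / 100.0) * (x - midpoint_db)))
    return p if p.ndim else float(p)


def _as_arrays(trials: Iterable) -> tuple[np.ndarray, np.ndarray]:
    """Extract (snr, percent-correct) per presentation from trial records."""
    snr, pct = [], []
    for t in trials:
        if isinstance(t, TrialObservation):
            s, n, k = t.snr_db, t.n_keywords, t.k_correct
        else:  # (snr, n_keywords, k_correct) triple
            s, n, k = t
        if not math.isfinite(s):
            raise ValueError("non-finite SNR in trials")
        snr.append(float(s))
        pct.append(100.0 * k / n)
    return np.asarray(snr), np.asarray(pct)


def fit_psychometric(trials: Sequence) -> PsychometricFunction:
    """Fit the logistic curve to scored presentations by least squares.

    Each presentation contributes its percent-correct (100 * k / n) at its
    presented SNR; the residuals are minimized with a damped iterative
    least-squares solver (trust-region reflective), multi-started over
    candidate midpoints spanning the observed SNR range, because per-track
    samples are small (typically <= 20 points).

    Requires at least 3 distinct SNR levels.  All-correct or all-wrong
    response sets carry no information about the midpoint and yield a
    result flagged ``converged=False`` rather than arbitrary numbers.
    """
    snr, pct = _as_arrays(trials)
    if len(np.unique(snr)) < 3:
        raise ValueError("need >= 3 distinct SNR levels to fit")
    if np.all(pct == pct[0]):
        # includes all-correct and all-wrong: no midpoint information
        return PsychometricFunction(float("nan"), float("nan"), float("nan"), False)

    def residuals(theta):
        m, s = theta
        return 100.0 * logistic_p(snr, m, s) - pct

    lo, hi = snr.min(), snr.max()
    m_starts = np.quantile(snr, [0.0, 0.25, 0.5, 0.75, 1.0])
    s_starts = (5.0, 15.0, 30.0)
    best = None
    for m0 in m_starts:
        for s0 in s_starts:
            try:
                res = least_squares(
                    residuals,
                    x0=[m0, s0],
                    bounds=([lo - 30.0, 1e-3], [hi + 30.0, 1e3]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        return PsychometricFunction(float("nan"), float("nan"), float("nan"), False)
    m, s = best.x
    mse = float(np.mean(residuals(best.x) ** 2))
    return PsychometricFunction(float(m), float(s), mse, True)


def compute_offsets(midpoints, reference_mean: float) -> np.ndarray:
    """Per-sentence normalization offsets in dB.

    offset_i = midpoint_i - reference_mean.  Applying a level gain of
    offset_i dB to sentence i shifts its effective midpoint by -offset_i,
    aligning it with the reference: positive offsets boost hard sentences.
    """
    m = np.asarray(midpoints, dtype=float)
    if not np.all(np.isfinite(m)) or not math.isfinite(reference_mean):
        raise ValueError("non-finite midpoint or reference")
    return m - reference_mean
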