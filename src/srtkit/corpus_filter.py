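"""Retention filtering of a sentence-metadata table.

A sentence corpus arrives as a table with one row per sentence carrying
playback-quality flags, listener-survey scores (naturalness on a 1-7
scale, fraction of raters reporting discomfort) and the three parameters
of its psychometric function (midpoint, slope, fit MSE).  Sentences are
retained only if every criterion passes; psychometric cutoffs follow the
1.5-IQR outlier convention.  A final single-pass trim removes sentences
whose midpoint lies more than 3 dB from the corpus mean, which caps the
level-normalization offsets at 3 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FilterCriteria",
    "REQUIRED_COLUMNS",
    "iqr_cutoffs",
    "apply_filters",
    "trim_by_offset",
]

#: Columns a corpus metadata table must provide.
REQUIRED_COLUMNS = (
    "sentence_id",
    "template_id",
    "midpoint_db",
    "slope_pct_per_db",
    "mse_pct2",
    "naturalness_mean",
    "discomfort_fraction",
    "quality_ok",
)

#: Attribution order for the per-criterion rejection report: a rejected
#: sentence is counted against the FIRST criterion it fails, in this order.
CRITERIA_ORDER = (
    "quality",
    "discomfort",
    "naturalness",
    "midpoint",
    "slope",
    "mse",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds.

    Bounds on midpoint and slope are open intervals (strict comparisons);
    naturalness is inclusive ("at least"); discomfort strict ("less than").
    ``mse_direction`` selects whether sentences must fall below or above
    ``mse_bound_pct2`` — upper-outlier removal ("below") is the default.
    """

    midpoint_bounds_db: tuple[float, float] = (-9.2, -0.5)
    slope_bounds: tuple[float, float] = (0.0, 33.5)
    mse_bound_pct2: float = 897.0
    mse_direction: str = "below"  # retain mse < bound; "above" retains >
    naturalness_min: float = 4.5
    discomfort_max: float = 0.25
    quality_required: bool = True
    max_abs_offset_db: float = 3.0

    def __post_init__(self):
        if self.midpoint_bounds_db[0] >= self.midpoint_bounds_db[1]:
            raise ValueError("midpoint bounds must satisfy lower < upper")
        if self.slope_bounds[0] >= self.slope_bounds[1]:
            raise ValueError("slope bounds must satisfy lower < upper")
        if self.mse_direction not in ("below", "above"):
            raise ValueError("mse_direction must be 'below' or 'above'")


def iqr_cutoffs(values) -> tuple[float, float]:
    """Outlier cutoffs (Q1 - 1.5*IQR, Q3 + 1.5*IQR), quartiles by linear
    interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile cutoffs")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def _validate_corpus(corpus: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in corpus.columns]
    if missing_cols:
        raise ValueError(f"corpus table missing columns: {missing_cols}")
    check = corpus[list(REQUIRED_COLUMNS)].drop(columns=["quality_ok"])
    bad = corpus.loc[check.isna().any(axis=1), "sentence_id"]
    if len(bad):
        raise ValueError(
            f"incomplete metadata for sentence_id(s): {sorted(bad.tolist())[:10]}"
        )


def apply_filters(
    corpus: pd.DataFrame, criteria: Optional[FilterCriteria] = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the retention criteria; return (retained, rejection report).

    The report maps each criterion name to the count of sentences whose
    first failing criterion it was (see CRITERIA_ORDER), plus ``retained``
    and ``input`` counts; counts always sum to the input size.  Row order
    is preserved and re-application is idempotent.
    """
    c = criteria or FilterCriteria()
    _validate_corpus(corpus)

    mlo, mhi = c.midpoint_bounds_db
    slo, shi = c.slope_bounds
    pass_by = {
        "quality": corpus["quality_ok"].astype(bool) | (not c.quality_required),
        "discomfort": corpus["discomfort_fraction"] < c.discomfort_max,
        "naturalness": corpus["naturalness_mean"] >= c.naturalness_min,
        "midpoint": (corpus["midpoint_db"] > mlo) & (corpus["midpoint_db"] < mhi),
        "slope": (corpus["slope_pct_per_db"] > slo)
        & (corpus["slope_pct_per_db"] < shi),
        "mse": corpus["mse_pct2"] < c.mse_bound_pct2
        if c.mse_direction == "below"
        else corpus["mse_pct2"] > c.mse_bound_pct2,
    }

    report = {name: 0 for name in CRITERIA_ORDER}
    rejected = pd.Series(False, index=corpus.index)
    for name in CRITERIA_ORDER:
        newly = ~pass_by[name] & ~rejected
        report[name] = int(newly.sum())
        rejected |= newly
    retained = corpus.loc[~rejected].copy()
    report["retained"] = int(len(retained))
    report["input"] = int(len(corpus))
    return retained, report


def trim_by_offset(
    corpus: pd.DataFrame,
    max_abs_offset_db: float = 3.0,
    iterate: bool = False,
    tol_db: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Drop sentences whose midpoint is > ``max_abs_offset_db`` from the mean.

    Returns the surviving rows and the pre-trim mean midpoint, which is the
    normalization reference: offsets computed against it are bounded by the
    cap for every survivor.  Single-pass by default; with ``iterate=True``
    the trim repeats with the updated mean until it moves < ``tol_db``.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    df = corpus
    reference = float(df["midpoint_db"].mean())
    while True:
        keep = (df["midpoint_db"] - reference).abs() <= max_abs_offset_db
        if not keep.any():
            raise ValueError("offset trim removed every sentence")
        trimmed = df.loc[keep]
        if not iterate:
            return trimmed.copy(), reference
        new_reference = float(trimmed["midpoint_db"].mean())
        if abs(new_reference - reference) < tol_db:
            return trimmed.copy(), reference
        df, reference = trimmed, new_reference
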