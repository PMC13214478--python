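"""Synthetic corpora, virtual listeners, and whole-study simulation.

Nothing here touches audio.  A synthetic corpus emulates the metadata
table of a psychoacoustically characterized sentence corpus (10 syntactic
templates, per-sentence logistic midpoint/slope, fit MSE, naturalness and
discomfort survey scores, playback-quality flags), with distribution
parameters matching the reference material: midpoints centred on
-4.8 dB SNR and a small configurable fraction of sentences violating each
retention filter.

A virtual listener responds to a sentence at a given nominal SNR by
drawing three independent Bernoulli keywords from the sentence's logistic
curve, shifted by the sentence's normalization offset and the listener's
own SRT deviation.  Session plans mirror the counterbalanced design of
the reference study: participants come in pairs, a seeded permutation of
the lists is split between the two, each participant trains on two lists
drawn from the half they will not be tested on, and with 20 participants
and 44 lists every list collects exactly 10 test scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adaptive_track import Track, compute_srt, start_track
from .corpus_filter import REQUIRED_COLUMNS
from .list_optimizer import ListSet
from .psychometrics import fit_psychometric, logistic_p

__all__ = [
    "CorpusParams",
    "VirtualListener",
    "SessionPlan",
    "StudyResult",
    "generate_synthetic_corpus",
    "simulate_keyword_response",
    "simulate_track",
    "make_listeners",
    "make_session_plan",
    "simulate_study",
]

N_KEYWORDS = 3


@dataclass(frozen=True)
class CorpusParams:
    """Distribution parameters of the synthetic sentence-metadata table.

    Midpoints are Normal(midpoint_mean_db, midpoint_sd_db); the default SD
    of 1.6 dB puts the 1.5-IQR outlier cutoffs of a normal sample
    (~ mean +/- 2.7 SD) near the -9.2 / -0.5 dB retention bounds.  Slopes
    are Normal(13, 6) %/dB — individual sentences are considerably
    shallower than a full adaptive track, whose effective slope pools many
    sentences.  Each of the survey/quality/fit-error fields is drawn as a
    mixture: a compliant bulk plus a small violating fraction, so the
    retention filters have something to reject.
    """

    midpoint_mean_db: float = -4.8
    midpoint_sd_db: float = 1.6
    slope_mean: float = 13.0
    slope_sd: float = 6.0
    mse_bulk_range_pct2: tuple[float, float] = (50.0, 800.0)
    mse_violation_range_pct2: tuple[float, float] = (950.0, 1500.0)
    mse_violation_frac: float = 0.02
    naturalness_bulk: tuple[float, float] = (4.6, 7.0)
    naturalness_violation_frac: float = 0.03
    discomfort_bulk_max: float = 0.2
    discomfort_violation_frac: float = 0.03
    quality_fail_frac: float = 0.03


@dataclass(frozen=True)
class VirtualListener:
    """An idealized participant.

    ``srt_shift_db`` moves the listener's effective midpoint relative to
    the corpus reference (positive = worse); ``slope_scale`` multiplies
    every sentence slope (values > 1 give steeper, more deterministic
    psychometric behaviour).
    """

    listener_id: int
    srt_shift_db: float = 0.0
    slope_scale: float = 1.0

    def __post_init__(self):
        if self.slope_scale <= 0:
            raise ValueError("slope_scale must be positive")


@dataclass(frozen=True)
class SessionPlan:
    """One participant's session: 2 training lists then ordered test lists."""

    participant_id: int
    training_list_ids: tuple[int, ...]
    test_list_ids: tuple[int, ...]
    pair_index: int

    def __post_init__(self):
        if set(self.training_list_ids) & set(self.test_list_ids):
            raise ValueError("training lists must not appear among test lists")


@dataclass
class StudyResult:
    """Long-format study outcome plus (optionally) per-track trial logs."""

    results: pd.DataFrame
    trial_logs: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)


def generate_synthetic_corpus(n_per_template: int = 120,
                              params: Optional[CorpusParams] = None,
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a synthetic sentence-metadata table (10 templates, seeded).

    Returns a DataFrame with the standard corpus columns; sentence_ids are
    1..10*n_per_template, templates cycling 1..10.  At the default scale
    (120 per template) the retention filters comfortably leave the >= 88
    sentences per template needed for a 44-list set.
    """
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    p = params or CorpusParams()
    if not (0 < p.midpoint_sd_db or p.midpoint_sd_db == 0):
        raise ValueError("midpoint_sd_db must be non-negative")
    rng = np.random.default_rng(seed)
    n = 10 * n_per_template

    template_id = np.tile(np.arange(1, 11), n_per_template)
    midpoint = rng.normal(p.midpoint_mean_db, p.midpoint_sd_db, size=n)
    slope = rng.normal(p.slope_mean, p.slope_sd, size=n)

    mse = rng.uniform(*p.mse_bulk_range_pct2, size=n)
    viol = rng.random(n) < p.mse_violation_frac
    mse[viol] = rng.uniform(*p.mse_violation_range_pct2, size=int(viol.sum()))

    naturalness = rng.uniform(*p.naturalness_bulk, size=n)
    viol = rng.random(n) < p.naturalness_violation_frac
    naturalness[viol] = rng.uniform(1.0, 4.4, size=int(viol.sum()))

    discomfort = rng.uniform(0.0, p.discomfort_bulk_max, size=n)
    viol = rng.random(n) < p.discomfort_violation_frac
    discomfort[viol] = rng.uniform(0.25, 0.8, size=int(viol.sum()))

    quality_ok = rng.random(n) >= p.quality_fail_frac

    df = pd.DataFrame(
        {
            "sentence_id": np.arange(1, n + 1),
            "template_id": template_id,
            "midpoint_db": midpoint,
            "slope_pct_per_db": slope,
            "mse_pct2": mse,
            "naturalness_mean": naturalness,
            "discomfort_fraction": discomfort,
            "quality_ok": quality_ok,
        }
    )
    assert list(df.columns) == list(REQUIRED_COLUMNS)
    return df


def simulate_keyword_response(listener: VirtualListener, midpoint_db: float,
                              slope_pct_per_db: float, offset_db: float,
                              nominal_snr_db: float,
                              rng: np.random.Generator) -> int:
    """Number of keywords (0-3) the listener repeats correctly.

    The sentence's normalization gain of ``offset_db`` shifts its
    effective midpoint to midpoint - offset; the listener's own deviation
    adds on top.  The three keywords are conditionally independent given
    the SNR.
    """
    m_eff = midpoint_db - offset_db + listener.srt_shift_db
    s_eff = slope_pct_per_db * listener.slope_scale
    prob = logistic_p(nominal_snr_db, m_eff, s_eff)
    return int(rng.binomial(N_KEYWORDS, prob))


def simulate_track(sentences: pd.DataFrame, listener: VirtualListener,
                   rng: np.random.Generator,
                   extra_shift_db: float = 0.0, **track_kwargs) -> Track:
    """Run one full adaptive track against a virtual listener.

    ``sentences`` needs columns sentence_id, midpoint_db, slope_pct_per_db
    and offset_db (one row per list sentence, in presentation order).
    ``extra_shift_db`` adds a temporary midpoint shift, used to inject
    within-session learning drift.
    """
    ids = sentences["sentence_id"].to_numpy()
    mids = sentences["midpoint_db"].to_numpy(dtype=float)
    slopes = sentences["slope_pct_per_db"].to_numpy(dtype=float)
    offs = sentences["offset_db"].to_numpy(dtype=float)
    by_id = {int(i): (m, s, o) for i, m, s, o in zip(ids, mids, slopes, offs)}

    eff = replace(listener, srt_shift_db=listener.srt_shift_db + extra_shift_db)
    track = start_track(list(zip(ids, offs)), **track_kwargs)
    while track.running:
        pres = track.pending
        m, s, o = by_id[pres.sentence_id]
        k = simulate_keyword_response(eff, m, s, o, pres.nominal_snr_db, rng)
        track.score(k)
    return track


def make_listeners(n: int, seed: Optional[int] = None,
                   srt_shift_sd_db: float = 0.5,
                   slope_scale: float = 1.0) -> list[VirtualListener]:
    """Draw a cohort with Normal(0, srt_shift_sd_db) individual deviations."""
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, srt_shift_sd_db, size=n)
    return [
        VirtualListener(i + 1, float(shifts[i]), slope_scale) for i in range(n)
    ]


def make_session_plan(n_participants: int, n_lists: int,
                      seed: Optional[int] = None,
                      n_training: int = 2) -> list[SessionPlan]:
    """Counterbalanced session plans for pairs of participants.

    Per pair, a seeded permutation of the list ids (1-based) is halved:
    the first half becomes participant A's ordered test lists, the second
    half B's.  Each participant's training lists are drawn from the other
    half, so training material never reappears in that participant's test.
    Over the whole cohort every list is tested exactly
    n_participants/2 times.
    """
    if n_participants % 2 or n_lists % 2:
        raise ValueError("participant and list counts must both be even")
    half = n_lists // 2
    if n_training > half:
        raise ValueError("not enough complement lists for training")
    rng = np.random.default_rng(seed)
    plans = []
    for pair in range(n_participants // 2):
        perm = rng.permutation(n_lists) + 1
        first, second = perm[:half], perm[half:]
        for offset, (test, complement) in enumerate(
            [(first, second), (second, first)]
        ):
            training = rng.choice(complement, size=n_training, replace=False)
            plans.append(
                SessionPlan(
                    participant_id=2 * pair + offset + 1,
                    training_list_ids=tuple(int(x) for x in training),
                    test_list_ids=tuple(int(x) for x in test),
                    pair_index=pair,
                )
            )
    return plans


def _track_rng(master_seed: Optional[int], participant_id: int,
               order: int) -> np.random.Generator:
    # a SeedSequence keyed on (master, participant, order) gives every track
    # its own stream: reordering sessions cannot perturb other tracks
    base = 0 if master_seed is None else int(master_seed)
    return np.random.default_rng(
        np.random.SeedSequence([base, int(participant_id), int(order)])
    )


def simulate_study(corpus: pd.DataFrame, list_set: ListSet,
                   listeners: Sequence[VirtualListener],
                   plans: Sequence[SessionPlan],
                   seed: Optional[int] = None,
                   learning_db_per_measurement: float = 0.0,
                   fit_slopes: bool = True,
                   keep_logs: bool = False,
                   **track_kwargs) -> StudyResult:
    """Simulate every planned session: training tracks then test tracks.

    Rows of the returned table: participant_id, presentation_order (1-based
    across the whole session, training included), list_id, is_training,
    srt_db, se_db, n_phase23, slope_pct_per_db (post hoc logistic fit to
    the track's own trials; NaN when not requested or non-convergent).

    ``learning_db_per_measurement`` injects a linear drift of the
    listener's effective midpoint with presentation order (negative =
    improvement), for power checks of the training-effect analysis.
    """
    by_listener = {l.listener_id: l for l in listeners}
    meta = corpus.set_index("sentence_id")[["midpoint_db", "slope_pct_per_db"]]
    lists_by_number = {}
    for i, lst in enumerate(list_set.lists, start=1):
        sids = [sid for sid, _ in lst]
        df = meta.loc[sids].reset_index()
        df["offset_db"] = [off for _, off in lst]
        lists_by_number[i] = df

    rows = []
    logs: dict[tuple[int, int], pd.DataFrame] = {}
    for plan in plans:
        listener = by_listener[plan.participant_id]
        session = [(lid, True) for lid in plan.training_list_ids]
        session += [(lid, False) for lid in plan.test_list_ids]
        for order, (list_id, is_training) in enumerate(session, start=1):
            if list_id not in lists_by_number:
                raise ValueError(
                    f"plan for participant {plan.participant_id} references "
                    f"list {list_id} absent from the list set"
                )
            rng = _track_rng(seed, plan.participant_id, order)
            drift = learning_db_per_measurement * (order - 1)
            track = simulate_track(
                lists_by_number[list_id], listener, rng,
                extra_shift_db=drift, **track_kwargs,
            )
            srt, se = compute_srt(track)
            phase23 = track.scored(phases=(2, 3))
            slope = float("nan")
            if fit_slopes:
                try:
                    fit = fit_psychometric(
                        [
                            (p.nominal_snr_db, N_KEYWORDS, p.k_correct)
                            for p in track.scored()
                        ]
                    )
                except ValueError:  # < 3 distinct levels: unfittable track
                    fit = None
                if fit is not None and fit.converged:
                    slope = fit.slope
            rows.append(
                {
                    "participant_id": plan.participant_id,
                    "presentation_order": order,
                    "list_id": list_id,
                    "is_training": is_training,
                    "srt_db": srt,
                    "se_db": se,
                    "n_phase23": len(phase23),
                    "slope_pct_per_db": slope,
                }
            )
            if keep_logs:
                logs[(plan.participant_id, order)] = track.to_frame()
    return StudyResult(results=pd.DataFrame(rows), trial_logs=logs)
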