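"""Three-phase adaptive staircase for speech-reception-threshold (SRT)
measurement, as a pure state machine with no audio dependencies.

One track consumes a 20-sentence list.  The first sentence starts at
0 dB SNR; if it is not repeated completely correctly (all three keywords)
it is replayed 5 dB louder until it is — these escalation replays do not
consume list sentences and never enter the SRT.  Thereafter the SNR moves
down after a correct response and up after an incorrect one, with step
sizes that shrink by phase:

  phase 1: 5 dB steps, for at least 4 sentences and until the first
           reversal (a change of direction between consecutive moves);
  phase 2: 2 dB steps, for at least 4 sentences and until the standard
           error of the phase-2 presentation levels falls below 1 dB;
  phase 3: 1 dB steps until the list is exhausted (not always reached).

The SRT is the mean of the *nominal* (pre-offset) SNRs of the phase-2 and
phase-3 presentations, and the reported SE is their sample SD / sqrt(n).
Sentence-specific normalization offsets shift only the adjusted playback
level, never the staircase bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Presentation",
    "Track",
    "sentence_correct",
    "start_track",
    "compute_srt",
]

DEFAULT_STEPS_DB = (5.0, 2.0, 1.0)


def sentence_correct(k_correct: int, rule: str = "majority",
                     n_keywords: int = 3) -> bool:
    """Sentence-level up/down decision from the keyword score.

    ``majority`` (default): correct iff more than half the keywords were
    repeated (>= 2 of 3).  ``all``: correct only with every keyword, the
    convention of tests scored sentence-wise.
    """
    if not (0 <= k_correct <= n_keywords):
        raise ValueError(f"k_correct={k_correct} outside 0..{n_keywords}")
    if rule == "majority":
        return 2 * k_correct > n_keywords
    if rule == "all":
        return k_correct == n_keywords
    raise ValueError(f"unknown scoring rule {rule!r}")


@dataclass
class Presentation:
    """One played sentence: levels, phase, and (once scored) the outcome."""

    index: int
    sentence_id: int
    nominal_snr_db: float
    adjusted_snr_db: float
    phase: int
    k_correct: Optional[int] = None
    correct: Optional[bool] = None
    is_escalation_replay: bool = False


class Track:
    """State of one adaptive SRT measurement over a sentence list.

    Drive it by calling :meth:`score` with the keyword count of the
    currently pending presentation (see :attr:`pending`); the track
    prepares the next presentation itself and flips ``status`` to
    ``"complete"`` when all list sentences have been consumed.
    """

    def __init__(self, sentences: Sequence[tuple[int, float]],
                 start_snr_db: float = 0.0,
                 steps_db: Sequence[float] = DEFAULT_STEPS_DB,
                 se_threshold_db: float = 1.0,
                 min_sentences_per_phase: int = 4,
                 scoring_rule: str = "majority",
                 noise_level_dba: float = 70.0,
                 list_size: int = 20):
        if len(sentences) != list_size:
            raise ValueError(f"expected a {list_size}-sentence list, got {len(sentences)}")
        self.sentences = [(int(s), float(o)) for s, o in sentences]
        self.start_snr_db = float(start_snr_db)
        self.steps_db = tuple(float(s) for s in steps_db)
        self.se_threshold_db = float(se_threshold_db)
        self.min_sentences_per_phase = int(min_sentences_per_phase)
        self.scoring_rule = scoring_rule
        self.noise_level_dba = float(noise_level_dba)

        self.presentations: list[Presentation] = []
        self.phase = 1
        self.status = "running"
        self._directions: list[int] = []  # -1 down / +1 up, post-escalation
        self._cursor = 0  # next list sentence to consume
        self._first_resolved = False
        self._warned_first_four = False
        sid, off = self.sentences[0]
        self.pending: Optional[Presentation] = Presentation(
            1, sid, self.start_snr_db, self.start_snr_db + off, 1
        )

    # -- queries ---------------------------------------------------------

    @property
    def running(self) -> bool:
        return self.status == "running"

    def scored(self, phases: Optional[tuple[int, ...]] = None,
               include_replays: bool = False) -> list[Presentation]:
        """Scored presentations, optionally restricted by phase."""
        out = []
        for p in self.presentations:
            if p.k_correct is None:
                continue
            if p.is_escalation_replay and not include_replays:
                continue
            if phases is not None and p.phase not in phases:
                continue
            out.append(p)
        return out

    def _phase_count(self, phase: int) -> int:
        return len(self.scored(phases=(phase,)))

    def _phase2_se(self) -> float:
        levels = [p.nominal_snr_db for p in self.scored(phases=(2,))]
        if len(levels) < 2:
            return float("inf")
        return float(np.std(levels, ddof=1) / math.sqrt(len(levels)))

    @property
    def n_reversals(self) -> int:
        d = self._directions
        return sum(1 for a, b in zip(d, d[1:]) if a != b)

    # -- state transitions ----------------------------------------------

    def score(self, k_correct: int) -> "Track":
        """Score the pending presentation and prepare the next one."""
        if not self.running or self.pending is None:
            raise RuntimeError("cannot score a completed track")
        p = self.pending
        k_correct = int(k_correct)

        if not self._first_resolved:
            # first sentence: requires a completely correct repetition
            ok = sentence_correct(k_correct, rule="all")
            p.k_correct, p.correct = k_correct, ok
            self.presentations.append(p)
            if not ok:
                sid, off = self.sentences[0]
                nominal = p.nominal_snr_db + self.steps_db[0]
                self.pending = Presentation(
                    p.index + 1, sid, nominal, nominal + off, 1,
                    is_escalation_replay=True,
                )
                return self
            self._first_resolved = True
            self._cursor = 1
            self._directions.append(-1)  # resolves correct, next move is down
            self._advance(p.nominal_snr_db, went_down=True)
            return self

        ok = sentence_correct(k_correct, rule=self.scoring_rule)
        p.k_correct, p.correct = k_correct, ok
        self.presentations.append(p)
        self._directions.append(-1 if ok else +1)
        self._cursor += 1
        self._maybe_warn_first_four()
        if self._cursor >= len(self.sentences):
            self.status = "complete"
            self.pending = None
            return self
        self._advance(p.nominal_snr_db, went_down=ok)
        return self

    def _maybe_warn_first_four(self) -> None:
        first_four = self.scored()[:4]
        if (not self._warned_first_four and len(first_four) == 4
                and all(q.correct for q in first_four)):
            self._warned_first_four = True
            warnings.warn(
                "first four sentences all correct: a restart would normally "
                "be considered", stacklevel=3,
            )

    def _advance(self, current_nominal: float, went_down: bool) -> None:
        """Prepare the next presentation.

        The adjustment uses the step size of the phase the just-scored
        sentence belonged to; the phase transition (evaluated afterwards)
        affects only subsequent presentations' phase and step.
        """
        step = self.steps_db[self.phase - 1]
        nominal = current_nominal - step if went_down else current_nominal + step
        if (self.phase == 1
                and self._phase_count(1) >= self.min_sentences_per_phase
                and self.n_reversals >= 1):
            self.phase = 2
        elif (self.phase == 2
                and self._phase_count(2) >= self.min_sentences_per_phase
                and self._phase2_se() < self.se_threshold_db):
            self.phase = 3
        sid, off = self.sentences[self._cursor]
        self.pending = Presentation(
            len(self.presentations) + 1, sid, nominal, nominal + off, self.phase
        )

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Track log, one row per scored presentation."""
        return pd.DataFrame(
            [
                {
                    "index": p.index,
                    "sentence_id": p.sentence_id,
                    "phase": p.phase,
                    "nominal_snr_db": p.nominal_snr_db,
                    "adjusted_snr_db": p.adjusted_snr_db,
                    "k_correct": p.k_correct,
                    "correct": p.correct,
                    "is_escalation_replay": p.is_escalation_replay,
                }
                for p in self.presentations
            ]
        )


def start_track(sentences: Sequence[tuple[int, float]], **kwargs) -> Track:
    """Open a new adaptive track over ``sentences`` (id, offset) pairs."""
    return Track(sentences, **kwargs)


def compute_srt(track: Track) -> tuple[float, float]:
    """SRT and SE of a completed track.

    Both are computed over the nominal (unadjusted) SNRs of the phase-2 and
    phase-3 presentations only; phase-1 sentences and first-sentence
    escalation replays are excluded.  A track that never left phase 1 has
    no defined SRT and raises with a diagnostic.
    """
    if track.running:
        raise RuntimeError("track still running")
    levels = [p.nominal_snr_db for p in track.scored(phases=(2, 3))]
    if not levels:
        raise ValueError(
            "track never reached phase 2: no reversal within the list or "
            "the staircase failed to settle; the measurement would normally "
            "be discarded or restarted"
        )
    srt = float(np.mean(levels))
    se = (
        float(np.std(levels, ddof=1) / math.sqrt(len(levels)))
        if len(levels) >= 2
        else float("nan")
    )
    return srt, se
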