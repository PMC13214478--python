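"""Sorting sentences into psychometrically equivalent test lists.

Each 20-sentence list must contain exactly two sentences of each of the
ten syntactic templates.  Within a template, sentences are sorted by their
normalization offset and paired middle-out — the innermost pair holds the
two offsets closest to the template median, the outermost pair the most
extreme negative and positive offsets — so every pair roughly cancels.
Pairs are then distributed across lists by a seeded random permutation
(both members of a pair stay together).  The whole arrangement is repeated
many times; the candidate minimizing a dispersion cost

    cost = w_slope * SD_over_lists(mean slope) + w_offset * SD_over_lists(mean offset)

is kept.  Offsets are recomputed each iteration against the mean midpoint
of that iteration's selected sentences, so the exported reference is
specific to the winning arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SentencePair",
    "ListSet",
    "max_list_count",
    "pair_by_offset",
    "assign_pairs_to_lists",
    "cost",
    "optimize_lists",
]

N_TEMPLATES = 10
SENTENCES_PER_LIST = 20
PER_LIST_PER_TEMPLATE = 2


@dataclass(frozen=True)
class SentencePair:
    """Two same-template sentences; rank 0 is the innermost (middle) pair."""

    template_id: int
    members: tuple[int, int]
    rank: int

    def __post_init__(self):
        if self.members[0] == self.members[1]:
            raise ValueError("pair members must be distinct")


@dataclass
class ListSet:
    """An arrangement of sentences into equal-size lists.

    ``lists[i]`` is the i-th list as a sequence of (sentence_id, offset_db)
    entries; ``reference_mean_db`` is the midpoint mean the offsets were
    computed against.  ``cost``/``iteration``/``seed`` record where the
    arrangement came from; ``iteration_log`` holds every candidate's cost.
    """

    lists: list[list[tuple[int, float]]]
    reference_mean_db: float
    cost: float = float("nan")
    iteration: int = 0
    seed: Optional[int] = None
    iteration_log: list[float] = field(default_factory=list, repr=False)

    @property
    def n_lists(self) -> int:
        return len(self.lists)

    def sentence_ids(self) -> list[int]:
        return [sid for lst in self.lists for sid, _ in lst]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: list_number (1-based), sentence_number, offset_db."""
        rows = [
            (i + 1, sid, off)
            for i, lst in enumerate(self.lists)
            for sid, off in lst
        ]
        return pd.DataFrame(rows, columns=["list_number", "sentence_number", "offset_db"])


def max_list_count(per_template_counts: Sequence[int],
                   per_list_per_template: int = PER_LIST_PER_TEMPLATE) -> int:
    """Largest number of lists supportable by the scarcest template."""
    counts = [int(c) for c in per_template_counts]
    if any(c < 0 for c in counts):
        raise ValueError("negative template count")
    return min(counts) // per_list_per_template


def pair_by_offset(records: pd.DataFrame, n_pairs: int,
                   rng: np.random.Generator) -> list[SentencePair]:
    """Middle-out pairing of one template's sentences by offset.

    ``records`` needs columns sentence_id, template_id and offset_db (or
    midpoint_db, an equivalent sort key).  If more than 2*n_pairs sentences
    are available, a uniform seeded subsample is taken first.  With the
    selection sorted ascending as s_1..s_2m, the pair of rank j is
    (s_{m-j}, s_{m+1+j}) for j = 0..m-1: rank 0 is the central pair and the
    last pair joins the minimum and maximum offsets.
    """
    if len(records) < 2 * n_pairs:
        raise ValueError(
            f"need {2 * n_pairs} sentences for {n_pairs} pairs, have {len(records)}"
        )
    template_ids = records["template_id"].unique()
    if len(template_ids) != 1:
        raise ValueError("pair_by_offset expects sentences of a single template")
    key = "offset_db" if "offset_db" in records.columns else "midpoint_db"
    # tie-break on sentence_id for a deterministic sort
    df = records.sort_values([key, "sentence_id"], kind="mergesort")
    if len(df) > 2 * n_pairs:
        take = np.sort(rng.choice(len(df), size=2 * n_pairs, replace=False))
        df = df.iloc[take]
    ids = df["sentence_id"].to_numpy()
    m = n_pairs
    return [
        SentencePair(int(template_ids[0]), (int(ids[m - 1 - j]), int(ids[m + j])), j)
        for j in range(m)
    ]


def assign_pairs_to_lists(pairs_by_template: dict[int, list[SentencePair]],
                          n_lists: int, rng: np.random.Generator,
                          offsets: Optional[dict[int, float]] = None,
                          reference_mean_db: float = float("nan")) -> ListSet:
    """Distribute each template's pairs over lists by a seeded permutation.

    Every template must contribute exactly ``n_lists`` pairs; both members
    of a pair land in the same list.  ``offsets`` maps sentence_id to its
    offset (0.0 when omitted).
    """
    lists: list[list[tuple[int, float]]] = [[] for _ in range(n_lists)]
    offsets = offsets or {}
    for template_id in sorted(pairs_by_template):
        pairs = pairs_by_template[template_id]
        if len(pairs) != n_lists:
            raise ValueError(
                f"template {template_id}: {len(pairs)} pairs for {n_lists} lists"
            )
        perm = rng.permutation(n_lists)
        for pair, dest in zip(pairs, perm):
            for sid in pair.members:
                lists[dest].append((sid, float(offsets.get(sid, 0.0))))
    return ListSet(lists=lists, reference_mean_db=reference_mean_db)


def cost(list_set: ListSet, corpus: pd.DataFrame,
         weights: tuple[float, float] = (1.0, 1.0), ddof: int = 1) -> float:
    """Dispersion cost: weighted sum of the across-list SDs of the per-list
    mean slope and mean offset (sample SD, n-1 denominator by default)."""
    if list_set.n_lists < 2:
        raise ValueError("cost needs at least 2 lists (SD undefined)")
    slope_by_id = corpus.set_index("sentence_id")["slope_pct_per_db"]
    mean_slopes, mean_offsets = [], []
    for lst in list_set.lists:
        sids = [sid for sid, _ in lst]
        missing = [s for s in sids if s not in slope_by_id.index]
        if missing:
            raise ValueError(f"sentences absent from corpus: {missing[:5]}")
        mean_slopes.append(float(slope_by_id.loc[sids].mean()))
        mean_offsets.append(float(np.mean([off for _, off in lst])))
    w_slope, w_offset = weights
    return float(
        w_slope * np.std(mean_slopes, ddof=ddof)
        + w_offset * np.std(mean_offsets, ddof=ddof)
    )


def optimize_lists(corpus: pd.DataFrame, n_lists: int, n_iter: int = 1000,
                   seed: Optional[int] = None,
                   weights: tuple[float, float] = (1.0, 1.0),
                   ddof: int = 1) -> ListSet:
    """Best-of-``n_iter`` random list arrangement under the dispersion cost.

    Each iteration independently (a) subsamples and middle-out pairs each
    template's sentences, (b) recomputes the reference mean midpoint over
    the 20*n_lists selected sentences and their offsets, (c) permutes pairs
    onto lists, and (d) evaluates the cost.  The lowest-cost iteration wins;
    ties go to the earliest.  Bit-for-bit reproducible under a fixed seed.
    """
    counts = corpus.groupby("template_id")["sentence_id"].count()
    templates = sorted(counts.index)
    feasible = max_list_count(counts.reindex(templates).to_numpy())
    if n_lists > feasible or n_lists < 1:
        raise ValueError(
            f"cannot build {n_lists} lists: template counts support at most "
            f"{feasible} (scarcest template has {counts.min()} sentences)"
        )
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    rng = np.random.default_rng(seed)
    by_template = {t: corpus.loc[corpus["template_id"] == t] for t in templates}
    midpoint_by_id = corpus.set_index("sentence_id")["midpoint_db"]

    best: Optional[ListSet] = None
    log: list[float] = []
    for it in range(n_iter):
        pairs_by_template = {
            t: pair_by_offset(by_template[t], n_lists, rng) for t in templates
        }
        selected = [
            sid
            for t in templates
            for pair in pairs_by_template[t]
            for sid in pair.members
        ]
        reference = float(midpoint_by_id.loc[selected].mean())
        offsets = (midpoint_by_id.loc[selected] - reference).to_dict()
        candidate = assign_pairs_to_lists(
            pairs_by_template, n_lists, rng, offsets, reference
        )
        candidate.cost = cost(candidate, corpus, weights=weights, ddof=ddof)
        candidate.iteration = it
        log.append(candidate.cost)
        if best is None or candidate.cost < best.cost:
            best = candidate
    assert best is not None
    best.seed = seed
    best.iteration_log = log
    return best
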