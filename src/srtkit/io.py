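"""CSV formats, run configuration, and the bundled example list.

Every file written by the toolkit starts with a provenance comment line
(``# srtkit <version> ...``) that all readers here — and pandas with
``comment='#'`` — skip.  The list-definition format is the deposited
convention: columns list_number, sentence_number, offset_db, comma
separated, dot decimal, offsets printed with one decimal place (full
precision is kept in memory; serialization is the quantizing step).
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .corpus_filter import REQUIRED_COLUMNS
from .list_optimizer import ListSet, SENTENCES_PER_LIST
from .psychometrics import TrialObservation

__all__ = [
    "RunConfig",
    "write_list_csv",
    "read_list_csv",
    "write_corpus_csv",
    "read_corpus_csv",
    "write_study_csv",
    "read_study_csv",
    "write_trials_csv",
    "read_trials_csv",
    "load_example_list",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]

#: Accepted aliases for list-definition columns (deposited headers vary).
LIST_COLUMN_ALIASES = {
    "list_number": ("list_number", "list", "list_id"),
    "sentence_number": ("sentence_number", "sentence", "sentence_id"),
    "offset_db": ("offset_db", "offset", "offset_dB"),
}


def _provenance(seed: Optional[int] = None, extra: str = "") -> str:
    parts = [f"# srtkit {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return " ".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path: PathLike, seed: Optional[int] = None,
               extra: str = "", float_format: Optional[str] = None) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=float_format)
    Path(path).write_text(_provenance(seed, extra) + buf.getvalue(), encoding="utf-8")


# -- list definitions -----------------------------------------------------


def write_list_csv(list_set: ListSet, path: PathLike) -> None:
    """Export a list set in the deposited CSV convention (1-decimal offsets)."""
    df = list_set.to_frame()
    df["offset_db"] = df["offset_db"].round(1)
    extra = ""
    if list_set.reference_mean_db == list_set.reference_mean_db:  # not NaN
        extra = f"reference_mean_db={list_set.reference_mean_db:.4f}"
    _write_csv(df, path, seed=list_set.seed, extra=extra, float_format="%.1f")


def read_list_csv(path: PathLike,
                  list_size: int = SENTENCES_PER_LIST) -> ListSet:
    """Read and validate a list-definition CSV back into a :class:`ListSet`.

    Validation errors name the offending row or list: duplicate
    (list, sentence) rows, non-numeric offsets, and lists whose size is
    not ``list_size`` are all rejected.
    """
    text = Path(path).read_text(encoding="utf-8")
    seed = reference = None
    for line in text.splitlines():
        if line.startswith("#"):
            for token in line.split():
                if token.startswith("seed="):
                    seed = int(token[5:])
                if token.startswith("reference_mean_db="):
                    reference = float(token[18:])
        break
    df = pd.read_csv(_io.StringIO(text), comment="#")
    rename = {}
    for canon, aliases in LIST_COLUMN_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                rename[a] = canon
                break
        else:
            raise ValueError(f"list CSV missing a '{canon}' column")
    df = df.rename(columns=rename)

    offs = pd.to_numeric(df["offset_db"], errors="coerce")
    bad = df.loc[offs.isna()]
    if len(bad):
        raise ValueError(f"non-numeric offset at row(s) {bad.index.tolist()[:5]}")
    df["offset_db"] = offs

    dup = df.duplicated(subset=["list_number", "sentence_number"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate entry: list {first['list_number']} sentence "
            f"{first['sentence_number']}"
        )
    lists = []
    for list_number, grp in df.groupby("list_number", sort=True):
        if len(grp) != list_size:
            raise ValueError(
                f"list {list_number} has {len(grp)} rows, expected {list_size}"
            )
        lists.append(
            [(int(r.sentence_number), float(r.offset_db)) for r in grp.itertuples()]
        )
    return ListSet(
        lists=lists,
        reference_mean_db=float("nan") if reference is None else reference,
        seed=seed,
    )


def load_example_list(list_size: int = SENTENCES_PER_LIST) -> pd.DataFrame:
    """The bundled reference list definition (with template ids), as a table."""
    with resources.files("srtkit.data").joinpath("example_list.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    if len(df) != list_size:
        raise ValueError("bundled example list is malformed")
    return df


# -- corpus and study tables ----------------------------------------------


def write_corpus_csv(corpus: pd.DataFrame, path: PathLike,
                     seed: Optional[int] = None) -> None:
    _write_csv(corpus[list(REQUIRED_COLUMNS)], path, seed=seed)


def read_corpus_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"corpus CSV missing columns: {missing}")
    df["quality_ok"] = df["quality_ok"].astype(bool)
    return df


def write_study_csv(results: pd.DataFrame, path: PathLike,
                    seed: Optional[int] = None) -> None:
    _write_csv(results, path, seed=seed)


def read_study_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    needed = {"participant_id", "presentation_order", "list_id", "is_training",
              "srt_db"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"study CSV missing columns: {sorted(missing)}")
    df["is_training"] = df["is_training"].astype(bool)
    return df


def write_trials_csv(trials, path: PathLike) -> None:
    """Write scored presentations as a trial-log CSV
    (snr_db, n_keywords, k_correct)."""
    df = pd.DataFrame(
        [
            (t.snr_db, t.n_keywords, t.k_correct)
            if isinstance(t, TrialObservation)
            else tuple(t)
            for t in trials
        ],
        columns=["snr_db", "n_keywords", "k_correct"],
    )
    _write_csv(df, path)


def read_trials_csv(path: PathLike) -> list[TrialObservation]:
    """Read a trial-log CSV (header required, dot decimal separator)."""
    df = pd.read_csv(path, comment="#")
    missing = {"snr_db", "n_keywords", "k_correct"} - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return [
        TrialObservation(float(r.snr_db), int(r.n_keywords), int(r.k_correct))
        for r in df.itertuples()
    ]


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings, serializable to a single YAML file."""

    seed: int = 0
    # corpus generation
    n_per_template: int = 120
    # optimizer
    n_lists: int = 44
    n_iter: int = 1000
    cost_weights: tuple[float, float] = (1.0, 1.0)
    # adaptive track
    start_snr_db: float = 0.0
    steps_db: tuple[float, float, float] = (5.0, 2.0, 1.0)
    se_threshold_db: float = 1.0
    scoring_rule: str = "majority"
    # study
    n_participants: int = 20
    n_training: int = 2
    listener_srt_sd_db: float = 0.5

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: PathLike) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("cost_weights", "steps_db"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: PathLike) -> None:
    Path(path).write_text(
        yaml.safe_dump(asdict(config), sort_keys=False), encoding="utf-8"
    )
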