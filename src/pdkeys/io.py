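"""Reading and writing keystroke logs and subject metadata.

The canonical keystroke format is a delimited text file with header
``subject_id,visit_index,key_id,press_time,release_time`` where times are
seconds as decimals and one file may hold many subjects and visits.  Other
dialects (different column names, millisecond timestamps, per-subject file
layouts such as the PhysioNet ``nqmitcsxpd`` archive) are described by a
:class:`DialectConfig` rather than hard-coded, because dataset dialects drift.

Timestamps are normalised to be session-relative: the reader subtracts each
session's first press time, since only the intervals matter to every
downstream statistic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KeystrokeEvent",
    "TypingSession",
    "SubjectMetadata",
    "DialectConfig",
    "ReadReport",
    "KeystrokeFormatError",
    "CANONICAL_DIALECT",
    "GROUPS",
    "FEATURE_TABLE_COLUMNS",
    "METADATA_COLUMNS",
    "read_sessions",
    "write_sessions",
    "select_first_visit",
    "read_metadata",
    "write_metadata",
    "write_feature_table",
    "read_feature_table",
    "normalize_key_id",
]

#: the three cohort labels, in canonical (severity) order
GROUPS = ("control", "de_novo_pd", "early_pd")

FEATURE_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "hl_sd",
    "il_sd",
    "pl_sd",
    "rl_sd",
    "sd_restricted",
    "typing_speed",
    "word_count",
    "updrs3",
    "stap",
    "aftap",
    "nqi",
]

METADATA_COLUMNS = ["subject_id", "group", "updrs3", "stap", "aftap", "nqi", "visit_index"]

#: common raw labels for special (non-printing) keys, mapped to canonical names
_SPECIAL_KEYS = {
    " ": "space",
    "spacebar": "space",
    "space_bar": "space",
    "bksp": "backspace",
    "back_space": "backspace",
    "del": "delete",
    "esc": "escape",
    "return": "enter",
    "cr": "enter",
    "lshift": "shift",
    "rshift": "shift",
    "shift_l": "shift",
    "shift_r": "shift",
    "lctrl": "ctrl",
    "rctrl": "ctrl",
    "control": "ctrl",
    "lalt": "alt",
    "ralt": "alt",
    "caps_lock": "capslock",
}


class KeystrokeFormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


def normalize_key_id(raw: str) -> str:
    """Normalise a raw key label: lower-case, canonical names for specials."""
    key = str(raw).strip().lower()
    if key == "" and str(raw) != "":
        # a literal space character was the label
        key = "space"
    return _SPECIAL_KEYS.get(key, key)


@dataclass(frozen=True)
class KeystrokeEvent:
    """One keystroke: press and release instants of a single key, in seconds."""

    key_id: str
    press_time: float
    release_time: float

    def __post_init__(self) -> None:
        if not self.key_id:
            raise ValueError("key_id must be non-empty")
        if self.release_time < self.press_time:
            raise ValueError(
                f"release_time ({self.release_time}) precedes press_time ({self.press_time})"
            )

    @property
    def hold(self) -> float:
        return self.release_time - self.press_time


@dataclass(frozen=True)
class ReadReport:
    """Per-session account of what the reader accepted and rejected."""

    n_rows: int = 0
    n_rejected_negative_hold: int = 0


@dataclass
class TypingSession:
    """Ordered keystroke events for one subject and visit.

    Events are kept sorted ascending by press time (ties broken by release
    time, then key id), so the event order is invariant under input row
    shuffling.
    """

    subject_id: str
    visit_index: int
    events: list[KeystrokeEvent]
    source: str = "synthetic"
    read_report: ReadReport = field(default_factory=ReadReport)

    def __post_init__(self) -> None:
        if self.visit_index < 1:
            raise ValueError("visit_index must be >= 1")
        self.events = sorted(
            self.events, key=lambda e: (e.press_time, e.release_time, e.key_id)
        )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def press_times(self) -> np.ndarray:
        return np.array([e.press_time for e in self.events], dtype=float)

    @property
    def release_times(self) -> np.ndarray:
        return np.array([e.release_time for e in self.events], dtype=float)

    @property
    def key_ids(self) -> list[str]:
        return [e.key_id for e in self.events]


@dataclass(frozen=True)
class SubjectMetadata:
    """Clinical covariates for one subject.

    Missing values are ``nan`` (or ``None`` at construction) and propagate as
    missing — never as zero.
    """

    subject_id: str
    group: str
    updrs3: float = math.nan
    stap: float = math.nan      # msec
    aftap: float = math.nan     # msec
    nqi: float = math.nan
    visit_index: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not math.isnan(self.updrs3) and self.updrs3 < 0:
            raise ValueError("updrs3 must be non-negative")


@dataclass(frozen=True)
class DialectConfig:
    """Mapping from a source file's columns to the canonical keystroke schema.

    Parameters
    ----------
    key_column, press_column, release_column
        Source column names (or, for headerless files, 0-based column indices
        given as strings of digits).
    unit
        Time unit of the source timestamps, ``"s"`` or ``"ms"``.
    subject_column, visit_column
        Columns carrying subject and visit identity; when absent these are
        taken from the file name via ``filename_pattern`` or default to the
        file stem and visit 1.
    filename_pattern
        Optional regex with named groups ``subject`` and/or ``visit`` applied
        to the file stem (used by per-subject-file archives).
    delimiter, has_header
        Parsing details of the delimited source.
    """

    key_column: str = "key_id"
    press_column: str = "press_time"
    release_column: str = "release_time"
    unit: str = "s"
    subject_column: str | None = "subject_id"
    visit_column: str | None = "visit_index"
    filename_pattern: str | None = None
    delimiter: str = ","
    has_header: bool = True

    def __post_init__(self) -> None:
        if self.unit not in ("s", "ms"):
            raise ValueError("unit must be 's' or 'ms'")

    @property
    def time_scale(self) -> float:
        return 1e-3 if self.unit == "ms" else 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


CANONICAL_DIALECT = DialectConfig()


def _load_frame(path: Path, dialect: DialectConfig) -> pd.DataFrame:
    header = 0 if dialect.has_header else None
    df = pd.read_csv(path, sep=dialect.delimiter, header=header, dtype=str)
    if not dialect.has_header:
        df.columns = [str(i) for i in range(df.shape[1])]
    needed = [dialect.key_column, dialect.press_column, dialect.release_column]
    for opt in (dialect.subject_column, dialect.visit_column):
        if opt is not None and opt in df.columns:
            needed.append(opt)
    for col in (dialect.key_column, dialect.press_column, dialect.release_column):
        if col not in df.columns:
            raise KeystrokeFormatError(
                f"{path}: required column {col!r} not found (columns: {list(df.columns)})"
            )
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise KeystrokeFormatError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} "
            f"at line {line}"
        )
    return vals.to_numpy(dtype=float)


def read_sessions(
    path: str | Path, dialect: DialectConfig = CANONICAL_DIALECT
) -> list[TypingSession]:
    """Read keystroke logs into :class:`TypingSession` objects.

    Events whose release precedes their press are dropped and counted in the
    session's :class:`ReadReport`; timestamps are unit-normalised to seconds
    and re-based so each session starts at its first press.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _load_frame(path, dialect)

    press = _numeric(df, dialect.press_column, path) * dialect.time_scale
    release = _numeric(df, dialect.release_column, path) * dialect.time_scale
    keys = df[dialect.key_column].map(normalize_key_id)

    # subject / visit identity
    if dialect.subject_column and dialect.subject_column in df.columns:
        subjects = df[dialect.subject_column].astype(str)
    else:
        subjects = pd.Series([_subject_from_name(path, dialect)] * len(df))
    if dialect.visit_column and dialect.visit_column in df.columns:
        visits = pd.to_numeric(df[dialect.visit_column]).astype(int)
    else:
        visits = pd.Series([_visit_from_name(path, dialect)] * len(df))

    work = pd.DataFrame(
        {"subject": subjects, "visit": visits, "key": keys, "press": press, "release": release}
    )
    sessions: list[TypingSession] = []
    for (subj, visit), grp in work.groupby(["subject", "visit"], sort=True):
        ok = grp["release"] >= grp["press"]
        n_rejected = int((~ok).sum())
        grp = grp[ok]
        if grp.empty:
            continue
        t0 = float(grp["press"].min())
        events = [
            KeystrokeEvent(k, p - t0, r - t0)
            for k, p, r in zip(grp["key"], grp["press"], grp["release"])
        ]
        sessions.append(
            TypingSession(
                subject_id=str(subj),
                visit_index=int(visit),
                events=events,
                source=str(path),
                read_report=ReadReport(n_rows=len(grp) + n_rejected,
                                       n_rejected_negative_hold=n_rejected),
            )
        )
    return sessions


def _subject_from_name(path: Path, dialect: DialectConfig) -> str:
    if dialect.filename_pattern:
        m = re.match(dialect.filename_pattern, path.stem)
        if m and "subject" in m.groupdict():
            return m.group("subject")
    return path.stem


def _visit_from_name(path: Path, dialect: DialectConfig) -> int:
    if dialect.filename_pattern:
        m = re.match(dialect.filename_pattern, path.stem)
        if m and "visit" in (m.groupdict() or {}) and m.group("visit"):
            return int(m.group("visit"))
    return 1


def write_sessions(sessions: Iterable[TypingSession], path: str | Path) -> None:
    """Write sessions in the canonical CSV format (seconds, 6 decimals)."""
    rows = []
    for s in sessions:
        for e in s.events:
            rows.append((s.subject_id, s.visit_index, e.key_id, e.press_time, e.release_time))
    df = pd.DataFrame(
        rows, columns=["subject_id", "visit_index", "key_id", "press_time", "release_time"]
    )
    df.to_csv(path, index=False, float_format="%.6f")


def select_first_visit(sessions: Sequence[TypingSession]) -> list[TypingSession]:
    """Keep exactly one session per subject: the minimum visit index.

    Repeated typing tests show imprinting/adaptation effects, so analyses use
    each subject's first available test only.
    """
    seen: dict[tuple[str, int], TypingSession] = {}
    dups = []
    for s in sessions:
        key = (s.subject_id, s.visit_index)
        if key in seen:
            dups.append(key)
        seen[key] = s
    if dups:
        raise ValueError(f"duplicate (subject, visit) pairs: {sorted(set(dups))}")
    best: dict[str, TypingSession] = {}
    for s in sessions:
        if s.subject_id not in best or s.visit_index < best[s.subject_id].visit_index:
            best[s.subject_id] = s
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# metadata and feature tables


def read_metadata(path: str | Path) -> list[SubjectMetadata]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(["subject_id", "group"]) - set(df.columns)
    if missing:
        raise KeystrokeFormatError(f"{path}: metadata missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectMetadata(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                updrs3=_opt_float(row.get("updrs3")),
                stap=_opt_float(row.get("stap")),
                aftap=_opt_float(row.get("aftap")),
                nqi=_opt_float(row.get("nqi")),
                visit_index=int(row.get("visit_index", 1) if pd.notna(row.get("visit_index", 1)) else 1),
            )
        )
    return out


def write_metadata(metadata: Iterable[SubjectMetadata], path: str | Path) -> None:
    df = pd.DataFrame([m.__dict__ for m in metadata], columns=METADATA_COLUMNS)
    df.to_csv(path, index=False)


def _opt_float(v) -> float:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return math.nan
    return float(v)


def write_feature_table(records, path: str | Path) -> None:
    """Write per-subject feature records as a delimited table.

    One row per subject, stable column order, missing values rendered as
    empty fields.  Round-trips through :func:`read_feature_table` losslessly
    to the written precision.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        d = r if isinstance(r, Mapping) else r.__dict__
        rows.append({c: d.get(c) for c in FEATURE_TABLE_COLUMNS})
    pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise KeystrokeFormatError(f"{path}: feature table missing columns {sorted(missing)}")
    return df[FEATURE_TABLE_COLUMNS]
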