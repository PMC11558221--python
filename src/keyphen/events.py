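"""Keystroke metadata handling: typing sessions and daily backspace rates.

The mobile keyboard logs only keypress metadata: a UTC timestamp, the
user's IANA timezone, and a coarse key category (alphanumeric, backspace,
autocorrection, punctuation, autosuggestion, special). A typing session
ends after 6 seconds of keyboard inactivity. The daily backspace rate for
a subject is the number of backspace keypresses that local calendar day
divided by the total number of keypresses that day, a proportion in
[0, 1]; this is the observation the mixture model consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

#: The six key categories recorded by the keyboard.
CATEGORIES = (
    "alphanumeric",
    "backspace",
    "autocorrection",
    "punctuation",
    "autosuggestion",
    "special",
)

#: Default inactivity gap (seconds) that terminates a typing session.
SESSION_GAP_SECONDS = 6.0

EVENT_COLUMNS = ["subject_id", "session_id", "timestamp_utc", "timezone", "category"]
DAILY_COLUMNS = ["subject_id", "date", "n_keypresses", "n_backspaces", "rate"]


@dataclass(frozen=True)
class KeypressEvent:
    """A single keypress metadata record."""

    subject_id: str
    session_id: str
    timestamp_utc: datetime
    timezone: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown key category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass
class TypingSession:
    """A maximal run of keypresses with inter-key gaps <= the session gap."""

    session_id: str
    subject_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    events: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class DailyRate:
    """Per-subject-day keypress totals and the backspace rate.

    Backspaces count toward the denominator: ``rate = n_backspaces /
    n_keypresses`` where ``n_keypresses`` includes every keypress of any
    category that day.
    """

    subject_id: str
    local_date: object  # datetime.date
    n_keypresses: int
    n_backspaces: int

    @property
    def rate(self) -> float:
        return self.n_backspaces / self.n_keypresses

    def __post_init__(self) -> None:
        if self.n_keypresses <= 0:
            raise ValueError("a DailyRate requires at least one keypress")
        if not 0 <= self.n_backspaces <= self.n_keypresses:
            raise ValueError("n_backspaces must lie in [0, n_keypresses]")


def _as_event_frame(events) -> pd.DataFrame:
    """Normalize a list of KeypressEvent or a DataFrame to the event schema."""
    if isinstance(events, pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise ValueError(f"event table is missing columns {missing}")
        df = events.loc[:, EVENT_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "subject_id": e.subject_id,
                    "session_id": e.session_id,
                    "timestamp_utc": e.timestamp_utc,
                    "timezone": e.timezone,
                    "category": e.category,
                }
                for e in events
            ],
            columns=EVENT_COLUMNS,
        )
    ts = pd.to_datetime(df["timestamp_utc"], utc=True, errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp_utc'].iloc[bad]!r} at row {bad}"
        )
    df["timestamp_utc"] = ts
    bad_cat = ~df["category"].isin(CATEGORIES)
    if bad_cat.any():
        bad = int(np.flatnonzero(bad_cat.to_numpy())[0])
        raise ValueError(
            f"unknown key category {df['category'].iloc[bad]!r} at row {bad}; "
            f"expected one of {CATEGORIES}"
        )
    return df


def segment_sessions(events, gap_seconds: float = SESSION_GAP_SECONDS) -> list[TypingSession]:
    """Split one subject's ordered keypresses into typing sessions.

    Consecutive events more than ``gap_seconds`` apart fall into different
    sessions; a gap of exactly ``gap_seconds`` stays within the session
    (the keyboard dismisses *after* 6 seconds of inactivity). Unsorted
    input is stably sorted by timestamp first; duplicate timestamps are
    allowed.
    """
    df = _as_event_frame(events)
    if df.empty:
        return []
    if df["subject_id"].nunique() > 1:
        raise ValueError("segment_sessions expects events from a single subject")
    df = df.sort_values("timestamp_utc", kind="stable").reset_index(drop=True)
    gaps = df["timestamp_utc"].diff().dt.total_seconds().to_numpy()
    new_session = np.zeros(len(df), dtype=bool)
    new_session[0] = True
    new_session[1:] = gaps[1:] > gap_seconds
    ids = np.cumsum(new_session)
    subject = df["subject_id"].iloc[0]
    sessions = []
    for sid, chunk in df.groupby(ids, sort=True):
        sessions.append(
            TypingSession(
                session_id=f"{subject}-s{sid}",
                subject_id=subject,
                start=chunk["timestamp_utc"].iloc[0],
                end=chunk["timestamp_utc"].iloc[-1],
                events=chunk.reset_index(drop=True),
            )
        )
    return sessions


def aggregate_daily(
    events,
    min_keypresses: int = 1,
    include_categories: Sequence[str] = CATEGORIES,
) -> pd.DataFrame:
    """Compute per-subject daily backspace rates from keypress events.

    Days are bounded at local midnight in each event's recorded timezone.
    All categories in ``include_categories`` count toward the keypress
    denominator (default: all six, including backspaces themselves). Days
    with fewer than ``min_keypresses`` retained keypresses are omitted.

    Returns a DataFrame with columns ``subject_id, date, n_keypresses,
    n_backspaces, rate``.
    """
    if min_keypresses < 1:
        raise ValueError("min_keypresses must be >= 1")
    unknown = set(include_categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in include_categories: {sorted(unknown)}")
    df = _as_event_frame(events)
    df = df[df["category"].isin(include_categories)]
    if df.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)

    # Convert UTC instants to local calendar dates, one timezone at a time.
    local_date = pd.Series(index=df.index, dtype=object)
    for tz, idx in df.groupby("timezone").groups.items():
        ZoneInfo(tz)  # validates the zone name
        local = df.loc[idx, "timestamp_utc"].dt.tz_convert(tz)
        local_date.loc[idx] = local.dt.date
    df = df.assign(date=local_date)

    grouped = df.groupby(["subject_id", "date"], sort=True)
    out = grouped.agg(
        n_keypresses=("category", "size"),
        n_backspaces=("category", lambda c: int((c == "backspace").sum())),
    ).reset_index()
    out = out[out["n_keypresses"] >= min_keypresses].reset_index(drop=True)
    out["rate"] = out["n_backspaces"] / out["n_keypresses"]
    return out[DAILY_COLUMNS]


def read_events(path, format: str | None = None) -> pd.DataFrame:
    """Read a keypress event table from CSV or JSONL.

    ``format`` defaults to the file suffix (``.csv`` or ``.jsonl``). The
    file must carry the columns ``subject_id, session_id, timestamp_utc
    (ISO-8601), timezone, category``; malformed rows raise a ValueError
    naming the offending row.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        raw = pd.read_csv(path, dtype=str)
    elif fmt in ("jsonl", "json"):
        raw = pd.read_json(path, lines=True, dtype=str, convert_dates=False)
    else:
        raise ValueError(f"unsupported event file format {fmt!r}")
    return _as_event_frame(raw)


def write_events(events, path) -> None:
    """Write a keypress event table to CSV or JSONL (by suffix)."""
    df = _as_event_frame(events).copy()
    df["timestamp_utc"] = df["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_json(path, orient="records", lines=True)


def write_daily_rates(rates: pd.DataFrame, path) -> None:
    """Write a daily-rate table to CSV (subject_id, date, counts, rate)."""
    missing = [c for c in DAILY_COLUMNS if c not in rates.columns]
    if missing:
        raise ValueError(f"daily-rate table is missing columns {missing}")
    rates.loc[:, DAILY_COLUMNS].to_csv(path, index=False)


def read_daily_rates(path) -> pd.DataFrame:
    """Read a daily-rate CSV written by :func:`write_daily_rates`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"daily-rate file is missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    bad = (df["rate"] < 0) | (df["rate"] > 1) | df["rate"].isna()
    if bad.any():
        raise ValueError(f"rate outside [0, 1] at row {int(np.flatnonzero(bad)[0])}")
    return df[DAILY_COLUMNS]
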