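"""Raw proximity-logger records -> labelled 5-minute proximity events.

Proximity loggers store one record per encounter *per collar*, so a dyad
whose two collars were both retrieved contributes mirrored duplicates.
Pre-processing removes those duplicates, slices each encounter onto a fixed
grid of 5-minute intervals ("proximity events"), classifies each parent
encounter as 'active' (short) or 'passive' (long, sleep-like), and labels
every event with its day/night phase and aggregation period.

Records are plain pandas DataFrames with columns
``reporter, partner, start, duration_s``; events are DataFrames with columns
``dyad_a, dyad_b, interval_index, source_duration_s, context`` plus, after
phase labelling, ``date, phase, period``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["reporter", "partner", "start", "duration_s"]
EVENT_COLUMNS = ["dyad_a", "dyad_b", "interval_index", "source_duration_s", "context"]

#: encounters at or below this duration (seconds) are 'active', above 'passive'
DEFAULT_THRESHOLD_S = 1500
#: fixed 5-minute sampling interval
DEFAULT_INTERVAL_S = 300
#: shortest encounter a logger registers
MIN_DURATION_S = 11

DAY = "day"
NIGHT = "night"
ACTIVE = "active"
PASSIVE = "passive"


@dataclass(frozen=True)
class PhaseConfig:
    """Day/night boundaries over the study span.

    The study runs from ``day_start`` on ``start_date`` for ``n_days`` full
    day+night cycles: the night of date *d* spans dusk of *d* to dawn of
    *d + 1* and is one aggregation period, so the span holds ``2 * n_days``
    periods ordered day 0, night 0, day 1, ...  Interval starts are binned
    closed-left: an interval starting exactly at ``day_start`` is day.

    ``overrides`` maps a date to ``(day_start, day_end)`` clock times for
    that date, for sites where dawn/dusk drift matters.
    """

    start_date: dt.date
    n_days: int
    day_start: dt.time = dt.time(6, 0)
    day_end: dt.time = dt.time(19, 30)
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for d, (s, e) in self.bounds_items():
            if not s < e:
                raise ValueError(f"day_start must precede day_end on {d}")

    def bounds_items(self):
        out = [(None, (self.day_start, self.day_end))]
        out.extend((d, b) for d, b in self.overrides.items())
        return out

    def bounds(self, date: dt.date) -> tuple[dt.time, dt.time]:
        return self.overrides.get(date, (self.day_start, self.day_end))

    def date_of(self, index: int) -> dt.date:
        return self.start_date + dt.timedelta(days=index)

    @property
    def epoch(self) -> pd.Timestamp:
        """Origin of the 5-minute interval grid: first dawn of the study."""
        s, _ = self.bounds(self.start_date)
        return pd.Timestamp(dt.datetime.combine(self.start_date, s))

    @property
    def span_end(self) -> pd.Timestamp:
        d = self.date_of(self.n_days)
        s, _ = self.bounds(d)
        return pd.Timestamp(dt.datetime.combine(d, s))

    @property
    def n_periods(self) -> int:
        return 2 * self.n_days

    def period_bounds(self, period: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        day_index, is_night = divmod(period, 2)
        if not 0 <= period < self.n_periods:
            raise ValueError(f"period {period} outside study span")
        date = self.date_of(day_index)
        s, e = self.bounds(date)
        if not is_night:
            return (
                pd.Timestamp(dt.datetime.combine(date, s)),
                pd.Timestamp(dt.datetime.combine(date, e)),
            )
        nxt = self.date_of(day_index + 1)
        s2, _ = self.bounds(nxt)
        return (
            pd.Timestamp(dt.datetime.combine(date, e)),
            pd.Timestamp(dt.datetime.combine(nxt, s2)),
        )

    def n_slots(self, period: int, interval_s: int = DEFAULT_INTERVAL_S) -> int:
        lo, hi = self.period_bounds(period)
        return int(np.ceil((hi - lo).total_seconds() / interval_s))

    def locate(self, ts: pd.Timestamp) -> tuple[dt.date, str, int]:
        """Return (period date, phase, period id) for a timestamp."""
        ts = pd.Timestamp(ts)
        if ts < self.epoch or ts >= self.span_end:
            raise ValueError(f"timestamp {ts} outside configured study span")
        date = ts.date()
        s, e = self.bounds(date)
        t = ts.time()
        if t < s:  # before dawn: previous date's night
            date = date - dt.timedelta(days=1)
            phase = NIGHT
        elif t < e:
            phase = DAY
        else:
            phase = NIGHT
        day_index = (date - self.start_date).days
        period = 2 * day_index + (1 if phase == NIGHT else 0)
        return date, phase, period


def validate_records(records: pd.DataFrame, roster=None) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if len(records) == 0:
        return
    if (records["reporter"] == records["partner"]).any():
        raise ValueError("record with reporter == partner")
    if (records["duration_s"] <= 0).any():
        raise ValueError("non-positive duration in records")
    if roster is not None:
        known = set(roster)
        ids = set(records["reporter"]) | set(records["partner"])
        unknown = ids - known
        if unknown:
            raise ValueError(f"records reference unknown individuals: {sorted(unknown)}")


def deduplicate(records: pd.DataFrame, retrieved: set, seed: int) -> pd.DataFrame:
    """Drop mirrored duplicates from dyads where both collars were retrieved.

    For each such dyad and each calendar date, records stored by one of the
    two collars are discarded, the side chosen uniformly at random (but
    reproducibly under ``seed``).  A dyad with one lost collar keeps the
    surviving collar's records untouched.
    """
    validate_records(records)
    if len(records) == 0:
        return records.copy()
    ids = set(records["reporter"]) | set(records["partner"])
    unknown = ids - set(retrieved)
    bad = set(records["reporter"]) - set(retrieved)
    if bad:
        raise ValueError(
            f"records stored by non-retrieved collars: {sorted(bad)}"
        )
    del unknown
    rec = records.copy()
    a = np.minimum(rec["reporter"], rec["partner"])
    b = np.maximum(rec["reporter"], rec["partner"])
    date = pd.to_datetime(rec["start"]).dt.date
    both = rec["partner"].isin(retrieved)
    keys = pd.DataFrame({"a": a, "b": b, "date": date})
    uniq = keys[both.to_numpy()].drop_duplicates().sort_values(["a", "b", "date"])
    rng = np.random.default_rng(seed)
    # chosen side: 0 -> keep records reported by the lexicographically
    # smaller id, 1 -> by the larger
    pick = rng.integers(0, 2, size=len(uniq))
    keep_reporter = np.where(pick == 0, uniq["a"], uniq["b"])
    chosen = dict(zip(map(tuple, uniq.to_numpy()), keep_reporter))
    key_tuples = list(map(tuple, keys.to_numpy()))
    keep = np.array(
        [
            (not bo) or (rep == chosen[k])
            for bo, rep, k in zip(both.to_numpy(), rec["reporter"], key_tuples)
        ]
    )
    return rec[keep].reset_index(drop=True)


def classify_context(duration_s, threshold_s: int = DEFAULT_THRESHOLD_S):
    """'active' for encounters <= threshold (default 25 min), else 'passive'."""
    arr = np.asarray(duration_s)
    out = np.where(arr <= threshold_s, ACTIVE, PASSIVE)
    return out.item() if np.isscalar(duration_s) else out


def discretize(
    records: pd.DataFrame,
    epoch: pd.Timestamp,
    interval_s: int = DEFAULT_INTERVAL_S,
    threshold_s: int = DEFAULT_THRESHOLD_S,
) -> pd.DataFrame:
    """Slice records onto the 5-minute grid; one event per (dyad, slot).

    A record generates an event for every slot it overlaps by at least one
    second.  Events inherit the active/passive context of their parent
    record (classified on the raw encounter duration).  Duplicate
    (dyad, slot) events from overlapping same-dyad records are merged,
    keeping the longest parent's attributes.
    """
    validate_records(records)
    if len(records) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if (records["duration_s"] <= 0).any():
        raise ValueError("non-positive duration")
    start_off = (
        (pd.to_datetime(records["start"]) - pd.Timestamp(epoch)).dt.total_seconds()
    ).to_numpy()
    dur = records["duration_s"].to_numpy()
    first = np.floor_divide(start_off, interval_s).astype(np.int64)
    last = np.floor_divide(start_off + dur - 1, interval_s).astype(np.int64)
    counts = (last - first + 1).astype(np.int64)
    rep_idx = np.repeat(np.arange(len(records)), counts)
    slots = np.concatenate([np.arange(f, l + 1) for f, l in zip(first, last)])
    a = np.minimum(records["reporter"], records["partner"]).to_numpy()
    b = np.maximum(records["reporter"], records["partner"]).to_numpy()
    ev = pd.DataFrame(
        {
            "dyad_a": a[rep_idx],
            "dyad_b": b[rep_idx],
            "interval_index": slots,
            "source_duration_s": dur[rep_idx],
        }
    )
    ev["context"] = classify_context(ev["source_duration_s"].to_numpy(), threshold_s)
    ev = (
        ev.sort_values("source_duration_s")
        .drop_duplicates(["dyad_a", "dyad_b", "interval_index"], keep="last")
        .sort_values(["interval_index", "dyad_a", "dyad_b"])
        .reset_index(drop=True)
    )
    return ev


def label_phase(
    events: pd.DataFrame,
    phase_config: PhaseConfig,
    interval_s: int = DEFAULT_INTERVAL_S,
) -> pd.DataFrame:
    """Attach period date, day/night phase and ordered period id to events.

    Phase is decided by the interval *start* time (closed-left at dawn and
    dusk); intervals between midnight and dawn belong to the preceding
    date's night period.
    """
    ev = events.copy()
    if len(ev) == 0:
        for c in ("date", "phase", "period"):
            ev[c] = pd.Series([], dtype=object)
        return ev
    epoch = phase_config.epoch
    starts = epoch + pd.to_timedelta(ev["interval_index"] * interval_s, unit="s")
    located = [phase_config.locate(ts) for ts in starts]
    ev["date"] = [d for d, _, _ in located]
    ev["phase"] = [p for _, p, _ in located]
    ev["period"] = np.array([pid for _, _, pid in located], dtype=np.int64)
    return ev


def preprocess_records(
    records: pd.DataFrame,
    retrieved: set,
    phase_config: PhaseConfig,
    seed: int,
    interval_s: int = DEFAULT_INTERVAL_S,
    threshold_s: int = DEFAULT_THRESHOLD_S,
) -> pd.DataFrame:
    """Full pre-processing chain: deduplicate -> discretize -> label."""
    deduped = deduplicate(records, retrieved, seed)
    ev = discretize(deduped, phase_config.epoch, interval_s, threshold_s)
    return label_phase(ev, phase_config, interval_s)
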