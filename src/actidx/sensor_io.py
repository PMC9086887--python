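"""Reading, validation and alignment of the study's input artifacts.

Three artifacts describe one participant-day:

* an accelerometer stream — CSV with header ``t,x,y,z``; ``t`` in seconds
  since the start of the day, ``x``/``y``/``z`` in units of g;
* an activity diary — CSV with header ``time,category``; one row per
  30-minute slot between 06:00 and midnight, category drawn from a fixed
  5-value set (parent-reported context);
* optional contextual channels — CSV with header ``t,channel,value`` where
  ``channel`` is one of ``hr`` (heart rate, bpm), ``lat``/``lon`` (degrees)
  and ``bt_count`` (nearby Bluetooth device count).

A manifest CSV (``participant_id,group,day_index,medicated,accel_file,
diary_file,context_file``) ties the files of a cohort together.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("actidx")

# ---------------------------------------------------------------------------
# Constants: the diary taxonomy and the day grid
# ---------------------------------------------------------------------------

#: The five parent-reported activity categories.
CATEGORIES = ("sleeping", "sitting_quiet", "household", "exercise", "not_worn")

#: Categories whose motion data enter the analysis. Sleeping and not-worn
#: slots (and unlabeled time) are excluded from every feature, including
#: whole-day features.
ANALYSIS_CONTEXTS = ("sitting_quiet", "household", "exercise")

WHOLE_DAY = "whole_day"
UNLABELED = "unlabeled"

#: Diary window: 06:00 to 24:00 in minutes since midnight.
DAY_START_MIN = 360
DAY_END_MIN = 1440
SLOT_MIN = 30
N_SLOTS = (DAY_END_MIN - DAY_START_MIN) // SLOT_MIN  # 36

GROUPS = ("ADHD", "control")


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """A parsed artifact violates a domain invariant."""


class UsageError(ValueError):
    """Operations combined on mismatched or unusable inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorStream:
    """Tri-axial acceleration for one participant-day.

    ``t`` is seconds since the start of the day, strictly increasing;
    ``x``/``y``/``z`` are in g. ``sample_rate_hz`` is nominal metadata: the
    stream flags (but tolerates) a median inter-sample gap more than 20% away
    from ``1/sample_rate_hz``.
    """

    participant_id: str
    day_index: int
    sample_rate_hz: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        t = np.asarray(self.t, dtype=float)
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError("timestamps must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(np.asarray(self.t).size)

    @property
    def rate_consistent(self) -> bool:
        """True when the median gap matches the nominal rate within 20%."""
        if len(self) < 2:
            return True
        gap = float(np.median(np.diff(self.t)))
        return abs(gap - 1.0 / self.sample_rate_hz) <= 0.2 / self.sample_rate_hz


@dataclass(frozen=True)
class ContextStream:
    """Optional contextual channels for one participant-day.

    Each channel is independently optional (``None`` when absent):
    ``heart_rate`` and ``bluetooth_counts`` are ``(t, value)`` arrays,
    ``locations`` is ``(t, lat, lon)``. Timestamps are nondecreasing.
    """

    heart_rate: tuple[np.ndarray, np.ndarray] | None = None
    locations: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    bluetooth_counts: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name in ("heart_rate", "locations", "bluetooth_counts"):
            chan = getattr(self, name)
            if chan is None:
                continue
            t = np.asarray(chan[0], dtype=float)
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValidationError(f"{name} timestamps must be nondecreasing")

    @property
    def empty(self) -> bool:
        return all(
            c is None or np.asarray(c[0]).size == 0
            for c in (self.heart_rate, self.locations, self.bluetooth_counts)
        )


@dataclass(frozen=True)
class DiaryEntry:
    """One 30-minute diary slot: start (minutes since midnight) + category."""

    slot_start: int
    category: str

    def __post_init__(self) -> None:
        if self.slot_start % SLOT_MIN != 0:
            raise ValidationError(f"slot_start {self.slot_start} not on the 30-min grid")
        if not (DAY_START_MIN <= self.slot_start <= DAY_END_MIN - SLOT_MIN):
            raise ValidationError(f"slot_start {self.slot_start} outside 06:00-24:00")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ActivityDiary:
    participant_id: str
    day_index: int
    entries: tuple[DiaryEntry, ...]

    def __post_init__(self) -> None:
        starts = [e.slot_start for e in self.entries]
        if len(set(starts)) != len(starts):
            raise ValidationError("duplicate diary slots")
        if len(self.entries) > N_SLOTS:
            raise ValidationError("more than 36 diary entries")

    def category_by_slot(self) -> dict[int, str]:
        return {e.slot_start: e.category for e in self.entries}


@dataclass(frozen=True)
class DayRecord:
    """One study day of one participant: sensors + diary + medication flag."""

    day_index: int
    stream: SensorStream
    diary: ActivityDiary
    context: ContextStream | None = None
    medicated: bool = False


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    days: tuple[DayRecord, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.group == "control" and any(d.medicated for d in self.days):
            raise ValidationError("control participants have no medicated days")


@dataclass(frozen=True)
class StudyDataset:
    participants: tuple[ParticipantRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            {p.participant_id: p.group for p in self.participants}, name="group"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _as_text_buffer(source) -> io.StringIO | Path:
    """Accept a path or raw CSV text (anything containing a newline)."""
    if isinstance(source, (io.StringIO, io.TextIOBase)):
        return source
    s = os.fspath(source) if isinstance(source, Path) else source
    if isinstance(s, str) and "\n" in s:
        return io.StringIO(s)
    return Path(s)


def read_accel_csv(
    source, participant_id: str, day_index: int, sample_rate_hz: float = 50.0
) -> SensorStream:
    """Parse an accelerometer CSV (header ``t,x,y,z``) into a SensorStream.

    Rows containing non-finite values are dropped and counted in a warning;
    rows are stably sorted by ``t`` and duplicate timestamps rejected.
    """
    try:
        df = pd.read_csv(_as_text_buffer(source), float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"unreadable accelerometer CSV: {exc}") from exc
    if list(df.columns) != ["t", "x", "y", "z"]:
        raise FormatError(f"expected header t,x,y,z, got {list(df.columns)}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning(
            "%s day %d: dropped %d non-finite accelerometer rows",
            participant_id,
            day_index,
            n_dropped,
        )
    values = values[finite]
    order = np.argsort(values[:, 0], kind="stable")
    values = values[order]
    if values.shape[0] > 1 and np.any(np.diff(values[:, 0]) <= 0):
        raise FormatError("duplicate timestamps: t not strictly increasing after sort")
    return SensorStream(
        participant_id=participant_id,
        day_index=day_index,
        sample_rate_hz=sample_rate_hz,
        t=values[:, 0],
        x=values[:, 1],
        y=values[:, 2],
        z=values[:, 3],
    )


def write_accel_csv(stream: SensorStream, path) -> None:
    """Write a stream using shortest round-trip float formatting."""
    with open(path, "w") as fh:
        fh.write("t,x,y,z\n")
        for t, x, y, z in zip(stream.t, stream.x, stream.y, stream.z):
            # float() gives the shortest round-trip repr (plain Python float)
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(z)!r}\n")


def _parse_hhmm(text: str) -> int:
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise FormatError(f"bad time {text!r}, expected HH:MM")
    try:
        h, m = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(f"bad time {text!r}") from exc
    if not (0 <= h <= 23 and 0 <= m <= 59):
        raise FormatError(f"time {text!r} out of range")
    return h * 60 + m


def read_diary(source, participant_id: str, day_index: int) -> ActivityDiary:
    """Parse a diary CSV (header ``time,category``; HH:MM on the 30-min grid)."""
    df = pd.read_csv(_as_text_buffer(source), dtype=str)
    if list(df.columns) != ["time", "category"]:
        raise FormatError(f"expected header time,category, got {list(df.columns)}")
    entries = tuple(
        DiaryEntry(slot_start=_parse_hhmm(row.time), category=str(row.category).strip())
        for row in df.itertuples()
    )
    return ActivityDiary(
        participant_id=participant_id, day_index=day_index, entries=entries
    )


def write_diary(diary: ActivityDiary, path) -> None:
    with open(path, "w") as fh:
        fh.write("time,category\n")
        for e in sorted(diary.entries, key=lambda e: e.slot_start):
            fh.write(f"{e.slot_start // 60:02d}:{e.slot_start % 60:02d},{e.category}\n")


CONTEXT_CHANNELS = ("hr", "lat", "lon", "bt_count")


def read_context_csv(source) -> ContextStream:
    """Parse a long-format context CSV (header ``t,channel,value``)."""
    df = pd.read_csv(_as_text_buffer(source), float_precision="round_trip")
    if list(df.columns) != ["t", "channel", "value"]:
        raise FormatError(f"expected header t,channel,value, got {list(df.columns)}")
    bad = set(df["channel"].unique()) - set(CONTEXT_CHANNELS)
    if bad:
        raise FormatError(f"unknown context channels {sorted(bad)}")

    def chan(name):
        sub = df[df["channel"] == name].sort_values("t", kind="stable")
        return sub["t"].to_numpy(float), sub["value"].to_numpy(float)

    t_hr, v_hr = chan("hr")
    t_lat, v_lat = chan("lat")
    t_lon, v_lon = chan("lon")
    t_bt, v_bt = chan("bt_count")
    if t_lat.size != t_lon.size or not np.array_equal(t_lat, t_lon):
        raise FormatError("lat and lon channels must share timestamps")
    return ContextStream(
        heart_rate=(t_hr, v_hr) if t_hr.size else None,
        locations=(t_lat, v_lat, v_lon) if t_lat.size else None,
        bluetooth_counts=(t_bt, v_bt) if t_bt.size else None,
    )


def write_context_csv(context: ContextStream, path) -> None:
    rows: list[tuple[float, str, float]] = []
    if context.heart_rate is not None:
        rows += [(t, "hr", v) for t, v in zip(*context.heart_rate)]
    if context.locations is not None:
        t, lat, lon = context.locations
        rows += [(ti, "lat", la) for ti, la in zip(t, lat)]
        rows += [(ti, "lon", lo) for ti, lo in zip(t, lon)]
    if context.bluetooth_counts is not None:
        rows += [(t, "bt_count", v) for t, v in zip(*context.bluetooth_counts)]
    rows.sort(key=lambda r: (r[0], CONTEXT_CHANNELS.index(r[1])))
    with open(path, "w") as fh:
        fh.write("t,channel,value\n")
        for t, c, v in rows:
            fh.write(f"{float(t)!r},{c},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Alignment and day filtering
# ---------------------------------------------------------------------------


def label_samples(stream: SensorStream, diary: ActivityDiary) -> np.ndarray:
    """Assign every sample the category of its covering 30-minute slot.

    Slots are half-open ``[start, start + 30 min)``; samples outside the
    diary window or in slots with no entry are labeled ``"unlabeled"``. The
    function is total: every sample receives exactly one category.
    """
    if (stream.participant_id, stream.day_index) != (
        diary.participant_id,
        diary.day_index,
    ):
        raise UsageError("stream and diary belong to different participant-days")
    labels = np.full(len(stream), UNLABELED, dtype=object)
    by_slot = diary.category_by_slot()
    minutes = np.asarray(stream.t, dtype=float) / 60.0
    slot_starts = (np.floor(minutes / SLOT_MIN) * SLOT_MIN).astype(int)
    for slot, cat in by_slot.items():
        labels[slot_starts == slot] = cat
    return labels


def filter_analysis_days(dataset: StudyDataset) -> StudyDataset:
    """Keep only unmedicated days for ADHD participants.

    Control participants are returned unchanged. An ADHD participant whose
    days are all medicated is retained with zero days; downstream feature
    extraction produces an all-missing row for them.
    """
    out = []
    for p in dataset.participants:
        if p.group == "ADHD":
            days = tuple(d for d in p.days if not d.medicated)
            out.append(replace(p, days=days))
        else:
            out.append(p)
    return StudyDataset(participants=tuple(out))


# ---------------------------------------------------------------------------
# Manifest-level loading / writing
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "participant_id",
    "group",
    "day_index",
    "medicated",
    "accel_file",
    "diary_file",
    "context_file",
]


def load_dataset(manifest_path, sample_rate_hz: float = 50.0) -> StudyDataset:
    """Load a whole cohort from a manifest CSV.

    File paths in the manifest are resolved relative to the manifest's
    directory. An empty ``context_file`` field means no contextual data.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise FormatError(
            f"expected manifest header {','.join(MANIFEST_COLUMNS)}, got {list(df.columns)}"
        )
    base = manifest_path.parent
    by_participant: dict[str, dict] = {}
    for row in df.itertuples():
        pid = str(row.participant_id)
        rec = by_participant.setdefault(pid, {"group": str(row.group), "days": []})
        if rec["group"] != str(row.group):
            raise ValidationError(f"{pid}: inconsistent group labels in manifest")
        day_index = int(row.day_index)
        for name in ("accel_file", "diary_file"):
            if not (base / str(getattr(row, name))).exists():
                raise FormatError(f"{pid} day {day_index}: missing file {getattr(row, name)}")
        stream = read_accel_csv(
            base / str(row.accel_file), pid, day_index, sample_rate_hz
        )
        diary = read_diary(base / str(row.diary_file), pid, day_index)
        context = None
        ctx_field = getattr(row, "context_file")
        if isinstance(ctx_field, str) and ctx_field.strip():
            ctx_path = base / ctx_field.strip()
            if not ctx_path.exists():
                raise FormatError(f"{pid} day {day_index}: missing file {ctx_field}")
            context = read_context_csv(ctx_path)
        rec["days"].append(
            DayRecord(
                day_index=day_index,
                stream=stream,
                diary=diary,
                context=context,
                medicated=bool(int(row.medicated)),
            )
        )
    participants = tuple(
        ParticipantRecord(
            participant_id=pid,
            group=rec["group"],
            days=tuple(sorted(rec["days"], key=lambda d: d.day_index)),
        )
        for pid, rec in by_participant.items()
    )
    return StudyDataset(participants=participants)


def write_dataset(dataset: StudyDataset, out_dir) -> Path:
    """Write a cohort as per-day CSVs plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in dataset.participants:
        for day in p.days:
            stem = f"{p.participant_id}_d{day.day_index}"
            accel = f"{stem}_accel.csv"
            diary = f"{stem}_diary.csv"
            write_accel_csv(day.stream, out_dir / accel)
            write_diary(day.diary, out_dir / diary)
            ctx = ""
            if day.context is not None and not day.context.empty:
                ctx = f"{stem}_context.csv"
                write_context_csv(day.context, out_dir / ctx)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "day_index": day.day_index,
                    "medicated": int(day.medicated),
                    "accel_file": accel,
                    "diary_file": diary,
                    "context_file": ctx,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
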