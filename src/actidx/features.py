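"""Participant-level feature matrix from labeled accelerometer streams.

Three motion-feature families are computed per window:

* **shape** — population skewness ``m3/m2^1.5`` and kurtosis ``m4/m2^2``
  (the type of motion);
* **summary** — mean, population variance, median, and mean magnitude
  (mean |value| per axis, mean Euclidean norm for the composite axis);
* **cumulative** — total variation ``sum |delta|`` (composite: norm of the
  delta vector), the total amount of motion in the window, insensitive to
  the static gravity offset.

Each statistic is computed for axes {X, Y, Z, composite} over non-overlapping
windows of 1, 5 and 10 minutes tiled on the 06:00-24:00 grid (window lengths
divide the 30-minute diary slot, so every window has a unique context). A
window is valid when at least 50% of its expected samples are present;
invalid windows carry no feature values.

Per participant, windows from all analysis days are pooled and aggregated
with MEAN and VARIANCE per context in {whole_day, sitting_quiet, household,
exercise}; whole_day is the union of the three analysis contexts (sleeping,
not-worn and unlabeled time never enter any feature). Hour-quantile features
(25/50/75% of the 1-minute cumulative motion within each clock hour,
averaged over hours) and optional context-sensor features (heart rate, GPS,
Bluetooth) complete the vector. Missing features are imputed with -1, the
pipeline's missing-data sentinel.

Column-name grammar: ``<family>__<stat>__<axis>__<win>s__<context>__<agg>``
(axis/window read ``na`` for sensor features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sensor_io import (
    ANALYSIS_CONTEXTS,
    DAY_START_MIN,
    DAY_END_MIN,
    SLOT_MIN,
    UNLABELED,
    WHOLE_DAY,
    ActivityDiary,
    ContextStream,
    SensorStream,
    StudyDataset,
    UsageError,
    label_samples,
)

WINDOW_LENGTHS_S = (60, 300, 600)
AXES = ("x", "y", "z", "composite")
CONTEXTS = (WHOLE_DAY,) + ANALYSIS_CONTEXTS
AGGREGATORS = ("mean", "var")
QUANTILES = (0.25, 0.5, 0.75)

DAY_START_S = DAY_START_MIN * 60.0
DAY_END_S = DAY_END_MIN * 60.0

#: per-window statistics by family
FAMILY_STATS = {
    "shape": ("skewness", "kurtosis"),
    "summary": ("mean", "variance", "median", "mean_magnitude"),
    "cumulative": ("motion",),
}
MOTION_FAMILIES = ("shape", "summary", "cumulative", "hourq")
SENSOR_FAMILIES = ("hr", "gps", "bt")

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks build_feature_matrix emits."""

    window_lengths_s: tuple[int, ...] = WINDOW_LENGTHS_S
    contexts: tuple[str, ...] = CONTEXTS
    include_hour_quantiles: bool = True
    include_context_sensors: bool = True
    center_windows: bool = False  # mean-center each window before moments

    def __post_init__(self) -> None:
        for L in self.window_lengths_s:
            if (SLOT_MIN * 60) % L != 0:
                raise UsageError(f"window length {L}s must divide the 30-min slot")


@dataclass
class FeatureMatrix:
    """Rectangular participants x features table plus group labels."""

    values: pd.DataFrame
    groups: pd.Series

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="participant_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="participant_id")
        groups = df.pop("group")
        return cls(values=df, groups=groups)


# ---------------------------------------------------------------------------
# Per-window scalar operations (reference API; windows are (n, 3) arrays)
# ---------------------------------------------------------------------------


def _axis_signal(window: np.ndarray, axis: str) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if axis == "composite":
        if window.shape[1] < 3:
            raise UsageError("composite axis needs (n, 3) windows")
        return np.sqrt((window[:, :3] ** 2).sum(axis=1))
    idx = {"x": 0, "y": 1, "z": 2}[axis]
    return window[:, min(idx, window.shape[1] - 1)]


def shape_features(window: np.ndarray, axis: str = "x") -> tuple[float, float]:
    """Population skewness and kurtosis; (0, 0) for (near-)constant signals.

    Returns (nan, nan) for windows with fewer than 3 samples.
    """
    v = _axis_signal(window, axis)
    if v.size < 3:
        return (float("nan"), float("nan"))
    v = v - v.mean()
    m2 = float(np.mean(v**2))
    if m2 < _VAR_EPS:
        return (0.0, 0.0)
    m3 = float(np.mean(v**3))
    m4 = float(np.mean(v**4))
    return (m3 / m2**1.5, m4 / m2**2)


def summary_features(
    window: np.ndarray, axis: str = "x"
) -> tuple[float, float, float, float]:
    """(mean, population variance, median, mean magnitude) of one window.

    For the composite axis all four statistics are computed on the Euclidean
    norm signal; mean magnitude is then the mean norm, while for single axes
    it is the mean absolute value. Returns all-nan for empty windows.
    """
    v = _axis_signal(window, axis)
    if v.size == 0:
        return (float("nan"),) * 4
    magnitude = float(np.mean(v)) if axis == "composite" else float(np.mean(np.abs(v)))
    return (float(np.mean(v)), float(np.var(v)), float(np.median(v)), magnitude)


def cumulative_motion(window: np.ndarray, axis: str = "x") -> float:
    """Total variation of the signal: sum over consecutive samples of |delta|.

    The composite axis sums the Euclidean norms of the delta vectors. A
    gravity offset contributes nothing. Returns nan for < 2 samples.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.shape[0] < 2:
        return float("nan")
    if axis == "composite":
        d = np.diff(window[:, :3], axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())
    return float(np.abs(np.diff(_axis_signal(window, axis))).sum())


def hour_quantiles(
    values_by_hour: dict[int, Sequence[float]], quantiles: Sequence[float] = QUANTILES
) -> tuple[float, ...]:
    """Day-level hour-quantile features of 1-minute cumulative motion.

    For each clock hour, take the requested quantiles (linear interpolation)
    of that hour's per-window values; the day-level feature is the mean over
    hours with at least one value. All-nan when no hour has values.
    """
    per_hour = [
        np.quantile(np.asarray(vals, dtype=float), quantiles)
        for vals in values_by_hour.values()
        if len(vals) > 0
    ]
    if not per_hour:
        return tuple(float("nan") for _ in quantiles)
    return tuple(float(v) for v in np.mean(per_hour, axis=0))


# ---------------------------------------------------------------------------
# Window segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    start_s: float
    length_s: int
    context: str
    valid: bool
    sample_slice: slice

    @property
    def hour(self) -> int:
        return int(self.start_s // 3600)


def segment_windows(
    stream: SensorStream, diary: ActivityDiary, length_s: int
) -> list[Window]:
    """Tile [06:00, 24:00) into non-overlapping windows of ``length_s``.

    Each window inherits the category of its covering diary slot (window
    lengths divide the slot, so the slot is unique); validity requires at
    least 50% of the expected ``length_s * rate`` samples.
    """
    if (SLOT_MIN * 60) % length_s != 0:
        raise UsageError(f"window length {length_s}s must divide the 30-min slot")
    n_win = int((DAY_END_S - DAY_START_S) / length_s)
    edges = DAY_START_S + length_s * np.arange(n_win + 1)
    t = np.asarray(stream.t, dtype=float)
    idx = np.searchsorted(t, edges, side="left")
    by_slot = diary.category_by_slot()
    expected = length_s * stream.sample_rate_hz
    windows = []
    for i in range(n_win):
        start = edges[i]
        slot = int(start // 60 // SLOT_MIN) * SLOT_MIN
        context = by_slot.get(slot, UNLABELED)
        count = idx[i + 1] - idx[i]
        windows.append(
            Window(
                start_s=float(start),
                length_s=length_s,
                context=context,
                valid=count >= 0.5 * expected,
                sample_slice=slice(int(idx[i]), int(idx[i + 1])),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Vectorized per-day window statistics
# ---------------------------------------------------------------------------


def _segment_sums(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sums of ``values`` over segments [idx[i], idx[i+1]) via cumsum."""
    c = np.concatenate([[0.0], np.cumsum(values)])
    return c[idx[1:]] - c[idx[:-1]]


def _day_cumsums(stream: SensorStream) -> dict:
    """Per-axis cumulative-sum arrays shared by all window lengths.

    Raw first moment feeds the window mean; higher moments are computed on
    the day-mean-centered signal (shift-invariant, numerically better
    behaved when the signal sits on a ~1 g gravity offset).
    """
    signals = {
        "x": np.asarray(stream.x, dtype=float),
        "y": np.asarray(stream.y, dtype=float),
        "z": np.asarray(stream.z, dtype=float),
    }
    signals["composite"] = np.sqrt(
        signals["x"] ** 2 + signals["y"] ** 2 + signals["z"] ** 2
    )
    dx, dy, dz = (np.diff(signals[a]) for a in ("x", "y", "z"))
    dnorm = np.sqrt(dx**2 + dy**2 + dz**2)

    def cs(v):
        return np.concatenate([[0.0], np.cumsum(v)])

    prep = {"signals": signals}
    for axis, v in signals.items():
        vc = v - (v.mean() if v.size else 0.0)
        vc2 = vc * vc
        d = dnorm if axis == "composite" else np.abs(np.diff(v))
        prep[axis] = {
            "s1": cs(v),
            "c1": cs(vc),
            "c2": cs(vc2),
            "c3": cs(vc2 * vc),
            "c4": cs(vc2 * vc2),
            "abs": None if axis == "composite" else cs(np.abs(v)),
            "dcum": cs(d),
        }
    return prep


def day_window_table(
    stream: SensorStream,
    diary: ActivityDiary,
    length_s: int,
    _prep: dict | None = None,
) -> pd.DataFrame:
    """All per-window statistics of one day for one window length.

    Returns a DataFrame with one row per window and one column per
    ``<stat>__<axis>`` pair plus window metadata (context, validity, hour,
    sample count). Equivalent to calling the scalar operations window by
    window, but computed with cumulative-sum segment reductions.
    """
    prep = _prep if _prep is not None else _day_cumsums(stream)
    signals = prep["signals"]
    windows = segment_windows(stream, diary, length_s)
    n_win = len(windows)
    idx = np.fromiter(
        (w.sample_slice.start for w in windows), dtype=np.int64, count=n_win
    )
    idx = np.append(idx, windows[-1].sample_slice.stop if n_win else 0)
    counts = np.diff(idx).astype(float)
    valid = np.array([w.valid for w in windows])

    def seg(cum):
        return cum[idx[1:]] - cum[idx[:-1]]

    out: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_n = np.where(counts > 0, counts, 1.0)
        for axis in AXES:
            p = prep[axis]
            mean = np.where(counts > 0, seg(p["s1"]) / safe_n, np.nan)
            c1 = seg(p["c1"]) / safe_n
            c2 = seg(p["c2"]) / safe_n
            c3 = seg(p["c3"]) / safe_n
            c4 = seg(p["c4"]) / safe_n
            m2 = np.maximum(c2 - c1**2, 0.0)
            m3 = c3 - 3 * c1 * c2 + 2 * c1**3
            m4 = c4 - 4 * c1 * c3 + 6 * c1**2 * c2 - 3 * c1**4
            variance = np.where(counts > 0, m2, np.nan)
            tiny = m2 < _VAR_EPS
            skew = np.where(tiny, 0.0, m3 / np.where(tiny, 1.0, m2) ** 1.5)
            kurt = np.where(tiny, 0.0, m4 / np.where(tiny, 1.0, m2) ** 2)
            skew = np.where(counts >= 3, skew, np.nan)
            kurt = np.where(counts >= 3, kurt, np.nan)
            if axis == "composite":
                magnitude = mean
            else:
                magnitude = np.where(counts > 0, seg(p["abs"]) / safe_n, np.nan)
            # total variation with window-boundary deltas excluded
            dcum = p["dcum"]
            lo = np.minimum(idx[:-1], dcum.size - 1)
            hi = np.clip(idx[1:] - 1, lo, dcum.size - 1)
            cum = np.where(counts >= 2, dcum[hi] - dcum[lo], np.nan)

            out[f"shape__skewness__{axis}"] = skew
            out[f"shape__kurtosis__{axis}"] = kurt
            out[f"summary__mean__{axis}"] = mean
            out[f"summary__variance__{axis}"] = variance
            out[f"summary__mean_magnitude__{axis}"] = magnitude
            out[f"cumulative__motion__{axis}"] = cum

    df = pd.DataFrame(out)
    # medians via a grouped C-level reduction
    win_id = np.repeat(np.arange(n_win), np.diff(idx))
    if win_id.size:
        med = (
            pd.DataFrame({a: signals[a] for a in AXES})
            .groupby(win_id)
            .median()
            .reindex(np.arange(n_win))
        )
    else:
        med = pd.DataFrame(np.nan, index=np.arange(n_win), columns=list(AXES))
    for axis in AXES:
        df[f"summary__median__{axis}"] = med[axis].to_numpy()

    df[df.columns] = df.to_numpy() * np.where(valid, 1.0, np.nan)[:, None]
    df["context"] = [w.context for w in windows]
    df["valid"] = valid
    df["hour"] = [w.hour for w in windows]
    df["count"] = counts
    df["length_s"] = length_s
    df["day_index"] = stream.day_index
    return df


def day_window_tables(
    stream: SensorStream, diary: ActivityDiary, lengths: Sequence[int] = WINDOW_LENGTHS_S
) -> list[pd.DataFrame]:
    """Window tables for several lengths sharing one cumulative-sum pass."""
    prep = _day_cumsums(stream)
    return [day_window_table(stream, diary, L, _prep=prep) for L in lengths]


# ---------------------------------------------------------------------------
# Context-sensor features
# ---------------------------------------------------------------------------

EARTH_RADIUS_M = 6_371_000.0


def radius_of_gyration(lat: np.ndarray, lon: np.ndarray) -> float:
    """RMS distance (meters) of location fixes from their centroid.

    Uses a local equirectangular approximation around the centroid, adequate
    for the within-city scales of a day of child activity.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return float("nan")
    lat0, lon0 = lat.mean(), lon.mean()
    dy = np.radians(lat - lat0) * EARTH_RADIUS_M
    dx = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    return float(np.sqrt(np.mean(dx**2 + dy**2)))


def modal_location_fraction(
    lat: np.ndarray, lon: np.ndarray, decimals: int = 4
) -> float:
    """Fraction of fixes at the most-visited location (grid-rounded ~11 m)."""
    lat = np.asarray(lat, dtype=float)
    if lat.size == 0:
        return float("nan")
    cells = list(zip(np.round(lat, decimals), np.round(lon, decimals)))
    _, counts = np.unique(np.asarray(cells), axis=0, return_counts=True)
    return float(counts.max() / lat.size)


def _timestamp_contexts(t: np.ndarray, diary: ActivityDiary) -> np.ndarray:
    labels = np.full(t.shape, UNLABELED, dtype=object)
    by_slot = diary.category_by_slot()
    slot_starts = (np.floor(np.asarray(t) / 60.0 / SLOT_MIN) * SLOT_MIN).astype(int)
    for slot, cat in by_slot.items():
        labels[slot_starts == slot] = cat
    return labels


def context_features(
    day_pairs: Sequence[tuple[ContextStream | None, ActivityDiary]],
) -> dict[str, float]:
    """Heart-rate, GPS and Bluetooth summaries pooled over analysis days.

    Heart rate: mean and population variance per context; Bluetooth: mean
    and max device count per context; GPS: radius of gyration and modal
    location fraction over the day (context-independent mobility summaries).
    Missing channels yield missing (nan) features.
    """
    hr_vals: dict[str, list[np.ndarray]] = {c: [] for c in CONTEXTS}
    bt_vals: dict[str, list[np.ndarray]] = {c: [] for c in CONTEXTS}
    lats: list[np.ndarray] = []
    lons: list[np.ndarray] = []
    for context, diary in day_pairs:
        if context is None:
            continue
        for store, chan in ((hr_vals, context.heart_rate), (bt_vals, context.bluetooth_counts)):
            if chan is None:
                continue
            t, v = np.asarray(chan[0]), np.asarray(chan[1])
            labels = _timestamp_contexts(t, diary)
            in_analysis = np.isin(labels, ANALYSIS_CONTEXTS)
            store[WHOLE_DAY].append(v[in_analysis])
            for c in ANALYSIS_CONTEXTS:
                store[c].append(v[labels == c])
        if context.locations is not None:
            t, la, lo = context.locations
            lats.append(np.asarray(la))
            lons.append(np.asarray(lo))

    out: dict[str, float] = {}
    for c in CONTEXTS:
        hv = np.concatenate(hr_vals[c]) if hr_vals[c] else np.empty(0)
        out[f"hr__mean__na__na__{c}__pooled"] = float(hv.mean()) if hv.size else float("nan")
        out[f"hr__variance__na__na__{c}__pooled"] = float(np.var(hv)) if hv.size else float("nan")
        bv = np.concatenate(bt_vals[c]) if bt_vals[c] else np.empty(0)
        out[f"bt__mean__na__na__{c}__pooled"] = float(bv.mean()) if bv.size else float("nan")
        out[f"bt__max__na__na__{c}__pooled"] = float(bv.max()) if bv.size else float("nan")
    la = np.concatenate(lats) if lats else np.empty(0)
    lo = np.concatenate(lons) if lons else np.empty(0)
    out["gps__radius_gyration__na__na__whole_day__pooled"] = radius_of_gyration(la, lo)
    out["gps__modal_fraction__na__na__whole_day__pooled"] = modal_location_fraction(la, lo)
    return out


# ---------------------------------------------------------------------------
# Participant-level aggregation
# ---------------------------------------------------------------------------


def feature_columns(config: FeatureConfig) -> list[str]:
    """Deterministic full column order implied by a FeatureConfig."""
    cols = []
    for family, stats in FAMILY_STATS.items():
        for stat in stats:
            for axis in AXES:
                for L in config.window_lengths_s:
                    for c in config.contexts:
                        for agg in AGGREGATORS:
                            cols.append(f"{family}__{stat}__{axis}__{L}s__{c}__{agg}")
    if config.include_hour_quantiles:
        for axis in AXES:
            for c in config.contexts:
                for q in QUANTILES:
                    cols.append(f"hourq__q{int(q * 100)}__{axis}__60s__{c}__mean")
    if config.include_context_sensors:
        for c in config.contexts:
            cols.append(f"hr__mean__na__na__{c}__pooled")
            cols.append(f"hr__variance__na__na__{c}__pooled")
            cols.append(f"bt__mean__na__na__{c}__pooled")
            cols.append(f"bt__max__na__na__{c}__pooled")
        cols.append("gps__radius_gyration__na__na__whole_day__pooled")
        cols.append("gps__modal_fraction__na__na__whole_day__pooled")
    return cols


def aggregate_participant(
    window_tables: Sequence[pd.DataFrame], config: FeatureConfig
) -> dict[str, float]:
    """Pool per-window statistics across days into one feature fragment.

    For each (statistic, axis, window length, context) the day-level
    aggregators are the MEAN and population VARIANCE over all valid matching
    windows (whole_day = union of the three analysis contexts); contexts
    with no valid windows yield nan. Hour-quantile features come from the
    1-minute cumulative-motion values grouped by (day, clock hour).
    """
    out: dict[str, float] = {}
    table = (
        pd.concat(window_tables, ignore_index=True)
        if window_tables
        else pd.DataFrame(columns=["context", "valid", "hour", "length_s", "day_index"])
    )
    stat_cols = [
        f"{family}__{stat}__{axis}"
        for family, stats in FAMILY_STATS.items()
        for stat in stats
        for axis in AXES
    ]
    for c in config.contexts:
        if c == WHOLE_DAY:
            mask = table["context"].isin(ANALYSIS_CONTEXTS) if len(table) else []
        else:
            mask = table["context"] == c if len(table) else []
        sub = table[mask] if len(table) else table
        for L in config.window_lengths_s:
            rows = sub[(sub["length_s"] == L) & sub["valid"]] if len(sub) else sub
            for col in stat_cols:
                vals = rows[col].to_numpy(dtype=float) if len(rows) else np.empty(0)
                vals = vals[np.isfinite(vals)]
                name = f"{col}__{L}s__{c}"
                if vals.size:
                    out[f"{name}__mean"] = float(vals.mean())
                    out[f"{name}__var"] = float(np.var(vals))
                else:
                    out[f"{name}__mean"] = float("nan")
                    out[f"{name}__var"] = float("nan")
        if config.include_hour_quantiles:
            rows = sub[(sub["length_s"] == 60) & sub["valid"]] if len(sub) else sub
            for axis in AXES:
                col = f"cumulative__motion__{axis}"
                if len(rows):
                    grouped = {
                        key: grp[col].dropna().to_numpy()
                        for key, grp in rows.groupby(["day_index", "hour"])
                    }
                    grouped = {k: v for k, v in grouped.items() if v.size}
                else:
                    grouped = {}
                qs = hour_quantiles(grouped)
                for q, val in zip(QUANTILES, qs):
                    out[f"hourq__q{int(q * 100)}__{axis}__60s__{c}__mean"] = val
    return out


def impute_missing(matrix: FeatureMatrix, sentinel: float = -1.0) -> FeatureMatrix:
    """Replace every missing (nan) entry with the sentinel value -1."""
    return FeatureMatrix(values=matrix.values.fillna(sentinel), groups=matrix.groups)


def build_feature_matrix(
    dataset: StudyDataset, config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Full participants x features matrix, -1-imputed, deterministic order.

    Expects a day-filtered dataset (see ``filter_analysis_days``);
    participants with zero retained days get an all-(-1) row, mirroring the
    imputation-not-exclusion policy of the pipeline.
    """
    if config is None:
        config = FeatureConfig()
    if len(dataset) == 0:
        raise UsageError("empty dataset")
    columns = feature_columns(config)
    rows = {}
    for p in dataset.participants:
        tables = [
            tbl
            for day in p.days
            for tbl in day_window_tables(day.stream, day.diary, config.window_lengths_s)
        ]
        frag = aggregate_participant(tables, config)
        if config.include_context_sensors:
            frag.update(context_features([(d.context, d.diary) for d in p.days]))
        rows[p.participant_id] = [frag.get(c, float("nan")) for c in columns]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    values.index.name = "participant_id"
    matrix = FeatureMatrix(values=values, groups=dataset.groups.reindex(values.index))
    return impute_missing(matrix)
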