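"""Seeded synthetic cohorts with the statistical structure the classifier assumes.

The generator emulates a two-group wrist-actigraphy study of school-age
children: each participant-day has a parent-style activity diary (36
half-hour slots, 06:00-24:00), a tri-axial accelerometer stream whose
dynamic intensity depends on the diary category, and optional contextual
channels (heart rate, GPS, Bluetooth device counts).

The group contrast is deliberately context-conditioned: hyperactive-group
children receive a multiplicative elevation of motion intensity *during
quiet contexts only* (default x1.35, within the 24.7%-41.2% elevations
observed between matched children during play and reading). Groups share
household and exercise intensities, so the contrast is essentially invisible
in whole-day summaries but strong once features are stratified by context —
the separability structure the pipeline is designed to detect.

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence`` spawning; per-participant child seeds are a
stable function of (cohort seed, participant index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sensor_io import (
    ANALYSIS_CONTEXTS,
    CATEGORIES,
    DAY_START_MIN,
    N_SLOTS,
    SLOT_MIN,
    ActivityDiary,
    ContextStream,
    DayRecord,
    DiaryEntry,
    ParticipantRecord,
    SensorStream,
    StudyDataset,
    ValidationError,
)

MOTION_CATEGORIES = ("sleeping", "sitting_quiet", "household", "exercise")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionModel:
    """Per-category Gaussian-intensity motion model with movement bursts.

    Each 30-minute slot of category *c* draws an intensity
    ``lam = max(0, N(mu[c], sigma[c])) * trait`` (g); the dynamic part of
    each axis is ``lam * N(0, 1)`` per sample on top of a static gravity
    offset. ``trait`` is a per-child lognormal activity multiplier
    (sd ``trait_sigma``) shared by all categories — an overall "active kid"
    factor. For unmedicated hyperactive-group children, ``lam`` is further
    multiplied by ``adhd_quiet_multiplier`` in ``multiplier_contexts``.

    Bursts: within each minute, with probability ``burst_per_minute`` a
    ``burst_duration_s`` stretch gets extra noise of std
    ``burst_amplitude * lam`` — short fidgets/gestures.

    Heart rate rises linearly with slot intensity; GPS is a two-state
    home/away jitter process; Bluetooth counts are Poisson per category.
    """

    mu: dict[str, float] = field(
        default_factory=lambda: {
            "sleeping": 0.003,
            "sitting_quiet": 0.012,
            "household": 0.05,
            "exercise": 0.15,
        }
    )
    sigma: dict[str, float] = field(
        default_factory=lambda: {
            "sleeping": 0.00075,
            "sitting_quiet": 0.003,
            "household": 0.0125,
            "exercise": 0.0375,
        }
    )
    adhd_quiet_multiplier: float = 1.35
    multiplier_contexts: tuple[str, ...] = ("sitting_quiet",)
    burst_per_minute: float = 0.1
    burst_amplitude: float = 3.0
    burst_duration_s: float = 2.0
    trait_sigma: float = 0.15
    gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    hr_base: float = 75.0
    hr_base_sd: float = 5.0
    hr_gain: float = 350.0  # bpm per g of intensity
    hr_noise_sd: float = 3.0
    bt_rate: dict[str, float] = field(
        default_factory=lambda: {
            "sleeping": 1.0,
            "sitting_quiet": 3.0,
            "household": 5.0,
            "exercise": 8.0,
        }
    )
    home: tuple[float, float] = (40.44, -79.96)
    away_offset_deg: float = 0.01
    gps_jitter_deg: float = 1e-4
    away_prob: float = 0.5

    def __post_init__(self) -> None:
        order = ["sleeping", "sitting_quiet", "household", "exercise"]
        mus = [self.mu[c] for c in order]
        if any(a > b for a, b in zip(mus, mus[1:])):
            raise ValidationError("category intensities must be nondecreasing")
        if any(self.sigma[c] < 0 for c in order):
            raise ValidationError("dispersions must be nonnegative")
        if self.adhd_quiet_multiplier < 1:
            raise ValidationError("adhd_quiet_multiplier must be >= 1")


@dataclass(frozen=True)
class ScheduleSpec:
    """Semi-Markov day schedule over the five diary categories.

    Realized as a slot-level Markov chain: in category *c*, each subsequent
    slot re-draws the category from ``weights`` with probability
    ``1/dwell_slots[c]`` and stays put otherwise; the first slot is drawn
    from the stationary distribution, which is proportional to
    ``weights[c] * dwell_slots[c]``.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "sleeping": 0.15,
            "sitting_quiet": 0.40,
            "household": 0.25,
            "exercise": 0.20,
            "not_worn": 0.08,
        }
    )
    dwell_slots: dict[str, float] = field(
        default_factory=lambda: {
            "sleeping": 2.0,
            "sitting_quiet": 3.0,
            "household": 2.0,
            "exercise": 2.0,
            "not_worn": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("schedule weights must be nonnegative")
        if all(self.weights.get(c, 0.0) == 0.0 for c in ANALYSIS_CONTEXTS):
            raise ValidationError("at least one analysis context needs weight > 0")
        if any(d < 1 for d in self.dwell_slots.values()):
            raise ValidationError("dwell times must be >= 1 slot")

    def stationary_frequencies(self) -> dict[str, float]:
        """Expected long-run slot fraction per category: w_c d_c / sum."""
        raw = {c: self.weights.get(c, 0.0) * self.dwell_slots.get(c, 1.0) for c in CATEGORIES}
        total = sum(raw.values())
        return {c: v / total for c, v in raw.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes, sampling rate and missingness levels."""

    n_adhd: int = 15
    n_control: int = 15
    days_per_participant: int = 2
    sample_rate_hz: float = 50.0
    watch_off_slot_prob: float = 0.05
    context_drop_prob: float = 0.10
    #: probability that an ADHD day beyond the guaranteed unmedicated first
    #: day is medicated. Default 0: families schedule the whole 2-day wear on
    #: weekends or medication holidays, so both groups contribute the same
    #: data volume and day counts carry no group information.
    adhd_extra_day_medicated_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd < 1 or self.n_control < 1 or self.days_per_participant < 1:
            raise ValidationError("cohort counts must be >= 1")
        for p in (self.watch_off_slot_prob, self.context_drop_prob,
                  self.adhd_extra_day_medicated_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------


def generate_schedule(
    spec: ScheduleSpec, seed, participant_id: str = "synthetic", day_index: int = 0
) -> ActivityDiary:
    """Draw a full 36-slot diary from the slot-level Markov chain."""
    rng = np.random.default_rng(seed)
    cats = [c for c in CATEGORIES if spec.weights.get(c, 0.0) > 0]
    w = np.array([spec.weights[c] for c in cats], dtype=float)
    w = w / w.sum()
    stat = spec.stationary_frequencies()
    pi = np.array([stat[c] for c in cats], dtype=float)
    pi = pi / pi.sum()
    current = cats[rng.choice(len(cats), p=pi)]
    entries = []
    for slot in range(N_SLOTS):
        entries.append(
            DiaryEntry(slot_start=DAY_START_MIN + slot * SLOT_MIN, category=current)
        )
        if rng.random() < 1.0 / spec.dwell_slots[current]:
            current = cats[rng.choice(len(cats), p=w)]
    return ActivityDiary(
        participant_id=participant_id, day_index=day_index, entries=tuple(entries)
    )


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------


def _slot_intensity(rng, model: MotionModel, category: str, trait: float,
                    hyper_multiplier: float) -> float:
    lam = max(0.0, rng.normal(model.mu[category], model.sigma[category])) * trait
    if category in model.multiplier_contexts:
        lam *= hyper_multiplier
    return lam


def generate_stream(
    diary: ActivityDiary,
    model: MotionModel,
    group: str,
    sample_rate_hz: float,
    seed,
    *,
    medicated: bool = False,
    trait: float = 1.0,
    hr_base: float | None = None,
    dropped_slots: frozenset[int] = frozenset(),
) -> tuple[SensorStream, ContextStream]:
    """Simulate one participant-day of accelerometer + context data.

    ``dropped_slots`` (slot_start minutes) simulates the watch being off
    without a diary update: those slots produce no sensor samples at all.
    Not-worn diary slots likewise produce nothing. The quiet-context
    multiplier applies only when ``group == "ADHD"`` and the day is
    unmedicated (properly titrated stimulants normalize motion).
    """
    rng = np.random.default_rng(seed)
    multiplier = (
        model.adhd_quiet_multiplier if (group == "ADHD" and not medicated) else 1.0
    )
    if hr_base is None:
        hr_base = model.hr_base
    g = np.asarray(model.gravity, dtype=float)

    t_parts: list[np.ndarray] = []
    a_parts: list[np.ndarray] = []
    hr_t: list[np.ndarray] = []
    hr_v: list[np.ndarray] = []
    loc_t: list[np.ndarray] = []
    loc_lat: list[np.ndarray] = []
    loc_lon: list[np.ndarray] = []
    bt_t: list[np.ndarray] = []
    bt_v: list[np.ndarray] = []

    n_slot = int(round(SLOT_MIN * 60 * sample_rate_hz))
    for entry in sorted(diary.entries, key=lambda e: e.slot_start):
        cat = entry.category
        # RNG draws are consumed identically for every generated slot so that
        # two runs differing only in `group` stay draw-aligned.
        if cat == "not_worn" or entry.slot_start in dropped_slots:
            continue
        start_s = entry.slot_start * 60.0
        lam = _slot_intensity(rng, model, cat, trait, multiplier)
        t = start_s + np.arange(n_slot) / sample_rate_hz
        a = g[None, :] + lam * rng.standard_normal((n_slot, 3))
        # bursts: short stretches of amplified movement
        for minute in range(SLOT_MIN):
            if rng.random() < model.burst_per_minute:
                i0 = minute * int(round(60 * sample_rate_hz))
                i0 += int(rng.integers(0, max(1, int(round(60 * sample_rate_hz))
                                              - int(round(model.burst_duration_s * sample_rate_hz)))))
                i1 = min(n_slot, i0 + int(round(model.burst_duration_s * sample_rate_hz)))
                a[i0:i1] += model.burst_amplitude * lam * rng.standard_normal((i1 - i0, 3))
        t_parts.append(t)
        a_parts.append(a)

        # heart rate: one reading per minute, linear in slot intensity
        ht = start_s + 60.0 * np.arange(SLOT_MIN)
        hr_t.append(ht)
        hr_v.append(hr_base + model.hr_gain * lam + model.hr_noise_sd * rng.standard_normal(SLOT_MIN))

        # GPS: one fix per 5 minutes; away from home during active contexts
        away = cat in ("household", "exercise") and rng.random() < model.away_prob
        lat0, lon0 = model.home
        if away:
            lat0 += model.away_offset_deg
        lt = start_s + 300.0 * np.arange(6)
        loc_t.append(lt)
        loc_lat.append(lat0 + model.gps_jitter_deg * rng.standard_normal(6))
        loc_lon.append(lon0 + model.gps_jitter_deg * rng.standard_normal(6))

        # Bluetooth: one scan per 5 minutes, Poisson device counts
        bt_t.append(lt.copy())
        bt_v.append(rng.poisson(model.bt_rate[cat], 6).astype(float))

    if t_parts:
        t = np.concatenate(t_parts)
        a = np.concatenate(a_parts)
    else:
        t = np.empty(0)
        a = np.empty((0, 3))
    stream = SensorStream(
        participant_id=diary.participant_id,
        day_index=diary.day_index,
        sample_rate_hz=sample_rate_hz,
        t=t,
        x=a[:, 0],
        y=a[:, 1],
        z=a[:, 2],
    )
    context = ContextStream(
        heart_rate=(np.concatenate(hr_t), np.concatenate(hr_v)) if hr_t else None,
        locations=(
            np.concatenate(loc_t),
            np.concatenate(loc_lat),
            np.concatenate(loc_lon),
        )
        if loc_t
        else None,
        bluetooth_counts=(np.concatenate(bt_t), np.concatenate(bt_v)) if bt_t else None,
    )
    return stream, context


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def participant_seed(cohort_seed: int, participant_index: int) -> np.random.SeedSequence:
    """Stable child seed for one participant: SeedSequence(cohort, key=(index,))."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(participant_index,))


def generate_cohort(
    spec: CohortSpec,
    schedule: ScheduleSpec | None = None,
    model: MotionModel | None = None,
) -> StudyDataset:
    """Generate a full two-group cohort as an in-memory StudyDataset.

    Hyperactive-group participants get exactly one guaranteed unmedicated
    day; each further day is medicated with probability
    ``adhd_extra_day_medicated_prob`` (weekend versus school-day dosing).
    Control days are always unmedicated.
    """
    schedule = schedule or ScheduleSpec()
    model = model or MotionModel()
    participants = []
    n_total = spec.n_adhd + spec.n_control
    for idx in range(n_total):
        group = "ADHD" if idx < spec.n_adhd else "control"
        pid = f"{'adhd' if group == 'ADHD' else 'ctrl'}{idx + 1:02d}"
        ss = participant_seed(spec.seed, idx)
        rng = np.random.default_rng(ss)
        trait = float(rng.lognormal(-0.5 * model.trait_sigma**2, model.trait_sigma))
        hr_base = float(rng.normal(model.hr_base, model.hr_base_sd))
        day_seeds = ss.spawn(spec.days_per_participant)
        days = []
        for d in range(spec.days_per_participant):
            if group == "ADHD":
                medicated = d > 0 and rng.random() < spec.adhd_extra_day_medicated_prob
            else:
                medicated = False
            day_ss = day_seeds[d]
            sched_ss, stream_ss, miss_ss = day_ss.spawn(3)
            diary = generate_schedule(schedule, sched_ss, pid, d)
            miss_rng = np.random.default_rng(miss_ss)
            dropped = frozenset(
                e.slot_start
                for e in diary.entries
                if e.category != "not_worn" and miss_rng.random() < spec.watch_off_slot_prob
            )
            stream, context = generate_stream(
                diary,
                model,
                group,
                spec.sample_rate_hz,
                stream_ss,
                medicated=medicated,
                trait=trait,
                hr_base=hr_base,
                dropped_slots=dropped,
            )
            hr = context.heart_rate if miss_rng.random() >= spec.context_drop_prob else None
            loc = context.locations if miss_rng.random() >= spec.context_drop_prob else None
            bt = (
                context.bluetooth_counts
                if miss_rng.random() >= spec.context_drop_prob
                else None
            )
            context = ContextStream(heart_rate=hr, locations=loc, bluetooth_counts=bt)
            days.append(
                DayRecord(
                    day_index=d,
                    stream=stream,
                    diary=diary,
                    context=context,
                    medicated=medicated,
                )
            )
        participants.append(
            ParticipantRecord(participant_id=pid, group=group, days=tuple(days))
        )
    return StudyDataset(participants=tuple(participants))
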