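import numpy as np
import pytest

from actidx import (
    ActivityDiary,
    CohortSpec,
    DiaryEntry,
    MotionModel,
    ScheduleSpec,
    filter_analysis_days,
    generate_cohort,
)


def make_diary(categories, participant_id="p1", day_index=0, start_slot=360):
    """Diary from a list of categories filling consecutive 30-min slots."""
    entries = tuple(
        DiaryEntry(slot_start=start_slot + 30 * i, category=c)
        for i, c in enumerate(categories)
    )
    return ActivityDiary(
        participant_id=participant_id, day_index=day_index, entries=entries
    )


def full_day_diary(category="sitting_quiet", **kw):
    return make_diary([category] * 36, **kw)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-participant cohort at a low sampling rate, shared across tests."""
    spec = CohortSpec(n_adhd=3, n_control=3, sample_rate_hz=4.0, seed=5)
    return filter_analysis_days(generate_cohort(spec))


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_cohort):
    from actidx import write_dataset

    out = tmp_path_factory.mktemp("cohort")
    manifest = write_dataset(tiny_cohort, out)
    return manifest
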