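import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from actidx import (
    FeatureConfig,
    FeatureMatrix,
    build_feature_matrix,
    cumulative_motion,
    hour_quantiles,
    impute_missing,
    radius_of_gyration,
    segment_windows,
    shape_features,
    summary_features,
)
from actidx.features import (
    AXES,
    aggregate_participant,
    context_features,
    day_window_table,
    day_window_tables,
    feature_columns,
    modal_location_fraction,
)
from actidx.sensor_io import ContextStream, SensorStream
from tests.conftest import full_day_diary, make_diary


def col(values):
    return np.asarray(values, dtype=float)[:, None]


class TestWindowStatistics:
    def test_shape_features_hand_checked(self):
        # values [0,0,0,4]: m2=3, m3=6, m4=21 about the mean 1
        skew, kurt = shape_features(col([0, 0, 0, 4]))
        assert skew == pytest.approx(6 / 3**1.5)
        assert kurt == pytest.approx(21 / 9)

    def test_constant_window_convention(self):
        assert shape_features(col([5, 5, 5, 5])) == (0.0, 0.0)

    def test_symmetric_window_has_zero_skew(self):
        skew, _ = shape_features(col([1, 2, 3]))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_missing(self):
        assert np.isnan(shape_features(col([1, 2]))[0])

    def test_summary_hand_checked(self):
        mean, var, med, mag = summary_features(col([1, 2, 3]))
        assert (mean, var, med, mag) == (2.0, pytest.approx(2 / 3), 2.0, 2.0)

    def test_composite_magnitude_is_euclidean(self):
        window = np.tile([3.0, 4.0, 0.0], (5, 1))
        assert summary_features(window, "composite")[3] == pytest.approx(5.0)

    def test_magnitude_uses_absolute_value(self):
        mean, _, _, mag = summary_features(col([-1, 1]))
        assert mean == 0.0 and mag == 1.0

    def test_cumulative_motion_hand_checked(self):
        assert cumulative_motion(col([0, 1, 0, 1])) == 3.0
        assert cumulative_motion(col([7, 7, 7])) == 0.0

    def test_cumulative_motion_gravity_invariant(self):
        assert cumulative_motion(col([1] * 8)) == cumulative_motion(col([0] * 8))

    def test_hour_quantiles_linear_interpolation(self):
        q = hour_quantiles({9: list(range(1, 61))})
        assert q == (pytest.approx(15.75), pytest.approx(30.5), pytest.approx(45.25))

    def test_hour_quantiles_mean_over_hours_idempotent(self):
        one = hour_quantiles({9: [1, 2, 3]})
        several = hour_quantiles({h: [1, 2, 3] for h in range(6, 24)})
        assert one == several

    def test_hour_quantiles_empty(self):
        assert all(np.isnan(v) for v in hour_quantiles({}))


class TestOracleEquivalence:
    def test_moments_match_scipy_on_random_windows(self):
        """Population skewness/kurtosis equal the scipy definitions (1000 draws)."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            v = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            skew, kurt = shape_features(col(v))
            assert skew == pytest.approx(sps.skew(v, bias=True), abs=1e-9)
            assert kurt == pytest.approx(sps.kurtosis(v, bias=True, fisher=False), abs=1e-9)
            mean, var, med, mag = summary_features(col(v))
            assert var == pytest.approx(np.var(v))
            assert med == pytest.approx(np.median(v))
            assert cumulative_motion(col(v)) == pytest.approx(np.abs(np.diff(v)).sum())

    def test_vectorized_day_table_matches_scalar_ops(self):
        """The cumulative-sum fast path equals window-by-window computation."""
        from actidx import CohortSpec, generate_cohort

        ds = generate_cohort(CohortSpec(n_adhd=1, n_control=1, sample_rate_hz=2.0, seed=9))
        day = ds.participants[0].days[0]
        table = day_window_table(day.stream, day.diary, 600)
        windows = segment_windows(day.stream, day.diary, 600)
        samples = np.c_[day.stream.x, day.stream.y, day.stream.z]
        checked = 0
        for i, w in enumerate(windows):
            if not w.valid:
                assert np.isnan(table.loc[i, "summary__mean__x"])
                continue
            win = samples[w.sample_slice]
            for axis in AXES:
                skew, kurt = shape_features(win, axis)
                mean, var, med, mag = summary_features(win, axis)
                assert table.loc[i, f"shape__skewness__{axis}"] == pytest.approx(skew, rel=1e-6, abs=1e-9)
                assert table.loc[i, f"shape__kurtosis__{axis}"] == pytest.approx(kurt, rel=1e-6, abs=1e-9)
                assert table.loc[i, f"summary__mean__{axis}"] == pytest.approx(mean, rel=1e-9)
                assert table.loc[i, f"summary__variance__{axis}"] == pytest.approx(var, rel=1e-6, abs=1e-12)
                assert table.loc[i, f"summary__median__{axis}"] == pytest.approx(med, rel=1e-9)
                assert table.loc[i, f"summary__mean_magnitude__{axis}"] == pytest.approx(mag, rel=1e-9)
                assert table.loc[i, f"cumulative__motion__{axis}"] == pytest.approx(
                    cumulative_motion(win, axis), rel=1e-9
                )
            checked += 1
        assert checked >= 10


finite_windows = arrays(
    np.float64,
    st.integers(4, 25),
    elements=st.floats(-5, 5, allow_nan=False, width=32),
)


class TestInvarianceProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(finite_windows, st.floats(-3, 3, allow_nan=False), st.floats(0.1, 4))
    def test_offset_and_scale_laws(self, v, offset, scale):
        from hypothesis import assume

        base_var = summary_features(col(v))[1]
        # stay clear of the documented constant-signal threshold (1e-12)
        assume(base_var * min(scale, 1.0) ** 2 > 1e-6)
        base_cum = cumulative_motion(col(v))
        base_shape = shape_features(col(v))

        shifted = v + offset
        assert summary_features(col(shifted))[1] == pytest.approx(base_var, rel=1e-6, abs=1e-9)
        assert cumulative_motion(col(shifted)) == pytest.approx(base_cum, rel=1e-6, abs=1e-9)
        assert shape_features(col(shifted))[0] == pytest.approx(base_shape[0], rel=1e-4, abs=1e-6)

        scaled = v * scale
        assert summary_features(col(scaled))[1] == pytest.approx(base_var * scale**2, rel=1e-6, abs=1e-12)
        assert cumulative_motion(col(scaled)) == pytest.approx(base_cum * scale, rel=1e-6, abs=1e-12)
        assert shape_features(col(scaled))[1] == pytest.approx(base_shape[1], rel=1e-4, abs=1e-6)


class TestSegmentation:
    @pytest.mark.parametrize("length_s,expected", [(60, 1080), (300, 216), (600, 108)])
    def test_window_counts_tile_the_day(self, length_s, expected, tiny_cohort):
        day = tiny_cohort.participants[0].days[0]
        assert len(segment_windows(day.stream, day.diary, length_s)) == expected

    def test_not_worn_windows_invalid_and_empty(self):
        diary = make_diary(["not_worn"] + ["sitting_quiet"] * 35)
        stream = SensorStream("p1", 0, 1.0, np.array([360 * 60 + 1800.5]),
                              np.zeros(1), np.zeros(1), np.ones(1))
        windows = segment_windows(stream, diary, 600)
        assert not windows[0].valid
        assert windows[0].sample_slice.stop == windows[0].sample_slice.start

    def test_context_partition(self, tiny_cohort):
        """Whole-day windows = disjoint union of the three analysis contexts."""
        day = tiny_cohort.participants[0].days[0]
        for length in (60, 300, 600):
            windows = segment_windows(day.stream, day.diary, length)
            whole = [w for w in windows if w.context in ("sitting_quiet", "household", "exercise")]
            by_context = {
                c: [w for w in windows if w.context == c]
                for c in ("sitting_quiet", "household", "exercise")
            }
            assert len(whole) == sum(len(v) for v in by_context.values())


class TestAggregation:
    def test_mean_and_variance_over_windows(self):
        table = pd.DataFrame(
            {
                "cumulative__motion__x": [2.0, 4.0],
                "context": ["sitting_quiet", "sitting_quiet"],
                "valid": [True, True],
                "hour": [6, 6],
                "count": [10, 10],
                "length_s": [600, 600],
                "day_index": [0, 0],
            }
        )
        for c in feature_columns(FeatureConfig()):
            pass
        config = FeatureConfig(window_lengths_s=(600,), include_hour_quantiles=False,
                               include_context_sensors=False)
        # fill the remaining stat columns so aggregation sees a full table
        from actidx.features import FAMILY_STATS

        for family, stats_ in FAMILY_STATS.items():
            for stat in stats_:
                for axis in AXES:
                    name = f"{family}__{stat}__{axis}"
                    if name not in table:
                        table[name] = [0.0, 0.0]
        frag = aggregate_participant([table], config)
        assert frag["cumulative__motion__x__600s__sitting_quiet__mean"] == 3.0
        assert frag["cumulative__motion__x__600s__sitting_quiet__var"] == 1.0
        # no exercise windows -> missing
        assert np.isnan(frag["cumulative__motion__x__600s__exercise__mean"])
        # single-window variance convention comes from population ddof=0
        solo = table.iloc[:1].copy()
        frag1 = aggregate_participant([solo], config)
        assert frag1["cumulative__motion__x__600s__sitting_quiet__mean"] == 2.0
        assert frag1["cumulative__motion__x__600s__sitting_quiet__var"] == 0.0


class TestContextFeatures:
    def test_constant_heart_rate(self):
        diary = full_day_diary("sitting_quiet")
        t = 360 * 60 + 60.0 * np.arange(100)
        ctx = ContextStream(heart_rate=(t, np.full(100, 80.0)))
        frag = context_features([(ctx, diary)])
        assert frag["hr__mean__na__na__sitting_quiet__pooled"] == 80.0
        assert frag["hr__variance__na__na__sitting_quiet__pooled"] == 0.0

    def test_single_location_degenerate_geometry(self):
        diary = full_day_diary("sitting_quiet")
        ctx = ContextStream(locations=(np.array([0.0]), np.array([40.0]), np.array([-80.0])))
        frag = context_features([(ctx, diary)])
        assert frag["gps__radius_gyration__na__na__whole_day__pooled"] == 0.0
        assert frag["gps__modal_fraction__na__na__whole_day__pooled"] == 1.0

    def test_two_point_radius_of_gyration(self):
        # two equal-weight fixes 1 km apart -> RMS distance from centroid 500 m
        dlat = 1000.0 / 111194.9  # meters per degree latitude
        rog = radius_of_gyration(np.array([0.0, dlat]), np.array([0.0, 0.0]))
        assert rog == pytest.approx(500.0, rel=1e-3)

    def test_missing_channels_missing_features(self):
        diary = full_day_diary("sitting_quiet")
        frag = context_features([(ContextStream(), diary)])
        assert np.isnan(frag["hr__mean__na__na__whole_day__pooled"])
        assert np.isnan(frag["bt__max__na__na__exercise__pooled"])


class TestMatrix:
    def test_impute_replaces_only_missing_cells(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0], "c": [3.0, 4.0]},
                          index=["p1", "p2"])
        groups = pd.Series(["ADHD", "control"], index=df.index)
        out = impute_missing(FeatureMatrix(values=df, groups=groups))
        assert out.values.loc["p2", "a"] == -1.0
        assert out.values.loc["p1", "b"] == -1.0
        assert out.values.loc["p1", "c"] == 3.0
        again = impute_missing(out)
        pd.testing.assert_frame_equal(out.values, again.values)

    def test_column_count_formula(self, tiny_cohort):
        # 7 statistics x 4 axes x 3 windows x 4 contexts x 2 aggregators
        # + 3 quantiles x 4 axes x 4 contexts
        # + (2 hr + 2 bt) x 4 contexts + 2 gps
        motion = 7 * 4 * 3 * 4 * 2
        hourq = 3 * 4 * 4
        sensors = 4 * 4 + 2
        m_full = build_feature_matrix(tiny_cohort, FeatureConfig())
        assert m_full.values.shape == (6, motion + hourq + sensors)
        m_motion = build_feature_matrix(
            tiny_cohort, FeatureConfig(include_context_sensors=False)
        )
        assert m_motion.values.shape[1] == motion + hourq
        assert not m_full.values.isna().any().any()

    def test_matrix_deterministic(self, tiny_cohort):
        a = build_feature_matrix(tiny_cohort, FeatureConfig(window_lengths_s=(600,)))
        b = build_feature_matrix(tiny_cohort, FeatureConfig(window_lengths_s=(600,)))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_zero_day_participant_row_is_all_sentinel(self):
        import dataclasses

        from actidx import CohortSpec, generate_cohort

        ds = generate_cohort(CohortSpec(n_adhd=1, n_control=1, sample_rate_hz=2.0, seed=4))
        empty = dataclasses.replace(ds.participants[0], days=())
        ds = dataclasses.replace(ds, participants=(empty, ds.participants[1]))
        m = build_feature_matrix(ds, FeatureConfig(window_lengths_s=(600,)))
        assert (m.values.loc[empty.participant_id] == -1.0).all()

    def test_csv_roundtrip(self, tiny_cohort, tmp_path):
        m = build_feature_matrix(tiny_cohort, FeatureConfig(window_lengths_s=(600,)))
        m.to_csv(tmp_path / "features.csv")
        back = FeatureMatrix.from_csv(tmp_path / "features.csv")
        pd.testing.assert_frame_equal(m.values, back.values)
        pd.testing.assert_series_equal(m.groups, back.groups, check_names=False)
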