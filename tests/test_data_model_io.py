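"""Session domain types, on-disk round-trips and uniform resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wodwatch import (
    ExerciseSet,
    FormatError,
    SensorStream,
    Session,
    ValidationError,
    assemble_channels,
    read_session,
    resample_stream,
    write_session,
)
from wodwatch.signals import ALL_SENSORS, canonical_selection


def _stream(device="wrist", sensor="accelerometer", t=None, v=None):
    if t is None:
        t = np.arange(0, 10, 0.01)
    if v is None:
        v = np.column_stack([np.sin(t), np.cos(t), t])
    return SensorStream(device=device, sensor=sensor, timestamps=t, values=v)


class TestInvariants:
    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            _stream(t=np.array([0.0, 0.2, 0.1]), v=np.zeros((3, 3)))

    def test_vibration_outside_set_bounds_rejected(self):
        with pytest.raises(ValidationError, match="outside set bounds"):
            ExerciseSet(label="E1", start_time=0, end_time=10, vibration_times=[11.0])

    def test_declared_reps_must_match_vibrations(self):
        with pytest.raises(ValidationError, match="declared_reps"):
            ExerciseSet(
                label="E1",
                start_time=0,
                end_time=10,
                vibration_times=[1.0, 2.0],
                declared_reps=3,
            )

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            Session(
                participant_id="p",
                sets=[
                    ExerciseSet(label="E1", start_time=0, end_time=5),
                    ExerciseSet(label="E2", start_time=4, end_time=9),
                ],
                streams=[_stream()],
            )


class TestSessionRoundTrip:
    def test_minimal_session(self, tmp_path):
        s = Session(
            participant_id="p1",
            sets=[ExerciseSet(label="E1", start_time=1, end_time=9)],
            streams=[_stream()],
        )
        write_session(s, tmp_path / "s")
        back = read_session(tmp_path / "s")
        assert back.participant_id == "p1"
        assert len(back.sets) == 1 and back.sets[0].label == "E1"
        assert len(back.streams) == 1

    def test_empty_sets_session(self, tmp_path):
        s = Session(participant_id="p", sets=[], streams=[_stream()])
        write_session(s, tmp_path / "s")
        assert read_session(tmp_path / "s").sets == []

    def test_two_device_session_writes_six_files(self, tmp_path, small_sessions):
        write_session(small_sessions[0], tmp_path / "s")
        assert len(list((tmp_path / "s").glob("*.csv"))) == 6

    def test_generated_session_round_trips_exactly(self, tmp_path, small_sessions):
        s = small_sessions[0]
        write_session(s, tmp_path / "s")
        back = read_session(tmp_path / "s")
        assert back.participant_id == s.participant_id
        assert back.experience == s.experience
        for a, b in zip(back.sets, s.sets):
            assert a.label == b.label
            assert a.start_time == pytest.approx(b.start_time)
            assert a.vibration_times == pytest.approx(b.vibration_times)
            assert a.declared_reps == b.declared_reps
        for key in [st.key for st in s.streams]:
            sa, sb = back.stream(*key), s.stream(*key)
            np.testing.assert_allclose(sa.timestamps, sb.timestamps, atol=1e-9)
            np.testing.assert_allclose(sa.values, sb.values, atol=1e-9)

    def test_missing_manifest_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="manifest"):
            read_session(tmp_path)

    def test_unknown_csv_ignored_with_warning(self, tmp_path, caplog):
        s = Session(participant_id="p", sets=[], streams=[_stream()])
        write_session(s, tmp_path / "s")
        (tmp_path / "s" / "heartrate_ppg.csv").write_text("t,x,y,z\n0,0,0,0\n")
        with caplog.at_level("WARNING"):
            back = read_session(tmp_path / "s")
        assert len(back.streams) == 1
        assert "ignoring" in caplog.text

    @settings(deadline=None, max_examples=20)
    @given(
        n=st.integers(3, 30),
        label=st.sampled_from(["E1", "E5", "E10"]),
        data=st.data(),
    )
    def test_round_trip_property(self, tmp_path_factory, n, label, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.005, 0.02, size=n))
        v = rng.normal(size=(n, 3)) * 10
        s = Session(
            participant_id=f"p{seed % 100}",
            sets=[ExerciseSet(label=label, start_time=t[0], end_time=t[-1] + 0.1)],
            streams=[_stream(t=t, v=v)],
        )
        path = tmp_path_factory.mktemp("rt") / "s"
        write_session(s, path)
        back = read_session(path)
        np.testing.assert_allclose(back.streams[0].values, v, atol=1e-9)
        np.testing.assert_allclose(back.streams[0].timestamps, t, atol=1e-9)


class TestResampling:
    def test_linear_signal_resampled_exactly(self, rng):
        t = np.sort(rng.uniform(0, 10, size=200))
        t[0], t[-1] = 0.0, 10.0
        stream = _stream(t=t, v=np.column_stack([2 * t, -t, 0.5 * t + 3]))
        times, values = resample_stream(stream, rate=100, grid=(0, 10))
        np.testing.assert_allclose(values[:, 0], 2 * times, atol=1e-9)
        np.testing.assert_allclose(values[:, 1], -times, atol=1e-9)
        np.testing.assert_allclose(values[:, 2], 0.5 * times + 3, atol=1e-9)

    def test_constant_stream_stays_constant(self):
        t = np.array([0.0, 0.3, 0.35, 1.0])
        stream = _stream(t=t, v=np.full((4, 3), 7.5))
        _, values = resample_stream(stream, rate=100, grid=(0, 1))
        np.testing.assert_allclose(values, 7.5)

    def test_hand_computed_interpolation_point(self):
        t = np.array([0.0, 0.013, 0.019])
        x = np.array([0.0, 1.3, 2.5])
        stream = _stream(t=t, v=np.column_stack([x, x, x]))
        times, values = resample_stream(stream, rate=100, grid=(0.0, 0.019))
        # grid point t=0.01 sits inside [0, 0.013): 0 + (0.01/0.013)*1.3 = 1.0
        assert times[1] == pytest.approx(0.01)
        assert values[1, 0] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        stream = _stream(t=np.array([0.0]), v=np.zeros((1, 3)))
        with pytest.raises(ValidationError, match="at least 2"):
            resample_stream(stream)

    def test_no_extrapolation(self):
        stream = _stream(t=np.linspace(0, 1, 50), v=np.zeros((50, 3)))
        with pytest.raises(ValidationError, match="outside raw coverage"):
            resample_stream(stream, grid=(0.0, 2.0))

    def test_jittered_sampling_of_smooth_signal_recovered(self, rng):
        # irregular ~100 Hz sampling of a band-limited signal: linear
        # interpolation onto the uniform grid recovers it to small error
        dt = 0.01 + rng.normal(0, 0.001, size=1000)
        t = np.cumsum(np.maximum(dt, 0.002))
        f = lambda t: np.sin(2 * np.pi * 0.7 * t) + 0.5 * np.cos(2 * np.pi * 1.3 * t)
        stream = _stream(t=t, v=np.column_stack([f(t)] * 3))
        times, values = resample_stream(stream, rate=100, grid=(t[0], t[-1]))
        assert np.max(np.abs(values[:, 0] - f(times))) < 0.01


class TestAssembleChannels:
    def test_all_six_sensors_give_18_channels(self, small_sessions):
        m = assemble_channels(small_sessions[0], ALL_SENSORS)
        assert m.n_channels == 18
        assert len(m.channel_order) == 18

    def test_single_sensor_gives_3_channels(self, small_sessions):
        m = assemble_channels(small_sessions[0], [("wrist", "accelerometer")])
        assert m.n_channels == 3

    def test_canonical_order_accel_before_gyro(self, small_sessions):
        m = assemble_channels(
            small_sessions[0],
            [("wrist", "gyroscope"), ("wrist", "accelerometer")],
        )
        sensors = [c[1] for c in m.channel_order]
        assert sensors == ["accelerometer"] * 3 + ["gyroscope"] * 3
        assert [c[2] for c in m.channel_order[:3]] == ["x", "y", "z"]

    def test_invariant_to_stream_order(self, small_sessions):
        s = small_sessions[0]
        shuffled = Session(
            participant_id=s.participant_id,
            experience=s.experience,
            sets=s.sets,
            streams=list(reversed(s.streams)),
        )
        a = assemble_channels(s, ALL_SENSORS)
        b = assemble_channels(shuffled, ALL_SENSORS)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.channel_order == b.channel_order

    def test_missing_stream_named_in_error(self, small_sessions):
        s = small_sessions[0]
        partial = Session(
            participant_id=s.participant_id,
            sets=[],
            streams=[st for st in s.streams if st.device == "wrist"],
        )
        with pytest.raises(ValidationError, match=r"ankle.*accelerometer"):
            assemble_channels(partial, ALL_SENSORS)

    def test_canonical_selection_rejects_unknown_pair(self):
        with pytest.raises(ValidationError):
            canonical_selection([("hip", "accelerometer")])
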