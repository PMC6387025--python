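"""Stride computation, window extraction and window labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wodwatch import (
    ChannelMatrix,
    ExerciseConfig,
    ExerciseSet,
    Session,
    ValidationError,
    Window,
    compute_stride,
    extract_windows,
    label_counting_window,
    label_recognition_window,
    sample_training_batch,
)
from wodwatch.windowing import counting_bits_for_positions, window_starts


def _matrix(n, channels=3):
    order = tuple(("wrist", "accelerometer", ax) for ax in "xyz") * (channels // 3)
    return ChannelMatrix(rate=100, data=np.zeros((n, channels)), channel_order=order)


class TestStride:
    @pytest.mark.parametrize(
        "W,gamma,expected",
        [(400, 0.0, 400), (400, 0.95, 20), (10, 0.99, 1), (400, 0.5, 200)],
    )
    def test_stride_values(self, W, gamma, expected):
        assert compute_stride(W, gamma) == expected

    @pytest.mark.parametrize("gamma", [-0.1, 1.0, 1.5])
    def test_invalid_gamma(self, gamma):
        with pytest.raises(ValidationError):
            compute_stride(400, gamma)


class TestExtractWindows:
    def test_disjoint_windows(self):
        ws = extract_windows(_matrix(1000), 400, 400)
        assert [w.start_index for w in ws] == [0, 400]

    def test_overlapping_window_count(self):
        assert len(extract_windows(_matrix(1000), 400, 20)) == 31  # floor(600/20)+1

    def test_too_short_sequence_gives_no_windows(self, caplog):
        with caplog.at_level("WARNING"):
            assert extract_windows(_matrix(399), 400, 20) == []
        assert "shorter than window" in caplog.text

    def test_windows_are_contiguous_slices(self):
        m = _matrix(500)
        m.data[:] = np.arange(500)[:, None]
        ws = extract_windows(m, 100, 50)
        for w in ws:
            np.testing.assert_array_equal(
                w.data[:, 0], np.arange(w.start_index, w.start_index + 100)
            )

    @settings(deadline=None, max_examples=200)
    @given(
        n=st.integers(1, 5000), W=st.integers(1, 500), stride=st.integers(1, 500)
    )
    def test_window_count_formula(self, n, W, stride):
        starts = window_starts(n, W, stride)
        expected = 0 if n < W else (n - W) // stride + 1
        assert len(starts) == expected
        assert all(s + W <= n for s in starts)


class TestRecognitionLabels:
    def _session(self):
        from wodwatch import SensorStream

        t = np.arange(0, 30, 0.01)
        # one stream is enough for the labeling geometry
        stream = [
            SensorStream(
                device="wrist",
                sensor="accelerometer",
                timestamps=t,
                values=np.zeros((t.size, 3)),
            )
        ]
        sets = [
            ExerciseSet(label="E3", start_time=2.0, end_time=12.0),
            ExerciseSet(label="E5", start_time=15.0, end_time=25.0),
        ]
        return Session(participant_id="p", sets=sets, streams=stream)

    def test_window_inside_set(self):
        session = self._session()
        m = _matrix(3000)
        w = Window(data=m.data[400:800], start_index=400)  # 4..8 s, inside E3
        assert label_recognition_window(w, session, m) == "E3"

    def test_window_in_null_gap(self):
        session = self._session()
        m = _matrix(3000)
        w = Window(data=m.data[1250:1450], start_index=1250)  # 12.5..14.5 s
        assert label_recognition_window(w, session, m) == "NULL"

    def test_majority_coverage_wins(self):
        session = self._session()
        m = _matrix(3000)
        # 10.0..15.0 s: 2.0 s inside E3 (40%), 0 s E5... use 9.0..14.0: 60% E3
        w = Window(data=m.data[900:1400], start_index=900)
        assert label_recognition_window(w, session, m) == "E3"
        # 11.9..16.9 s: 0.1 s E3, 1.9 s E5, rest null -> below half -> NULL
        w = Window(data=m.data[1190:1690], start_index=1190)
        assert label_recognition_window(w, session, m) == "NULL"


class TestCountingLabels:
    def _cfg(self):
        return ExerciseConfig(t_min={"E1": 1.0})  # w = 100 samples

    def _set(self, vibs):
        return ExerciseSet(
            label="E1", start_time=0.0, end_time=10.0, vibration_times=vibs
        )

    def test_fully_contained_start_segment(self):
        m = _matrix(1000)
        # vibration at sample 250; start segment [250, 300) inside [200, 300)
        w = Window(data=m.data[200:300], start_index=200)
        assert label_counting_window(w, self._set([2.5]), self._cfg()) == 1

    def test_partially_contained_segment_is_zero(self):
        m = _matrix(1000)
        # window [160, 260) misses samples 260..299 of the start segment
        w = Window(data=m.data[160:260], start_index=160)
        assert label_counting_window(w, self._set([2.5]), self._cfg()) == 0
        # and a window ending exactly one sample early
        w = Window(data=m.data[199:299], start_index=199)
        assert label_counting_window(w, self._set([2.5]), self._cfg()) == 0

    def test_window_length_mismatch_rejected(self):
        m = _matrix(1000)
        w = Window(data=m.data[0:50], start_index=0)
        with pytest.raises(ValidationError, match="window length"):
            label_counting_window(w, self._set([2.5]), self._cfg())

    @pytest.mark.parametrize("stride", [1, 5, 10, 25, 50])
    def test_positive_positions_match_bruteforce_scan(self, stride):
        w, half = 100, 50
        vib = 437  # not aligned to any stride
        positions = window_starts(1000, w, stride)
        bits = counting_bits_for_positions(positions, w, [(vib, vib + half)])
        brute = np.array(
            [1 if p <= vib and vib + half <= p + w else 0 for p in positions]
        )
        np.testing.assert_array_equal(bits, brute)
        # the 1-positions are consecutive and roughly (w/2)/stride of them
        ones = np.flatnonzero(bits)
        assert np.all(np.diff(ones) == 1)
        assert len(ones) in (int(np.ceil(half / stride)), half // stride + 1)


class TestBatchSampling:
    def test_single_window_pool_repeats(self):
        pool = np.arange(1).reshape(1, 1)
        batch = sample_training_batch(pool, 30, np.random.default_rng(0))
        assert len(batch) == 30

    def test_seeded_batches_are_reproducible(self):
        pool = np.arange(50).reshape(50, 1)
        a = sample_training_batch(pool, 30, np.random.default_rng(3))
        b = sample_training_batch(pool, 30, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_uniform_sampling_frequencies(self):
        pool = np.arange(4).reshape(4, 1)
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [sample_training_batch(pool, 100, rng).ravel() for _ in range(100)]
        )
        freqs = np.bincount(draws, minlength=4) / draws.size
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            sample_training_batch(np.empty((0, 1)), 30, np.random.default_rng(0))
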