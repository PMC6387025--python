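"""Determinism, annotation consistency and signal structure of the simulator."""

import numpy as np
import pytest

from wodwatch import (
    SyntheticConfig,
    ValidationError,
    generate_dataset,
    generate_null_segment,
    generate_schedules,
    ground_truth_table,
)
from wodwatch.types import NULL_LABEL


class TestDeterminism:
    def test_identical_datasets_under_fixed_seed(self, small_cfg):
        a = generate_dataset(small_cfg)
        b = generate_dataset(small_cfg)
        for sa, sb in zip(a, b):
            assert sa.participant_id == sb.participant_id
            for ka, kb in zip(sa.streams, sb.streams):
                np.testing.assert_array_equal(ka.timestamps, kb.timestamps)
                np.testing.assert_array_equal(ka.values, kb.values)
            for xa, xb in zip(sa.sets, sb.sets):
                assert xa.vibration_times == xb.vibration_times

    def test_different_seed_differs(self, small_cfg, small_sessions):
        import dataclasses

        other = generate_dataset(dataclasses.replace(small_cfg, seed=8))
        assert not np.array_equal(
            other[0].streams[0].values, small_sessions[0].streams[0].values
        )

    def test_schedules_match_rendered_annotations(self, small_cfg, small_sessions):
        schedules = generate_schedules(small_cfg)
        for sched, full in zip(schedules, small_sessions):
            assert sched.streams == []
            assert len(sched.sets) == len(full.sets)
            for a, b in zip(sched.sets, full.sets):
                assert a.label == b.label
                assert a.vibration_times == b.vibration_times
                assert a.start_time == b.start_time


class TestAnnotations:
    def test_constrained_sets_have_declared_vibrations(self, small_cfg, small_sessions):
        for session in small_sessions:
            for s in session.sets:
                if s.label == NULL_LABEL:
                    continue
                assert len(s.vibration_times) == small_cfg.reps_per_set
                assert s.declared_reps == small_cfg.reps_per_set

    def test_intervals_respect_configured_range(self, small_cfg, small_sessions):
        lo, _ = small_cfg.rep_interval_s
        for session in small_sessions:
            for s in session.sets:
                if len(s.vibration_times) > 1:
                    gaps = np.diff(s.vibration_times)
                    assert gaps.min() > lo * 0.7  # subject tempo can compress a bit

    def test_free_workout_retains_reference_starts(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, scheme="free10", n_subjects=1)
        (session,) = generate_dataset(cfg)
        for s in session.sets:
            if s.label == NULL_LABEL:
                continue
            assert s.vibration_times == ()
            assert len(s.reference_starts) == 10
            assert s.declared_reps == 10

    def test_one_two_three_scheme_set_sizes(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, scheme="one-two-three", n_subjects=1)
        (session,) = generate_schedules(cfg)
        counts = [
            s.declared_reps for s in session.sets if s.label != NULL_LABEL
        ]
        k = len(cfg.exercises)
        assert counts == [1] * k + [2] * k + [3] * k

    def test_ground_truth_table_covers_all_sets(self, small_cfg, small_sessions):
        table = ground_truth_table(small_sessions)
        n_ex_sets = sum(
            1 for s in small_sessions for x in s.sets if x.label != NULL_LABEL
        )
        assert len(table) == n_ex_sets
        assert (table["n_reps"] == small_cfg.reps_per_set).all()
        assert all(len(r) == small_cfg.reps_per_set for r in table["rep_starts"])


class TestSignals:
    def test_sampling_close_to_nominal_rate(self, small_sessions):
        stream = small_sessions[0].streams[0]
        dt = np.diff(stream.timestamps)
        assert abs(dt.mean() - 0.01) < 5e-4
        assert dt.min() > 0

    def test_classes_have_distinct_spectra(self, small_cfg, small_sessions):
        """Mean per-channel spectra of different exercises must differ."""
        from wodwatch import assemble_channels

        session = small_sessions[0]
        spectra = {}
        for s in session.sets:
            if s.label == NULL_LABEL:
                continue
            m = assemble_channels(
                session,
                [("wrist", "accelerometer"), ("ankle", "accelerometer")],
                grid=(s.start_time, s.end_time),
            )
            assert m.n_samples >= 768
            x = m.data[:768] - m.data[:768].mean(axis=0)
            p = np.abs(np.fft.rfft(x, axis=0)) ** 2
            p = p.mean(axis=1)
            spectra[s.label] = p / p.sum()
        labels = list(spectra)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                dist = 0.5 * np.abs(spectra[a] - spectra[b]).sum()
                assert dist > 0.1, f"{a} and {b} spectra too similar"

    def test_null_segment_length_and_aperiodicity(self, small_cfg):
        rng = np.random.default_rng(0)
        t, values = generate_null_segment(90.0, small_cfg, rng)
        assert abs(t.size - 9000) < 50
        # Welch-style averaged periodogram above 0.5 Hz: no dominant peak
        x = values[:, 0] - values[:, 0].mean()
        seg = 512
        n_seg = x.size // seg
        psd = np.zeros(seg // 2 + 1)
        for i in range(n_seg):
            psd += np.abs(np.fft.rfft(x[i * seg : (i + 1) * seg])) ** 2
        freqs = np.fft.rfftfreq(seg, d=0.01)
        # the walk has a smooth low-frequency roll-off; aperiodicity means no
        # bin pokes above its own lower-frequency neighborhood (a repetition
        # frequency peak would rise well above the local trend)
        for i in np.flatnonzero(freqs >= 0.5):
            lo = max(0, i - 6)
            assert psd[i] < 3 * np.median(psd[lo:i])

    def test_zero_noise_segment_is_smooth(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, noise_sd=0.0, sampling_jitter_sd=0.0)
        rng = np.random.default_rng(1)
        _, values = generate_null_segment(10.0, cfg, rng)
        # a leaky random walk moves slowly: consecutive deltas stay tiny
        assert np.max(np.abs(np.diff(values[:, 0]))) < 5 * cfg.walk_sd


class TestConfigValidation:
    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(scheme="circuit")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(noise_sd=-0.1)

    def test_unknown_exercise_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(exercises=("E1", "E99"))
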