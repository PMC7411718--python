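import numpy as np
import pytest

from gaitid.segmentation import UnitStep
from gaitid.standardize import (
    StandardSample,
    build_standard_samples,
    concat_feet,
    group_k_steps,
    pair_feet,
    resize_channels,
    resize_step,
    scale_modality,
    standard_length,
)


def make_step(length, foot="left", pid="P01", fill=None, rng=None):
    rng = rng or np.random.default_rng(0)
    if fill is not None:
        pressure = np.full((length, 8), fill, dtype=int)
        accel = np.full((length, 3), fill, dtype=int)
        rotation = np.full((length, 3), fill, dtype=int)
    else:
        pressure = rng.integers(0, 3, (length, 8))
        accel = rng.integers(-100, 100, (length, 3))
        rotation = rng.integers(-100, 100, (length, 3))
    return UnitStep(
        foot=foot, start_index=0, end_index=length, pressure=pressure,
        accel=accel, rotation=rotation, participant_id=pid,
    )


class TestStandardLength:
    def test_realized_minimum(self):
        steps = [make_step(n) for n in (91, 87, 103)]
        assert standard_length(steps) == 87

    def test_singleton(self):
        assert standard_length([make_step(55)]) == 55

    def test_random_lengths_match_exhaustive_min(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(40, 200, size=25)
        steps = [make_step(int(n)) for n in lengths]
        expected = lengths[0]
        for n in lengths[1:]:  # brute force
            if n < expected:
                expected = n
        assert standard_length(steps) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            standard_length([])


class TestResize:
    def test_identity_when_len_equals_d(self):
        step = make_step(30)
        out = resize_step(step, 30)
        assert np.allclose(out["p"], step.pressure)
        assert np.allclose(out["a"], step.accel)
        assert np.allclose(out["r"], step.rotation)

    def test_linear_ramp_closed_form(self):
        """A cubic spline through affine data is affine: ramp 0..9 at d=5."""
        ramp = np.arange(10.0)[:, None]
        out = resize_channels(ramp, 5)
        assert np.allclose(out[:, 0], [0.0, 2.25, 4.5, 6.75, 9.0])

    def test_constant_channel_stays_constant(self):
        out = resize_channels(np.full((40, 2), 3.0), 87)
        assert np.allclose(out, 3.0)

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((31, 4))
        out = resize_channels(values, 87)
        assert np.allclose(out[0], values[0]) and np.allclose(out[-1], values[-1])

    def test_affine_round_trip_exact(self):
        """Resizing an affine channel down and back reproduces it exactly."""
        line = (2.5 * np.arange(25.0) - 3.0)[:, None]
        back = resize_channels(resize_channels(line, 87), 25)
        assert np.allclose(back, line, atol=1e-8)

    def test_short_step_linear_fallback(self):
        out = resize_channels(np.array([[0.0], [1.0], [2.0]]), 5)
        assert np.allclose(out[:, 0], [0.0, 0.5, 1.0, 1.5, 2.0])

    def test_d_too_small_rejected(self):
        with pytest.raises(ValueError):
            resize_channels(np.zeros((10, 1)), 1)


class TestConcatFeet:
    def test_pressure_has_16_columns_imu_6(self):
        left = [np.ones((87, 8))]
        right = [np.zeros((87, 8))]
        (joined,) = concat_feet(left, right)
        assert joined.shape == (87, 16)
        assert joined[:, :8].all() and not joined[:, 8:].any()
        (rot,) = concat_feet([np.ones((87, 3))], [np.zeros((87, 3))])
        assert rot.shape == (87, 6)

    def test_mismatched_d_rejected(self):
        with pytest.raises(ValueError, match="standard length"):
            concat_feet([np.ones((87, 3))], [np.ones((43, 3))])

    def test_index_pairing_drops_remainder(self):
        left = [make_step(20, "left") for _ in range(5)]
        right = [make_step(20, "right") for _ in range(3)]
        assert len(pair_feet(left, right)) == 3


class TestGrouping:
    def _samples(self, counts, d=12):
        rng = np.random.default_rng(0)
        out = []
        for pid, n in counts.items():
            for _ in range(n):
                out.append(
                    StandardSample(
                        participant_id=pid, k=1, d=d,
                        pressure=rng.random((d, 16)),
                        accel=rng.random((d, 6)),
                        rotation=rng.random((d, 6)),
                    )
                )
        return out

    def test_seven_steps_k2_gives_three(self):
        grouped = group_k_steps(self._samples({"A": 7}), 2)
        assert len(grouped) == 3
        assert all(g.pressure.shape == (24, 16) for g in grouped)

    def test_k1_is_identity(self):
        samples = self._samples({"A": 4, "B": 3})
        assert group_k_steps(samples, 1) == samples

    def test_counts_match_floor_sum_oracle(self):
        rng = np.random.default_rng(5)
        counts = {f"P{i}": int(rng.integers(1, 30)) for i in range(8)}
        for k in (2, 3, 4):
            grouped = group_k_steps(self._samples(counts), k)
            expected = sum(n // k for n in counts.values())  # brute force
            assert len(grouped) == expected

    def test_rows_stack_in_temporal_order(self):
        samples = self._samples({"A": 2})
        (g,) = group_k_steps(samples, 2)
        assert np.array_equal(g.pressure[:12], samples[0].pressure)
        assert np.array_equal(g.pressure[12:], samples[1].pressure)

    def test_invalid_k_rejected(self):
        samples = self._samples({"A": 4})
        for k in (0, 5):
            with pytest.raises(ValueError):
                group_k_steps(samples, k)


class TestStandardSampleInvariants:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="pressure"):
            StandardSample(participant_id="A", k=1, d=10,
                           pressure=np.zeros((10, 15)))
        with pytest.raises(ValueError, match="at least one"):
            StandardSample(participant_id="A", k=1, d=10)

    def test_scaling_ranges(self):
        p = scale_modality(np.array([[0, 1, 2]]), "p")
        assert np.allclose(p, [[0.0, 0.5, 1.0]])
        a = scale_modality(np.array([[-32768, 32768]]), "a")
        assert np.allclose(a, [[-1.0, 1.0]])


def test_build_standard_samples_cohort(clean_cohort):
    from gaitid.pipeline import segment_dataset

    steps = segment_dataset(clean_cohort.recordings)
    samples = build_standard_samples(steps)
    d = samples[0].d
    all_steps = [s for feet in steps.values() for ss in feet.values() for s in ss]
    assert d == min(len(s) for s in all_steps)
    for s in samples:
        assert s.pressure.shape == (d, 16)
        assert s.accel.shape == (d, 6) and s.rotation.shape == (d, 6)
    per_pid = {
        pid: min(len(feet["left"]), len(feet["right"]))
        for pid, feet in steps.items()
    }
    assert len(samples) == sum(per_pid.values())
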