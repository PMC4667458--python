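"""Module mean profiles, spline smoothing, dynamics classes, crossing timestamps,
wave grouping and response-stage assignment."""

import numpy as np
import pytest

from lipidtrn.filtering import compute_log_ratios, filter_transcripts
from lipidtrn.smoothing import SmoothProfile, smooth_and_resample
from lipidtrn.synthetic import simulate_expression, wave_bench_spec
from lipidtrn.waves import (
    NoCrossingError,
    assign_stage,
    classify_dynamics,
    classify_modules,
    crossing_timestamp,
    group_into_waves,
    module_mean_profile,
)

from conftest import ratios_from_planted

TIMES = [0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0]


def profile_from(values, step=1.0):
    values = np.asarray(values, dtype=float)
    grid = step * np.arange(len(values))
    return SmoothProfile("p", grid, values, None)


class TestMeanProfile:
    def test_single_member_is_identity(self):
        ratios = ratios_from_planted({"a": np.linspace(0, 2, 8), "b": np.zeros(8)}, TIMES)
        got = module_mean_profile(ratios, ["a"])
        assert np.allclose(got, ratios.profile("a"))

    def test_opposite_members_cancel(self):
        r = np.linspace(0, 2, 8)
        r[0] = 0
        ratios = ratios_from_planted({"a": r, "b": -r}, TIMES)
        assert np.allclose(module_mean_profile(ratios, ["a", "b"]), 0.0)

    def test_identical_members_average_to_themselves(self):
        r = np.sin(np.asarray(TIMES) / 40.0)
        r[0] = 0
        ratios = ratios_from_planted({f"m{i}": r for i in range(3)}, TIMES)
        assert np.allclose(module_mean_profile(ratios, ["m0", "m1", "m2"]), r, atol=1e-12)

    def test_no_overlap_errors(self):
        ratios = ratios_from_planted({"a": np.zeros(8)}, TIMES)
        with pytest.raises(ValueError, match="no members"):
            module_mean_profile(ratios, ["zz"])


class TestSmoothing:
    def test_constant_profile_stays_constant(self):
        sp = smooth_and_resample(TIMES, np.full(8, 1.7))
        assert np.allclose(sp.values, 1.7, atol=1e-9)

    def test_interpolation_limit_reproduces_linear_data(self):
        t = np.asarray(TIMES)
        sp = smooth_and_resample(t, 0.05 * t, lam=0.0)
        assert np.abs(sp.values - 0.05 * sp.grid).max() <= 1e-9

    def test_heavy_smoothing_reduces_variance(self, rng):
        t = np.linspace(0, 120, 40)
        y = np.sin(t / 8.0) + rng.normal(0, 0.5, t.size)
        sp = smooth_and_resample(t, y, lam=1e5)
        assert np.var(sp.values) < np.var(y)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            smooth_and_resample([0.0, 10.0, 5.0, 20.0], [0, 1, 2, 3])

    def test_grid_covers_span_at_requested_step(self):
        sp = smooth_and_resample(TIMES, np.zeros(8), grid_step_min=1.0)
        assert sp.grid[0] == 0.0 and sp.grid[-1] == 120.0 and sp.step == 1.0


class TestClassifyAndCrossing:
    def test_logistic_rise_is_monotonic_up(self):
        t = np.arange(0, 200.0)
        sp = profile_from(2.0 / (1 + np.exp(-(t - 60) / 10.0)))
        assert classify_dynamics(sp) == ("monotonic", "up")

    def test_pulse_is_transient_up(self):
        t = np.arange(0, 200.0)
        pulse = 2.0 * np.exp(-((t - 80) ** 2) / (2 * 20.0**2))
        assert classify_dynamics(profile_from(pulse)) == ("transient", "up")

    def test_bounded_profile_is_flat(self):
        t = np.arange(0, 200.0)
        sp = profile_from(0.9 * np.sin(t / 30.0))
        assert classify_dynamics(sp) == ("flat", None)
        with pytest.raises(NoCrossingError):
            crossing_timestamp(sp)

    def test_downward_pulse_direction(self):
        t = np.arange(0, 200.0)
        pulse = -2.0 * np.exp(-((t - 80) ** 2) / (2 * 20.0**2))
        assert classify_dynamics(profile_from(pulse)) == ("transient", "down")

    def test_linear_ramp_crosses_at_thirty_minutes(self):
        sp = smooth_and_resample(TIMES, np.asarray(TIMES) / 30.0, lam=0.0)
        assert crossing_timestamp(sp, 1.0) == pytest.approx(30.0, abs=0.05)

    def test_step_profile_crossing_within_one_grid_step(self):
        t = np.arange(0, 121.0, 1.0)
        sp = profile_from(np.where(t >= 45, 2.0, 0.0))
        assert abs(crossing_timestamp(sp, 1.0) - 45.0) <= 1.0

    def test_doubling_threshold_never_decreases_timestamp(self):
        t = np.arange(0, 200.0)
        sp = profile_from(3.0 / (1 + np.exp(-(t - 60) / 15.0)))
        assert crossing_timestamp(sp, 2.0) >= crossing_timestamp(sp, 1.0)


class TestStageAssignment:
    @pytest.mark.parametrize(
        "timestamp,stage",
        [
            (12.0, "early"),
            (44.0, "mid"),
            (109.0, "late"),
            (13.0, "early"),
            (15.0, "early"),
            (26.0, "mid"),
            (18.0, "early"),  # boundary ties fall to the earlier stage
            (60.0, "mid"),
            (371.0, "late"),
            (418.0, "late"),
            (481.0, "late"),  # beyond the nominal 8-h window still counts as late
        ],
    )
    def test_printed_timestamp_stage_pairs(self, timestamp, stage):
        assert assign_stage(timestamp) == stage

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError):
            assign_stage(-1.0)


class TestWaveGrouping:
    def _dynamics(self, planted, times):
        ratios = ratios_from_planted(planted, times)
        assignment = {f"mod_{tid}": [tid] for tid in planted}
        return ratios, assignment, classify_modules(ratios, assignment, lam=0.0)

    def test_nearby_timestamps_quantize_to_one_wave(self):
        times = [0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 45.0, 60.0]
        t = np.asarray(times)
        a = np.clip((t - 12.0) / 12.0, 0, 2)  # crosses ~24
        b = np.clip((t - 13.0) / 12.0, 0, 2)  # crosses ~25
        ratios, assignment, mods = self._dynamics({"a": a, "b": b}, times)
        waves = group_into_waves(mods, ratios, assignment, lam=0.0)
        assert len(waves) == 1
        assert set(waves[0].module_ids) == {"mod_a", "mod_b"}
        assert 24.0 <= waves[0].timestamp < 30.0

    def test_dynamics_class_separates_waves(self):
        t = np.arange(0.0, 121.0, 6.0)
        mono = 2.0 / (1 + np.exp(-(t - 30) / 5.0))
        mono -= mono[0]
        pulse = 2.2 * np.exp(-((t - 40) ** 2) / (2 * 12.0**2))
        pulse -= pulse[0]
        ratios, assignment, mods = self._dynamics({"m": mono, "p": pulse}, list(t))
        waves = group_into_waves(mods, ratios, assignment, lam=0.0)
        assert len(waves) == 2
        assert {w.dynamics for w in waves} == {"monotonic", "transient"}

    def test_empty_module_list_gives_no_waves(self):
        times = [0.0, 10.0, 20.0, 30.0, 45.0]
        ratios = ratios_from_planted({"a": np.zeros(5)}, times)
        assert group_into_waves([], ratios, {}) == []

    def test_waves_partition_non_flat_modules(self):
        expr, assignment, _, _ = simulate_expression(wave_bench_spec(11))
        ratios = compute_log_ratios(expr)
        mods = classify_modules(ratios, assignment)
        waves = group_into_waves(mods, ratios, assignment)
        covered = [m for w in waves for m in w.module_ids]
        non_flat = [m.module_id for m in mods if m.dynamics != "flat"]
        assert sorted(covered) == sorted(non_flat)
        assert [w.timestamp for w in waves] == sorted(w.timestamp for w in waves)


class TestPlantedWaveRecovery:
    def test_noiseless_classes_and_timestamps(self):
        expr, assignment, _, truth = simulate_expression(wave_bench_spec(5))
        ratios = compute_log_ratios(expr)
        report = filter_transcripts(ratios)
        assert all(t in report.kept for mods in assignment.values() for t in mods)
        for md in classify_modules(ratios, assignment):
            kind, direction = truth.module_kind[md.module_id]
            assert (md.dynamics, md.direction) == (kind, direction)
            assert md.timestamp == pytest.approx(truth.module_crossing[md.module_id], abs=2.0)
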