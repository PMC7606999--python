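"""Objective-function tests: penalties, modulation term, analytic gradient."""

import numpy as np
import pytest

import brachyopt as b
from brachyopt.errors import ConfigurationError, InputError

from conftest import random_instance


def single_roi_points(n, name="tar"):
    return b.CalcPointSet(
        points=np.zeros((n, 3)), voxel_volume=1e-3,
        roi_membership={name: np.arange(n)},
    )


class TestRoiPenalty:
    def test_target_fully_above_objective_is_unpenalized(self):
        entry = b.ROIObjective("t", "target", minimum=b.DoseGoal(6.0, 100.0))
        assert b.roi_penalty(np.array([6.1, 7.0, 12.0]), entry) == 0.0

    def test_underdosed_target_voxel_hand_value(self):
        entry = b.ROIObjective("t", "target", minimum=b.DoseGoal(6.0, 100.0))
        assert b.roi_penalty(np.array([5.0]), entry) == pytest.approx(100.0)

    def test_overdosed_oar_voxel_hand_value(self):
        entry = b.ROIObjective("r", "oar", maximum=b.DoseGoal(4.5, 80.0))
        assert b.roi_penalty(np.array([5.0]), entry) == pytest.approx(80 * 0.25)

    def test_exact_equality_contributes_zero(self):
        tar = b.ROIObjective("t", "target", minimum=b.DoseGoal(6.0, 100.0))
        oar = b.ROIObjective("o", "oar", maximum=b.DoseGoal(4.5, 80.0))
        assert b.roi_penalty(np.array([6.0]), tar) == 0.0
        assert b.roi_penalty(np.array([4.5]), oar) == 0.0

    def test_both_sided_objective_sums_both_violations(self):
        entry = b.ROIObjective(
            "t", "target", minimum=b.DoseGoal(6.0, 10.0), maximum=b.DoseGoal(9.0, 2.0)
        )
        value = b.roi_penalty(np.array([5.0, 10.0, 7.0]), entry)
        assert value == pytest.approx(10 * 1.0 + 2 * 1.0)

    def test_invalid_spec_entries_rejected(self):
        with pytest.raises(ConfigurationError):
            b.ROIObjective("t", "target", minimum=None)
        with pytest.raises(ConfigurationError):
            b.ROIObjective("o", "oar", maximum=None)
        with pytest.raises(ConfigurationError):
            b.DoseGoal(dose=-1.0, weight=1.0)
        with pytest.raises(ConfigurationError):
            b.DoseGoal(dose=1.0, weight=-1.0)


class TestModulationTerm:
    def make_plan(self, *time_vectors):
        channels = tuple(
            b.Channel(f"c{i}", np.zeros((len(t), 3))) for i, t in enumerate(time_vectors)
        )
        return b.Plan(channels, tuple(np.asarray(t, dtype=float) for t in time_vectors))

    def test_uniform_times_give_zero(self):
        plan = self.make_plan([2.0, 2.0, 2.0], [5.0, 5.0])
        assert b.dwell_time_modulation_term(plan, 10.0) == 0.0

    def test_hand_value_single_channel(self):
        plan = self.make_plan([1.0, 1.0, 2.0])
        assert b.dwell_time_modulation_term(plan, 10.0) == pytest.approx(10 / 3)

    def test_zero_weight_gives_zero(self):
        plan = self.make_plan([1.0, 9.0, 4.0])
        assert b.dwell_time_modulation_term(plan, 0.0) == 0.0

    def test_channels_are_independent(self):
        # anchored at each channel's own minimum, so a large between-
        # channel difference with uniform channels costs nothing
        plan = self.make_plan([1.0, 1.0], [100.0, 100.0])
        assert b.dwell_time_modulation_term(plan, 50.0) == 0.0


class TestObjectiveValue:
    def test_feasible_uniform_plan_has_zero_objective(self):
        kernel = b.DoseKernel(
            values=np.full((4, 2), 5.0), dwell_index_map=((0, 0), (0, 1)),
            channel_sizes=(2,),
        )
        points = single_roi_points(4)
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(6.0, 100.0)),)
        )
        cfg = b.OptimizerConfig(dtmf=25.0)
        # uniform times of 1 s give 10 Gy everywhere: above the minimum
        assert b.objective_value(np.ones(2), kernel, points, spec, cfg) == 0.0

    def test_single_voxel_hand_value(self):
        kernel = b.DoseKernel(
            values=np.array([[5.0]]), dwell_index_map=((0, 0),), channel_sizes=(1,)
        )
        points = single_roi_points(1)
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(6.0, 100.0)),)
        )
        cfg = b.OptimizerConfig(dtmf=77.0)
        # dose 5 Gy, objective 6 Gy, weight 100 -> F = 100; one dwell so no spread
        assert b.objective_value(np.ones(1), kernel, points, spec, cfg) == pytest.approx(100.0)

    def test_objective_is_linear_in_weights(self):
        rng = np.random.default_rng(21)
        kernel, points, spec, times = random_instance(rng)
        cfg = b.OptimizerConfig(dtmf=7.0)
        f1 = b.objective_value(times, kernel, points, spec, cfg)
        f2 = b.objective_value(
            times, kernel, points, spec.scaled_weights(2.0),
            b.OptimizerConfig(dtmf=14.0),
        )
        assert f1 > 0
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_objective_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(5)
        cfg = b.OptimizerConfig(dtmf=3.0)
        for _ in range(20):
            kernel, points, spec, times = random_instance(rng)
            assert b.objective_value(times, kernel, points, spec, cfg) >= 0.0

    def test_shape_mismatch_rejected(self):
        kernel = b.DoseKernel(
            values=np.ones((2, 2)), dwell_index_map=((0, 0), (0, 1)), channel_sizes=(2,)
        )
        points = single_roi_points(2)
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(1.0, 1.0)),)
        )
        with pytest.raises(InputError):
            b.objective_value(np.ones(3), kernel, points, spec, b.OptimizerConfig())

    def test_subsample_weighting_is_unbiased_for_uniform_roi(self):
        # halving the sampled points while doubling their multiplicity
        # leaves the dose penalty unchanged for identical doses
        kernel_full = b.DoseKernel(
            values=np.full((4, 1), 2.0), dwell_index_map=((0, 0),), channel_sizes=(1,)
        )
        points_full = b.CalcPointSet(
            points=np.zeros((4, 3)), voxel_volume=1e-3,
            roi_membership={"tar": np.arange(4)}, roi_point_volume={"tar": 1e-3},
        )
        kernel_half = b.DoseKernel(
            values=np.full((2, 1), 2.0), dwell_index_map=((0, 0),), channel_sizes=(1,)
        )
        points_half = b.CalcPointSet(
            points=np.zeros((2, 3)), voxel_volume=1e-3,
            roi_membership={"tar": np.arange(2)}, roi_point_volume={"tar": 2e-3},
        )
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(6.0, 100.0)),)
        )
        cfg = b.OptimizerConfig(dtmf=0.0)
        t = np.array([1.0])
        full = b.objective_value(t, kernel_full, points_full, spec, cfg)
        half = b.objective_value(t, kernel_half, points_half, spec, cfg)
        assert full == pytest.approx(half)


class TestGradient:
    def test_zero_gradient_at_strictly_feasible_uniform_plan(self):
        kernel = b.DoseKernel(
            values=np.full((3, 2), 5.0), dwell_index_map=((0, 0), (0, 1)),
            channel_sizes=(2,),
        )
        points = single_roi_points(3)
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(6.0, 100.0)),)
        )
        grad = b.objective_gradient(np.ones(2), kernel, points, spec,
                                    b.OptimizerConfig(dtmf=9.0))
        np.testing.assert_array_equal(grad, np.zeros(2))

    def test_underdosed_single_dwell_gradient_hand_value(self):
        d = 0.5
        kernel = b.DoseKernel(
            values=np.array([[d]]), dwell_index_map=((0, 0),), channel_sizes=(1,)
        )
        points = single_roi_points(1)
        p, d0 = 100.0, 6.0
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(d0, p)),)
        )
        t = np.array([1.0])
        grad = b.objective_gradient(t, kernel, points, spec, b.OptimizerConfig(dtmf=0.0))
        expected = 2 * p * (d * t[0] - d0) * d
        assert grad[0] == pytest.approx(expected)
        assert grad[0] < 0

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(1234)
        cfg = b.OptimizerConfig(dtmf=5.0)
        h = 1e-5
        for _ in range(50):
            kernel, points, spec, times = random_instance(rng)
            grad = b.objective_gradient(times, kernel, points, spec, cfg)
            fd = np.empty_like(grad)
            for j in range(times.size):
                tp, tm = times.copy(), times.copy()
                tp[j] += h
                tm[j] -= h
                fd[j] = (
                    b.objective_value(tp, kernel, points, spec, cfg)
                    - b.objective_value(tm, kernel, points, spec, cfg)
                ) / (2 * h)
            np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-5)

    def test_modulation_gradient_couples_through_channel_minimum(self):
        # one channel, times (1, 3): d/dt of p/N * (t2 - t1)^2
        kernel = b.DoseKernel(
            values=np.zeros((1, 2)), dwell_index_map=((0, 0), (0, 1)), channel_sizes=(2,)
        )
        points = single_roi_points(1)
        spec = b.ObjectiveSpec(
            (b.ROIObjective("tar", "target", minimum=b.DoseGoal(1.0, 0.0)),)
        )
        p = 10.0
        grad = b.objective_gradient(
            np.array([1.0, 3.0]), kernel, points, spec, b.OptimizerConfig(dtmf=p)
        )
        np.testing.assert_allclose(grad, [-(2 * p / 2) * 2.0, (2 * p / 2) * 2.0])


class TestSpecSerialization:
    def test_json_round_trip(self, tmp_path):
        spec = b.standard_objectives()
        path = tmp_path / "objectives.json"
        spec.to_json(path)
        loaded = b.ObjectiveSpec.from_json(path)
        assert loaded == spec

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            b.ObjectiveSpec.from_json(tmp_path / "nope.json")
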