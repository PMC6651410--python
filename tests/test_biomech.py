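"""Geometry and kinematics of the COM-COP inclination angle."""

import numpy as np
import pytest

from comcop.biomech import (
    AnthropometricModel,
    inclination_angles,
    net_cop,
    segment_gait_cycle,
    time_normalize,
    whole_body_com,
)
from comcop.synthetic import GaitEvents, decompose_com_to_segments


class TestWholeBodyCom:
    def test_point_mass_returns_point(self):
        p = np.array([0.3, -0.1, 0.9])
        segs = np.tile(p, (15, 50, 1))
        com = whole_body_com(segs)
        assert np.allclose(com, p, atol=1e-12)

    def test_two_point_weighted_mean(self):
        # 0.6 at the origin, 0.4 at (1,0,0); the other 13 slots carry
        # negligible mass so the weighted mean is (0.4, 0, 0).
        eps = 1e-12
        fractions = (0.6 - 13 * eps, 0.4) + (eps,) * 13
        model = AnthropometricModel(
            segment_names=tuple(f"s{i}" for i in range(15)), mass_fractions=fractions
        )
        segs = np.zeros((15, 1, 3))
        segs[1, :, 0] = 1.0
        assert np.allclose(whole_body_com(segs, model), [0.4, 0, 0], atol=1e-9)

    def test_decomposition_round_trip(self, rng):
        com = rng.normal(0, 1, (200, 3))
        fractions = AnthropometricModel().fractions
        segs = decompose_com_to_segments(com, fractions, seed=5)
        assert np.allclose(whole_body_com(segs), com, atol=1e-9)

    def test_wrong_segment_count_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            whole_body_com(np.zeros((14, 10, 3)))


class TestNetCop:
    def test_equal_forces_midpoint(self):
        c1 = np.zeros((5, 2))
        c2 = np.ones((5, 2))
        cop, valid = net_cop(c1, c2, np.full(5, 400.0), np.full(5, 400.0))
        assert valid.all()
        assert np.allclose(cop, 0.5)

    def test_single_support_is_loaded_plate(self):
        c1 = np.array([[0.1, 0.2]] * 3)
        c2 = np.array([[9.9, 9.9]] * 3)
        cop, _ = net_cop(c1, c2, np.full(3, 700.0), np.zeros(3))
        assert np.allclose(cop, c1)

    def test_hand_computed_weighted_mean(self):
        cop, _ = net_cop(
            np.array([[0.0, 0.0]]), np.array([[0.4, 0.1]]),
            np.array([600.0]), np.array([200.0]),
        )
        assert np.allclose(cop, [[0.1, 0.025]], atol=1e-12)

    def test_convex_combination(self, rng):
        c1 = rng.normal(0, 1, (100, 2))
        c2 = rng.normal(0, 1, (100, 2))
        f1 = rng.uniform(0, 800, 100)
        f2 = rng.uniform(0, 800, 100)
        cop, valid = net_cop(c1, c2, f1, f2)
        lo = np.minimum(c1, c2)[valid]
        hi = np.maximum(c1, c2)[valid]
        assert np.all(cop[valid] >= lo - 1e-12)
        assert np.all(cop[valid] <= hi + 1e-12)

    def test_zero_total_force_flagged(self):
        cop, valid = net_cop(
            np.zeros((2, 2)), np.zeros((2, 2)), np.array([0.0, 500.0]), np.zeros(2)
        )
        assert list(valid) == [False, True]
        assert np.isnan(cop[0]).all()


class TestInclinationAngles:
    def test_vertical_alignment_is_zero(self):
        ia = inclination_angles(np.array([[0.0, 0.0, 1.0]]), np.zeros((1, 2)))
        assert ia.sagittal[0] == pytest.approx(0.0, abs=1e-12)
        assert ia.frontal[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p, expect_sag, expect_fro", [
        ((0.1, 0.0, 1.0), 5.710, 0.0),
        ((0.0, 0.1, 1.0), 0.0, 5.710),
    ])
    def test_worked_examples(self, p, expect_sag, expect_fro):
        ia = inclination_angles(np.array([p]), np.zeros((1, 2)))
        exact = np.degrees(np.arcsin(0.1 / np.sqrt(1.01)))
        got = ia.sagittal[0] if expect_sag else ia.frontal[0]
        assert got == pytest.approx(exact, abs=1e-9)
        assert got == pytest.approx(5.710, abs=1e-3)
        other = ia.frontal[0] if expect_sag else ia.sagittal[0]
        assert other == pytest.approx(0.0, abs=1e-12)

    def test_matches_atan2_oracle(self, rng):
        """asin-composed components equal the direct COP->COM vs vertical angle."""
        com = np.column_stack([
            rng.normal(0, 0.2, 1000), rng.normal(0, 0.2, 1000), rng.uniform(0.5, 1.5, 1000)
        ])
        cop = rng.normal(0, 0.2, (1000, 2))
        ia = inclination_angles(com, cop)
        p = com - np.column_stack([cop, np.zeros(1000)])
        direct = np.degrees(np.arctan2(np.hypot(p[:, 0], p[:, 1]), p[:, 2]))
        composed = np.degrees(np.arcsin(np.sqrt(
            np.sin(np.radians(ia.sagittal)) ** 2 + np.sin(np.radians(ia.frontal)) ** 2
        )))
        assert np.max(np.abs(composed - direct)) < 1e-9

    def test_scale_invariance(self, rng):
        com = np.array([[0.2, -0.1, 1.1]])
        cop = np.array([[0.05, 0.02]])
        base = inclination_angles(com, cop)
        for k in (0.1, 3.7):
            scaled = inclination_angles(
                np.column_stack([cop, [0]]) + k * (com - np.column_stack([cop, [0]])), cop
            )
            assert scaled.sagittal[0] == pytest.approx(base.sagittal[0], abs=1e-9)
            assert scaled.frontal[0] == pytest.approx(base.frontal[0], abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="height"):
            inclination_angles(np.array([[0.0, 0.0, 0.0]]), np.zeros((1, 2)))


class TestGaitCycle:
    def test_modified_cycle_spec_example(self):
        events = GaitEvents(
            heel_strikes=((0.0, "R"), (0.62, "L")), toe_offs=((0.12, "L"),)
        )
        windows = segment_gait_cycle(events, policy="paper_modified")
        assert windows == [(0.12, 0.62)]

    def test_standard_cycle_heel_strike_to_heel_strike(self):
        events = GaitEvents(
            heel_strikes=((0.0, "R"), (0.55, "L"), (1.1, "R")), toe_offs=((0.12, "L"),)
        )
        windows = segment_gait_cycle(events, policy="standard")
        assert (0.0, 1.1) in windows

    def test_windows_ordered_on_generated_trial(self, trial):
        for start, end in segment_gait_cycle(trial.events):
            assert start < end

    def test_unknown_policy_rejected(self, trial):
        with pytest.raises(ValueError, match="policy"):
            segment_gait_cycle(trial.events, policy="bogus")


class TestTimeNormalize:
    def test_constant_preserved(self):
        t = np.linspace(0, 1, 37)
        out = time_normalize(t, np.full(37, 4.2), n=100)
        assert out.shape == (100,)
        assert np.allclose(out, 4.2, atol=1e-12)

    def test_linear_ramp_endpoints_exact(self):
        t = np.linspace(0, 2, 50)
        out = time_normalize(t, 3.0 + 2.5 * t, n=100)
        assert out[0] == pytest.approx(3.0, abs=1e-9)
        assert out[-1] == pytest.approx(8.0, abs=1e-9)
        assert np.allclose(out, np.linspace(3.0, 8.0, 100), atol=1e-9)

    def test_sine_resampling_accuracy(self):
        t = np.linspace(0, 1, 120)
        out = time_normalize(t, np.sin(2 * np.pi * t), n=100)
        assert np.max(np.abs(out - np.sin(2 * np.pi * np.linspace(0, 1, 100)))) < 1e-3

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            time_normalize(np.array([0.0]), np.array([1.0]))
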