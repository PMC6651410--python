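"""Physical consistency of the synthetic gait generator."""

import numpy as np
import pytest

from comcop.biomech import trial_ground_truth
from comcop.synthetic import (
    G,
    NoiseSpec,
    TrunkMotion,
    decompose_com_to_segments,
    sample_subject,
    simulate_trial,
    synthesize_imu,
)
from comcop.biomech import AnthropometricModel


class TestSampleSubject:
    def test_same_seed_identical(self):
        assert sample_subject(7) == sample_subject(7)

    def test_population_statistics(self):
        heights = np.array([sample_subject(i).height for i in range(1000)])
        assert abs(heights.mean() - 171.2) < 0.5
        assert np.all(heights >= 171.2 - 3 * 4.3)
        assert np.all(heights <= 171.2 + 3 * 4.3)

    def test_speed_scalars_bracket_unity(self, subject):
        assert subject.speed_scalars["slow"] < 1.0 < subject.speed_scalars["fast"]


class TestSimulateTrial:
    def test_deterministic(self, subject):
        a = simulate_trial(subject, "normal", seed=11)
        b = simulate_trial(subject, "normal", seed=11)
        assert np.array_equal(a.imu, b.imu)
        assert np.array_equal(a.segment_coms, b.segment_coms)
        assert np.array_equal(a.fz_1, b.fz_1)
        assert a.events == b.events

    def test_unknown_speed_rejected(self, subject):
        with pytest.raises(ValueError, match="speed_class"):
            simulate_trial(subject, "sprint", seed=0)

    @pytest.mark.parametrize("speed", ["slow", "normal", "fast"])
    def test_ia_envelopes(self, subject, speed):
        """Ground-truth IA stays within the physiological envelopes."""
        ia = trial_ground_truth(simulate_trial(subject, speed, seed=21))
        assert np.all(np.abs(ia.sagittal) <= 20.0)
        assert np.all(np.abs(ia.frontal) <= 10.0)

    def test_grf_impulse_balance(self, trial):
        """Mean total vertical GRF over one full stride equals body weight."""
        t0 = trial.events.heel_strikes[1][0]
        stride = trial.meta["stride_time"]
        m = (trial.force_times >= t0) & (trial.force_times < t0 + stride)
        mean_force = (trial.fz_1[m] + trial.fz_2[m]).mean()
        assert mean_force == pytest.approx(trial.meta["mass"] * G, rel=0.02)

    def test_support_never_lost_mid_trial(self, trial):
        total = trial.fz_1 + trial.fz_2
        mid = (trial.force_times >= trial.events.heel_strikes[0][0] + 0.01)
        assert np.all(total[mid] > 0)

    def test_speed_ordering(self, subject):
        speeds = {
            s: simulate_trial(subject, s, seed=2).meta["speed"]
            for s in ("slow", "normal", "fast")
        }
        assert speeds["slow"] < speeds["normal"] < speeds["fast"]

    def test_segments_recompose_to_com(self, quiet_trial):
        """Mass-weighted segment sum reproduces the prescribed COM exactly."""
        from comcop.biomech import whole_body_com
        com = whole_body_com(quiet_trial.segment_coms)
        # the weighted offsets cancel by construction
        segs2 = decompose_com_to_segments(
            com, AnthropometricModel().fractions, seed=99
        )
        assert np.allclose(whole_body_com(segs2), com, atol=1e-9)


class TestDecompose:
    def test_zero_amplitude_returns_copies(self, rng):
        com = rng.normal(0, 1, (30, 3))
        segs = decompose_com_to_segments(
            com, AnthropometricModel().fractions, seed=1, amplitude=0.0
        )
        assert np.allclose(segs, com[None], atol=1e-12)

    def test_weighted_offsets_cancel(self, rng):
        com = rng.normal(0, 1, (60, 3))
        fr = AnthropometricModel().fractions
        segs = decompose_com_to_segments(com, fr, seed=3)
        offset_sum = np.einsum("s,snc->nc", fr, segs - com[None])
        assert np.max(np.abs(offset_sum)) < 1e-9

    def test_bad_fractions_rejected(self, rng):
        com = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError, match="15"):
            decompose_com_to_segments(com, np.full(14, 1 / 14), seed=0)
        with pytest.raises(ValueError, match="sum"):
            decompose_com_to_segments(com, np.full(15, 0.1), seed=0)


class TestSynthesizeImu:
    @staticmethod
    def _static_motion(n=200, rate=100.0):
        t = np.arange(n) / rate
        return TrunkMotion(
            times=t,
            sensor_pos=np.tile([0.0, 0.0, 1.0], (n, 1)),
            rot=np.tile(np.eye(3), (n, 1, 1)),
        )

    def test_static_upright_reads_gravity_and_field(self):
        silent = NoiseSpec(0.0, 0.0, 0.0, 0.0)
        _, sig = synthesize_imu(self._static_motion(), silent)
        accel, gyro, mag = sig[:, :3], sig[:, 3:6], sig[:, 6:]
        assert np.allclose(np.linalg.norm(accel, axis=1), G, atol=1e-9)
        assert np.allclose(gyro, 0.0, atol=1e-9)
        from comcop.synthetic import EARTH_FIELD_UT
        assert np.allclose(
            np.linalg.norm(mag, axis=1), np.linalg.norm(EARTH_FIELD_UT), atol=1e-9
        )

    def test_accel_matches_finite_difference_oracle(self):
        """Noise-free accelerometer = FD of sensor position + rotated gravity."""
        rate = 1080.0
        t = np.arange(int(4 * rate)) / rate
        pos = np.column_stack([
            0.3 * np.sin(2 * np.pi * 1.0 * t),
            0.05 * np.sin(2 * np.pi * 0.9 * t + 0.4),
            1.0 + 0.02 * np.cos(2 * np.pi * 1.9 * t),
        ])
        angle = 0.05 * np.sin(2 * np.pi * 0.95 * t)
        rot = np.zeros((len(t), 3, 3))
        rot[:, 0, 0] = np.cos(angle)
        rot[:, 0, 1] = -np.sin(angle)
        rot[:, 1, 0] = np.sin(angle)
        rot[:, 1, 1] = np.cos(angle)
        rot[:, 2, 2] = 1.0
        motion = TrunkMotion(times=t, sensor_pos=pos, rot=rot)
        times, sig = synthesize_imu(motion, NoiseSpec(0, 0, 0, 0), imu_rate=rate)
        # independent oracle: plain central second difference
        h = 1.0 / rate
        acc = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) / h**2
        expected = np.einsum(
            "nij,nj->ni", rot[1:-1].transpose(0, 2, 1), acc + [0, 0, G]
        )
        # skip one sample at each end where the implementation's gradient
        # stencil is one-sided
        assert np.max(np.abs(sig[2:-2, :3] - expected[1:-1])) < 1e-3

    def test_channels_respect_sensor_ranges(self, trial):
        accel, gyro, mag = trial.imu[:, :3], trial.imu[:, 3:6], trial.imu[:, 6:]
        assert np.all(np.abs(accel) <= 16 * G)
        assert np.all(np.abs(gyro) <= 2000.0)
        assert np.all(np.abs(mag) <= 4800.0)

    def test_too_short_motion_rejected(self):
        one = TrunkMotion(
            times=np.array([0.0]), sensor_pos=np.zeros((1, 3)),
            rot=np.eye(3)[None],
        )
        with pytest.raises(ValueError, match="two samples"):
            synthesize_imu(one, NoiseSpec())
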