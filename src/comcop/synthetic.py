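"""Seeded, physically consistent synthetic walking trials.

Stands in for the motion-capture / force-plate / IMU experiment: each trial is
derived from one underlying motion so that the ground-truth COM-COP
inclination angle is exactly computable.  The gait model is a 3D
inverted-pendulum/sinusoidal hybrid:

* the whole-body COM progresses forward at the class speed with a vertical
  oscillation at step frequency (2 per stride) and a mediolateral sway at
  stride frequency, phase-locked to the footfalls;
* feet land alternately with a fixed step width; during each stance the foot
  centre of pressure advances linearly from heel to toe;
* the total vertical ground reaction force equals m*(g + z_com''), so the
  impulse-momentum balance over a periodic cycle is exact, and it is shared
  between the limbs with a smooth cosine load transfer during double support
  (single -> double -> single support pattern);
* the trunk (pelvis) tilts, obliques and rotates as small sinusoids locked to
  the stride, and a 9-channel IMU over the L5 vertebra is synthesized from the
  sensor's rigid-body motion (specific force, angular rate, rotated Earth
  magnetic field) plus white noise and random-walk drift.

Force streams are recorded per foot ("plate 1" = right foot, "plate 2" = left
foot, split-belt style), so the two-plate sum equals the whole-body vertical
force at every sample and the net COP is defined on every analysis frame.

Global frame: right-handed, X = anterior, Y = subject's left, Z = up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

G = 9.80665  # m/s^2

#: Sensor full-scale ranges: accelerometer +-16 g, gyroscope +-2000 deg/s,
#: magnetometer +-4800 uT.
ACCEL_RANGE = 16.0 * G
GYRO_RANGE = 2000.0
MAG_RANGE = 4800.0

#: Earth magnetic field in the global frame, uT (mid-latitude magnitude ~48).
EARTH_FIELD_UT = np.array([20.0, 0.0, -44.0])

SPEED_CLASSES = ("slow", "normal", "fast")

# Cohort anthropometrics emulated by the sampler (young adult males).
HEIGHT_MEAN_CM, HEIGHT_SD_CM = 171.2, 4.3
MASS_MEAN_KG, MASS_SD_KG = 67.3, 7.1

# Stride-to-stride irregularity and heel-strike transient magnitudes.
STRIDE_MOD_SIGMA = 0.05       # sd of per-stride amplitude modulation
IMPACT_ROT_AMP = 0.014        # rad, mean rotational jolt at heel strike

# Gait-template constants (fractions of stride time / body height).
STANCE_FRACTION = 0.62        # stance duration as a fraction of the stride
DOUBLE_SUPPORT_FRACTION = 0.12  # each double-support phase, fraction of stride
FOOT_LENGTH_RATIO = 0.152     # foot length / height
LEG_LENGTH_RATIO = 0.53       # greater trochanter height / height
COM_HEIGHT_RATIO = 0.575      # standing COM height / height


@dataclass(frozen=True)
class SubjectParams:
    """Anthropometrics and gait style of one simulated subject."""

    subject_id: str
    height: float               # cm
    mass: float                 # kg
    leg_length: float           # m
    preferred_cadence: float    # steps/min at the self-selected normal speed
    speed_scalars: dict = field(default_factory=lambda: {"slow": 0.8, "normal": 1.0, "fast": 1.2})
    style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.mass <= 0:
            raise ValueError("height and mass must be positive")
        if not self.leg_length < self.height / 100.0:
            raise ValueError("leg length (m) must be below height (m)")
        if set(self.speed_scalars) != set(SPEED_CLASSES):
            raise ValueError("speed_scalars must define exactly slow, normal, fast")
        if not (self.speed_scalars["slow"] < 1.0 < self.speed_scalars["fast"]):
            raise ValueError("require slow multiplier < 1 < fast multiplier")


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike and toe-off events as (time s, foot 'L'/'R') pairs."""

    heel_strikes: tuple
    toe_offs: tuple

    def __post_init__(self) -> None:
        feet = [f for _, f in sorted(self.heel_strikes)]
        if any(a == b for a, b in zip(feet, feet[1:])):
            raise ValueError("heel strikes must alternate feet")
        if len(self.heel_strikes) < 2:
            raise ValueError("at least one complete cycle of events required")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive IMU noise: white Gaussian per channel plus random-walk drift.

    ``drift_rate`` scales the per-sample random-walk step as a fraction of the
    channel's white-noise sigma.  The seed fully determines the realization.
    """

    accel_sigma: float = 0.15   # m/s^2
    gyro_sigma: float = 1.0     # deg/s
    mag_sigma: float = 1.0      # uT
    drift_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.accel_sigma, self.gyro_sigma, self.mag_sigma, self.drift_rate) < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class TrunkMotion:
    """Dense rigid-body motion of the L5-mounted sensor.

    ``rot`` maps sensor-frame vectors to the global frame per sample.
    """

    times: np.ndarray           # strictly increasing, s
    sensor_pos: np.ndarray      # (n, 3) m
    rot: np.ndarray             # (n, 3, 3) sensor -> world


@dataclass
class TrialRecording:
    """One walking trial with all streams on a shared clock.

    Plate 1 records the right foot's stances, plate 2 the left foot's.
    """

    subject_id: str
    speed_class: str
    mocap_times: np.ndarray
    segment_coms: np.ndarray    # (15, n_mocap, 3) m
    force_times: np.ndarray
    fz_1: np.ndarray            # N, right foot
    fz_2: np.ndarray            # N, left foot
    cop_1: np.ndarray           # (n_force, 2) m
    cop_2: np.ndarray
    imu_times: np.ndarray
    imu: np.ndarray             # (n_imu, 9): accel xyz, gyro xyz, mag xyz
    events: GaitEvents
    mocap_rate: float = 120.0
    force_rate: float = 1080.0
    imu_rate: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.mocap_times, self.force_times, self.imu_times):
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.segment_coms.shape[0] != 15:
            raise ValueError("exactly 15 segment trajectories required")
        if np.any(self.fz_1 < 0) or np.any(self.fz_2 < 0):
            raise ValueError("vertical GRF must be non-negative")


def sample_subject(seed: int, subject_id: str | None = None) -> SubjectParams:
    """Draw one subject from the emulated cohort.

    Height ~ N(171.2, 4.3) cm and mass ~ N(67.3, 7.1) kg, both clipped to
    +-3 SD; leg length, preferred cadence and gait-style parameters follow
    standard allometric fractions of height with small seeded variation.
    """
    seed = int(seed)
    rng = np.random.default_rng(seed)
    height = float(np.clip(rng.normal(HEIGHT_MEAN_CM, HEIGHT_SD_CM),
                           HEIGHT_MEAN_CM - 3 * HEIGHT_SD_CM,
                           HEIGHT_MEAN_CM + 3 * HEIGHT_SD_CM))
    mass = float(np.clip(rng.normal(MASS_MEAN_KG, MASS_SD_KG),
                         MASS_MEAN_KG - 3 * MASS_SD_KG,
                         MASS_MEAN_KG + 3 * MASS_SD_KG))
    h_m = height / 100.0
    # Latent frontal-plane "style" factor: subjects who sway more also walk
    # with a wider base and roll the trunk more, so the frontal offset of the
    # inclination angle is expressed in the inertial signals.
    phi = float(rng.normal(1.0, 0.12))
    style = {
        "step_length_ratio": float(rng.normal(0.41, 0.012)),   # step length / height
        "com_height_ratio": float(rng.normal(COM_HEIGHT_RATIO, 0.006)),
        "step_width": float((0.050 + 0.012 * phi) * h_m + rng.normal(0.0, 0.001)),
        "vertical_amp": float(rng.normal(0.016, 0.0015)),      # m, COM bounce
        "sway_amp": float(0.042 * phi + rng.normal(0.0, 0.001)),
        "pitch_amp_deg": float(rng.normal(2.0, 0.3)),
        "roll_amp_deg": float(2.5 * phi + rng.normal(0.0, 0.1)),
        "yaw_amp_deg": float(rng.normal(5.0, 0.8)),
        "impact_amp": float(rng.normal(5.5, 0.6)),             # m/s^2, heel-strike transient
    }
    return SubjectParams(
        subject_id=subject_id or f"S{seed:04d}",
        height=height,
        mass=mass,
        leg_length=LEG_LENGTH_RATIO * h_m,
        preferred_cadence=float(rng.normal(112.0, 4.0)),
        style=style,
    )


def decompose_com_to_segments(
    whole_com: np.ndarray,
    fractions: np.ndarray,
    seed: int,
    amplitude: float = 0.15,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Split a whole-body COM into 15 segment trajectories that recompose it.

    Each segment receives a smooth seeded offset (low-frequency sinusoids);
    the mass-weighted offset sum is subtracted so that
    sum_i f_i * seg_i(t) == whole_com(t) at every frame, to float precision.
    ``amplitude=0`` returns 15 copies of the COM.
    """
    whole_com = np.asarray(whole_com, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (15,):
        raise ValueError(f"expected 15 mass fractions, got {fractions.shape}")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions must sum to 1, got {fractions.sum()!r}")
    n = len(whole_com)
    t = np.asarray(times, dtype=float) if times is not None else np.linspace(0.0, 1.0, n)
    rng = np.random.default_rng(int(seed))
    # Two sinusoidal components per segment per axis, ~stride-scale frequencies.
    offsets = np.zeros((15, n, 3))
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    for i in range(15):
        for c in range(3):
            amps = amplitude * rng.uniform(0.2, 1.0, size=2)
            freqs = rng.uniform(0.5, 2.5, size=2) / span * span  # cycles over unit-time
            phases = rng.uniform(0, 2 * np.pi, size=2)
            offsets[i, :, c] = sum(
                a * np.sin(2 * np.pi * f * (t - t[0]) / span + p)
                for a, f, p in zip(amps, freqs, phases)
            )
    weighted_mean = np.einsum("s,snc->nc", fractions, offsets)
    offsets -= weighted_mean[None, :, :]
    return whole_com[None, :, :] + offsets


def synthesize_imu(
    motion: TrunkMotion,
    noise: NoiseSpec,
    imu_rate: float = 100.0,
    earth_field: np.ndarray = EARTH_FIELD_UT,
) -> tuple[np.ndarray, np.ndarray]:
    """9-channel IMU streams from the sensor's rigid-body motion.

    accelerometer = sensor-frame specific force R^T (a_world + g e_z);
    gyroscope = sensor-frame angular rate from R'(t) R(t)^T, deg/s;
    magnetometer = R^T applied to the fixed Earth field, uT.
    Channels get white noise plus random-walk drift and are clipped to the
    sensor full-scale ranges.

    Returns (imu_times, signals) with signals of shape (n, 9).
    """
    t = np.asarray(motion.times, dtype=float)
    if len(t) < 2:
        raise ValueError("motion must contain at least two samples")
    pos = np.asarray(motion.sensor_pos, dtype=float)
    rot = np.asarray(motion.rot, dtype=float)

    acc_world = np.gradient(np.gradient(pos, t, axis=0), t, axis=0)
    specific = np.einsum("nij,nj->ni", rot.transpose(0, 2, 1), acc_world + [0.0, 0.0, G])

    drot = np.gradient(rot, t, axis=0)
    omega_skew = np.einsum("nij,nkj->nik", drot, rot)  # R' R^T
    omega_world = np.column_stack([
        omega_skew[:, 2, 1], omega_skew[:, 0, 2], omega_skew[:, 1, 0]
    ])
    gyro = np.degrees(np.einsum("nij,nj->ni", rot.transpose(0, 2, 1), omega_world))

    mag = np.einsum("nij,j->ni", rot.transpose(0, 2, 1), np.asarray(earth_field, dtype=float))

    dense = np.hstack([specific, gyro, mag])
    n_imu = int(np.floor((t[-1] - t[0]) * imu_rate)) + 1
    imu_times = t[0] + np.arange(n_imu) / imu_rate
    signals = CubicSpline(t, dense, axis=0)(imu_times)

    rng = np.random.default_rng(int(noise.seed))
    sigmas = np.repeat([noise.accel_sigma, noise.gyro_sigma, noise.mag_sigma], 3)
    signals = signals + rng.normal(0.0, 1.0, signals.shape) * sigmas
    drift_steps = rng.normal(0.0, 1.0, signals.shape) * (noise.drift_rate * sigmas)
    signals = signals + np.cumsum(drift_steps, axis=0)

    limits = np.repeat([ACCEL_RANGE, GYRO_RANGE, MAG_RANGE], 3)
    return imu_times, np.clip(signals, -limits, limits)


class _GaitTemplate:
    """Closed-form COM / feet / force template for one trial."""

    def __init__(self, subject: SubjectParams, speed_class: str, rng: np.random.Generator,
                 n_strides: int = 3):
        if speed_class not in SPEED_CLASSES:
            raise ValueError(
                f"unknown speed_class {speed_class!r}; expected one of {SPEED_CLASSES}"
            )
        s = subject.style
        h_m = subject.height / 100.0
        scalar = subject.speed_scalars[speed_class]
        # Speed changes split between cadence and step length; small per-trial
        # jitter makes repeated trials distinct.
        cadence = subject.preferred_cadence * scalar ** 0.4 * rng.normal(1.0, 0.015)
        step_len = s["step_length_ratio"] * h_m * scalar ** 0.6 * rng.normal(1.0, 0.015)
        self.T = 2 * 60.0 / cadence                   # stride time, s
        self.step_len = step_len
        self.speed = 2 * step_len / self.T            # mean forward speed, m/s
        self.ds = DOUBLE_SUPPORT_FRACTION * self.T
        self.stance = STANCE_FRACTION * self.T
        self.z0 = s["com_height_ratio"] * h_m
        self.Az = s["vertical_amp"] * scalar ** 0.5
        self.Az2 = 0.003 * scalar ** 0.5  # second harmonic of the COM bounce
        self.Ay = s["sway_amp"] / scalar ** 0.25
        self.Ax = 0.010
        self.step_width = s["step_width"]
        self.foot_len = FOOT_LENGTH_RATIO * h_m
        self.pitch_amp = np.radians(s["pitch_amp_deg"])
        self.roll_amp = np.radians(s["roll_amp_deg"] * scalar ** 0.3)
        self.yaw_amp = np.radians(s["yaw_amp_deg"] * scalar ** 0.3)
        self.n_strides = n_strides
        self.t_start = 0.5 * self.T                   # first right heel strike
        self.duration = self.t_start + n_strides * self.T
        self.mass = subject.mass

        # Footfall schedule: right HS at t_start + k T, left HS half a stride
        # later; successive footfalls advance one step length.
        self.hs_R = self.t_start + np.arange(n_strides) * self.T
        self.hs_L = self.hs_R + 0.5 * self.T
        com_at = lambda tt: self.speed * (tt - self.t_start)  # mean forward COM
        self.x_R = com_at(self.hs_R) + 0.5 * step_len
        self.x_L = com_at(self.hs_L) + 0.5 * step_len
        # Pre-trial left stance so the load is defined from t = 0.
        self.hs_L = np.concatenate([[self.t_start - 0.5 * self.T], self.hs_L])
        self.x_L = np.concatenate([[com_at(self.hs_L[0]) + 0.5 * step_len], self.x_L])

        # Stride-to-stride variability: smooth multiplicative modulation of
        # the sway and trunk-angle amplitudes (real walking never repeats a
        # cycle exactly).  Nodes at stride boundaries, linear in between.
        self._mod_t = np.concatenate([[0.0], self.hs_R, [self.duration]])
        self._mod = {
            key: rng.normal(1.0, STRIDE_MOD_SIGMA, len(self._mod_t))
            for key in ("sway", "roll", "pitch", "yaw")
        }

        # Heel-strike impact transients felt at the sensor: short damped
        # oscillations (~14 Hz) with per-event amplitude/frequency jitter.
        impact_times = np.sort(np.concatenate([self.hs_R, self.hs_L]))
        self.impacts = []
        for tk in impact_times:
            amp = max(rng.normal(s["impact_amp"], 0.6), 0.2) * scalar ** 0.5
            freq = rng.normal(14.0, 1.0)
            direction = np.array([0.35, 0.10, 0.90]) + rng.normal(0.0, 0.15, 3)
            direction /= np.linalg.norm(direction)
            # Rotational jolt of the trunk at contact (radians), split between
            # roll and pitch with a per-event random mix.
            rot_amp = max(rng.normal(IMPACT_ROT_AMP, 0.002), 0.0) * scalar ** 0.5
            rot_mix = rng.normal(0.0, 1.0, 2)
            rot_mix /= max(np.linalg.norm(rot_mix), 1e-12)
            self.impacts.append(
                (float(tk), amp, 2 * np.pi * freq, 0.045, direction, rot_amp, rot_mix)
            )

    # -- COM kinematics ----------------------------------------------------
    def com(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        T, t0 = self.T, self.t_start
        phase_step = 4 * np.pi * (t - t0) / T         # 2 cycles per stride
        phase_stride = 2 * np.pi * (t - t0) / T
        x = self.speed * (t - t0) + self.Ax * np.sin(phase_step)
        # Rightmost sway / peak height at right mid single-support (t0+0.31T).
        y = -self.Ay * self._modulation("sway", t) * np.cos(phase_stride - 2 * np.pi * 0.31)
        z = (self.z0 + self.Az * np.cos(phase_step - 4 * np.pi * 0.31)
             + self.Az2 * np.cos(2 * phase_step + np.pi / 5))
        return np.column_stack([x, y, z])

    def com_zdd(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 4 * np.pi / self.T
        return (-self.Az * w**2 * np.cos(w * (t - self.t_start) - 4 * np.pi * 0.31)
                - self.Az2 * (2 * w) ** 2 * np.cos(2 * w * (t - self.t_start) + np.pi / 5))

    def impact_displacement(self, t: np.ndarray) -> np.ndarray:
        """World-frame sensor displacement of the heel-strike transients.

        Each impact is a damped sinusoidal acceleration of amplitude ``amp``;
        stored as the corresponding displacement (amp / omega^2) so the
        sensor position remains the single source of truth for the
        accelerometer synthesis.
        """
        t = np.asarray(t, dtype=float)
        d = np.zeros((len(t), 3))
        for tk, amp, omega, tau, direction, _, _ in self.impacts:
            dt = t - tk
            active = dt >= 0
            wave = np.zeros_like(t)
            wave[active] = (amp / omega**2) * np.exp(-dt[active] / tau) * np.sin(omega * dt[active])
            d += wave[:, None] * direction
        return d

    def impact_rotation(self, t: np.ndarray) -> np.ndarray:
        """Roll/pitch jolt (radians) of the heel-strike transients."""
        t = np.asarray(t, dtype=float)
        rp = np.zeros((len(t), 2))
        for tk, _, omega, tau, _, rot_amp, rot_mix in self.impacts:
            dt = t - tk
            active = dt >= 0
            wave = np.zeros_like(t)
            wave[active] = rot_amp * np.exp(-dt[active] / tau) * np.sin(omega * dt[active])
            rp += wave[:, None] * rot_mix
        return rp

    # -- support and COP ---------------------------------------------------
    def _activation(self, t: np.ndarray, hs_times: np.ndarray) -> np.ndarray:
        """Load share of one foot: cosine ramps over double support."""
        a = np.zeros_like(t)
        for hs in hs_times:
            u_in = np.clip((t - hs) / self.ds, 0.0, 1.0)
            u_out = np.clip((t - (hs + 0.5 * self.T)) / self.ds, 0.0, 1.0)
            a += 0.5 * (1 - np.cos(np.pi * u_in)) - 0.5 * (1 - np.cos(np.pi * u_out))
        return np.clip(a, 0.0, 1.0)

    def _cop(self, t: np.ndarray, hs_times: np.ndarray, x_feet: np.ndarray,
             y_foot: float) -> np.ndarray:
        """Heel-to-toe COP advance during each stance; held between stances.

        The anteroposterior advance is linear; mediolaterally the COP rolls
        from a slightly lateral heel contact toward the medial forefoot.
        """
        heel, toe = -0.20 * self.foot_len, 0.75 * self.foot_len
        toward_mid = -np.sign(y_foot) if y_foot != 0 else 0.0
        y_heel = y_foot - toward_mid * 0.015
        y_toe = y_foot + toward_mid * 0.055
        x = np.full_like(t, x_feet[0] + heel)
        y = np.full_like(t, y_heel)
        for hs, xf in zip(hs_times, x_feet):
            p = (t - hs) / self.stance
            inside = (p >= 0.0) & (p <= 1.0)
            pc = np.clip(p[inside], 0, 1)
            x[inside] = xf + heel + pc * (toe - heel)
            y[inside] = y_heel + pc * (y_toe - y_heel)
            x[p > 1.0] = xf + toe
            y[p > 1.0] = y_toe
        return np.column_stack([x, y])

    def forces_and_cops(self, t: np.ndarray):
        total = self.mass * (G + self.com_zdd(t))
        a_r = self._activation(t, self.hs_R)
        a_l = self._activation(t, self.hs_L)
        share = a_r + a_l
        share[share == 0] = 1.0
        fz_r = total * a_r / share
        fz_l = total * a_l / share
        cop_r = self._cop(t, self.hs_R, self.x_R, -0.5 * self.step_width)
        cop_l = self._cop(t, self.hs_L, self.x_L, +0.5 * self.step_width)
        return fz_r, fz_l, cop_r, cop_l

    # -- trunk -------------------------------------------------------------
    def trunk_euler(self, t: np.ndarray) -> np.ndarray:
        """(roll, pitch, yaw) radians; small sinusoids locked to the stride."""
        t = np.asarray(t, dtype=float)
        phase_stride = 2 * np.pi * (t - self.t_start) / self.T
        phase_step = 2 * phase_stride
        jolt = self.impact_rotation(t)
        # Trunk roll is mechanically coupled to the mediolateral sway, so it
        # shares the sway's stride-to-stride modulation.
        roll = (self.roll_amp * self._modulation("sway", t)
                * np.sin(phase_stride - 2 * np.pi * 0.31) + jolt[:, 0])
        pitch = (self.pitch_amp * self._modulation("pitch", t)
                 * np.sin(phase_step + np.pi / 3) + jolt[:, 1])
        yaw = self.yaw_amp * self._modulation("yaw", t) * np.sin(phase_stride)
        return np.column_stack([roll, pitch, yaw])

    def _modulation(self, key: str, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self._mod_t, self._mod[key])

    def events(self) -> GaitEvents:
        hs = [(float(ti), "R") for ti in self.hs_R] + [
            (float(ti), "L") for ti in self.hs_L if ti >= 0
        ]
        to = []
        for hs_t, foot in hs:
            t_off = hs_t + self.stance
            if t_off <= self.duration:
                to.append((float(t_off), foot))
        # Toe-offs of stances that began before recording started.
        pre_l = self.hs_L[0]
        if pre_l < 0 and pre_l + self.stance > 0:
            to.append((float(pre_l + self.stance), "L"))
        return GaitEvents(
            heel_strikes=tuple(sorted(hs)), toe_offs=tuple(sorted(to))
        )


def _euler_to_rot(euler: np.ndarray) -> np.ndarray:
    """Rz(yaw) Ry(pitch) Rx(roll), sensor -> world, vectorized."""
    r, p, y = euler[:, 0], euler[:, 1], euler[:, 2]
    cr, sr, cp, sp, cy, sy = np.cos(r), np.sin(r), np.cos(p), np.sin(p), np.cos(y), np.sin(y)
    R = np.empty((len(euler), 3, 3))
    R[:, 0, 0] = cy * cp
    R[:, 0, 1] = cy * sp * sr - sy * cr
    R[:, 0, 2] = cy * sp * cr + sy * sr
    R[:, 1, 0] = sy * cp
    R[:, 1, 1] = sy * sp * sr + cy * cr
    R[:, 1, 2] = sy * sp * cr - cy * sr
    R[:, 2, 0] = -sp
    R[:, 2, 1] = cp * sr
    R[:, 2, 2] = cp * cr
    return R


#: Sensor mounting offset from the COM in the trunk frame (posterior, over L5).
SENSOR_OFFSET = np.array([-0.10, 0.0, 0.02])


def trunk_motion(template: _GaitTemplate, rate: float = 1080.0) -> TrunkMotion:
    """Dense sensor rigid-body motion for a gait template."""
    n = int(np.floor(template.duration * rate)) + 1
    t = np.arange(n) / rate
    rot = _euler_to_rot(template.trunk_euler(t))
    pos = (template.com(t) + np.einsum("nij,j->ni", rot, SENSOR_OFFSET)
           + template.impact_displacement(t))
    return TrunkMotion(times=t, sensor_pos=pos, rot=rot)


def simulate_trial(
    subject: SubjectParams,
    speed_class: str,
    seed: int,
    noise: NoiseSpec | None = None,
    mocap_rate: float = 120.0,
    force_rate: float = 1080.0,
    imu_rate: float = 100.0,
) -> TrialRecording:
    """Generate one walking trial (>= 1 full cycle crossing two plates).

    The same (subject, speed_class, seed) always yields a bit-identical
    recording; the optional ``noise`` overrides the default IMU noise model
    (its own seed is ignored in favour of the trial seed).
    """
    seed = int(seed)
    rng = np.random.default_rng(seed)
    template = _GaitTemplate(subject, speed_class, rng)

    t_mocap = np.arange(int(np.floor(template.duration * mocap_rate)) + 1) / mocap_rate
    t_force = np.arange(int(np.floor(template.duration * force_rate)) + 1) / force_rate

    com = template.com(t_mocap)
    from comcop.biomech import AnthropometricModel

    fractions = AnthropometricModel().fractions
    seg_seed = int(rng.integers(0, 2**31))
    noise_seed = int(rng.integers(0, 2**31))
    segments = decompose_com_to_segments(com, fractions, seg_seed, times=t_mocap)

    fz_r, fz_l, cop_r, cop_l = template.forces_and_cops(t_force)

    base = noise or NoiseSpec()
    noise_spec = NoiseSpec(
        accel_sigma=base.accel_sigma, gyro_sigma=base.gyro_sigma,
        mag_sigma=base.mag_sigma, drift_rate=base.drift_rate, seed=noise_seed,
    )
    motion = trunk_motion(template, rate=force_rate)
    t_imu, imu = synthesize_imu(motion, noise_spec, imu_rate=imu_rate)

    return TrialRecording(
        subject_id=subject.subject_id,
        speed_class=speed_class,
        mocap_times=t_mocap,
        segment_coms=segments,
        force_times=t_force,
        fz_1=fz_r,
        fz_2=fz_l,
        cop_1=cop_r,
        cop_2=cop_l,
        imu_times=t_imu,
        imu=imu,
        events=template.events(),
        mocap_rate=mocap_rate,
        force_rate=force_rate,
        imu_rate=imu_rate,
        meta={
            "seed": seed,
            "mass": subject.mass,
            "stride_time": template.T,
            "speed": template.speed,
        },
    )
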