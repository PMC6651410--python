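"""Ground-truth COM-COP inclination angles from kinematics and force-plate data.

The centre of mass (COM) of the whole body is the mass-fraction weighted sum of
15 segment COM trajectories.  The net centre of pressure (COP) during double
support is the vertical-force weighted combination of the two single-foot COPs.
The inclination angle (IA) is the angle between the vertical through the COP
and the line from the COP to the COM:

    v  = (P x Z) / ||P||        with P the COP->COM vector, Z the global up axis
    IA = asin(v)

decomposed into a sagittal component (anterior lean, about the mediolateral
axis) and a frontal component (lateral lean, about the anteroposterior axis).

Global frame convention (shared across the package): right-handed, X = anterior
(direction of progression), Y = subject's left, Z = up.  Sagittal IA is
positive when the COM is anterior of the COP; frontal IA is positive when the
COM is toward the subject's left of the COP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

logger = logging.getLogger(__name__)

#: Default 15-segment anthropometric table (mass fractions of total body mass).
#: Head+neck and a two-piece trunk (torso above the pelvis, pelvis) plus paired
#: limb segments; values follow standard cadaver-based segment parameter tables.
DEFAULT_SEGMENT_FRACTIONS: dict[str, float] = {
    "head_neck": 0.081,
    "torso": 0.355,
    "pelvis": 0.142,
    "upper_arm_L": 0.028,
    "upper_arm_R": 0.028,
    "forearm_L": 0.016,
    "forearm_R": 0.016,
    "hand_L": 0.006,
    "hand_R": 0.006,
    "thigh_L": 0.100,
    "thigh_R": 0.100,
    "shank_L": 0.0465,
    "shank_R": 0.0465,
    "foot_L": 0.0145,
    "foot_R": 0.0145,
}


@dataclass(frozen=True)
class AnthropometricModel:
    """Per-segment mass fractions for the kinematic whole-body COM.

    Fractions must be strictly positive and sum to 1 (within 1e-9).  The
    default table has 15 segments; alternative tables may be supplied but the
    rest of the pipeline expects 15 trajectories.
    """

    segment_names: tuple[str, ...] = tuple(DEFAULT_SEGMENT_FRACTIONS)
    mass_fractions: tuple[float, ...] = tuple(DEFAULT_SEGMENT_FRACTIONS.values())

    def __post_init__(self) -> None:
        f = np.asarray(self.mass_fractions, dtype=float)
        if len(self.segment_names) != len(f):
            raise ValueError("segment_names and mass_fractions lengths differ")
        if np.any(f <= 0):
            raise ValueError("mass fractions must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {f.sum()!r}")

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.mass_fractions, dtype=float)


@dataclass
class InclinationAngleSeries:
    """Sagittal and frontal COM-COP inclination angles in degrees per frame."""

    sagittal: np.ndarray
    frontal: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sagittal = np.asarray(self.sagittal, dtype=float)
        self.frontal = np.asarray(self.frontal, dtype=float)
        if self.sagittal.shape != self.frontal.shape:
            raise ValueError("sagittal and frontal series must have equal length")
        if np.any(np.abs(self.sagittal) >= 90) or np.any(np.abs(self.frontal) >= 90):
            raise ValueError("inclination angles must satisfy |IA| < 90 degrees")

    @property
    def n_frames(self) -> int:
        return len(self.sagittal)

    def as_array(self) -> np.ndarray:
        """Stack as (n_frames, 2) with columns ordered sagittal, frontal."""
        return np.column_stack([self.sagittal, self.frontal])


def whole_body_com(segment_coms: np.ndarray, model: AnthropometricModel | None = None) -> np.ndarray:
    """Whole-body COM as the mass-fraction weighted sum of segment COMs.

    Parameters
    ----------
    segment_coms
        Array of shape (15, n_frames, 3), metres.
    model
        Anthropometric table; defaults to the package's 15-segment table.

    Returns
    -------
    (n_frames, 3) COM trajectory in metres.
    """
    model = model or AnthropometricModel()
    segs = np.asarray(segment_coms, dtype=float)
    n_seg = len(model.fractions)
    if segs.ndim != 3 or segs.shape[0] != n_seg or segs.shape[2] != 3:
        raise ValueError(
            f"expected segment_coms of shape ({n_seg}, n_frames, 3), got {segs.shape}"
        )
    return np.einsum("s,sfc->fc", model.fractions, segs)


def net_cop(
    cop_1: np.ndarray,
    cop_2: np.ndarray,
    fz_1: np.ndarray,
    fz_2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Net COP as the vertical-force weighted combination of two plate COPs.

    COP_net = (fz1 * cop1 + fz2 * cop2) / (fz1 + fz2) per frame.  Frames where
    both vertical forces vanish (no foot on either plate) cannot define a COP;
    they are returned as NaN together with a validity mask and a logged
    warning, and must be excluded from cycle analysis.

    Returns
    -------
    (cop_net, valid) where cop_net is (n, 2) metres and valid is a boolean
    mask of frames with positive total vertical force.
    """
    cop_1 = np.asarray(cop_1, dtype=float)
    cop_2 = np.asarray(cop_2, dtype=float)
    fz_1 = np.asarray(fz_1, dtype=float)
    fz_2 = np.asarray(fz_2, dtype=float)
    if not (len(cop_1) == len(cop_2) == len(fz_1) == len(fz_2)):
        raise ValueError("cop and force series must have equal lengths")
    if np.any(fz_1 < 0) or np.any(fz_2 < 0):
        raise ValueError("vertical ground reaction forces must be non-negative")
    total = fz_1 + fz_2
    valid = total > 0
    if not valid.all():
        logger.warning(
            "net_cop: %d/%d frames have zero total vertical force; flagged invalid",
            int((~valid).sum()), len(total),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(valid, fz_1 / np.where(valid, total, 1.0), np.nan)
    cop = w1[:, None] * cop_1 + (1.0 - w1)[:, None] * cop_2
    return cop, valid


def inclination_angles(
    com: np.ndarray,
    cop_net: np.ndarray,
    provenance: dict | None = None,
) -> InclinationAngleSeries:
    """COM-COP inclination angles from a 3D COM and a ground-plane net COP.

    The COP is lifted to the ground plane (height 0); P = COM - COP is the
    COP->COM vector.  With Z = (0, 0, 1), v = (P x Z)/||P|| and IA = asin(v):
    the sagittal angle is asin(P_x/||P||) (anterior lean positive) and the
    frontal angle asin(P_y/||P||) (lean toward the subject's left positive).
    Both are reported in degrees.
    """
    com = np.asarray(com, dtype=float)
    cop_net = np.asarray(cop_net, dtype=float)
    if com.ndim != 2 or com.shape[1] != 3:
        raise ValueError("com must have shape (n_frames, 3)")
    if cop_net.ndim != 2 or cop_net.shape[1] != 2:
        raise ValueError("cop_net must have shape (n_frames, 2)")
    if len(com) != len(cop_net):
        raise ValueError("com and cop_net must have equal lengths")
    if np.any(com[:, 2] <= 0):
        raise ValueError("COM height above the ground plane must be positive")

    p = com - np.column_stack([cop_net, np.zeros(len(cop_net))])
    norm = np.linalg.norm(p, axis=1)
    if np.any(norm == 0):
        raise ValueError("COM coincides with COP; inclination angle undefined")
    # v = (P x Z)/||P|| with Z = e_z gives v = (P_y, -P_x, 0)/||P||; the
    # anterior-lean component of asin(v) is asin(P_x/||P||), the lateral one
    # asin(P_y/||P||).
    sagittal = np.degrees(np.arcsin(np.clip(p[:, 0] / norm, -1.0, 1.0)))
    frontal = np.degrees(np.arcsin(np.clip(p[:, 1] / norm, -1.0, 1.0)))
    return InclinationAngleSeries(sagittal, frontal, provenance or {})


def segment_gait_cycle(events, policy: str = "paper_modified") -> list[tuple[float, float]]:
    """Analysis windows from gait events under a cycle-definition policy.

    ``paper_modified`` (default): each window runs from a toe-off to the next
    heel strike of the *same* foot, i.e. that foot's swing phase, which is the
    single-support interval of the opposite limb during the two-plate crossing.
    ``standard``: heel strike to the next ipsilateral heel strike.

    Parameters
    ----------
    events
        A :class:`~comcop.synthetic.GaitEvents` (or any object with
        ``heel_strikes`` and ``toe_offs`` lists of ``(time, foot)`` pairs).

    Returns
    -------
    List of (start, end) windows in seconds, in chronological order.
    """
    hs = sorted(events.heel_strikes)
    to = sorted(events.toe_offs)
    windows: list[tuple[float, float]] = []
    if policy == "paper_modified":
        for t_off, foot in to:
            nxt = [t for t, f in hs if f == foot and t > t_off]
            if nxt:
                windows.append((t_off, min(nxt)))
    elif policy == "standard":
        for foot in ("L", "R"):
            times = [t for t, f in hs if f == foot]
            windows.extend(zip(times[:-1], times[1:]))
        windows.sort()
    else:
        raise ValueError(f"unknown cycle policy {policy!r}")
    if not windows:
        raise ValueError(
            f"insufficient gait events for one cycle under policy {policy!r}: "
            f"{len(hs)} heel strikes, {len(to)} toe-offs"
        )
    logger.debug("segment_gait_cycle: policy=%s, %d windows", policy, len(windows))
    return windows


def time_normalize(
    times: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float] | None = None,
    n: int = 100,
    kind: str = "cubic",
) -> np.ndarray:
    """Resample a time series to ``n`` frames over a cycle window.

    Cubic interpolation by default (kinematic data are smooth); linear is
    available via ``kind``.  The window endpoints are evaluated exactly, so a
    series whose support equals the window keeps its end values.

    Parameters
    ----------
    times
        Strictly increasing sample times, seconds.
    values
        Samples, shape (n_samples,) or (n_samples, n_channels).
    window
        (start, end) in seconds; defaults to the full extent of ``times``.
        Must lie within the sampled interval.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValueError("series must have at least 2 samples")
    if n < 2:
        raise ValueError("n must be at least 2")
    if len(times) != len(values):
        raise ValueError("times and values must have equal length")
    t0, t1 = window if window is not None else (times[0], times[-1])
    if not (t0 < t1):
        raise ValueError("window start must precede window end")
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(
            f"window [{t0}, {t1}] exceeds stream coverage [{times[0]}, {times[-1]}]"
        )
    new_t = np.linspace(t0, t1, n)
    new_t = np.clip(new_t, times[0], times[-1])
    if kind == "cubic" and len(times) >= 4:
        return CubicSpline(times, values, axis=0)(new_t)
    return interp1d(times, values, axis=0, kind="linear")(new_t)


def trial_ground_truth(
    trial,
    model: AnthropometricModel | None = None,
    mocap_cutoff_hz: float = 7.0,
    n_frames: int = 100,
    policy: str = "paper_modified",
) -> InclinationAngleSeries:
    """Ground-truth IA for one trial, time-normalized over the crossing cycle.

    Mocap-derived segment trajectories and force-plate streams are low-pass
    filtered at ``mocap_cutoff_hz`` (4th-order zero-phase Butterworth), the
    whole-body COM and net COP are formed, the inclination angles are computed
    on the mocap clock (force streams interpolated onto it), and the series is
    cut to the central analysis window and resampled to ``n_frames``.
    """
    from comcop.preprocessing import FilterSpec, butterworth_lowpass

    model = model or AnthropometricModel()
    spec = FilterSpec(cutoff=mocap_cutoff_hz)
    segs = butterworth_lowpass(
        np.moveaxis(trial.segment_coms, 0, -1).reshape(trial.segment_coms.shape[1], -1),
        trial.mocap_rate, spec,
    ).reshape(trial.segment_coms.shape[1], trial.segment_coms.shape[2], trial.segment_coms.shape[0])
    segs = np.moveaxis(segs, -1, 0)
    com = whole_body_com(segs, model)

    fz = butterworth_lowpass(np.column_stack([trial.fz_1, trial.fz_2]), trial.force_rate, spec)
    fz = np.clip(fz, 0.0, None)  # filtering ripple may dip slightly below zero
    cops = butterworth_lowpass(
        np.hstack([trial.cop_1, trial.cop_2]), trial.force_rate, spec
    )
    cop, valid = net_cop(cops[:, :2], cops[:, 2:], fz[:, 0], fz[:, 1])

    t_force = trial.force_times
    t_mocap = trial.mocap_times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cop_mocap = interp1d(
            t_force[valid], cop[valid], axis=0, kind="linear",
            bounds_error=False, fill_value="extrapolate",
        )(t_mocap)

    windows = segment_gait_cycle(trial.events, policy=policy)
    t0, t1 = windows[len(windows) // 2]
    lo = max(t0, t_mocap[0])
    hi = min(t1, t_mocap[-1])
    com_n = time_normalize(t_mocap, com, (lo, hi), n=n_frames)
    cop_n = time_normalize(t_mocap, cop_mocap, (lo, hi), n=n_frames)
    series = inclination_angles(com_n, cop_n)
    series.provenance = {
        "subject": trial.subject_id,
        "speed": trial.speed_class,
        "window": (lo, hi),
    }
    return series
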