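"""Signal filtering, feature scaling, and learning-matrix assembly.

Raw inertial signals carry thermal-mechanical and electronic noise and are
smoothed with a 4th-order Butterworth digital low-pass filter before being fed
to the estimators; the experiment compares cutoff frequencies of 2, 10 and
25 Hz for the sensor channels, while mocap/force streams are filtered at 7 Hz
before the ground truth is computed.  Input and output columns are linearly
scaled to [-1, 1] from per-column minima and maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, filtfilt

from comcop.biomech import time_normalize

INPUT_COLUMNS = (
    "accel_x", "accel_y", "accel_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
)
OUTPUT_COLUMNS = ("sagittal_deg", "frontal_deg")


@dataclass(frozen=True)
class FilterSpec:
    """4th-order Butterworth low-pass filter specification.

    ``zero_phase=True`` (default) applies the filter forward and backward
    (zero lag, squared magnitude response: -6 dB at the cutoff); ``False``
    gives a single causal pass.
    """

    cutoff: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be a positive even integer")


def butterworth_lowpass(signal: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply the Butterworth low-pass filter along axis 0.

    Zero-phase mode pads with odd reflection (3 x filter order samples) before
    the forward-backward pass.  DC gain is exactly 1.
    """
    signal = np.asarray(signal, dtype=float)
    nyq = rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyq} Hz")
    if signal.shape[0] <= 3 * spec.order:
        raise ValueError(f"signal too short to filter: {signal.shape[0]} samples")
    b, a = butter(spec.order, spec.cutoff / nyq, btype="low")
    if spec.zero_phase:
        return filtfilt(b, a, signal, axis=0, padtype="odd", padlen=3 * spec.order)
    return lfilter(b, a, signal, axis=0)


@dataclass(frozen=True)
class ScaleParams:
    """Per-column minima and maxima backing the [-1, 1] linear scaling."""

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return minmax_scale(x, self.lo, self.hi)

    def inverse(self, x_scaled: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        return (np.asarray(x_scaled, dtype=float) + 1.0) * (hi - lo) / 2.0 + lo


def minmax_scale(x: np.ndarray, lo, hi) -> np.ndarray:
    """Linear scaling x' = 2(x - lo)/(hi - lo) - 1 mapping [lo, hi] -> [-1, 1]."""
    x = np.asarray(x, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate column: hi must exceed lo")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


@dataclass
class DatasetMatrices:
    """Stacked learning matrices with per-row provenance.

    ``X`` is (frames, 9) scaled sensor channels ordered accelerometer (x,y,z),
    gyroscope (x,y,z), magnetometer (x,y,z); ``Y`` is (frames, 2) scaled
    inclination angles ordered sagittal, frontal.  ``row_meta`` carries
    subject / trial / speed / frame indices for every row; cycles are
    contiguous blocks of ``frames_per_cycle`` rows.
    """

    X: np.ndarray
    Y: np.ndarray
    row_meta: pd.DataFrame
    x_scale: ScaleParams
    y_scale: ScaleParams
    frames_per_cycle: int = 100
    scaling_mode: str = "paper"

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.Y) == len(self.row_meta)):
            raise ValueError("X, Y and row_meta must have equal row counts")

    @property
    def subjects(self) -> list:
        return sorted(self.row_meta["subject"].unique())

    def rows_for(self, subjects) -> np.ndarray:
        return self.row_meta["subject"].isin(list(subjects)).to_numpy()

    def cycles_for(self, subjects) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Cycle-major views: (n_cycles, frames, 9), (n_cycles, frames, 2), meta."""
        mask = self.rows_for(subjects)
        n = self.frames_per_cycle
        Xs = self.X[mask].reshape(-1, n, self.X.shape[1])
        Ys = self.Y[mask].reshape(-1, n, self.Y.shape[1])
        meta = self.row_meta[mask].iloc[::n].reset_index(drop=True)
        return Xs, Ys, meta

    def angles_deg(self, y_scaled: np.ndarray) -> np.ndarray:
        """Inverse-transform scaled outputs back to degrees."""
        return self.y_scale.inverse(y_scaled)


def assemble_matrices(
    trials: list[tuple[np.ndarray, np.ndarray, dict]],
    scaling_mode: str = "paper",
    train_subjects=None,
) -> DatasetMatrices:
    """Stack per-cycle (inputs, outputs, meta) triples into learning matrices.

    Each triple holds a (frames, 9) filtered IMU cycle, a (frames, 2) IA cycle
    in degrees, and a meta dict with ``subject``, ``trial`` and ``speed``.
    ``scaling_mode='paper'`` computes the per-column minima/maxima over the
    whole matrix; ``'train_only'`` computes them on the rows of
    ``train_subjects`` only (leakage-safe alternative).
    """
    if not trials:
        raise ValueError("no trials to assemble")
    if scaling_mode not in ("paper", "train_only"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    n_frames = len(trials[0][0])
    xs, ys, meta_rows = [], [], []
    for x, y, meta in trials:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != (n_frames, 9) or y.shape != (n_frames, 2):
            raise ValueError(
                f"ragged cycle for trial {meta}: input {x.shape}, output {y.shape}; "
                f"expected ({n_frames}, 9) and ({n_frames}, 2)"
            )
        xs.append(x)
        ys.append(y)
        meta_rows.append(
            pd.DataFrame({
                "subject": meta["subject"],
                "trial": meta.get("trial", 0),
                "speed": meta.get("speed", "normal"),
                "frame": np.arange(n_frames),
            })
        )
    X_raw = np.vstack(xs)
    Y_raw = np.vstack(ys)
    row_meta = pd.concat(meta_rows, ignore_index=True)

    if scaling_mode == "train_only":
        if train_subjects is None:
            raise ValueError("train_only scaling requires train_subjects")
        fit_mask = row_meta["subject"].isin(list(train_subjects)).to_numpy()
        if not fit_mask.any():
            raise ValueError("train_subjects select no rows")
    else:
        fit_mask = np.ones(len(X_raw), dtype=bool)

    x_scale = ScaleParams(X_raw[fit_mask].min(axis=0), X_raw[fit_mask].max(axis=0))
    y_scale = ScaleParams(Y_raw[fit_mask].min(axis=0), Y_raw[fit_mask].max(axis=0))
    return DatasetMatrices(
        X=x_scale.transform(X_raw),
        Y=y_scale.transform(Y_raw),
        row_meta=row_meta,
        x_scale=x_scale,
        y_scale=y_scale,
        frames_per_cycle=n_frames,
        scaling_mode=scaling_mode,
    )


def resample_to_cycle(
    imu_times: np.ndarray,
    imu_signals: np.ndarray,
    window: tuple[float, float],
    n: int = 100,
) -> np.ndarray:
    """Cut 9 IMU channels to a cycle window and time-normalize to ``n`` frames.

    Uses the same interpolator as the ground-truth normalization so inputs and
    outputs are frame-aligned over the cycle.
    """
    imu_signals = np.asarray(imu_signals, dtype=float)
    if imu_signals.ndim != 2 or imu_signals.shape[1] != 9:
        raise ValueError(f"expected (n, 9) IMU signals, got {imu_signals.shape}")
    return time_normalize(imu_times, imu_signals, window, n=n)
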