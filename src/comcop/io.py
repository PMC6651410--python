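"""Native file I/O: bundled HDF5 trial containers, per-stream CSV, IA CSV.

The container mirrors the recording layout: groups ``/segments`` (15 named
COM trajectories at the mocap rate), ``/grf`` (per-plate vertical force and
COP at the force rate), ``/imu`` (9 channels at the sensor rate),
``/events`` (heel strikes and toe-offs) and ``/meta``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from comcop.biomech import AnthropometricModel
from comcop.preprocessing import INPUT_COLUMNS
from comcop.synthetic import GaitEvents, TrialRecording


def save_trial(trial: TrialRecording, path) -> None:
    """Write one trial to a bundled HDF5 container."""
    names = AnthropometricModel().segment_names
    with h5py.File(path, "w") as f:
        seg = f.create_group("segments")
        seg.create_dataset("times", data=trial.mocap_times)
        for i, name in enumerate(names):
            seg.create_dataset(name, data=trial.segment_coms[i])
        grf = f.create_group("grf")
        grf.create_dataset("times", data=trial.force_times)
        grf.create_dataset("fz_1", data=trial.fz_1)
        grf.create_dataset("fz_2", data=trial.fz_2)
        grf.create_dataset("cop_1", data=trial.cop_1)
        grf.create_dataset("cop_2", data=trial.cop_2)
        imu = f.create_group("imu")
        imu.create_dataset("times", data=trial.imu_times)
        imu.create_dataset("signals", data=trial.imu)
        ev = f.create_group("events")
        ev.create_dataset("heel_strike_times",
                          data=[t for t, _ in trial.events.heel_strikes])
        ev.create_dataset("heel_strike_feet",
                          data=[f_.encode() for _, f_ in trial.events.heel_strikes])
        ev.create_dataset("toe_off_times", data=[t for t, _ in trial.events.toe_offs])
        ev.create_dataset("toe_off_feet",
                          data=[f_.encode() for _, f_ in trial.events.toe_offs])
        meta = f.create_group("meta")
        meta.attrs["subject_id"] = trial.subject_id
        meta.attrs["speed_class"] = trial.speed_class
        meta.attrs["mocap_rate"] = trial.mocap_rate
        meta.attrs["force_rate"] = trial.force_rate
        meta.attrs["imu_rate"] = trial.imu_rate
        meta.attrs["extra"] = json.dumps(trial.meta, default=float)


def load_trial(path) -> TrialRecording:
    """Read a trial back from a bundled HDF5 container."""
    names = AnthropometricModel().segment_names
    with h5py.File(path, "r") as f:
        segments = np.stack([f[f"segments/{n}"][()] for n in names])
        events = GaitEvents(
            heel_strikes=tuple(zip(
                (float(t) for t in f["events/heel_strike_times"][()]),
                (b.decode() for b in f["events/heel_strike_feet"][()]),
            )),
            toe_offs=tuple(zip(
                (float(t) for t in f["events/toe_off_times"][()]),
                (b.decode() for b in f["events/toe_off_feet"][()]),
            )),
        )
        meta = f["meta"].attrs
        return TrialRecording(
            subject_id=str(meta["subject_id"]),
            speed_class=str(meta["speed_class"]),
            mocap_times=f["segments/times"][()],
            segment_coms=segments,
            force_times=f["grf/times"][()],
            fz_1=f["grf/fz_1"][()],
            fz_2=f["grf/fz_2"][()],
            cop_1=f["grf/cop_1"][()],
            cop_2=f["grf/cop_2"][()],
            imu_times=f["imu/times"][()],
            imu=f["imu/signals"][()],
            events=events,
            mocap_rate=float(meta["mocap_rate"]),
            force_rate=float(meta["force_rate"]),
            imu_rate=float(meta["imu_rate"]),
            meta=json.loads(meta["extra"]),
        )


def trial_to_csv(trial: TrialRecording, out_dir) -> list[Path]:
    """Write per-stream CSV files (header: time + channel names, time in s)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = AnthropometricModel().segment_names
    written = []

    seg_cols = {"time": trial.mocap_times}
    for i, name in enumerate(names):
        for j, ax in enumerate("xyz"):
            seg_cols[f"{name}_{ax}"] = trial.segment_coms[i, :, j]
    written.append(out / "segments.csv")
    pd.DataFrame(seg_cols).to_csv(written[-1], index=False)

    grf = pd.DataFrame({
        "time": trial.force_times,
        "fz_1": trial.fz_1, "cop_1_x": trial.cop_1[:, 0], "cop_1_y": trial.cop_1[:, 1],
        "fz_2": trial.fz_2, "cop_2_x": trial.cop_2[:, 0], "cop_2_y": trial.cop_2[:, 1],
    })
    written.append(out / "grf.csv")
    grf.to_csv(written[-1], index=False)

    imu = pd.DataFrame({"time": trial.imu_times} |
                       {c: trial.imu[:, i] for i, c in enumerate(INPUT_COLUMNS)})
    written.append(out / "imu.csv")
    imu.to_csv(written[-1], index=False)

    ev = pd.DataFrame(
        [{"time": t, "foot": f, "event": "heel_strike"} for t, f in trial.events.heel_strikes]
        + [{"time": t, "foot": f, "event": "toe_off"} for t, f in trial.events.toe_offs]
    ).sort_values("time")
    written.append(out / "events.csv")
    ev.to_csv(written[-1], index=False)
    return written


def ia_to_csv(series_list, path) -> None:
    """Per-cycle inclination-angle CSV (frame 1..n, angles, provenance)."""
    rows = []
    for s in series_list:
        prov = s.provenance
        for k in range(s.n_frames):
            rows.append({
                "frame": k + 1,
                "sagittal_deg": s.sagittal[k],
                "frontal_deg": s.frontal[k],
                "subject": prov.get("subject", ""),
                "trial": prov.get("trial", ""),
                "speed": prov.get("speed", ""),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report: dict, out_dir) -> list[Path]:
    """Persist a study report: long results, Table-1 grid, rRMSE, ANOVA, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = report["summary"]
    written = []
    for key, fname in (("long", "results.csv"), ("table1", "table1.csv"),
                       ("rrmse_by_model", "rrmse_by_model.csv"),
                       ("rrmse_by_cutoff", "rrmse_by_cutoff.csv"),
                       ("anova", "anova.csv")):
        written.append(out / fname)
        summary[key].to_csv(written[-1], index=False)
    written.append(out / "manifest.json")
    with open(written[-1], "w") as fh:
        json.dump(report["manifest"], fh, indent=2)
    return written
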