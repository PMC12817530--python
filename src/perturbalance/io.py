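"""Plain-text serialization of cohorts and trial recordings.

Layout: one directory per participant-session-attempt holding a
``metadata.json`` sidecar and one two-column CSV per channel
(``time_s,value``; the header names the unit), plus a ``cohort.csv`` table
at the root (id, group, cait, mass_kg, height_m, leg_length_m, test_side).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries
from .synthdata import ParticipantProfile, TrialRecording

__all__ = ["save_cohort", "load_cohort", "save_trial", "load_trial", "trial_dir"]


def save_cohort(profiles: list[ParticipantProfile], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([
        dict(id=p.id, group=p.group, cait=p.cait, mass_kg=p.mass,
             height_m=p.height, leg_length_m=p.leg_length, test_side=p.test_side)
        for p in profiles
    ])
    path = out / "cohort.csv"
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def load_cohort(in_dir: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(Path(in_dir) / "cohort.csv")
    return [
        ParticipantProfile(id=row.id, group=row.group, cait=int(row.cait),
                           mass=row.mass_kg, height=row.height_m,
                           leg_length=row.leg_length_m, test_side=row.test_side)
        for row in df.itertuples()
    ]


def trial_dir(root: str | Path, rec: TrialRecording) -> Path:
    return (Path(root) / rec.participant_id
            / f"session{rec.session}" / f"attempt{rec.attempt}")


def _write_channel(path: Path, ts: TimeSeries) -> None:
    df = pd.DataFrame({"time_s": ts.times(), f"value_{ts.units}": ts.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def _read_channel(path: Path) -> TimeSeries:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy()
    units = df.columns[1].removeprefix("value_")
    rate = (t.size - 1) / (t[-1] - t[0])
    return TimeSeries(df.iloc[:, 1].to_numpy(), rate=rate,
                      t0=float(t[0]), units=units)


def save_trial(root: str | Path, rec: TrialRecording) -> Path:
    d = trial_dir(root, rec)
    d.mkdir(parents=True, exist_ok=True)
    meta = dict(participant_id=rec.participant_id, group=rec.group,
                session=rec.session, attempt=rec.attempt, success=rec.success)
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
    for muscle, ts in rec.emg.items():
        _write_channel(d / f"emg_{muscle}.csv", ts)
    _write_channel(d / "grf_fz.csv", rec.grf_fz)
    _write_channel(d / "cop_platform.csv", rec.cop_platform)
    for name, ts in rec.kinematics.items():
        _write_channel(d / f"kin_{name}.csv", ts)
    _write_channel(d / "accel.csv", rec.accel)
    return d


def load_trial(d: str | Path) -> TrialRecording:
    d = Path(d)
    meta = json.loads((d / "metadata.json").read_text())
    emg = {p.stem.removeprefix("emg_"): _read_channel(p)
           for p in sorted(d.glob("emg_*.csv"))}
    kin = {p.stem.removeprefix("kin_"): _read_channel(p)
           for p in sorted(d.glob("kin_*.csv"))}
    return TrialRecording(
        participant_id=meta["participant_id"], group=meta["group"],
        session=meta["session"], attempt=meta["attempt"],
        success=meta["success"], emg=emg,
        grf_fz=_read_channel(d / "grf_fz.csv"),
        cop_platform=_read_channel(d / "cop_platform.csv"),
        kinematics=kin, accel=_read_channel(d / "accel.csv"))
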