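"""Session data model and on-disk layout.

A session directory contains plain-text/flat-binary files:

* ``tracking.csv`` — header ``t,x,y,z,qw,qx,qy,qz`` (s, cm, unit quaternion);
  occluded samples have empty position/quaternion fields.
* ``spikes.csv`` — ``unit_id,t`` (s); ``units.csv`` — ``unit_id,channel,n_spikes``.
* ``lfp_<channel>.f32`` — little-endian float32 stream, with a JSON sidecar
  ``lfp_<channel>.json`` holding ``{fs_hz, channel_id, t0}``.
* ``maze.json`` — extent, floors, ports and bin specs.
* ``meta.json`` — free-form session metadata.

``write_session`` is bit-stable for identical inputs and emits a manifest
with SHA-256 checksums; ``load_session`` validates invariants on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import LfpSeries
from .kinematics import PoseSeries
from .maze import MazeModel
from .unit_metrics import SpikeTrain, UnitProfile

__all__ = ["SessionBundle", "load_session", "write_session"]

_TRACKING_COLS = ["t", "x", "y", "z", "qw", "qx", "qy", "qz"]


@dataclass
class SessionBundle:
    session_id: str
    tracking: PoseSeries
    units: list[UnitProfile]
    lfp: list[LfpSeries]
    maze: MazeModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        dur = self.duration
        for u in self.units:
            tt = u.train.times
            if tt.size and (tt[0] < 0 or tt[-1] > dur + 1e-9):
                raise ValueError(
                    f"unit {u.unit_id}: spike times outside [0, {dur:.3f}]")

    @property
    def duration(self) -> float:
        return self.tracking.duration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_session(bundle: SessionBundle, path: str | Path) -> dict:
    """Write a bundle to a directory; returns the checksum manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tr = bundle.tracking
    df = pd.DataFrame({
        "t": tr.t,
        "x": tr.position[:, 0], "y": tr.position[:, 1], "z": tr.position[:, 2],
        "qw": tr.quaternion[:, 0], "qx": tr.quaternion[:, 1],
        "qy": tr.quaternion[:, 2], "qz": tr.quaternion[:, 3],
    })
    df.loc[~tr.valid, ["x", "y", "z", "qw", "qx", "qy", "qz"]] = np.nan
    df.to_csv(path / "tracking.csv", index=False, float_format="%.17g",
              na_rep="")

    rows = []
    meta_rows = []
    for u in bundle.units:
        for t in u.train.times:
            rows.append((u.unit_id, t))
        meta_rows.append((u.unit_id, u.train.channel, u.train.n))
    pd.DataFrame(rows, columns=["unit_id", "t"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.17g")
    pd.DataFrame(meta_rows, columns=["unit_id", "channel", "n_spikes"]).to_csv(
        path / "units.csv", index=False)

    for ch in bundle.lfp:
        ch.samples.astype("<f4").tofile(path / f"lfp_{ch.channel_id}.f32")
        (path / f"lfp_{ch.channel_id}.json").write_text(json.dumps(
            {"fs_hz": ch.fs, "channel_id": ch.channel_id, "t0": ch.t0},
            sort_keys=True))

    (path / "maze.json").write_text(json.dumps(bundle.maze.to_dict(),
                                               sort_keys=True))
    (path / "meta.json").write_text(json.dumps(
        {"session_id": bundle.session_id, **bundle.meta},
        sort_keys=True, default=float))

    files = sorted(p.name for p in path.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {"session_id": bundle.session_id,
                "files": {f: _sha256(path / f) for f in files}}
    (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                   indent=1))
    return manifest


def load_session(path: str | Path) -> SessionBundle:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for required in ("tracking.csv", "spikes.csv", "maze.json", "meta.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"incomplete session: missing {required}")
    df = pd.read_csv(path / "tracking.csv", float_precision="round_trip")
    if list(df.columns) != _TRACKING_COLS:
        raise ValueError("incomplete session: bad tracking header")
    t = df["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("clock error: tracking time axis non-monotone")
    pos = df[["x", "y", "z"]].to_numpy(float)
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    valid = np.isfinite(pos).all(axis=1) & np.isfinite(quat).all(axis=1)
    quat = np.where(valid[:, None], quat, [[1.0, 0.0, 0.0, 0.0]])
    pos = np.nan_to_num(pos)
    tracking = PoseSeries(t=t, position=pos, quaternion=quat, valid=valid)

    meta = json.loads((path / "meta.json").read_text())
    session_id = meta.pop("session_id", path.name)

    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    units_meta = (pd.read_csv(path / "units.csv")
                  if (path / "units.csv").exists() else None)
    units = []
    order = (units_meta["unit_id"].tolist() if units_meta is not None
             else sorted(spikes["unit_id"].unique().tolist()))
    chan = ({str(r.unit_id): int(r.channel) for r in units_meta.itertuples()}
            if units_meta is not None else {})
    grouped = {str(k): v["t"].to_numpy(float)
               for k, v in spikes.groupby("unit_id")} if len(spikes) else {}
    for uid in order:
        uid = str(uid)
        times = np.sort(grouped.get(uid, np.empty(0)))
        units.append(UnitProfile(train=SpikeTrain(
            unit_id=uid, times=times, channel=chan.get(uid, -1))))

    lfp = []
    for sidecar in sorted(path.glob("lfp_*.json")):
        info = json.loads(sidecar.read_text())
        raw = np.fromfile(sidecar.with_suffix(".f32"), dtype="<f4")
        lfp.append(LfpSeries(fs=float(info["fs_hz"]),
                             samples=raw.astype(float),
                             t0=float(info.get("t0", 0.0)),
                             channel_id=str(info["channel_id"])))

    maze = MazeModel.from_dict(json.loads((path / "maze.json").read_text()))
    return SessionBundle(session_id=session_id, tracking=tracking,
                         units=units, lfp=lfp, maze=maze, meta=meta)
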