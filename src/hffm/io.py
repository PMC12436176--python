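"""File I/O: the wide CSV trajectory dialect, optional C3D, run configuration.

CSV dialect: a header row ``time,<LABEL>_x,<LABEL>_y,<LABEL>_z,...`` followed
by one row per sample; positions in mm, time in seconds on a uniform grid.
C3D support requires the optional ``ezc3d`` dependency; positions declared in
metres are converted to mm on read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trial import GaitEvents, MarkerTrajectories

__all__ = [
    "RunConfig",
    "read_trial",
    "write_trial_csv",
    "read_trial_csv",
    "write_curves_csv",
    "read_events_csv",
    "write_events_csv",
]


@dataclass
class RunConfig:
    """Serializable pipeline configuration."""

    side: str = "R"
    label_map: dict[str, str] = field(default_factory=dict)
    vertical_axis: str = "z"
    smoothing_cutoff_hz: float = 6.0
    smoothing: bool = True
    classification_window_percent: float = 5.0
    output_dir: str = "."
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def write_trial_csv(path: str | Path, traj: MarkerTrajectories) -> None:
    n = traj.n_samples
    cols = {"time": np.arange(n) / traj.rate}
    for lbl, xyz in traj.data.items():
        for k, ax in enumerate("xyz"):
            cols[f"{lbl}_{ax}"] = xyz[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(
    path: str | Path, side: str = "R", label_map: dict[str, str] | None = None
) -> MarkerTrajectories:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: CSV dialect requires a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 1:
        raise ValueError(f"{path}: empty trial")
    if len(t) > 1:
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError(f"{path}: time base is not uniform")
        rate = 1.0 / float(dt.mean())
    else:  # a single-sample (static) file has no meaningful rate
        rate = 1.0
    labels = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    data = {}
    for lbl in labels:
        missing = [f"{lbl}_{ax}" for ax in "xyz" if f"{lbl}_{ax}" not in df.columns]
        if missing:
            raise ValueError(f"{path}: incomplete components for {lbl}: {missing}")
        out_lbl = (label_map or {}).get(lbl, lbl)
        data[out_lbl] = df[[f"{lbl}_x", f"{lbl}_y", f"{lbl}_z"]].to_numpy(dtype=float)
    return MarkerTrajectories(data, rate=rate, side=side)


def _read_trial_c3d(
    path: str | Path, side: str, label_map: dict[str, str] | None
) -> MarkerTrajectories:
    try:
        import ezc3d
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package "
            "(pip install hffm[c3d]); the CSV dialect needs no extras"
        ) from e
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = 1000.0 if units and units[0].strip().lower() in ("m", "meter", "metre") else 1.0
    data = {}
    for i, lbl in enumerate(labels):
        out_lbl = (label_map or {}).get(lbl, lbl)
        data[out_lbl] = (pts[:3, i, :].T * scale).astype(float)
    return MarkerTrajectories(data, rate=rate, side=side)


def read_trial(
    path: str | Path, side: str = "R", label_map: dict[str, str] | None = None
) -> MarkerTrajectories:
    """Read a trial by extension (.csv dialect or .c3d)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix.lower() == ".c3d":
        return _read_trial_c3d(p, side, label_map)
    return read_trial_csv(p, side, label_map)


def write_curves_csv(path: str | Path, curves: dict) -> None:
    """Write gait-cycle curves: 101 rows, one column pair per angle."""
    cols = {"percent_cycle": np.arange(101, dtype=float)}
    for name, curve in curves.items():
        cols[name] = curve.values
        if curve.sd is not None:
            cols[f"{name}_sd"] = curve.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def write_events_csv(path: str | Path, events: GaitEvents) -> None:
    n = len(events.initial_contact)
    to = np.full(n, -1, dtype=int)
    to[: len(events.toe_off)] = events.toe_off
    pd.DataFrame(
        {"initial_contact": events.initial_contact, "toe_off": to}
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path, side: str = "R") -> GaitEvents:
    df = pd.read_csv(path)
    to = df["toe_off"].to_numpy(dtype=int)
    return GaitEvents(
        initial_contact=df["initial_contact"].to_numpy(dtype=int),
        toe_off=to[to >= 0],
        side=side,
    )
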