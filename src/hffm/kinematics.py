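"""Angle time-series, gait-cycle curves, summaries and classification.

Fifteen channels are computed per time sample:

* nine rigid-segment Euler-Cardan angles (XYZ: sagittal, frontal, transverse)
  between shank/hindfoot, hindfoot/forefoot and shank/forefoot;
* hallux flexion and abduction as projected angles of the hallux axis in the
  forefoot frame;
* four phenomenological angles measured directly on markers: medial arch
  (apex angle MCL-NAV-DMT1), medial arch inclination, metatarsal I-V angle,
  and subtalar eversion.

Sign conventions (both sides): dorsiflexion +, varus/inversion/supination +,
internal rotation and adduction +, eversion + on the subtalar channel.

For trajectories the package calibrates once (static or first sample): joint
centers and segment frames are constructed on the calibration sample and then
tracked rigidly with each segment's marker cluster (least-squares rigid fit),
the standard anatomical-calibration approach.  This keeps every angle exactly
rigid-invariant and free of cross-segment regression coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import interp1d
from scipy.signal import find_peaks

from .errors import (
    DegenerateGeometryError,
    MissingMarkerError,
    NoCycleError,
    TrialRejectedError,
)
from .geometry import (
    Frame,
    apex_angle,
    euler_xyz_decompose,
    fit_rigid_transform,
    signed_projected_angle,
    unit,
)
from .model import (
    SEGMENT_MARKERS,
    MarkerFrame,
    build_model,
    compute_mra_ffc,
    local_foot_frame,
    sole_normal,
)
from .trial import GaitEvents, MarkerTrajectories

__all__ = [
    "ANGLE_NAMES",
    "CARDAN_BASIS",
    "AngleSet",
    "GaitCycleCurve",
    "SummaryRow",
    "compute_angles_frame",
    "compute_angle_trajectories",
    "smooth_trajectories",
    "default_smoothing_penalty",
    "detect_gait_events",
    "normalize_to_cycle",
    "summarize_curve",
    "classify_foot_type",
]

log = logging.getLogger(__name__)

#: permutation from segment-frame axes (x anterior, y mediolateral, z distal)
#: to the Cardan rotation basis (X mediolateral, Y anterior, Z proximal/up),
#: so that the X-Y-Z sequence reads sagittal, frontal, transverse
CARDAN_BASIS = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])

ANGLE_NAMES = (
    "hindfoot_shank_flexion",
    "hindfoot_shank_varus",
    "hindfoot_shank_rotation",
    "forefoot_hindfoot_flexion",
    "forefoot_hindfoot_supination",
    "forefoot_hindfoot_adduction",
    "forefoot_shank_flexion",
    "forefoot_shank_supination",
    "forefoot_shank_adduction",
    "hallux_flexion",
    "hallux_abduction",
    "medial_arch",
    "medial_arch_inclination",
    "metatarsal_I_V",
    "subtalar_eversion",
)


@dataclass
class AngleSet:
    """The fifteen named angles (degrees) at one time sample; NaN if missing."""

    hindfoot_shank_flexion: float = np.nan
    hindfoot_shank_varus: float = np.nan
    hindfoot_shank_rotation: float = np.nan
    forefoot_hindfoot_flexion: float = np.nan
    forefoot_hindfoot_supination: float = np.nan
    forefoot_hindfoot_adduction: float = np.nan
    forefoot_shank_flexion: float = np.nan
    forefoot_shank_supination: float = np.nan
    forefoot_shank_adduction: float = np.nan
    hallux_flexion: float = np.nan
    hallux_abduction: float = np.nan
    medial_arch: float = np.nan
    medial_arch_inclination: float = np.nan
    metatarsal_I_V: float = np.nan
    subtalar_eversion: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GaitCycleCurve:
    """A 101-point (0-100% cycle) normalized angle curve."""

    angle_name: str
    values: np.ndarray
    sd: np.ndarray | None = None
    n_cycles: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError("a gait-cycle curve has exactly 101 samples")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != (101,):
                raise ValueError("sd must have 101 samples")
            if np.nanmin(self.sd) < 0:
                raise ValueError("sd must be non-negative")


@dataclass
class SummaryRow:
    """Mean / max / range-of-motion of one angle over the gait cycle."""

    angle_name: str
    mean: float
    max: float
    rom: float
    mean_sd: float = np.nan
    max_sd: float = np.nan
    rom_sd: float = np.nan


def _relative_cardan(prox: Frame, dist: Frame):
    R_rel = prox.rotation.T @ dist.rotation
    return euler_xyz_decompose(CARDAN_BASIS.T @ R_rel @ CARDAN_BASIS)


def _hallux_angles(hallux_dir, forefoot: Frame, side: str):
    d = forefoot.rotation.T @ np.asarray(hallux_dir, float)  # forefoot components
    if side == "L":  # left frames are anti-aligned; the toe points along -x there
        d = -d
    flexion = np.degrees(np.arctan2(-d[2], d[0]))
    abduction = np.degrees(np.arctan2(-d[1], d[0]))
    return float(flexion), float(abduction)


def _phenomenological(m: MarkerFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        mcl, nav, dmt1 = m.require("MCL", "NAV", "DMT1")
        out["medial_arch"] = apex_angle(mcl, nav, dmt1)
    except MissingMarkerError:
        pass
    try:
        down = -sole_normal(m)
        mcl, dmt1 = m.require("MCL", "DMT1")
        v = unit(dmt1 - mcl)
        # + when the first-ray line dives plantarward towards the forefoot
        out["medial_arch_inclination"] = float(np.degrees(np.arcsin(
            np.clip(np.dot(v, down), -1.0, 1.0)
        )))
    except (MissingMarkerError, DegenerateGeometryError):
        pass
    try:
        n = sole_normal(m)
        p1, d1, p5, d5 = m.require("PMT1", "DMT1", "PMT5", "DMT5")
        r1 = unit((d1 - p1) - np.dot(d1 - p1, n) * n)
        r5 = unit((d5 - p5) - np.dot(d5 - p5, n) * n)
        out["metatarsal_I_V"] = float(np.degrees(np.arccos(
            np.clip(np.dot(r1, r5), -1.0, 1.0)
        )))
    except (MissingMarkerError, DegenerateGeometryError):
        pass
    try:
        frame = local_foot_frame(m)
        mcl, lcl, mml, lml = m.require("MCL", "LCL", "MML", "LML")
        s = 1.0 if m.side == "R" else -1.0
        out["subtalar_eversion"] = signed_projected_angle(
            lml - mml, lcl - mcl, -s * frame.x
        )
    except (MissingMarkerError, DegenerateGeometryError):
        pass
    return out


def compute_angles_frame(m: MarkerFrame) -> AngleSet:
    """All fifteen angles from one marker sample (per-frame construction).

    Missing markers null only the affected channels; degenerate geometry is
    re-raised with the channel name attached.
    """
    result = AngleSet()
    try:
        _, poses = build_model(m)
    except MissingMarkerError:
        poses = None
    except DegenerateGeometryError as e:
        raise DegenerateGeometryError(f"rigid-segment channels: {e}") from e
    if poses is not None:
        sh, hf, ff = poses.shank, poses.hindfoot, poses.forefoot
        for prox, dist, names in (
            (sh, hf, ANGLE_NAMES[0:3]),
            (hf, ff, ANGLE_NAMES[3:6]),
            (sh, ff, ANGLE_NAMES[6:9]),
        ):
            a, b, g = _relative_cardan(prox, dist)
            for name, value in zip(names, (a, b, g)):
                setattr(result, name, value)
        flex, abd = _hallux_angles(poses.hallux_dir, ff, m.side)
        result.hallux_flexion = flex
        result.hallux_abduction = abd
    for name, value in _phenomenological(m).items():
        setattr(result, name, value)
    return result


# ---------------------------------------------------------------------------
# smoothing: discrete penalized least squares (Whittaker graduation) with a
# third-order difference penalty -- the uniform-grid analogue of a quintic
# smoothing spline, as used by clinical spline filters.

def default_smoothing_penalty(rate_hz: float, cutoff_hz: float = 6.0) -> float:
    """Penalty giving a -3 dB (amplitude 1/sqrt(2)) point at ``cutoff_hz``."""
    omega = 2.0 * np.sin(np.pi * cutoff_hz / rate_hz)
    return (np.sqrt(2.0) - 1.0) / omega**6


def _whittaker(y: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    n = len(y)
    D = sp.diags([1.0, -3.0, 3.0, -1.0], [0, 1, 2, 3], shape=(n - 3, n))
    W = sp.diags(weights)
    A = (W + lam * (D.T @ D)).tocsc()
    return spla.spsolve(A, weights * np.where(weights > 0, y, 0.0))


def smooth_trajectories(
    traj: MarkerTrajectories,
    penalty: float | None = None,
    cutoff_hz: float = 6.0,
    max_gap_s: float = 0.1,
) -> MarkerTrajectories:
    """Smooth every marker component; interpolate NaN gaps up to ``max_gap_s``.

    A gap longer than the maximum rejects the trial.
    """
    lam = penalty if penalty is not None else default_smoothing_penalty(
        traj.rate, cutoff_hz
    )
    max_gap = int(round(max_gap_s * traj.rate))
    out: dict[str, np.ndarray] = {}
    for lbl, xyz in traj.data.items():
        ok = np.all(np.isfinite(xyz), axis=1)
        if not ok.any():
            raise TrialRejectedError(f"marker {lbl} has no valid samples")
        gaps = _gap_lengths(ok)
        if gaps and max(gaps) > max_gap:
            raise TrialRejectedError(
                f"marker {lbl}: gap of {max(gaps)} samples exceeds "
                f"the allowed {max_gap}"
            )
        w = ok.astype(float)
        sm = np.column_stack([_whittaker(xyz[:, k], w, lam) for k in range(3)])
        out[lbl] = sm
    return MarkerTrajectories(out, rate=traj.rate, side=traj.side)


def _gap_lengths(ok: np.ndarray) -> list[int]:
    lengths, run = [], 0
    for v in ok:
        if not v:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


# ---------------------------------------------------------------------------
# gait events

def detect_gait_events(
    traj: MarkerTrajectories,
    min_stride_s: float = 0.5,
    velocity_threshold: float = 0.05,
) -> GaitEvents:
    """Coordinate-based event detection.

    Initial contact: local minima of the heel (CCL) vertical position.
    Toe off: within each cycle, the first sample where the forward velocity of
    DMT2 exceeds ``velocity_threshold`` times its swing peak.
    """
    for lbl in ("CCL", "DMT2"):
        if lbl not in traj.data:
            raise MissingMarkerError([lbl])
    z = traj.data["CCL"][:, 2]
    span = float(np.nanmax(z) - np.nanmin(z))
    if span < 5.0:  # < 5 mm of heel excursion: nothing resembling gait
        raise NoCycleError("no heel-height excursion; no detectable gait cycle")
    distance = max(1, int(min_stride_s * traj.rate))
    # swing is unambiguous (large heel lift); IC is the heel-height minimum
    # between consecutive swing peaks (edge segments allowed, but a minimum
    # sitting on the trial boundary cannot be confirmed and is dropped)
    peaks, _ = find_peaks(z, prominence=0.25 * span, distance=distance)
    if len(peaks) < 2:
        raise NoCycleError("fewer than two swing phases detected")
    bounds = [0, *peaks.tolist(), len(z) - 1]
    ic = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 3:
            continue
        cand = a + int(np.argmin(z[a : b + 1]))
        if 2 <= cand <= len(z) - 3:
            ic.append(cand)
    ic = np.asarray(sorted(set(ic)), dtype=int)
    if len(ic) < 2:
        raise NoCycleError("fewer than two initial contacts detected")

    dmt2 = traj.data["DMT2"]
    disp = dmt2[-1] - dmt2[0]
    disp[2] = 0.0
    fwd = unit(disp) if np.linalg.norm(disp) > 1e-6 else np.array([1.0, 0.0, 0.0])
    v = np.gradient(dmt2 @ fwd, 1.0 / traj.rate)

    to = []
    for k in range(len(ic) - 1):
        a, b = ic[k], ic[k + 1]
        seg = v[a:b]
        vmax = float(np.max(seg))
        if vmax <= 0:
            continue
        idx = np.nonzero(seg > velocity_threshold * vmax)[0]
        if len(idx):
            to.append(a + int(idx[0]))
    if len(to) < len(ic) - 1:
        raise NoCycleError("toe-off could not be located in every cycle")
    return GaitEvents(initial_contact=np.asarray(ic), toe_off=np.asarray(to),
                      side=traj.side)


# ---------------------------------------------------------------------------
# cycle normalization, summaries, classification

def normalize_to_cycle(
    series: np.ndarray, events: GaitEvents, angle_name: str = ""
) -> GaitCycleCurve:
    """Resample each IC-to-IC cycle to 101 points and average across cycles."""
    series = np.asarray(series, dtype=float)
    grid = np.linspace(0.0, 1.0, 101)
    cycles = []
    for k in range(events.n_cycles):
        a, b = events.initial_contact[k], events.initial_contact[k + 1]
        if b >= len(series) or b - a < 4:
            log.info("skipping incomplete cycle %d (%d..%d)", k, a, b)
            continue
        seg = series[a : b + 1]
        if not np.all(np.isfinite(seg)):
            log.info("skipping cycle %d with missing samples", k)
            continue
        x = np.linspace(0.0, 1.0, len(seg))
        cycles.append(interp1d(x, seg, kind="cubic")(grid))
    if not cycles:
        raise NoCycleError("no complete cycle available for normalization")
    arr = np.vstack(cycles)
    sd = arr.std(axis=0, ddof=0) if len(cycles) > 1 else np.zeros(101)
    return GaitCycleCurve(
        angle_name=angle_name, values=arr.mean(axis=0), sd=sd, n_cycles=len(cycles)
    )


def summarize_curve(curve: GaitCycleCurve) -> SummaryRow:
    """Mean, maximum and range of motion of the 101-point curve."""
    v = curve.values
    return SummaryRow(
        angle_name=curve.angle_name,
        mean=float(np.mean(v)),
        max=float(np.max(v)),
        rom=float(np.max(v) - np.min(v)),
    )


def classify_foot_type(
    curve: GaitCycleCurve, window_percent: float = 5.0
) -> tuple[str, float]:
    """Equinovarus screen: sign of the early hindfoot/shank flexion slope.

    A positive least-squares slope of the curve over the first
    ``window_percent`` of the cycle (the foot dorsiflexing immediately after
    contact, i.e. forefoot-first contact) labels the trial ``"EV"``;
    otherwise ``"non-EV"``.  Returns the label and the slope (deg per %cycle).
    """
    n_pts = int(np.floor(window_percent)) + 1
    if n_pts < 2:
        raise ValueError("classification window must span at least 2 curve points")
    x = np.arange(n_pts, dtype=float)
    slope = float(np.polyfit(x, curve.values[:n_pts], 1)[0])
    return ("EV" if slope > 0 else "non-EV"), slope


# ---------------------------------------------------------------------------
# trajectory pipeline

def _cluster(traj: MarkerTrajectories, labels: Iterable[str]) -> list[str]:
    return [lbl for lbl in labels if lbl in traj.data]


def compute_angle_trajectories(
    traj: MarkerTrajectories,
    calibration: MarkerFrame | None = None,
    smooth: bool = True,
    penalty: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-sample angle time-series for a whole trial.

    Joint centers, axes and segment frames are constructed once on the
    calibration sample (a static pose if available, else the first trial
    sample) and tracked rigidly with each segment's marker cluster.
    Phenomenological channels are evaluated directly on the (smoothed) markers
    of every sample.
    """
    if smooth:
        traj = smooth_trajectories(traj, penalty=penalty)
    n = traj.n_samples
    cal = calibration if calibration is not None else traj.frame(0)
    if cal.side != traj.side:
        raise ValueError("calibration side does not match the trial side")
    _, cal_poses = build_model(cal)
    cal_frames = {
        "shank": cal_poses.shank,
        "hindfoot": cal_poses.hindfoot,
        "forefoot": cal_poses.forefoot,
    }
    # the hallux axis needs the FFC, carried with the forefoot cluster
    _, _, ffc0 = compute_mra_ffc(cal, down=-sole_normal(cal))

    clusters = {
        seg: _cluster(traj, lbls)
        for seg, lbls in SEGMENT_MARKERS.items()
        if seg != "hallux"
    }
    cal_pts = {
        seg: np.array([cal[lbl] for lbl in lbls]) if all(l in cal for l in lbls) else None
        for seg, lbls in clusters.items()
    }

    out = {name: np.full(n, np.nan) for name in ANGLE_NAMES}
    for i in range(n):
        mf = traj.frame(i)
        frames_i: dict[str, Frame] = {}
        fits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for seg, lbls in clusters.items():
            pts0 = cal_pts[seg]
            if pts0 is None or len(lbls) < 3 or not all(l in mf for l in lbls):
                continue
            pts = np.array([mf[lbl] for lbl in lbls])
            R, t = fit_rigid_transform(pts0, pts)
            fits[seg] = (R, t)
            f0 = cal_frames[seg]
            frames_i[seg] = Frame(R @ f0.origin + t, R @ f0.rotation)
        pairs = (
            ("shank", "hindfoot", ANGLE_NAMES[0:3]),
            ("hindfoot", "forefoot", ANGLE_NAMES[3:6]),
            ("shank", "forefoot", ANGLE_NAMES[6:9]),
        )
        for prox, dist, names in pairs:
            if prox in frames_i and dist in frames_i:
                a, b, g = _relative_cardan(frames_i[prox], frames_i[dist])
                for name, value in zip(names, (a, b, g)):
                    out[name][i] = value
        if "forefoot" in fits and "HLX" in mf:
            R, t = fits["forefoot"]
            ffc_i = R @ ffc0 + t
            d = mf["HLX"] - ffc_i
            if np.linalg.norm(d) > 1e-6:
                flex, abd = _hallux_angles(unit(d), frames_i["forefoot"], traj.side)
                out["hallux_flexion"][i] = flex
                out["hallux_abduction"][i] = abd
        for name, value in _phenomenological(mf).items():
            out[name][i] = value
    return out
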