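"""Functional foot model: joint centers, axes and segment coordinate systems.

From one labelled marker sample the model constructs

* the knee and ankle joint centers (epicondyle / malleolar midpoints),
* the heel rotation center (HRC) and midfoot joint center (MFJC) via the
  published three-marker regression formulas, evaluated in a marker-anchored
  local foot frame,
* the metatarsal rotation axis (MRA): the DMT1-DMT5 line shifted plantarward
  by 11 mm (8 mm metatarsal head radius + 3 mm marker radius), and the
  forefoot center (FFC) as the projection of DMT2 onto the MRA,
* four segment coordinate systems (shank, hindfoot, forefoot; the hallux is
  a single axis FFC->HLX).

Conventions
-----------
For right feet every segment frame has x anterior, y lateral and z distal
(pointing from knee towards ankle).  Left-foot frames are *anti-aligned*: the
mirrored construction is rotated 180 deg about its own mediolateral axis
(x posterior, y medial, z proximal).  Under this convention the Cardan
conjugation between sides is the identity, so anatomically equivalent left and
right motions report identical angles with one clinical sign convention
(dorsiflexion +, varus/inversion +, internal rotation/adduction +).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegenerateGeometryError, MissingMarkerError
from .geometry import Frame, midpoint, project_point_onto_line, unit

__all__ = [
    "MARKER_LABELS",
    "SEGMENT_MARKERS",
    "MarkerFrame",
    "JointSet",
    "SegmentPoses",
    "MRA_PLANTAR_SHIFT_MM",
    "local_foot_frame",
    "compute_primary_centers",
    "hrc_regression",
    "mfjc_regression",
    "compute_hrc",
    "compute_mfjc",
    "compute_mra_ffc",
    "build_shank_frame",
    "build_hindfoot_frame",
    "build_forefoot_frame",
    "build_hallux_axis",
    "build_model",
]

#: the full 17-label marker set, one foot
MARKER_LABELS = (
    "LEP", "MEP", "TTU", "SH1", "SH2", "LML", "MML",
    "LCL", "CCL", "MCL",
    "NAV", "DMT1", "PMT1", "DMT2", "DMT5", "PMT5",
    "HLX",
)

#: rigid-cluster membership used for tracking (placement aids TTU/SH1/SH2 included
#: with the shank; NAV/PMT markers travel with the forefoot, which also carries
#: the midfoot joint center they define)
SEGMENT_MARKERS = {
    "shank": ("LEP", "MEP", "TTU", "SH1", "SH2", "LML", "MML"),
    "hindfoot": ("LCL", "CCL", "MCL"),
    "forefoot": ("NAV", "DMT1", "PMT1", "DMT2", "DMT5", "PMT5"),
    "hallux": ("HLX",),
}

#: plantar shift of the metatarsal rotation axis below the DMT1-DMT5 marker
#: line: 8 mm metatarsal head radius plus 3 mm marker radius
MRA_PLANTAR_SHIFT_MM = 11.0

# Regression coefficients mapping (CCL, LCL, MCL) local coordinates to the HRC
_HRC_COEF = np.array([
    [0.54, -0.15, 0.15],   # X
    [0.28, 0.43, 0.42],    # Y
    [0.29, 0.025, 1.74],   # Z
])
# and (NAV, PMT1, PMT5) to the MFJC
_MFJC_COEF = np.array([
    [0.16, 0.25, 0.30],
    [0.52, -0.17, 0.26],
    [0.50, 0.00, 0.50],
])


@dataclass
class MarkerFrame:
    """One time sample: marker label -> position (mm, lab frame), plus side."""

    markers: dict[str, np.ndarray]
    side: str = "R"
    time_index: int = 0

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        self.markers = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.markers.items()
        }

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.markers[label]
        except KeyError:
            raise MissingMarkerError([label]) from None

    def __contains__(self, label: str) -> bool:
        return label in self.markers

    def require(self, *labels: str) -> list[np.ndarray]:
        missing = [lbl for lbl in labels if lbl not in self.markers]
        if missing:
            raise MissingMarkerError(missing)
        return [self.markers[lbl] for lbl in labels]

    def transformed(self, R, t) -> "MarkerFrame":
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return MarkerFrame(
            {k: R @ v + t for k, v in self.markers.items()},
            side=self.side,
            time_index=self.time_index,
        )


@dataclass
class JointSet:
    """Joint centers and axes of one marker sample, lab frame (mm)."""

    KJC: np.ndarray
    AJC: np.ndarray
    HRC: np.ndarray
    MFJC: np.ndarray
    FFC: np.ndarray
    KJA_dir: np.ndarray
    MRA_dir: np.ndarray
    MRA_point: np.ndarray
    #: lateral epicondyle retained for the shank frame build
    LEP: np.ndarray = field(default=None)


@dataclass
class SegmentPoses:
    """The four segment coordinate systems (hallux is axis-only)."""

    shank: Frame
    hindfoot: Frame
    forefoot: Frame
    hallux_dir: np.ndarray


def _side_sign(side: str) -> float:
    return 1.0 if side == "R" else -1.0


#: left-foot frames are rotated 180 deg about their own y axis so that the
#: left/right Cardan sign conventions coincide
_LEFT_FLIP = np.diag([-1.0, 1.0, -1.0])


def _side_adjust(R: np.ndarray, side: str) -> np.ndarray:
    return R @ _LEFT_FLIP if side == "L" else R


def sole_normal(m: MarkerFrame) -> np.ndarray:
    """Unit normal of the CCL-DMT1-DMT5 sole plane, pointing dorsally.

    Marker-anchored (no lab-vertical reference), hence equivariant under any
    rigid transform of the foot; the side flag fixes the dorsal sign.
    """
    ccl, dmt1, dmt5 = m.require("CCL", "DMT1", "DMT5")
    n = np.cross(dmt5 - ccl, dmt1 - ccl)
    if np.linalg.norm(n) < 1e-9:
        raise DegenerateGeometryError("CCL, DMT1, DMT5 are collinear")
    return _side_sign(m.side) * (n / np.linalg.norm(n))


def local_foot_frame(m: MarkerFrame) -> Frame:
    """Marker-anchored foot frame used to evaluate the HRC/MFJC regressions.

    Origin CCL; x from CCL towards the DMT1/DMT5 midpoint; z the dorsal
    sole-plane normal (orthogonalized against x); y completes the frame and is
    sign-fixed to point lateral using DMT5 (the fifth metatarsal is lateral on
    both sides).  For left feet the returned axes form a left-handed triad,
    i.e. the frame is the mirror of the right-foot one, so the regression
    coefficients act in mirror-consistent coordinates.
    """
    ccl, dmt1, dmt5 = m.require("CCL", "DMT1", "DMT5")
    fwd = midpoint(dmt1, dmt5) - ccl
    if np.linalg.norm(fwd) < 1e-6:
        raise DegenerateGeometryError("CCL coincides with the metatarsal midpoint")
    x = unit(fwd, "foot long axis")
    n = sole_normal(m)
    z = n - np.dot(n, x) * x
    if np.linalg.norm(z) < np.sin(np.radians(5.0)):
        raise DegenerateGeometryError("foot long axis within 5 deg of the sole normal")
    z = unit(z, "foot vertical axis")
    y = np.cross(z, x)
    if np.dot(y, dmt5 - dmt1) < 0:  # +y lateral on both sides
        y = -y
    R = np.column_stack([x, y, z])
    return Frame(ccl, R)


def compute_primary_centers(m: MarkerFrame):
    """Knee/ankle centers and the knee joint axis from the four leg markers."""
    lep, mep, lml, mml = m.require("LEP", "MEP", "LML", "MML")
    if np.linalg.norm(lep - mep) < 1e-6:
        raise DegenerateGeometryError("LEP and MEP coincide")
    kjc = midpoint(lep, mep)
    ajc = midpoint(lml, mml)
    kja = unit(lep - mep, "knee joint axis")
    return kjc, ajc, kja


def hrc_regression(ccl_local, lcl_local, mcl_local) -> np.ndarray:
    """Heel rotation center from local-frame CCL/LCL/MCL coordinates (mm)."""
    P = np.column_stack([
        np.asarray(ccl_local, float),
        np.asarray(lcl_local, float),
        np.asarray(mcl_local, float),
    ])
    return np.array([P[i] @ _HRC_COEF[i] for i in range(3)])


def mfjc_regression(nav_local, pmt1_local, pmt5_local) -> np.ndarray:
    """Midfoot joint center from local-frame NAV/PMT1/PMT5 coordinates (mm)."""
    P = np.column_stack([
        np.asarray(nav_local, float),
        np.asarray(pmt1_local, float),
        np.asarray(pmt5_local, float),
    ])
    return np.array([P[i] @ _MFJC_COEF[i] for i in range(3)])


def compute_hrc(m: MarkerFrame) -> np.ndarray:
    """HRC in lab coordinates: regression applied in the local foot frame."""
    frame = local_foot_frame(m)
    ccl, lcl, mcl = m.require("CCL", "LCL", "MCL")
    hrc_local = hrc_regression(
        frame.to_local(ccl), frame.to_local(lcl), frame.to_local(mcl)
    )
    return frame.to_parent(hrc_local)


def compute_mfjc(m: MarkerFrame) -> np.ndarray:
    """MFJC in lab coordinates: regression applied in the local foot frame."""
    frame = local_foot_frame(m)
    nav, pmt1, pmt5 = m.require("NAV", "PMT1", "PMT5")
    mfjc_local = mfjc_regression(
        frame.to_local(nav), frame.to_local(pmt1), frame.to_local(pmt5)
    )
    return frame.to_parent(mfjc_local)


def compute_mra_ffc(m: MarkerFrame, down: np.ndarray | None = None):
    """Metatarsal rotation axis and forefoot center.

    The MRA is parallel to DMT1-DMT5, shifted 11 mm plantarward.  ``down``
    is the plantar unit direction; by default it is the (marker-anchored)
    negative sole normal when the hindfoot markers are present, else the lab
    -z axis.  FFC is the orthogonal projection of DMT2 onto the MRA.
    """
    dmt1, dmt5 = m.require("DMT1", "DMT5")
    if np.linalg.norm(dmt1 - dmt5) < 1e-6:
        raise DegenerateGeometryError("DMT1 and DMT5 coincide")
    if down is None:
        if "CCL" in m:
            down = -sole_normal(m)
        else:
            down = np.array([0.0, 0.0, -1.0])
    down = unit(down, "plantar direction")
    mra_dir = unit(dmt1 - dmt5, "metatarsal axis")
    mra_point = dmt1 + MRA_PLANTAR_SHIFT_MM * down
    (dmt2,) = m.require("DMT2")
    ffc = project_point_onto_line(dmt2, mra_point, mra_dir)
    return mra_point, mra_dir, ffc


def _checked_cross(a, b, what: str) -> np.ndarray:
    c = np.cross(a, b)
    # reject near-parallel construction vectors (< 1 degree separation)
    if np.linalg.norm(c) < np.sin(np.radians(1.0)) * np.linalg.norm(a) * np.linalg.norm(b):
        raise DegenerateGeometryError(f"near-parallel construction vectors for {what}")
    return c


def build_shank_frame(j: JointSet, side: str = "R") -> Frame:
    """Shank frame: origin KJC, z towards AJC, y towards the epicondyle line.

    ``y_raw`` points at LEP (lateral) for right feet and away from it for left
    feet, so y is lateral(R)/medial(L) and x = y_raw x z is anterior.
    """
    if np.linalg.norm(j.AJC - j.KJC) < 1e-6:
        raise DegenerateGeometryError("KJC and AJC coincide")
    z = unit(j.AJC - j.KJC, "shank long axis")
    y_raw = _side_sign(side) * unit(j.LEP - j.KJC, "knee axis direction")
    x = unit(_checked_cross(y_raw, z, "shank frame"), "shank x")
    y = np.cross(z, x)
    return Frame(j.KJC, _side_adjust(np.column_stack([x, y, z]), side))


def build_hindfoot_frame(j: JointSet, side: str = "R") -> Frame:
    """Hindfoot frame: origin HRC, x towards MFJC, y from x x (HRC->AJC).

    With the ankle above the heel, ``x x up`` lands on the lateral side for
    right feet and the medial side for left feet, matching the shank
    convention without an explicit side flag.
    """
    x = unit(j.MFJC - j.HRC, "hindfoot long axis")
    u = unit(j.AJC - j.HRC, "HRC to AJC")
    y = unit(_checked_cross(x, u, "hindfoot frame"), "hindfoot y")
    z = np.cross(x, y)
    return Frame(j.HRC, _side_adjust(np.column_stack([x, y, z]), side))


def build_forefoot_frame(
    j: JointSet, side: str = "R", down_hint: np.ndarray | None = None
) -> Frame:
    """Forefoot frame: origin MFJC, x towards FFC, z normal to x and the MRA.

    The z sign is fixed to point distally/plantarward (consistent with the
    shank and hindfoot frames) using ``down_hint``; when omitted, the hint is
    derived from MFJC-to-MRA drop.
    """
    x = unit(j.FFC - j.MFJC, "forefoot long axis")
    z = unit(_checked_cross(x, j.MRA_dir, "forefoot frame"), "forefoot z")
    if down_hint is None:
        down_hint = j.MRA_point - j.MFJC  # axis sits plantar of the joint center
    if np.dot(z, down_hint) < 0:
        z = -z
    y = np.cross(z, x)
    return Frame(j.MFJC, _side_adjust(np.column_stack([x, y, z]), side))


def build_hallux_axis(m: MarkerFrame, j: JointSet) -> np.ndarray:
    """Unit hallux long axis FFC -> HLX."""
    (hlx,) = m.require("HLX")
    if np.linalg.norm(hlx - j.FFC) < 1e-6:
        raise DegenerateGeometryError("HLX coincides with the forefoot center")
    return unit(hlx - j.FFC, "hallux axis")


def build_model(m: MarkerFrame) -> tuple[JointSet, SegmentPoses]:
    """Full per-sample construction: joint set plus the four segment poses."""
    kjc, ajc, kja = compute_primary_centers(m)
    hrc = compute_hrc(m)
    mfjc = compute_mfjc(m)
    down = -sole_normal(m)
    mra_point, mra_dir, ffc = compute_mra_ffc(m, down=down)
    joints = JointSet(
        KJC=kjc, AJC=ajc, HRC=hrc, MFJC=mfjc, FFC=ffc,
        KJA_dir=kja, MRA_dir=mra_dir, MRA_point=mra_point, LEP=m["LEP"],
    )
    poses = SegmentPoses(
        shank=build_shank_frame(joints, m.side),
        hindfoot=build_hindfoot_frame(joints, m.side),
        forefoot=build_forefoot_frame(joints, m.side, down_hint=down),
        hallux_dir=build_hallux_axis(m, joints),
    )
    return joints, poses
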