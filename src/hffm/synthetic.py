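"""Rigid four-segment synthetic gait generator.

The generator is the test bed for the whole package: it moves a rigid foot
template (shank, hindfoot, forefoot, hallux) through prescribed joint-angle
waveforms using forward kinematics, attaches the 17 markers rigidly to their
segments, and optionally adds isotropic Gaussian marker noise.  Because the
joint rotations pivot exactly about the model's own joint centers (AJC, MFJC,
FFC computed on the neutral template), the angles the model measures back from
the noiseless trajectories equal the prescribed waveforms to numerical
precision.

The template is stylized, not subject-specific: marker heights are arranged so
that on the neutral pose the four segment frames are exactly aligned (all nine
rigid-segment angles are zero) while keeping adult-foot proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .geometry import apex_angle, euler_xyz_compose, euler_xyz_decompose, unit
from .kinematics import CARDAN_BASIS
from .model import (
    MRA_PLANTAR_SHIFT_MM,
    SEGMENT_MARKERS,
    MarkerFrame,
    build_model,
    hrc_regression,
    mfjc_regression,
)
from .trial import GaitEvents, MarkerTrajectories

__all__ = [
    "FootTemplate",
    "Sinusoid",
    "Waveform",
    "GaitWaveformConfig",
    "make_template_foot",
    "apply_deformity_preset",
    "generate_trial",
    "DEFAULT_WAVEFORMS",
    "PRESETS",
]

_MIRROR_Y = np.diag([1.0, -1.0, 1.0])


@dataclass(frozen=True)
class FootTemplate:
    """Neutral marker positions (mm, lab frame) plus segment membership."""

    markers: dict[str, np.ndarray]
    side: str
    scale: float = 1.0
    segment_markers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(SEGMENT_MARKERS)
    )

    @property
    def foot_length(self) -> float:
        """Heel-to-hallux marker distance (mm)."""
        return float(np.linalg.norm(self.markers["HLX"] - self.markers["CCL"]))

    def neutral_frame(self) -> MarkerFrame:
        return MarkerFrame(dict(self.markers), side=self.side)

    def with_nav_raised(self, dz_mm: float) -> "FootTemplate":
        """Raise the navicular marker dorsally (higher arch, smaller apex angle)."""
        m = {k: v.copy() for k, v in self.markers.items()}
        m["NAV"] = m["NAV"] + np.array([0.0, 0.0, float(dz_mm)])
        return replace(self, markers=m)

    def neutral_arch_deg(self) -> float:
        m = self.markers
        return apex_angle(m["MCL"], m["NAV"], m["DMT1"])

    def nav_raise_for_arch_drop(self, drop_deg: float) -> float:
        """Navicular raise (mm) that lowers the neutral arch angle by ``drop_deg``."""
        if drop_deg == 0.0:
            return 0.0
        target = self.neutral_arch_deg() - drop_deg
        f = lambda r: self.with_nav_raised(r).neutral_arch_deg() - target
        return float(brentq(f, 0.0, 80.0, xtol=1e-10))


def make_template_foot(side: str = "R", scale: float = 1.0) -> FootTemplate:
    """Deterministic stylized adult foot template.

    The heel/midfoot/forefoot marker heights are solved so that the regressed
    heel rotation center, midfoot joint center and forefoot center are
    collinear along the lab x-axis at neutral (scale 1), which makes the four
    segment frames exactly aligned and every rigid-segment angle zero.
    """
    if not (0.7 <= scale <= 1.3):
        raise ValueError("scale must be within [0.7, 1.3]")
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")

    sole_z = 30.0  # common height of CCL/DMT1/DMT5: a flat reference sole
    ccl = np.array([0.0, 0.0, sole_z])
    # heel marker height solved so the HRC sits 11 mm below CCL (same height
    # as the shifted metatarsal axis): 0.025*z + 1.74*z = -11 in local coords
    zc = sole_z - 11.0 / (0.025 + 1.74)
    mcl = np.array([15.0, 28.0, zc])
    lcl = np.array([15.0, -28.0, zc])
    dmt1 = np.array([150.0, 30.0, sole_z])
    dmt5 = np.array([140.0, -30.0, sole_z])
    pmt1 = np.array([95.0, 35.0, 35.0])
    # a low fifth-metatarsal base buys the navicular enough height that the
    # medial-arch apex sits above the MCL-DMT1 chord (arch monotone in NAV)
    pmt5 = np.array([85.0, -35.0, 8.0])

    # local (foot-frame) coordinates at neutral: x = lab x, y = -lab y
    # (lateral positive for a right foot), z relative to CCL height
    loc = lambda p: np.array([p[0], -p[1], p[2] - ccl[2]])
    lab = lambda q: np.array([q[0], -q[1], q[2] + ccl[2]])

    hrc_l = hrc_regression(loc(ccl), loc(lcl), loc(mcl))
    # navicular height/offset solved so MFJC matches the HRC height and y
    nav_z = ccl[2] + 2.0 * hrc_l[2] - (pmt5[2] - ccl[2])
    nav_yl = (hrc_l[1] - (-0.17 * loc(pmt1)[1] + 0.26 * loc(pmt5)[1])) / 0.52
    nav = lab(np.array([70.0, nav_yl, nav_z - ccl[2]]))

    mfjc = lab(mfjc_regression(loc(nav), loc(pmt1), loc(pmt5)))
    hrc = lab(hrc_l)

    # forefoot center must also lie on that line: choose DMT2 so its
    # projection onto the shifted metatarsal axis lands at y = MFJC_y
    mra_point = dmt1 - np.array([0.0, 0.0, MRA_PLANTAR_SHIFT_MM])
    u = unit(dmt1 - dmt5)
    t_par = (mfjc[1] - mra_point[1]) / u[1]
    ffc = mra_point + t_par * u
    w = unit(np.array([u[1], -u[0], 0.0]))  # horizontal, perpendicular to the axis
    dmt2 = ffc + 12.0 * w + np.array([0.0, 0.0, 13.0])
    hlx = ffc + np.array([60.0, 0.0, 0.0])

    ajc_y = hrc[1]
    mml = np.array([0.0, ajc_y + 40.0, 73.0])
    lml = np.array([0.0, ajc_y - 40.0, 73.0])
    lep = np.array([0.0, ajc_y - 50.0, 473.0])
    mep = np.array([0.0, ajc_y + 50.0, 473.0])
    ttu = np.array([40.0, ajc_y, 430.0])
    sh1 = np.array([10.0, 30.0, 200.0])
    sh2 = np.array([15.0, 32.0, 330.0])

    markers = {
        "LEP": lep, "MEP": mep, "TTU": ttu, "SH1": sh1, "SH2": sh2,
        "LML": lml, "MML": mml,
        "LCL": lcl, "CCL": ccl, "MCL": mcl,
        "NAV": nav, "DMT1": dmt1, "PMT1": pmt1, "DMT2": dmt2,
        "DMT5": dmt5, "PMT5": pmt5, "HLX": hlx,
    }
    markers = {k: scale * v for k, v in markers.items()}
    if side == "L":
        markers = {k: _MIRROR_Y @ v for k, v in markers.items()}
    return FootTemplate(markers=markers, side=side, scale=scale)


@dataclass(frozen=True)
class Sinusoid:
    """One waveform term: amplitude (deg) x sin(2*pi*k*tau + phase)."""

    amplitude: float
    harmonic: int = 1
    phase: float = 0.0


@dataclass(frozen=True)
class Waveform:
    """Offset plus up to three sinusoids of the stride frequency."""

    offset: float = 0.0
    terms: tuple[Sinusoid, ...] = ()

    def __post_init__(self):
        if len(self.terms) > 3:
            raise ValueError("at most three sinusoid terms per waveform")

    def __call__(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.full_like(tau, self.offset, dtype=float)
        for s in self.terms:
            out = out + s.amplitude * np.sin(2.0 * np.pi * s.harmonic * tau + s.phase)
        return out

    @property
    def max_abs(self) -> float:
        return abs(self.offset) + sum(abs(s.amplitude) for s in self.terms)

    def shifted(self, delta: float) -> "Waveform":
        return replace(self, offset=self.offset + delta)


def _wf(offset, *terms):
    return Waveform(offset, tuple(Sinusoid(*t) for t in terms))


#: typical-gait joint waveforms (degrees vs. stride fraction); the ankle
#: sagittal curve has the physiologic loading-response plantarflexion (negative
#: slope right after initial contact), a stance dorsiflexion peak (~13 deg at
#: 38% cycle) and push-off plantarflexion (~-15 deg at 69%)
DEFAULT_WAVEFORMS = {
    "hindfoot_shank_flexion": _wf(
        -1.0012, (-8.021, 1, 2.8374), (8.0788, 2, 2.7512), (-1.0404, 3, 0.2943)
    ),
    "hindfoot_shank_varus": _wf(1.0, (2.0, 1, 0.8), (1.5, 2, 1.9)),
    "hindfoot_shank_rotation": _wf(-3.0, (3.0, 1, 2.2), (1.2, 2, 0.6)),
    "forefoot_hindfoot_flexion": _wf(-4.0, (3.0, 1, 1.2), (2.0, 2, 2.6)),
    "forefoot_hindfoot_supination": _wf(3.0, (2.5, 1, 0.4), (1.5, 2, 2.0)),
    "forefoot_hindfoot_adduction": _wf(2.0, (2.0, 1, 2.9), (1.0, 2, 1.1)),
    "hallux_flexion": _wf(15.0, (12.0, 1, -2.325), (8.0, 2, 1.63)),
    "hallux_abduction": _wf(-12.0, (2.0, 1, 1.0)),
}

#: equinus ankle pattern: plantarflexed throughout with a positive slope at
#: initial contact (forefoot-first contact)
_EV_FLEXION = _wf(-12.0, (5.0, 1, -1.3), (3.0, 2, -0.9), (1.5, 3, 0.5))


@dataclass(frozen=True)
class GaitWaveformConfig:
    """Study conditions for one synthetic trial."""

    waveforms: dict = field(default_factory=lambda: dict(DEFAULT_WAVEFORMS))
    cadence_steps_per_min: float = 110.0
    n_cycles: int = 5
    rate_hz: float = 100.0
    noise_sd_mm: float = 1.0
    seed: int = 0
    preset: str = "TD"
    #: additional neutral-arch lowering (deg) realized as a dorsal NAV raise
    arch_drop_deg: float = 0.0
    stride_length_mm: float = 1200.0

    @property
    def stride_time_s(self) -> float:
        return 120.0 / self.cadence_steps_per_min


#: deformity presets as waveform/arch offsets relative to the TD baseline
PRESETS = {
    "TD": {},
    "CV": {"flexion_offset": 4.0, "varus_offset": 5.0, "arch_drop_deg": 10.0},
    "EV": {"ev_flexion": True, "varus_offset": 7.0, "arch_drop_deg": 18.0},
}


def apply_deformity_preset(cfg: GaitWaveformConfig, preset: str) -> GaitWaveformConfig:
    """Return a config with the named deformity pattern applied to the baseline."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    mods = PRESETS[preset]
    wf = dict(DEFAULT_WAVEFORMS)
    wf.update({k: v for k, v in cfg.waveforms.items() if k not in DEFAULT_WAVEFORMS})
    if mods.get("ev_flexion"):
        wf["hindfoot_shank_flexion"] = _EV_FLEXION
    elif "flexion_offset" in mods:
        wf["hindfoot_shank_flexion"] = wf["hindfoot_shank_flexion"].shifted(
            mods["flexion_offset"]
        )
    if "varus_offset" in mods:
        wf["hindfoot_shank_varus"] = wf["hindfoot_shank_varus"].shifted(
            mods["varus_offset"]
        )
    return replace(
        cfg,
        waveforms=wf,
        preset=preset,
        arch_drop_deg=mods.get("arch_drop_deg", 0.0),
    )


# ---------------------------------------------------------------------------
# global hindfoot motion: foot-flat stance, heel lift and swing repositioning

_PITCH_KNOTS = (  # toe-down-positive segment pitch (deg) vs stride fraction
    (0.00, -8.0), (0.10, 0.0), (0.40, 0.0), (0.65, 22.0), (0.85, 5.0), (1.00, -8.0)
)
_STANCE_BOW_MM = 4.0  # slight heel rise mid-stance so CCL height dips at IC
_SWING_LIFT_MM = 60.0
_SWING_START = 0.60  # stance fraction; toe-off ground truth


def _pitch_deg(frac: np.ndarray) -> np.ndarray:
    k = np.array(_PITCH_KNOTS)
    return PchipInterpolator(k[:, 0], k[:, 1])(frac)


def _heel_lift_mm(frac: np.ndarray) -> np.ndarray:
    """Heel-marker height above neutral; its unique per-cycle minimum is at IC."""
    u = (frac - _SWING_START) / (1.0 - _SWING_START)
    return np.where(
        frac < _SWING_START,
        # monotone rise through stance (no return to baseline before swing)
        _STANCE_BOW_MM * np.sin(0.5 * np.pi * frac / _SWING_START) ** 2,
        # swing: lift bump decaying smoothly back to zero exactly at next IC
        _STANCE_BOW_MM * np.cos(0.5 * np.pi * u) ** 2
        + _SWING_LIFT_MM * np.sin(np.pi * u) ** 2,
    )


def _forward_frac(frac: np.ndarray) -> np.ndarray:
    """Within-cycle forward displacement fraction: 0 in stance, 1 by next IC."""
    out = np.zeros_like(frac)
    sw = frac >= _SWING_START
    out[sw] = 0.5 * (1.0 - np.cos(np.pi * (frac[sw] - _SWING_START) / (1.0 - _SWING_START)))
    return out


def _ry(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def realize_template(template: FootTemplate, cfg: GaitWaveformConfig) -> FootTemplate:
    """The template actually walked: the config's arch drop applied to NAV.

    Use this as the static calibration geometry for preset trials.
    """
    if cfg.arch_drop_deg:
        return template.with_nav_raised(
            template.nav_raise_for_arch_drop(cfg.arch_drop_deg)
        )
    return template


def generate_trial(template: FootTemplate, cfg: GaitWaveformConfig):
    """Forward-kinematic synthetic walking trial.

    Returns ``(trajectories, ground_truth, events)`` where ``ground_truth``
    maps each of the eleven rigid-segment/hallux channels to the prescribed
    (or, for the three shank-referenced forefoot channels, kinematically
    implied) waveform sampled at every trial sample.  Events are exact.
    """
    for name, wf in cfg.waveforms.items():
        if wf.max_abs > 80.0:
            raise ValueError(
                f"waveform {name!r} can exceed 80 deg (gimbal safety): {wf.max_abs:.1f}"
            )
    template = realize_template(template, cfg)

    joints, poses = build_model(template.neutral_frame())
    ajc0, mfjc0, ffc0 = joints.AJC, joints.MFJC, joints.FFC
    ccl0 = template.markers["CCL"]
    hlx_len = float(np.linalg.norm(template.markers["HLX"] - ffc0))
    R0 = poses.hindfoot.rotation  # shared neutral orientation of all frames
    Q = R0 @ CARDAN_BASIS
    mirror = template.side == "L"

    T = cfg.stride_time_s
    fs = cfg.rate_hz
    lead = 0.30  # fraction of a stride padded before the first and after the last IC
    n = int(round((cfg.n_cycles + 2 * lead) * T * fs)) + 1
    t = np.arange(n) / fs
    tau = t / T - lead  # stride coordinate; IC at integers 0..n_cycles
    frac = np.mod(tau, 1.0)
    cyc = np.floor(tau)

    pitch = _pitch_deg(frac)
    lift = _heel_lift_mm(frac)
    fwd = cfg.stride_length_mm * (cyc + _forward_frac(frac))

    def joint_rotation(alpha, beta, gamma):
        # expressed through the template's own neutral frame orientation, so
        # the measured Cardan angles equal the prescription on either side
        E = euler_xyz_compose((alpha, beta, gamma))
        return Q @ E @ Q.T

    wf = cfg.waveforms
    ankle = np.column_stack([
        wf["hindfoot_shank_flexion"](frac),
        wf["hindfoot_shank_varus"](frac),
        wf["hindfoot_shank_rotation"](frac),
    ])
    midfoot = np.column_stack([
        wf["forefoot_hindfoot_flexion"](frac),
        wf["forefoot_hindfoot_supination"](frac),
        wf["forefoot_hindfoot_adduction"](frac),
    ])
    hallux_flex = wf["hallux_flexion"](frac)
    hallux_abd = wf["hallux_abduction"](frac)

    seg_of = {
        lbl: seg for seg, lbls in template.segment_markers.items() for lbl in lbls
    }
    out = {lbl: np.empty((n, 3)) for lbl in template.markers}
    ffs_truth = np.empty((n, 3))

    for i in range(n):
        Rg = _ry(float(pitch[i]))
        tg = np.array([fwd[i], 0.0, lift[i]])

        def hf_pose(p):  # global hindfoot motion pitches about the heel marker
            return Rg @ (p - ccl0) + ccl0 + tg

        A = joint_rotation(*ankle[i])
        M = joint_rotation(*midfoot[i])

        def sh_pose(p):  # shank = hindfoot with the ankle rotation undone at the AJC
            return hf_pose(ajc0 + A.T @ (p - ajc0))

        def ff_pose(p):  # forefoot rotates about the (hindfoot-carried) MFJC
            return hf_pose(mfjc0 + M @ (p - mfjc0))

        # hallux direction whose projected flexion/abduction equal the
        # prescribed values exactly (in forefoot-frame components)
        df = unit(np.array([
            1.0,
            -np.tan(np.radians(hallux_abd[i])),
            -np.tan(np.radians(hallux_flex[i])),
        ]))
        d_template = (-1.0 if mirror else 1.0) * (R0 @ df)

        for lbl, p0 in template.markers.items():
            seg = seg_of[lbl]
            if seg == "shank":
                out[lbl][i] = sh_pose(p0)
            elif seg == "hindfoot":
                out[lbl][i] = hf_pose(p0)
            elif seg == "forefoot":
                out[lbl][i] = ff_pose(p0)
            else:  # hallux
                out[lbl][i] = ff_pose(ffc0 + hlx_len * d_template)

        # shank-referenced forefoot angles are the composition of the two joints
        E_fs = euler_xyz_compose(ankle[i]) @ euler_xyz_compose(midfoot[i])
        ffs_truth[i] = euler_xyz_decompose(E_fs)

    if cfg.noise_sd_mm > 0:
        rng = np.random.default_rng(cfg.seed)
        for lbl in out:
            out[lbl] = out[lbl] + rng.normal(0.0, cfg.noise_sd_mm, size=out[lbl].shape)

    traj = MarkerTrajectories(out, rate=fs, side=template.side)

    ground_truth = {
        "hindfoot_shank_flexion": ankle[:, 0],
        "hindfoot_shank_varus": ankle[:, 1],
        "hindfoot_shank_rotation": ankle[:, 2],
        "forefoot_hindfoot_flexion": midfoot[:, 0],
        "forefoot_hindfoot_supination": midfoot[:, 1],
        "forefoot_hindfoot_adduction": midfoot[:, 2],
        "forefoot_shank_flexion": ffs_truth[:, 0],
        "forefoot_shank_supination": ffs_truth[:, 1],
        "forefoot_shank_adduction": ffs_truth[:, 2],
        "hallux_flexion": hallux_flex,
        "hallux_abduction": hallux_abd,
    }

    ic = np.array([int(round((lead + k) * T * fs)) for k in range(cfg.n_cycles + 1)])
    to = np.array(
        [int(round((lead + k + _SWING_START) * T * fs)) for k in range(cfg.n_cycles)]
    )
    events = GaitEvents(initial_contact=ic, toe_off=to, side=template.side)
    return traj, ground_truth, events
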