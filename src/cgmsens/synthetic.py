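"""Forward generation of CGM-consistent synthetic gait sessions.

The generator inverts the kinematic model: marker positions are placed
on each segment so that the analysis pipeline's own constructions
(Davis hip regression, chord joint centres, wand coronal planes,
heel-toe foot axis) reproduce the generating segment frames exactly.
Driving those segments with known joint-angle curves then yields
trials for which the analyzed kinematics must recover the input curves
up to time-normalization interpolation error - the module's core
guarantee, and the property every downstream stage is tested against.

Cohorts emulate a paediatric gait-lab population: heights stepped
evenly over a wide range (default 1190-1875 mm) with leg length and
joint widths scaled allometrically from height plus a small seeded
jitter. Marker noise, when requested, is i.i.d. isotropic Gaussian per
frame; correlated soft-tissue artefact is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from . import cgm
from .datamodel import (
    N_CYCLE_SAMPLES,
    SIDES,
    Anthropometry,
    AngleCurveSet,
    GaitEvent,
    MarkerTrial,
    side_sign,
)
from .sensitivity import GaitSession

__all__ = [
    "SyntheticSubject",
    "default_angle_curves",
    "build_skeleton",
    "generate_trial",
    "make_cohort",
    "make_session",
]

# allometric ratios (fraction of height); a stated, overridable
# convention for plausible cohorts, not an anthropometric authority
LEG_LENGTH_RATIO = 0.53
KNEE_WIDTH_RATIO = 0.060
ANKLE_WIDTH_RATIO = 0.039
INTER_ASIS_RATIO = 0.145

THIGH_FRACTION = 0.48  # HJC->KJC as fraction of leg length
SHANK_FRACTION = 0.42  # KJC->AJC
ANKLE_HEIGHT_FRACTION = 0.075  # AJC above the sole
FOOT_MARKER_HEIGHT = 25.0  # mm above the sole
WAND_HEIGHT_FRACTION = 0.33  # wand height on the segment (lower third)
THIGH_WAND_LATERAL = 65.0  # mm lateral of the KNE offset
SHANK_WAND_LATERAL = 45.0


@dataclass
class SyntheticSubject:
    """Anthropometry + per-segment local marker placements."""

    anthropometry: Anthropometry
    seed: int
    pelvis_markers: Dict[str, np.ndarray]
    hjc_local: Dict[str, np.ndarray]
    thigh_length: Dict[str, float]
    shank_length: Dict[str, float]
    thigh_markers: Dict[str, Dict[str, np.ndarray]]  # side -> {KNE, THI} in thigh frame
    shank_markers: Dict[str, Dict[str, np.ndarray]]  # side -> {ANK, TIB} in shank frame
    foot_markers: Dict[str, Dict[str, np.ndarray]]  # side -> {TOE, HEE} in foot marker frame
    foot_reference: Dict[str, np.ndarray]  # side -> neutral shank->foot rotation
    pelvis_height: float


def _harmonics(t: np.ndarray, c0: float, terms) -> np.ndarray:
    """Sum of cosine/sine harmonics; periodic by construction."""
    out = np.full_like(t, c0)
    for k, ak, bk in terms:
        out = out + ak * np.cos(2 * np.pi * k * t) + bk * np.sin(2 * np.pi * k * t)
    return out


def default_angle_curves(profile: str = "typical") -> AngleCurveSet:
    """Smooth 101-point curves from a low-order Fourier parameterization.

    ``typical`` approximates the normative sagittal gait shape (hip
    flexed at foot-strike, single dominant knee-flexion peak in swing,
    ankle rocker pattern) with small frontal/transverse excursions;
    ``mild-crouch`` adds constant hip- and knee-flexion offsets. The
    curves stand in for recorded gait: they are not subject data.
    """
    t = np.linspace(0.0, 1.0, N_CYCLE_SAMPLES)
    curves = {
        ("hip", "flexion"): _harmonics(t, 10.0, [(1, 20.0, 0.0)]),
        ("hip", "adduction"): _harmonics(t, 1.0, [(1, 0.0, 4.0)]),
        ("hip", "rotation"): _harmonics(t, 2.0, [(1, 1.5, 2.5)]),
        # double-bump normative knee pattern: stance flexion wave
        # (~18 deg at 15 %), mid-stance extension trough (~5 deg at
        # 40 %), dominant swing peak (~59 deg at 72 %)
        ("knee", "flexion"): _harmonics(
            t, 22.01, [(1, -2.817, -18.573), (2, -13.13, 8.09), (3, -0.039, 3.851)]
        ),
        ("knee", "adduction"): _harmonics(t, 1.0, [(1, 0.0, 1.5)]),
        ("knee", "rotation"): _harmonics(t, -1.0, [(1, 1.0, 2.0)]),
        ("ankle", "flexion"): _harmonics(t, 2.0, [(1, -2.0, 6.0), (2, 0.0, -6.0)]),
        ("ankle", "adduction"): _harmonics(t, 1.0, [(1, 0.0, 2.0)]),
        ("ankle", "rotation"): _harmonics(t, -2.0, [(1, 0.0, 2.0)]),
    }
    if profile == "typical":
        pass
    elif profile == "mild-crouch":
        curves[("hip", "flexion")] = curves[("hip", "flexion")] + 12.0
        curves[("knee", "flexion")] = curves[("knee", "flexion")] + 15.0
    else:
        raise ValueError(f"unknown gait profile {profile!r}")
    full = {}
    for side in SIDES:
        for (joint, plane), curve in curves.items():
            full[(joint, plane, side)] = curve.copy()
    return AngleCurveSet(curves=full)


def build_skeleton(anthro: Anthropometry, seed: int = 0) -> SyntheticSubject:
    """Local marker placements that invert the CGM constructions.

    ASIS/PSIS realize the inter-ASIS distance; KNE/ANK sit exactly one
    chord offset lateral of the nominal joint centres, perpendicular
    to the segment axis; wands are placed in the segment coronal
    planes (lower third, lateral) with seeded jitter constrained to
    stay *within* the plane; foot markers give a horizontal heel-toe
    axis in the neutral flat-foot pose.
    """
    if anthro.inter_asis_distance is None:
        anthro = anthro.with_inter_asis(INTER_ASIS_RATIO * anthro.height)
    rng = np.random.default_rng(seed)
    iad = anthro.inter_asis_distance
    aa = iad / 2.0

    pelvis_markers = {
        "LASI": np.array([0.0, aa, 0.0]),
        "RASI": np.array([0.0, -aa, 0.0]),
        "LPSI": np.array([-0.50 * iad, 0.17 * iad, 0.0]),
        "RPSI": np.array([-0.50 * iad, -0.17 * iad, 0.0]),
    }

    hjc_local, thigh_length, shank_length = {}, {}, {}
    thigh_markers, shank_markers, foot_markers, foot_reference = {}, {}, {}, {}
    for side in SIDES:
        s = side_sign(side)
        ll = anthro.leg_length[side]
        if anthro.knee_offset >= SHANK_FRACTION * ll or anthro.ankle_offset >= SHANK_FRACTION * ll:
            raise ValueError("infeasible anthropometry: chord offsets exceed segment lengths")
        hjc_local[side] = cgm.davis_hip_offset(ll, iad, anthro.marker_radius, side)
        thigh_length[side] = THIGH_FRACTION * ll
        shank_length[side] = SHANK_FRACTION * ll

        jit = rng.uniform(-8.0, 8.0, size=4)
        thigh_markers[side] = {
            "KNE": np.array([0.0, s * anthro.knee_offset, 0.0]),
            # wand: lateral stick on the lower third; jitter stays in
            # the coronal (x = 0) plane by touching only y and z
            "THI": np.array(
                [
                    0.0,
                    s * (anthro.knee_offset + THIGH_WAND_LATERAL) + jit[0],
                    WAND_HEIGHT_FRACTION * thigh_length[side] + jit[1],
                ]
            ),
        }
        shank_markers[side] = {
            "ANK": np.array([0.0, s * anthro.ankle_offset, 0.0]),
            "TIB": np.array(
                [
                    0.0,
                    s * (anthro.ankle_offset + SHANK_WAND_LATERAL) + jit[2],
                    WAND_HEIGHT_FRACTION * shank_length[side] + jit[3],
                ]
            ),
        }

        ankle_height = ANKLE_HEIGHT_FRACTION * ll
        drop = -(ankle_height - FOOT_MARKER_HEIGHT)
        toe_rel = np.array([0.16 * ll, 0.0, drop])  # forefoot, relative to AJC
        hee_rel = np.array([-0.05 * ll, 0.0, drop])
        neutral_foot = cgm.foot_frame(np.zeros(3), toe_rel, hee_rel)
        a0 = neutral_foot.axes  # shank frame is identity in neutral
        foot_reference[side] = a0
        foot_markers[side] = {"TOE": a0.T @ toe_rel, "HEE": a0.T @ hee_rel}

    left_ll = anthro.leg_length["left"]
    pelvis_height = (
        ANKLE_HEIGHT_FRACTION * left_ll
        + shank_length["left"]
        + thigh_length["left"]
        - hjc_local["left"][2]
    )
    return SyntheticSubject(
        anthropometry=anthro,
        seed=seed,
        pelvis_markers=pelvis_markers,
        hjc_local=hjc_local,
        thigh_length=thigh_length,
        shank_length=shank_length,
        thigh_markers=thigh_markers,
        shank_markers=shank_markers,
        foot_markers=foot_markers,
        foot_reference=foot_reference,
        pelvis_height=pelvis_height,
    )


def _sample_curves(curves: AngleCurveSet, side: str, phase: np.ndarray) -> Dict[Tuple[str, str], np.ndarray]:
    """Angle values at fractional cycle phases (linear interpolation)."""
    grid = np.arange(N_CYCLE_SAMPLES, dtype=float)
    out = {}
    for joint in ("hip", "knee", "ankle"):
        for plane in ("flexion", "adduction", "rotation"):
            curve = curves[(joint, plane, side)]
            out[(joint, plane)] = np.interp(100.0 * phase, grid, curve)
    return out


def _pose_markers(
    subject: SyntheticSubject,
    pelvis_origin: np.ndarray,
    angles: Dict[str, Dict[Tuple[str, str], np.ndarray]],
) -> Dict[str, np.ndarray]:
    """Forward kinematics: joint angles -> lab-frame marker positions."""
    n = pelvis_origin.shape[0]
    markers: Dict[str, np.ndarray] = {}
    for label, local in subject.pelvis_markers.items():
        markers[label] = pelvis_origin + local  # pelvis orientation fixed to lab

    for side in SIDES:
        p = "L" if side == "left" else "R"
        ang = angles[side]
        r_thigh = cgm.clinical_to_matrix(
            ang[("hip", "flexion")], ang[("hip", "adduction")], ang[("hip", "rotation")], "hip", side
        )
        r_shank = r_thigh @ cgm.clinical_to_matrix(
            ang[("knee", "flexion")], ang[("knee", "adduction")], ang[("knee", "rotation")], "knee", side
        )
        r_foot = (
            r_shank
            @ cgm.clinical_to_matrix(
                ang[("ankle", "flexion")], ang[("ankle", "adduction")], ang[("ankle", "rotation")], "ankle", side
            )
            @ subject.foot_reference[side]
        )

        hjc = pelvis_origin + subject.hjc_local[side]
        kjc = hjc - r_thigh @ np.array([0.0, 0.0, subject.thigh_length[side]])
        ajc = kjc - r_shank @ np.array([0.0, 0.0, subject.shank_length[side]])
        for label, local in subject.thigh_markers[side].items():
            markers[p + label] = kjc + np.einsum("...ij,j->...i", r_thigh, local)
        for label, local in subject.shank_markers[side].items():
            markers[p + label] = ajc + np.einsum("...ij,j->...i", r_shank, local)
        for label, local in subject.foot_markers[side].items():
            markers[p + label] = ajc + np.einsum("...ij,j->...i", r_foot, local)
    return {k: np.atleast_2d(v) if v.ndim == 1 else v for k, v in markers.items()}


def generate_trial(
    subject: SyntheticSubject,
    curves: AngleCurveSet,
    n_cycles: int = 3,
    cadence: float = 120.0,
    fs: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    static_pose: Mapping[str, Tuple[float, float, float]] | None = None,
    n_static_frames: int = 50,
) -> Tuple[MarkerTrial, MarkerTrial]:
    """Forward-generate one static and one gait trial.

    The pelvis advances along lab +X at the speed implied by cadence
    (steps/min; one stride = two steps) and a height-scaled stride
    length; right-side curves run half a cycle out of phase; exact
    foot-strike frames are recorded as events. ``static_pose``
    optionally sets per-joint (flexion, adduction, rotation) degrees
    for the standing pose (default: neutral zeros, both sides).
    ``noise_sd`` adds isotropic Gaussian marker noise in mm.
    """
    if n_cycles < 1:
        raise ValueError("need at least one gait cycle")
    if fs <= 0 or cadence <= 0:
        raise ValueError("sampling rate and cadence must be positive")
    rng = np.random.default_rng(subject.seed + 1 if seed is None else seed)

    # static trial -----------------------------------------------------
    static_pose = dict(static_pose or {})
    zeros = np.zeros(n_static_frames)
    static_angles = {
        side: {
            (joint, plane): zeros + float(np.asarray(static_pose.get(joint, (0.0, 0.0, 0.0)))[i])
            for joint in ("hip", "knee", "ankle")
            for i, plane in enumerate(("flexion", "adduction", "rotation"))
        }
        for side in SIDES
    }
    static_origin = np.tile([0.0, 0.0, subject.pelvis_height], (n_static_frames, 1))
    static_markers = _pose_markers(subject, static_origin, static_angles)
    static = MarkerTrial(markers=static_markers, sampling_rate=fs, kind="static")

    # gait trial -------------------------------------------------------
    stride_time = 120.0 / cadence  # s (two steps per stride)
    fpc = int(round(fs * stride_time))  # frames per cycle
    n_frames = n_cycles * fpc + 1
    i = np.arange(n_frames)
    phase_left = (i % fpc) / fpc
    right_strike = int(round(fpc / 2))
    phase_right = ((i - right_strike) % fpc) / fpc

    gait_angles = {
        "left": _sample_curves(curves, "left", phase_left),
        "right": _sample_curves(curves, "right", phase_right),
    }
    stride_length = 0.75 * subject.anthropometry.height
    x = stride_length * i / fpc
    origin = np.stack([x, np.zeros(n_frames), np.full(n_frames, subject.pelvis_height)], axis=-1)
    gait_markers = _pose_markers(subject, origin, gait_angles)

    events: List[GaitEvent] = []
    for k in range(n_cycles + 1):
        events.append(GaitEvent(frame=k * fpc, side="left"))
    f = right_strike
    while f < n_frames:
        events.append(GaitEvent(frame=f, side="right"))
        f += fpc
    gait = MarkerTrial(markers=gait_markers, sampling_rate=fs, kind="gait", events=events)

    if noise_sd > 0:
        for trial in (static, gait):
            for label in trial.markers:
                trial.markers[label] = trial.markers[label] + rng.normal(
                    0.0, noise_sd, trial.markers[label].shape
                )
    return static, gait


def make_cohort(
    n: int, height_range: Tuple[float, float] = (1190.0, 1875.0), seed: int = 0
) -> List[SyntheticSubject]:
    """Subjects with heights evenly stepped across ``height_range`` (mm).

    Leg length and joint widths scale allometrically from height with
    +-2 % seeded jitter; the even stepping mirrors a cohort designed
    to cover a wide stature range.
    """
    if n < 2:
        raise ValueError("a cohort needs at least two subjects")
    rng = np.random.default_rng(seed)
    heights = np.linspace(height_range[0], height_range[1], n)
    subjects = []
    for h in heights:
        e = rng.uniform(-0.02, 0.02, size=4)
        anthro = Anthropometry(
            leg_length=LEG_LENGTH_RATIO * h * (1 + e[0]),
            knee_width=KNEE_WIDTH_RATIO * h * (1 + e[1]),
            ankle_width=ANKLE_WIDTH_RATIO * h * (1 + e[2]),
            height=h,
            mass=16.0 * (h / 1000.0) ** 2,
            inter_asis_distance=INTER_ASIS_RATIO * h * (1 + e[3]),
        )
        subjects.append(build_skeleton(anthro, seed=int(rng.integers(0, 2**31 - 1))))
    return subjects


def make_session(
    subject: SyntheticSubject,
    profile: str = "typical",
    n_cycles: int = 3,
    cadence: float = 120.0,
    fs: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> GaitSession:
    """Convenience: curves + trials -> ready-to-analyze session."""
    curves = default_angle_curves(profile)
    static, gait = generate_trial(
        subject, curves, n_cycles=n_cycles, cadence=cadence, fs=fs, noise_sd=noise_sd, seed=seed
    )
    return GaitSession(static=static, gait=gait, anthropometry=subject.anthropometry)
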