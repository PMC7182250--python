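"""Conventional Gait Model (Plug-in-Gait style) lower-limb kinematics.

The model is a hierarchical top-down chain: the pelvis frame is built
from the four ASIS/PSIS markers; hip joint centres follow from the
Davis/Newington regression; knee and ankle joint centres are placed by
the chord construction using the lateral epicondyle (KNE) and lateral
malleolus (ANK) markers together with the thigh/shank wand markers;
joint angles are mobile Y-X-Z Cardan decompositions of the relative
segment rotations, sign-mapped per side so that flexion, adduction and
internal rotation are positive on both sides.

Because the KNE marker defines both the knee joint centre and the
thigh coronal plane, and the knee centre feeds the shank construction,
a KNE misplacement propagates to hip, knee *and* ankle angles - the
error-propagation mechanism this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .datamodel import (
    N_CYCLE_SAMPLES,
    JOINTS,
    PLANES,
    SIDES,
    Anthropometry,
    AngleCurveSet,
    MarkerTrial,
    SegmentFrame,
    side_sign,
    validate_trial,
)
from .geometry import GeometryError, chord, compose_cardan_yxz, decompose_cardan_yxz, rot_y, unit

__all__ = [
    "DAVIS_THETA",
    "DAVIS_BETA",
    "Calibration",
    "pelvis_frame",
    "hip_joint_centre",
    "thigh_frame",
    "shank_frame",
    "foot_frame",
    "cardan_angles",
    "clinical_to_matrix",
    "matrix_to_clinical",
    "static_calibration",
    "segment_frames",
    "thigh_frames",
    "time_normalize",
    "extract_cycles",
    "compute_kinematics",
    "FOOT_NEUTRAL",
]

# Davis/Newington hip-regression constants (mm, radians)
DAVIS_THETA = 0.5
DAVIS_BETA = 0.314

# Neutral shank->foot rotation: the heel-toe long axis of a flat foot
# points horizontally backwards, i.e. the foot frame is the shank frame
# rotated by -90 deg about Y. Static offsets are measured relative to
# this reference, so a neutral flat foot calibrates to zero offsets.
FOOT_NEUTRAL = rot_y(-np.pi / 2)


# --------------------------------------------------------------------------
# segment frames
# --------------------------------------------------------------------------

def _frame_from_zy(z_dir: np.ndarray, y_dir: np.ndarray, origin: np.ndarray) -> SegmentFrame:
    """Right-handed frame with exact Z, Y orthogonalized against Z."""
    z = unit(z_dir, name="longitudinal axis")
    y = y_dir - np.sum(y_dir * z, axis=-1, keepdims=True) * z
    y = unit(y, name="medial-lateral axis")
    x = np.cross(y, z)
    return SegmentFrame(origin=origin, axes=np.stack([x, y, z], axis=-1))


def pelvis_frame(trial: MarkerTrial, frame: int | None = None) -> SegmentFrame:
    """Pelvis frame from LASI/RASI and the mid-PSIS point.

    Origin is the ASIS midpoint; Y runs from RASI to LASI; X is the
    anterior direction orthogonal to Y inside the plane containing the
    mid-PSIS; Z completes the right-handed frame.
    """
    try:
        lasi, rasi = trial.markers["LASI"], trial.markers["RASI"]
        lpsi, rpsi = trial.markers["LPSI"], trial.markers["RPSI"]
    except KeyError as exc:  # pragma: no cover - defensive
        raise GeometryError(f"pelvis marker missing: {exc}") from exc
    if frame is not None:
        lasi, rasi, lpsi, rpsi = (m[frame] for m in (lasi, rasi, lpsi, rpsi))
    origin = 0.5 * (lasi + rasi)
    sacrum = 0.5 * (lpsi + rpsi)
    y = unit(lasi - rasi, name="inter-ASIS axis")
    v = origin - sacrum
    x = v - np.sum(v * y, axis=-1, keepdims=True) * y
    x = unit(x, name="pelvis anterior axis")
    z = np.cross(x, y)
    return SegmentFrame(origin=origin, axes=np.stack([x, y, z], axis=-1))


def davis_hip_offset(leg_length: float, inter_asis: float, marker_radius: float, side: str) -> np.ndarray:
    """Hip joint centre in pelvis coordinates (Davis/Newington regression)."""
    if leg_length <= 0:
        raise ValueError("leg length must be positive")
    if inter_asis is None or inter_asis <= 0:
        raise ValueError("inter-ASIS distance required for the hip regression")
    c = 0.115 * leg_length - 15.3
    aa = inter_asis / 2.0
    d_at = 0.1288 * leg_length - 48.56  # ASIS to greater trochanter
    x = c * np.cos(DAVIS_THETA) * np.sin(DAVIS_BETA) - (d_at + marker_radius) * np.cos(DAVIS_BETA)
    y = side_sign(side) * (aa - c * np.sin(DAVIS_THETA))
    z = -c * np.cos(DAVIS_THETA) * np.cos(DAVIS_BETA) - (d_at + marker_radius) * np.sin(DAVIS_BETA)
    return np.array([x, y, z])


def hip_joint_centre(pelvis: SegmentFrame, anthro: Anthropometry, side: str) -> np.ndarray:
    """HJC in lab coordinates, one row per pelvis frame."""
    local = davis_hip_offset(
        anthro.leg_length[side], anthro.inter_asis_distance, anthro.marker_radius, side
    )
    return pelvis.origin + np.einsum("...ij,j->...i", pelvis.axes, local)


def thigh_frame(
    hjc: np.ndarray,
    kne: np.ndarray,
    wand: np.ndarray,
    knee_offset: float,
    side: str,
) -> Tuple[SegmentFrame, np.ndarray]:
    """Thigh frame + knee joint centre.

    KJC = chord(knee_offset, KNE, HJC, wand). Z points from KJC to the
    HJC; Y is the medial-lateral direction within the coronal plane
    spanned by HJC, KNE and the wand (pointing left on both sides);
    X = Y x Z is anterior. The wand marker enters only through plane
    membership: moving it within the coronal plane changes nothing.
    """
    kjc = chord(knee_offset, np.asarray(kne, float), np.asarray(hjc, float), np.asarray(wand, float))
    z = np.asarray(hjc, float) - kjc
    y = side_sign(side) * (np.asarray(kne, float) - kjc)
    return _frame_from_zy(z, y, kjc), kjc


def shank_frame(
    kjc: np.ndarray,
    ank: np.ndarray,
    tib_wand: np.ndarray,
    ankle_offset: float,
    side: str,
) -> Tuple[SegmentFrame, np.ndarray]:
    """Shank frame + ankle joint centre (chord analogue of the thigh)."""
    ajc = chord(ankle_offset, np.asarray(ank, float), np.asarray(kjc, float), np.asarray(tib_wand, float))
    z = np.asarray(kjc, float) - ajc
    y = side_sign(side) * (np.asarray(ank, float) - ajc)
    return _frame_from_zy(z, y, ajc), ajc


def foot_frame(ajc: np.ndarray, toe: np.ndarray, hee: np.ndarray) -> SegmentFrame:
    """Foot frame: heel-toe longitudinal axis, plane fixed by the AJC.

    Z runs from TOE towards HEE ("proximal" end of the foot segment is
    the hindfoot), so a flat foot has a horizontal longitudinal axis;
    Y is the normal of the AJC/TOE/HEE plane pointing left; the origin
    is the ankle joint centre. Dorsiflexion is referenced to this axis
    + 90 deg through :data:`FOOT_NEUTRAL` and the static offsets.
    """
    ajc = np.asarray(ajc, float)
    toe = np.asarray(toe, float)
    hee = np.asarray(hee, float)
    z = unit(hee - toe, name="foot longitudinal axis")
    y_dir = np.cross(hee - toe, ajc - toe)
    y = unit(y_dir, name="foot medial-lateral axis")
    x = np.cross(y, z)
    return SegmentFrame(origin=ajc, axes=np.stack([x, y, z], axis=-1))


# --------------------------------------------------------------------------
# clinical angle conventions
# --------------------------------------------------------------------------

def _flexion_sign(joint: str) -> float:
    # Knee flexion is the anatomical reverse of hip flexion / ankle
    # dorsiflexion: the distal segment swings posteriorly.
    return 1.0 if joint == "knee" else -1.0


def cardan_angles(R_rel: np.ndarray, joint: str, side: str) -> np.ndarray:
    """Clinical (flexion, adduction, internal-rotation) in degrees.

    ``R_rel`` expresses the distal frame in proximal coordinates
    (``R_prox.T @ R_dist``) with both frames in the Y-left convention;
    the mobile Y-X-Z sequence is sign-mapped per side so flexion,
    adduction and internal rotation are positive for either limb.
    Output shape ``(..., 3)``.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    s = side_sign(side)
    a, b, c = decompose_cardan_yxz(R_rel)
    flex = _flexion_sign(joint) * a
    add = s * b
    rot = -s * c
    return np.degrees(np.stack([flex, add, rot], axis=-1))


def clinical_to_matrix(flex_deg, add_deg, rot_deg, joint: str, side: str) -> np.ndarray:
    """Inverse of :func:`cardan_angles`: clinical angles -> rotation."""
    s = side_sign(side)
    a = _flexion_sign(joint) * np.radians(flex_deg)
    b = s * np.radians(add_deg)
    c = -s * np.radians(rot_deg)
    return compose_cardan_yxz(a, b, c)


def matrix_to_clinical(R: np.ndarray, joint: str, side: str) -> np.ndarray:
    return cardan_angles(R, joint, side)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclass
class Calibration:
    """Per-session constants derived from the static trial.

    ``foot_reference`` holds, per side, the mean static shank->foot
    marker-frame rotation; dynamic ankle angles are measured relative
    to it, which subtracts the static plantarflexion / foot-rotation
    offsets exactly (as a rotation composition rather than an angle
    subtraction). The offsets are also reported in degrees relative to
    the flat-foot neutral for inspection.
    """

    knee_offset: float
    ankle_offset: float
    inter_asis_distance: float
    foot_reference: Dict[str, np.ndarray] = field(default_factory=dict)
    foot_offsets_deg: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.knee_offset > 0 or not self.ankle_offset > 0:
            raise ValueError("chord offsets must be positive")


def _mean_marker(trial: MarkerTrial, label: str) -> np.ndarray:
    return trial.markers[label].mean(axis=0)


def static_calibration(static: MarkerTrial, anthro: Anthropometry, sides=SIDES) -> Calibration:
    """Compute session constants from the mean static pose."""
    for side in sides:
        report = validate_trial(static, side)
        if not report.passed:
            raise ValueError(f"invalid static trial ({side}): {report.issues}")

    mean_trial = MarkerTrial(
        markers={k: v.mean(axis=0, keepdims=True) for k, v in static.markers.items()},
        sampling_rate=static.sampling_rate,
        kind="static",
    )
    pelvis = pelvis_frame(mean_trial)
    inter_asis = anthro.inter_asis_distance
    if inter_asis is None:
        inter_asis = float(
            np.linalg.norm(_mean_marker(static, "LASI") - _mean_marker(static, "RASI"))
        )
    anthro_eff = anthro.with_inter_asis(inter_asis)

    calib = Calibration(
        knee_offset=anthro.knee_offset,
        ankle_offset=anthro.ankle_offset,
        inter_asis_distance=inter_asis,
    )
    prefix = {"left": "L", "right": "R"}
    for side in sides:
        p = prefix[side]
        hjc = hip_joint_centre(pelvis, anthro_eff, side)
        thigh, kjc = thigh_frame(
            hjc, mean_trial.markers[p + "KNE"], mean_trial.markers[p + "THI"], calib.knee_offset, side
        )
        shank, ajc = shank_frame(
            kjc, mean_trial.markers[p + "ANK"], mean_trial.markers[p + "TIB"], calib.ankle_offset, side
        )
        foot = foot_frame(ajc, mean_trial.markers[p + "TOE"], mean_trial.markers[p + "HEE"])
        a0 = np.swapaxes(shank.axes, -1, -2) @ foot.axes  # shank -> foot marker frame
        a0 = a0[0]
        calib.foot_reference[side] = a0
        # offsets relative to the flat-foot neutral, for reporting
        off = FOOT_NEUTRAL.T @ a0
        a, b, c = decompose_cardan_yxz(off)
        calib.foot_offsets_deg[side] = {
            "plantarflexion": float(np.degrees(a)),
            "rotation": float(np.degrees(-side_sign(side) * c)),
        }
    return calib


# --------------------------------------------------------------------------
# kinematics pipeline
# --------------------------------------------------------------------------

def segment_frames(
    trial: MarkerTrial, anthro: Anthropometry, side: str, calib: Calibration | None = None
) -> Dict[str, SegmentFrame]:
    """All segment frames of one side for every frame of a trial."""
    knee_offset = calib.knee_offset if calib else anthro.knee_offset
    ankle_offset = calib.ankle_offset if calib else anthro.ankle_offset
    inter_asis = calib.inter_asis_distance if calib else anthro.inter_asis_distance
    if inter_asis is None:
        inter_asis = float(
            np.linalg.norm((trial.markers["LASI"] - trial.markers["RASI"]), axis=-1).mean()
        )
    anthro_eff = anthro.with_inter_asis(inter_asis)

    p = "L" if side == "left" else "R"
    pelvis = pelvis_frame(trial)
    hjc = hip_joint_centre(pelvis, anthro_eff, side)
    thigh, kjc = thigh_frame(hjc, trial.markers[p + "KNE"], trial.markers[p + "THI"], knee_offset, side)
    shank, ajc = shank_frame(kjc, trial.markers[p + "ANK"], trial.markers[p + "TIB"], ankle_offset, side)
    foot = foot_frame(ajc, trial.markers[p + "TOE"], trial.markers[p + "HEE"])
    return {"pelvis": pelvis, "thigh": thigh, "shank": shank, "foot": foot}


def thigh_frames(trial: MarkerTrial, anthro: Anthropometry, side: str) -> SegmentFrame:
    """Per-frame thigh frames of the *unperturbed* trial.

    This is the reference context the misplacement simulator displaces
    the KNE marker in: anatomical AP/PD axes travelling with the thigh.
    """
    return segment_frames(trial, anthro, side)["thigh"]


def joint_angle_series(
    trial: MarkerTrial, calib: Calibration, anthro: Anthropometry, side: str
) -> Dict[Tuple[str, str], np.ndarray]:
    """Per-frame clinical angles for the 9 lower-limb curves of a side."""
    frames = segment_frames(trial, anthro, side, calib)
    rel = {}
    pelvisT = np.swapaxes(frames["pelvis"].axes, -1, -2)
    thighT = np.swapaxes(frames["thigh"].axes, -1, -2)
    shankT = np.swapaxes(frames["shank"].axes, -1, -2)
    rel["hip"] = pelvisT @ frames["thigh"].axes
    rel["knee"] = thighT @ frames["shank"].axes
    a0 = calib.foot_reference[side]
    rel["ankle"] = (shankT @ frames["foot"].axes) @ a0.T

    out: Dict[Tuple[str, str], np.ndarray] = {}
    for joint in JOINTS:
        angles = cardan_angles(rel[joint], joint, side)
        for i, plane in enumerate(PLANES):
            out[(joint, plane)] = angles[..., i]
    return out


def time_normalize(samples: np.ndarray, cycle: Tuple[int, int]) -> np.ndarray:
    """Linear interpolation of a per-frame series onto 0-100 % at 1 % steps."""
    start, end = cycle
    samples = np.asarray(samples, dtype=float)
    if not 0 <= start < end <= samples.shape[0] - 1:
        raise ValueError(f"cycle {cycle} outside trial of {samples.shape[0]} frames")
    if end <= start + 1:
        raise ValueError("cycle must span more than one frame")
    t = np.linspace(start, end, N_CYCLE_SAMPLES)
    return np.interp(t, np.arange(samples.shape[0]), samples)


def extract_cycles(trial: MarkerTrial, side: str) -> list[Tuple[int, int]]:
    """Full gait cycles = consecutive same-side foot-strikes."""
    strikes = trial.foot_strikes(side)
    return [(strikes[i], strikes[i + 1]) for i in range(len(strikes) - 1)]


def compute_kinematics(
    trial: MarkerTrial, calib: Calibration, anthro: Anthropometry, side: str
) -> AngleCurveSet:
    """Full CGM pipeline for one side of a gait trial.

    Per-frame segment frames -> relative rotations -> Cardan angles ->
    per-cycle time normalization -> pointwise average across cycles.
    The returned set carries the per-cycle curves as well.
    """
    report = validate_trial(trial, side)
    if not report.passed:
        raise ValueError(f"invalid gait trial ({side}): {report.issues}")
    cycles = extract_cycles(trial, side)
    if not cycles:
        raise ValueError("no complete gait cycle in trial")

    series = joint_angle_series(trial, calib, anthro, side)
    curves, per_cycle = {}, {}
    for (joint, plane), values in series.items():
        stacked = np.stack([time_normalize(values, cyc) for cyc in cycles])
        per_cycle[(joint, plane, side)] = stacked
        curves[(joint, plane, side)] = stacked.mean(axis=0)
    return AngleCurveSet(curves=curves, per_cycle=per_cycle)
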