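"""Domain types shared by every stage of the pipeline.

The pipeline works in a fixed lab convention for synthetic data:
Z vertical (up), the subject walks along +X, Y = Z x X points to the
subject's left. Positions are millimetres, angles degrees, rates Hz.
Real recordings in other axis conventions are remapped on read
(see :mod:`cgmsens.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "SIDES",
    "JOINTS",
    "PLANES",
    "PELVIS_MARKERS",
    "FOOT_STRIKE",
    "Anthropometry",
    "GaitEvent",
    "MarkerTrial",
    "SegmentFrame",
    "AngleCurveSet",
    "PerturbationSpec",
    "SensitivityRecord",
    "SensitivityTable",
    "ValidationReport",
    "side_sign",
    "side_markers",
    "required_markers",
    "validate_trial",
]

SIDES = ("left", "right")
JOINTS = ("hip", "knee", "ankle")
PLANES = ("flexion", "adduction", "rotation")
PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")
SEGMENT_MARKER_SUFFIXES = ("THI", "KNE", "TIB", "ANK", "HEE", "TOE")
FOOT_STRIKE = "foot-strike"

N_CYCLE_SAMPLES = 101  # 0-100 % of the gait cycle at 1 % steps


def side_sign(side: str) -> int:
    """+1 for the left side, -1 for the right (lab Y points left)."""
    if side == "left":
        return 1
    if side == "right":
        return -1
    raise ValueError(f"unknown side {side!r}")


def side_markers(side: str) -> Tuple[str, ...]:
    prefix = "L" if side == "left" else "R"
    side_sign(side)  # validate
    return tuple(prefix + s for s in SEGMENT_MARKER_SUFFIXES)


def required_markers(side: str) -> Tuple[str, ...]:
    return PELVIS_MARKERS + side_markers(side)


@dataclass
class Anthropometry:
    """Subject measurements parameterizing joint-centre regressions.

    ``leg_length`` may be a single number (symmetric subject) or a
    per-side mapping; it is stored per side. ``inter_asis_distance``
    may be left ``None`` and measured from the static trial instead.
    """

    leg_length: Mapping[str, float] | float
    knee_width: float
    ankle_width: float
    height: float
    mass: float
    inter_asis_distance: float | None = None
    marker_diameter: float = 12.5

    def __post_init__(self) -> None:
        if isinstance(self.leg_length, (int, float)):
            self.leg_length = {s: float(self.leg_length) for s in SIDES}
        else:
            self.leg_length = {s: float(self.leg_length[s]) for s in SIDES}
        for side, ll in self.leg_length.items():
            if not ll > 0:
                raise ValueError(f"{side} leg length must be positive")
        for name in ("knee_width", "ankle_width", "height", "mass", "marker_diameter"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_asis_distance is not None and not self.inter_asis_distance > 0:
            raise ValueError("inter_asis_distance must be positive")
        if any(self.knee_width >= ll for ll in self.leg_length.values()):
            raise ValueError("knee width must be smaller than leg length")
        if not 5.0 <= self.marker_diameter <= 30.0:
            raise ValueError("marker diameter outside the plausible 5-30 mm range")

    @property
    def marker_radius(self) -> float:
        return self.marker_diameter / 2.0

    @property
    def knee_offset(self) -> float:
        """Chord offset knee marker -> knee joint centre, mm."""
        return (self.knee_width + self.marker_diameter) / 2.0

    @property
    def ankle_offset(self) -> float:
        return (self.ankle_width + self.marker_diameter) / 2.0

    def with_inter_asis(self, value: float) -> "Anthropometry":
        return replace(self, inter_asis_distance=float(value))


@dataclass(frozen=True)
class GaitEvent:
    frame: int
    side: str
    kind: str = FOOT_STRIKE


@dataclass
class MarkerTrial:
    """Labelled 3-D marker trajectories of one capture.

    ``markers`` maps CGM labels to ``(n_frames, 3)`` arrays in mm,
    lab frame. ``kind`` is ``"static"`` (calibration standing trial)
    or ``"gait"``.
    """

    markers: Dict[str, np.ndarray]
    sampling_rate: float = 100.0
    kind: str = "gait"
    events: List[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("static", "gait"):
            raise ValueError("trial kind must be 'static' or 'gait'")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        coerced = {}
        for label, xyz in self.markers.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {label}: expected (n_frames, 3) array")
            coerced[label] = arr
        self.markers = coerced

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    def foot_strikes(self, side: str) -> List[int]:
        return sorted(e.frame for e in self.events if e.side == side and e.kind == FOOT_STRIKE)

    def copy(self) -> "MarkerTrial":
        return MarkerTrial(
            markers={k: v.copy() for k, v in self.markers.items()},
            sampling_rate=self.sampling_rate,
            kind=self.kind,
            events=list(self.events),
        )


@dataclass
class SegmentFrame:
    """Origin + right-handed orthonormal axes of a body segment.

    ``axes`` columns are X (anterior), Y (medial-lateral, pointing to
    the subject's left) and Z (longitudinal, pointing proximal). Both
    fields broadcast over a leading frame axis, so one instance holds
    the pose time series of a segment across a whole trial.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape[-2:] != (3, 3):
            raise ValueError("axes must be (..., 3, 3)")
        eye = np.eye(3)
        gram = self.axes @ np.swapaxes(self.axes, -1, -2)
        if not np.allclose(gram, eye, atol=1e-9):
            raise ValueError("segment axes are not orthonormal to 1e-9")
        if not np.allclose(np.linalg.det(self.axes), 1.0, atol=1e-9):
            raise ValueError("segment axes must be right-handed (det = +1)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[..., :, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[..., :, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[..., :, 2]

    def __getitem__(self, idx) -> "SegmentFrame":
        return SegmentFrame(origin=self.origin[idx], axes=self.axes[idx])


@dataclass(frozen=True)
class PerturbationSpec:
    """One virtual misplacement: magnitude eps (mm) at direction theta.

    theta convention: 0 deg = anterior, 90 = proximal, 180 = posterior,
    270 = distal, within the thigh's AP-PD plane.
    """

    magnitude: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 50.0:
            raise ValueError("perturbation magnitude must be in [0, 50] mm")
        if not 0.0 <= self.theta_deg < 360.0:
            raise ValueError("theta must be in [0, 360) degrees")

    @property
    def direction_label(self) -> str:
        labels = {0.0: "anterior", 90.0: "proximal", 180.0: "posterior", 270.0: "distal"}
        return labels.get(float(self.theta_deg) % 360.0, f"theta-{self.theta_deg:g}")


CurveKey = Tuple[str, str, str]  # (joint, plane, side)


@dataclass
class AngleCurveSet:
    """Time-normalized joint-angle curves, 101 samples over 0-100 % GC.

    ``curves`` maps ``(joint, plane, side)`` to a 101-sample array in
    degrees. ``per_cycle`` optionally carries the individual-cycle
    curves (``(n_cycles, 101)``) the means were taken from.
    """

    curves: Dict[CurveKey, np.ndarray]
    per_cycle: Dict[CurveKey, np.ndarray] | None = None

    def __post_init__(self) -> None:
        coerced = {}
        for key, curve in self.curves.items():
            joint, plane, side = key
            if joint not in JOINTS or plane not in PLANES or side not in SIDES:
                raise ValueError(f"invalid curve key {key!r}")
            arr = np.asarray(curve, dtype=float)
            if arr.shape != (N_CYCLE_SAMPLES,):
                raise ValueError(f"curve {key}: expected {N_CYCLE_SAMPLES} samples")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"curve {key}: non-finite samples")
            if np.any(arr <= -180.0) or np.any(arr > 180.0):
                raise ValueError(f"curve {key}: angles outside (-180, 180] deg")
            coerced[key] = arr
        self.curves = coerced

    def keys(self) -> Iterable[CurveKey]:
        return self.curves.keys()

    def __getitem__(self, key: CurveKey) -> np.ndarray:
        return self.curves[key]


@dataclass(frozen=True)
class SensitivityRecord:
    joint: str
    plane: str
    side: str
    kind: str  # "gait-cycle" | "peak"
    theta_deg: float
    magnitude: float
    rmsd: float
    band: str

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("RMSD must be non-negative")


@dataclass
class SensitivityTable:
    """Tidy collection of RMSD records for a perturbation grid run."""

    records: List[SensitivityRecord]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "joint": r.joint,
                    "plane": r.plane,
                    "side": r.side,
                    "kind": r.kind,
                    "theta_deg": r.theta_deg,
                    "magnitude_mm": r.magnitude,
                    "rmsd_deg": r.rmsd,
                    "band": r.band,
                    "direction": PerturbationSpec(r.magnitude, r.theta_deg).direction_label,
                }
                for r in self.records
            ]
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ValidationReport:
    issues: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.issues


def validate_trial(trial: MarkerTrial, side: str) -> ValidationReport:
    """Check a trial against the marker-set invariants for one side.

    Report-returning: problems are listed, nothing raises.
    """
    report = ValidationReport()
    lengths = {label: arr.shape[0] for label, arr in trial.markers.items()}
    if lengths and len(set(lengths.values())) > 1:
        report.issues.append("trajectories have unequal lengths")
    if lengths and min(lengths.values()) < 2:
        report.issues.append("trial shorter than 2 frames")

    for label in required_markers(side):
        if label not in trial.markers:
            report.issues.append(f"missing marker {label}")
        elif not np.all(np.isfinite(trial.markers[label])):
            bad = np.where(~np.all(np.isfinite(trial.markers[label]), axis=1))[0]
            report.issues.append(f"marker {label}: gap frames {bad[:5].tolist()}")

    if trial.kind == "gait":
        strikes = trial.foot_strikes(side)
        if len(strikes) < 2:
            report.issues.append(
                f"insufficient events: need >= 2 {side} foot-strikes, found {len(strikes)}"
            )
        if any(f < 0 or f >= trial.n_frames for f in strikes):
            report.issues.append("foot-strike event outside trial")
    return report
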