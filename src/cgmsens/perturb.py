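"""Virtual misplacement of the lateral femoral epicondyle (KNE) marker.

The misplaced marker is ``KNE_misp = KNE_ori + E(eps, theta)`` with
``E = eps * (cos(theta) * X_thigh + sin(theta) * Z_thigh)``: a
displacement of magnitude eps (mm) at direction theta within the
thigh's anterior-posterior / proximal-distal plane (0 deg = anterior,
90 = proximal, 180 = posterior, 270 = distal). The thigh axes are
taken from the *unperturbed* trial, frame by frame, so the offset
travels with the segment like a physically misplaced skin marker and
the perturbation is never self-referential.

The study grid is 8 directions every 45 deg x 5 magnitudes
{5, 10, 15, 20, 30} mm = 40 virtual misplacements.
"""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .datamodel import MarkerTrial, PerturbationSpec, SegmentFrame

__all__ = [
    "DEFAULT_MAGNITUDES",
    "DEFAULT_ANGULAR_STEP",
    "perturbation_grid",
    "displacement_vector",
    "perturb_trial",
]

DEFAULT_MAGNITUDES = (5.0, 10.0, 15.0, 20.0, 30.0)
DEFAULT_ANGULAR_STEP = 45.0


def perturbation_grid(
    magnitudes: Iterable[float] = DEFAULT_MAGNITUDES,
    angular_step: float = DEFAULT_ANGULAR_STEP,
) -> List[PerturbationSpec]:
    """Cartesian product of directions x magnitudes.

    Directions start at theta = 0 (anterior) and increase towards
    proximal in steps of ``angular_step``, which must divide 360.
    """
    magnitudes = [float(m) for m in magnitudes]
    if any(m <= 0 for m in magnitudes):
        raise ValueError("grid magnitudes must be positive")
    if angular_step <= 0 or 360.0 % angular_step != 0.0:
        raise ValueError("angular step must be a positive divisor of 360")
    thetas = np.arange(0.0, 360.0, angular_step)
    return [PerturbationSpec(magnitude=m, theta_deg=float(t)) for t in thetas for m in magnitudes]


def displacement_vector(spec: PerturbationSpec, thigh: SegmentFrame) -> np.ndarray:
    """Lab-frame displacement ``E(eps, theta)``, one row per frame."""
    theta = np.radians(spec.theta_deg)
    return spec.magnitude * (np.cos(theta) * thigh.x + np.sin(theta) * thigh.z)


def perturb_trial(
    trial: MarkerTrial, spec: PerturbationSpec, side: str, thigh: SegmentFrame
) -> MarkerTrial:
    """Copy of ``trial`` with the KNE marker of ``side`` misplaced.

    ``thigh`` must hold the per-frame thigh frames computed from the
    *original* (unperturbed) markers of this same trial (see
    :func:`cgmsens.cgm.thigh_frames`). All other markers are untouched.
    """
    label = ("L" if side == "left" else "R") + "KNE"
    if label not in trial.markers:
        raise ValueError(f"trial has no {label} marker to perturb")
    if np.shape(thigh.origin)[0] != trial.n_frames:
        raise ValueError("reference thigh frames do not match the trial length")
    out = trial.copy()
    out.markers[label] = out.markers[label] + displacement_vector(spec, thigh)
    return out
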