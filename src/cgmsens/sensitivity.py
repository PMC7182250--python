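"""RMSD sensitivity analysis of KNE misplacement on lower-limb kinematics.

For each virtual misplacement the whole session is re-processed and
the deviation of every joint-angle curve from the reference kinematics
is summarized as

    RMSD = sqrt( sum_i (Err_i - O_i)^2 / n )

over the 101 samples of the normalized gait cycle (``gait-cycle``
records), and as the root-mean-square across cycles of the absolute
peak-value change (``peak`` records). RMSDs are classified against the
clinical interpretation bands: < 2 deg optimal, 2-5 deg acceptable,
> 5 deg too high.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from . import cgm
from .datamodel import (
    JOINTS,
    PLANES,
    Anthropometry,
    AngleCurveSet,
    MarkerTrial,
    PerturbationSpec,
    SensitivityRecord,
    SensitivityTable,
)
from .perturb import perturb_trial, perturbation_grid

__all__ = [
    "rmsd",
    "peak_parameter",
    "classify_error",
    "GaitSession",
    "run_sensitivity",
    "OPTIMAL_LIMIT",
    "ACCEPTABLE_LIMIT",
]

log = logging.getLogger(__name__)

OPTIMAL_LIMIT = 2.0  # deg
ACCEPTABLE_LIMIT = 5.0  # deg


def rmsd(original: np.ndarray, perturbed: np.ndarray) -> float:
    """Root-mean-square deviation between two angle curves, degrees."""
    o = np.asarray(original, dtype=float)
    e = np.asarray(perturbed, dtype=float)
    if o.shape != e.shape:
        raise ValueError(f"curve length mismatch: {o.shape} vs {e.shape}")
    return float(np.sqrt(np.mean((e - o) ** 2)))


def peak_parameter(curve: np.ndarray, angle_id: Tuple[str, str]) -> float:
    """Signed extremum of a curve in the clinically named direction.

    Flexion and adduction peaks are maxima of the signed curve; the
    rotation parameter is the *external* rotation peak, i.e. the
    minimum of the internal-rotation-positive curve.
    """
    joint, plane = angle_id
    if joint not in JOINTS or plane not in PLANES:
        raise ValueError(f"unknown angle id {angle_id!r}")
    curve = np.asarray(curve, dtype=float)
    if plane == "rotation":
        return float(curve.min())
    return float(curve.max())


def classify_error(value: float) -> str:
    """2 deg / 5 deg clinical error bands for an RMSD."""
    if value < 0:
        raise ValueError("RMSD must be non-negative")
    if value < OPTIMAL_LIMIT:
        return "optimal"
    if value <= ACCEPTABLE_LIMIT:
        return "acceptable"
    return "too-high"


@dataclass
class GaitSession:
    """One static calibration trial + one gait trial of a subject."""

    static: MarkerTrial
    gait: MarkerTrial
    anthropometry: Anthropometry
    subject_id: str | None = None


def _peak_deviation(ref: AngleCurveSet, per: AngleCurveSet, key) -> float:
    """RMS across cycles of the per-cycle absolute peak change."""
    joint, plane, _side = key
    ref_cycles = ref.per_cycle[key]
    per_cycles = per.per_cycle[key]
    n = min(len(ref_cycles), len(per_cycles))
    deltas = [
        peak_parameter(per_cycles[i], (joint, plane)) - peak_parameter(ref_cycles[i], (joint, plane))
        for i in range(n)
    ]
    return float(np.sqrt(np.mean(np.square(deltas))))


def run_sensitivity(
    session: GaitSession,
    grid: Sequence[PerturbationSpec] | None = None,
    side: str = "left",
    apply_to_static: bool = False,
) -> SensitivityTable:
    """Run the full misplacement grid on one session.

    The reference kinematics is computed once from the original
    markers. For each grid entry the KNE marker is displaced in the
    reference thigh frame, the session is reprocessed (optionally
    recalibrating on an equally-perturbed static trial - see
    ``apply_to_static``) and the RMSD and peak deviations of all nine
    angle curves are recorded. The table therefore has
    ``len(grid) * 9 * 2`` rows.

    ``apply_to_static=False`` (default) perturbs the gait trial only,
    keeping the original calibration; ``True`` also misplaces the
    marker in the static trial, emulating an error present during
    calibration as well.
    """
    if grid is None:
        grid = perturbation_grid()
    anthro = session.anthropometry

    t0 = time.perf_counter()
    calib_ref = cgm.static_calibration(session.static, anthro)
    curves_ref = cgm.compute_kinematics(session.gait, calib_ref, anthro, side)
    thigh_gait = cgm.thigh_frames(session.gait, anthro, side)
    thigh_static = cgm.thigh_frames(session.static, anthro, side)
    log.debug("reference kinematics in %.3f s", time.perf_counter() - t0)

    records: List[SensitivityRecord] = []
    for spec in grid:
        try:
            gait_p = perturb_trial(session.gait, spec, side, thigh_gait)
            if apply_to_static:
                static_p = perturb_trial(session.static, spec, side, thigh_static)
                calib_p = cgm.static_calibration(static_p, anthro)
            else:
                calib_p = calib_ref
            curves_p = cgm.compute_kinematics(gait_p, calib_p, anthro, side)
        except Exception as exc:
            raise RuntimeError(
                f"sensitivity run failed for eps={spec.magnitude} mm, theta={spec.theta_deg} deg"
            ) from exc
        for key in curves_ref.keys():
            joint, plane, _ = key
            value_gc = rmsd(curves_ref[key], curves_p[key])
            value_pk = _peak_deviation(curves_ref, curves_p, key)
            for kind, value in (("gait-cycle", value_gc), ("peak", value_pk)):
                records.append(
                    SensitivityRecord(
                        joint=joint,
                        plane=plane,
                        side=side,
                        kind=kind,
                        theta_deg=spec.theta_deg,
                        magnitude=spec.magnitude,
                        rmsd=value,
                        band=classify_error(value),
                    )
                )
    log.info("sensitivity grid (%d specs) in %.3f s", len(grid), time.perf_counter() - t0)
    return SensitivityTable(records=records)
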