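"""Shared fixtures: a child-sized synthetic subject and cached
sensitivity runs (session-scoped, since the grid runs dominate the
suite's runtime)."""

from __future__ import annotations

import numpy as np
import pytest

import cgmsens as cs
from cgmsens.datamodel import PerturbationSpec

CARDINALS = (0.0, 90.0, 180.0, 270.0)


def anthro_for_leg(leg_length: float) -> cs.Anthropometry:
    """Allometrically consistent anthropometry for a given leg length."""
    h = leg_length / 0.53
    return cs.Anthropometry(
        leg_length=leg_length,
        knee_width=0.060 * h,
        ankle_width=0.039 * h,
        height=h,
        mass=16.0 * (h / 1000.0) ** 2,
        inter_asis_distance=0.145 * h,
    )


def rigid_transform(trial: cs.MarkerTrial, R: np.ndarray, t: np.ndarray) -> cs.MarkerTrial:
    out = trial.copy()
    for label in out.markers:
        out.markers[label] = out.markers[label] @ R.T + t
    return out


@pytest.fixture(scope="session")
def child_anthro() -> cs.Anthropometry:
    # leg length 700 mm: a child near the low-middle of the cohort range
    return cs.Anthropometry(
        leg_length=700.0,
        knee_width=90.0,
        ankle_width=60.0,
        height=1320.0,
        mass=28.0,
        inter_asis_distance=190.0,
    )


@pytest.fixture(scope="session")
def child_subject(child_anthro) -> cs.SyntheticSubject:
    return cs.build_skeleton(child_anthro, seed=3)


@pytest.fixture(scope="session")
def typical_curves() -> cs.AngleCurveSet:
    return cs.default_angle_curves("typical")


@pytest.fixture(scope="session")
def child_session(child_subject) -> cs.GaitSession:
    return cs.make_session(child_subject)


@pytest.fixture(scope="session")
def cardinal_frame(child_session):
    """RMSD table for 10 mm misplacements in the four cardinal directions."""
    grid = [PerturbationSpec(10.0, th) for th in CARDINALS]
    return cs.run_sensitivity(child_session, grid=grid, side="left").to_frame()


@pytest.fixture(scope="session")
def ap_cohort():
    """Sensitivity tables for an anterior/posterior magnitude sweep on
    four subjects spanning the leg-length range (used by the
    correlation, size-effect and prediction checks)."""
    grid = [PerturbationSpec(m, th) for th in (0.0, 180.0) for m in (5.0, 10.0, 15.0, 20.0, 30.0)]
    out = {}
    for leg in (650.0, 733.0, 816.0, 900.0):
        anthro = anthro_for_leg(leg)
        # matched design: common placement template (same jitter draw)
        # so between-subject differences reflect stature only
        session = cs.make_session(cs.build_skeleton(anthro, seed=11))
        out[leg] = (cs.run_sensitivity(session, grid=grid, side="left"), anthro)
    return out


def gc_rmsd(frame, joint: str, plane: str, direction: str) -> float:
    """Mean gait-cycle RMSD of one angle over one direction label."""
    sub = frame[
        (frame["kind"] == "gait-cycle")
        & (frame["joint"] == joint)
        & (frame["plane"] == plane)
        & (frame["direction"] == direction)
    ]
    assert len(sub) > 0
    return float(sub["rmsd_deg"].mean())
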