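"""Vector-geometry primitives of the Conventional Gait Model.

Everything here is deliberately free of gait semantics: the chord
construction that places a joint centre at a fixed offset from a skin
marker, and the mobile Y-X-Z Cardan decomposition used for clinical
joint angles. All functions broadcast over leading axes so a whole
trial (``(n_frames, 3)`` / ``(n_frames, 3, 3)``) is processed in one
call.

Units: millimetres for positions, radians for the low-level rotation
helpers (degree conversion happens at the clinical-angle layer).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "GeometryError",
    "GimbalWarning",
    "unit",
    "rot_x",
    "rot_y",
    "rot_z",
    "chord",
    "compose_cardan_yxz",
    "decompose_cardan_yxz",
]


class GeometryError(ValueError):
    """Degenerate geometric input (collinear points, infeasible offset...)."""


class GimbalWarning(RuntimeWarning):
    """Cardan decomposition evaluated within 1e-6 rad of gimbal lock."""


def unit(v: np.ndarray, *, name: str = "vector") -> np.ndarray:
    """Normalize ``v`` along the last axis; raise on (near-)zero norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise GeometryError(f"cannot normalize near-zero {name}")
    return v / n


def rot_x(a: float | np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [
            np.stack([one, zero, zero], axis=-1),
            np.stack([zero, c, -s], axis=-1),
            np.stack([zero, s, c], axis=-1),
        ],
        axis=-2,
    )


def rot_y(a: float | np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [
            np.stack([c, zero, s], axis=-1),
            np.stack([zero, one, zero], axis=-1),
            np.stack([-s, zero, c], axis=-1),
        ],
        axis=-2,
    )


def rot_z(a: float | np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [
            np.stack([c, -s, zero], axis=-1),
            np.stack([s, c, zero], axis=-1),
            np.stack([zero, zero, one], axis=-1),
        ],
        axis=-2,
    )


def chord(offset: float, M: np.ndarray, P: np.ndarray, W: np.ndarray) -> np.ndarray:
    """CGM chord construction of a joint centre.

    Returns the point ``J`` satisfying

    * ``|J - M| = offset`` (the marker sits half a joint width plus a
      marker radius away from the joint centre),
    * ``J`` lies in the plane of ``P`` (proximal centre), ``M`` (marker)
      and ``W`` (wand marker; its only role is to span that plane),
    * the angle at ``J`` between ``P - J`` and ``M - J`` is 90 deg,

    and, of the two candidates the first three constraints admit, the
    one on the side of line ``P-M`` *away* from the wand: the wand is
    mounted laterally while the joint centre lies medially to the
    marker, which is the solution the Plug-in-Gait chord selects.

    Parameters broadcast over leading axes; ``offset`` is scalar.
    """
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    W = np.asarray(W, dtype=float)
    offset = float(offset)
    if offset <= 0.0:
        raise GeometryError("chord offset must be > 0")

    pm = P - M
    d = np.linalg.norm(pm, axis=-1, keepdims=True)
    if np.any(offset >= d - 1e-9):
        raise GeometryError("chord offset must be smaller than |P - M|")
    u = pm / d

    wm = W - M
    # component of W - M orthogonal to the P-M line, inside the plane
    w_perp = wm - np.sum(wm * u, axis=-1, keepdims=True) * u
    n_perp = np.linalg.norm(w_perp, axis=-1, keepdims=True)
    if np.any(n_perp < 1e-9 * d):
        raise GeometryError("chord inputs are collinear; wand does not define a plane")
    v = -w_perp / n_perp  # in-plane normal pointing away from the wand

    along = offset**2 / d
    lateral = offset * np.sqrt(1.0 - (offset / d) ** 2)
    return M + along * u + lateral * v


def compose_cardan_yxz(a, b, c) -> np.ndarray:
    """Rotation matrix ``Ry(a) @ Rx(b) @ Rz(c)`` (mobile-axis Y-X'-Z'')."""
    return rot_y(a) @ rot_x(b) @ rot_z(c)


def decompose_cardan_yxz(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`compose_cardan_yxz`.

    Returns angles ``(a, b, c)`` in radians with ``a, c`` in (-pi, pi]
    and ``b`` in [-pi/2, pi/2]. Proximity of ``|b|`` to pi/2 (within
    1e-6 rad) is flagged with :class:`GimbalWarning` rather than
    rejected; in that regime ``a`` and ``c`` are not separable.
    """
    R = np.asarray(R, dtype=float)
    sb = np.clip(-R[..., 1, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if np.any(np.abs(np.abs(b) - np.pi / 2) < 1e-6):
        warnings.warn(
            "Cardan decomposition near gimbal lock (|second angle| ~ 90 deg)",
            GimbalWarning,
            stacklevel=2,
        )
    a = np.arctan2(R[..., 0, 2], R[..., 2, 2])
    c = np.arctan2(R[..., 1, 0], R[..., 1, 1])
    return a, b, c
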