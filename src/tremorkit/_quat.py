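"""Minimal scalar-first unit-quaternion helpers.

Quaternions are arrays ``(w, x, y, z)``; batched forms have shape (n, 4).
scipy's Rotation (xyzw order) is used for bulk frame transforms; these
helpers cover the cheap per-sample operations of the attitude filter and
the simulator without per-step object construction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b (either argument may be batched (n, 4))."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q (frame: sensor -> earth if q is)."""
    q = np.asarray(q, float)
    v = np.asarray(v, float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Unit quaternion for rotation vector(s) (axis * angle, rad)."""
    rv = np.asarray(rv, float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    small = angle[..., 0] < 1e-12
    axis = np.where(angle > 1e-12, rv / np.where(angle > 0, angle, 1.0), 0.0)
    half = angle[..., 0] / 2.0
    q = np.empty(rv.shape[:-1] + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1:] = axis * np.sin(half)[..., None]
    q[small] = np.array([1.0, 0.0, 0.0, 0.0])
    return q


def from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for rotation by ``angle`` (rad, may be an array)
    about a fixed unit ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle, float)
    q = np.empty(np.shape(angle) + (4,))
    q[..., 0] = np.cos(angle / 2.0)
    q[..., 1:] = np.sin(angle / 2.0)[..., None] * axis
    return q


def rotation_angle_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle (rad) between two unit quaternions (batched ok)."""
    dot = np.abs(np.sum(np.asarray(a, float) * np.asarray(b, float), axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def to_scipy(q: np.ndarray) -> Rotation:
    """Convert scalar-first quaternion(s) to a scipy Rotation."""
    q = np.asarray(q, float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))
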