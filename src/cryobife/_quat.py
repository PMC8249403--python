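"""Small quaternion toolbox (scalar-first convention ``q = (w, x, y, z)``).

All rotations here are *active* rotations of coordinates; unit quaternions
``q`` and ``-q`` represent the same rotation (antipodal identification).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_to_matrix",
    "quat_multiply",
    "quat_from_axis_angle",
    "geodesic_distance",
    "random_quaternion",
]


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (or stack of matrices) for unit quaternion(s).

    Parameters
    ----------
    q
        Array of shape ``(4,)`` or ``(n, 4)``, scalar-first, unit norm.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((q.shape[0], 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R[0] if single else R


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` (composition: rotate by ``b`` then ``a``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(np.atleast_2d(a), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.atleast_2d(b), -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    if a.ndim == 1 and b.ndim == 1:
        return out[0]
    return out


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation angle (radians, in [0, pi]) between quaternions a and b.

    Antipodal quaternions are identified, so the dot product enters through
    its absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def random_quaternion(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform random rotation(s) via Shoemake's subgroup algorithm."""
    m = 1 if n is None else n
    u1, u2, u3 = rng.random((3, m))
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=-1,
    )
    # reorder so the scalar part comes first (Shoemake's (x,y,z,w) layout)
    q = q[:, [3, 0, 1, 2]]
    return q[0] if n is None else q
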