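"""Shared 3D rotation and orthographic projection conventions.

Coordinate conventions used across the package:

* A voxel index is ``(z, y, x)`` with ``z`` the slice number from the top of
  the CTA stack; its Cartesian position is the point ``(x, y, z)``.
* View angles ``(theta_x, theta_y, theta_z)`` are in degrees and applied in
  x -> y -> z order, right-handed, about a given center (by default the
  volume centroid).
* Orthographic projection maps a rotated point ``(x', y', z')`` to the image
  pixel ``(u, v) = (round(x'), round(y'))``; ``z'`` is depth, and among
  points landing on one pixel the one with the smallest ``z'`` is nearest to
  the viewer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ViewAngles", "rotation_matrix", "rotate_points", "volume_center"]


@dataclass(frozen=True)
class ViewAngles:
    """Rotation angles in degrees about the x, y and z axes (applied x→y→z)."""

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    def __post_init__(self):
        for a in (self.theta_x, self.theta_y, self.theta_z):
            if not np.isfinite(a):
                raise ValueError("view angles must be finite")

    def as_tuple(self):
        return (self.theta_x, self.theta_y, self.theta_z)


def rotation_matrix(angles: ViewAngles) -> np.ndarray:
    """Combined right-handed rotation matrix R = Rz · Ry · Rx (x applied first)."""
    ax, ay, az = np.deg2rad(angles.as_tuple())
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def volume_center(shape_zyx) -> np.ndarray:
    """Cartesian (x, y, z) center of a volume given its (nz, ny, nx) shape."""
    nz, ny, nx = shape_zyx
    return np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])


def rotate_points(points_xyz, angles: ViewAngles, center=None) -> np.ndarray:
    """Rotate an (n, 3) array of (x, y, z) points about ``center``.

    ``center`` defaults to the origin.
    """
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    r = rotation_matrix(angles)
    if center is None:
        center = np.zeros(3)
    center = np.asarray(center, dtype=float)
    return (pts - center) @ r.T + center
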