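"""Planar rigid-body (isometric) transforms.

A transform ``T = {theta, tx, ty}`` acts on a point ``(x, y)`` as

    x' = cos(theta) x - sin(theta) y + tx
    y' = sin(theta) x + cos(theta) y + ty

i.e. rotation about the origin followed by a translation.  All coordinates
are in nm, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform"]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation of the plane (an orientation-preserving isometry)."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)

    def apply(self, x, y):
        """Transform coordinates; accepts scalars or arrays, returns (x', y')."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return c * x - s * y + self.tx, s * x + c * y + self.ty

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        tx = c * other.tx - s * other.ty + self.tx
        ty = s * other.tx + c * other.ty + self.ty
        return RigidTransform(self.theta + other.theta, tx, ty)

    def inverse(self) -> "RigidTransform":
        c, s = np.cos(self.theta), np.sin(self.theta)
        return RigidTransform(-self.theta, -(c * self.tx + s * self.ty), -(-s * self.tx + c * self.ty))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            abs(np.arctan2(np.sin(self.theta), np.cos(self.theta))) <= tol
            and abs(self.tx) <= tol
            and abs(self.ty) <= tol
        )
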