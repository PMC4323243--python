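"""Minimal exact 3D geometry kernel.

Coordinates are millimetres in a right-handed subject frame:
X = lateral axis, positive toward the subject's RIGHT;
Y = vertical axis, positive superior;
Z = antero-posterior axis, positive anterior.

Planes are stored in Hesse normal form ``{p : normal . p = offset}`` with a
unit normal, so signed point-plane distance is a single dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

# triangle area below which three points are treated as collinear (mm^2)
EPS_AREA = 1e-6
# containment / residual tolerance (mm)
EPS_CONTAIN = 1e-9


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinate: {p!r}")
    return a


@dataclass(frozen=True)
class Plane:
    """Infinite oriented plane ``normal . p = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(n)
        if not np.isfinite(nrm) or nrm == 0.0:
            raise ValueError("plane normal must be a nonzero finite vector")
        # normalising a non-unit normal rescales the offset with it
        object.__setattr__(self, "normal", n / nrm)
        object.__setattr__(self, "offset", float(self.offset) / nrm)
        if not np.isfinite(self.offset):
            raise ValueError("plane offset must be finite")

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance (mm); positive on the side the normal points to."""
        pts = np.asarray(points, dtype=float)
        d = pts @ self.normal - self.offset
        return float(d) if pts.ndim == 1 else d

    def distance(self, points) -> np.ndarray | float:
        """Unsigned Euclidean distance (mm)."""
        return np.abs(self.signed_distance(points))

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)

    def oriented(self, direction) -> "Plane":
        """Return a copy whose normal has positive component along `direction`.

        Used to pin the superior (+Y) convention for horizontal planes and
        the subject-right (+X) convention for midsagittal planes. If the
        normal is exactly perpendicular to `direction` the plane is returned
        unchanged.
        """
        d = float(np.dot(self.normal, np.asarray(direction, dtype=float)))
        return self.flipped() if d < 0 else self

    def transformed(self, transform: "RigidTransform") -> "Plane":
        n = transform.rotation @ self.normal
        return Plane(n, self.offset + float(n @ transform.translation))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = pts @ self.rotation.T + self.translation
        return out

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def midpoint(a, b) -> np.ndarray:
    """Componentwise midpoint of two points."""
    return 0.5 * (_as_point(a) + _as_point(b))


def plane_from_three_points(a, b, c, names=("a", "b", "c")) -> Plane:
    """Plane through three non-collinear points.

    The normal follows the right-hand rule on (b-a, c-a); callers pin the
    anatomical orientation afterwards via :meth:`Plane.oriented`.
    """
    pa, pb, pc = _as_point(a), _as_point(b), _as_point(c)
    cross = np.cross(pb - pa, pc - pa)
    area = 0.5 * np.linalg.norm(cross)
    if area <= EPS_AREA:
        raise DegenerateGeometryError(
            f"points {names[0]}, {names[1]}, {names[2]} are collinear or "
            f"coincident (triangle area {area:.3g} mm^2)"
        )
    normal = cross / np.linalg.norm(cross)
    return Plane(normal, float(normal @ pa))


def point_plane_distance(p, plane: Plane, signed: bool = False) -> float:
    """Euclidean distance (mm) from a point to a plane."""
    d = plane.signed_distance(_as_point(p))
    return float(d) if signed else float(abs(d))


def _check_spanning(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # two significant singular values = points span at least a plane
    if s.size < 2 or s[1] <= 1e-9 * max(1.0, s[0]):
        raise DegenerateGeometryError(f"{label} points are (near-)collinear")


def kabsch_superimpose(source, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid superimposition of paired landmark sets.

    Returns the proper rigid transform minimising the RMSD of the
    transformed source against the target (Kabsch algorithm via SVD, with
    reflection correction), together with the residual RMSD in mm.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have equal lengths")
    if len(src) < 3:
        raise DegenerateGeometryError(
            f"rigid superimposition needs >=3 correspondences, got {len(src)}"
        )
    _check_spanning(src, "source")
    _check_spanning(tgt, "target")

    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    transform = RigidTransform(R, t)
    resid = transform.apply(src) - tgt
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rmsd
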