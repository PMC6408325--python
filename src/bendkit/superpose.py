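"""Least-squares rigid-body superposition (Kabsch) and rotation angles.

Every conformational metric in the toolkit reduces to fitting one Cα set
onto another by a proper rigid motion and reading off the residual RMSD
and/or the magnitude of the rotation.  The fit is the classical Kabsch
solution via SVD of the cross-covariance matrix, with the determinant
correction so a reflection is never returned; the scalar rotation angle
comes from the trace formula ``angle = arccos((tr R − 1) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

#: Singular values of the cross-covariance below this are treated as degenerate.
DEGENERACY_EPS = 1e-10


@dataclass
class RigidTransform:
    """A proper rigid motion ``x ↦ R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("transform must be a 3x3 rotation and a 3-vector")

    def validate(self, tol: float = 1e-8) -> None:
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > tol:
            raise GeometryError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("rotation has determinant -1 (improper)")

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying *other* first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class SuperpositionResult:
    """Outcome of a least-squares rigid fit."""

    transform: RigidTransform
    rmsd: float
    n_points: int
    rotation_angle_deg: float


def _as_points(coords) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) coordinate array, got {pts.shape}")
    return pts


def rotation_angle(transform: RigidTransform) -> float:
    """Magnitude of the rotation in degrees, in [0, 180].

    Invariant under conjugation ``R → Q R Qᵀ`` for any proper rotation Q, so
    the value does not depend on the frame the coordinates were expressed in.
    """
    transform.validate()
    cos_theta = (np.trace(transform.rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def apply_transform(coords, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid motion to an ``(n, 3)`` coordinate array."""
    pts = _as_points(coords)
    return pts @ transform.rotation.T + transform.translation


def rmsd_fixed(coords_a, coords_b) -> float:
    """Root-mean-square deviation between paired coordinates, no fitting."""
    a, b = _as_points(coords_a), _as_points(coords_b)
    if a.shape != b.shape:
        raise GeometryError(f"coordinate count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise GeometryError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(moving, fixed) -> SuperpositionResult:
    """Optimal proper rigid motion of *moving* onto *fixed*.

    Minimises the RMSD over all rotations+translations; reflections are
    excluded by the standard determinant correction.  At least three
    non-collinear point pairs are required.

    Returns
    -------
    SuperpositionResult
        With the fitted transform, residual RMSD, point count and the
        scalar rotation angle in degrees.
    """
    m, f = _as_points(moving), _as_points(fixed)
    if m.shape != f.shape:
        raise GeometryError(f"coordinate count mismatch: {m.shape[0]} vs {f.shape[0]}")
    n = m.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    mc, fc = m.mean(axis=0), f.mean(axis=0)
    dm, df = m - mc, f - fc
    cov = dm.T @ df
    u, s, vt = np.linalg.svd(cov)
    if s[1] < DEGENERACY_EPS:  # rank < 2: collinear or coincident points
        raise GeometryError("degenerate point set (collinear or coincident)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    transform = RigidTransform(rotation=rot, translation=trans)
    rmsd = rmsd_fixed(apply_transform(m, transform), f)
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        n_points=n,
        rotation_angle_deg=rotation_angle(transform),
    )
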