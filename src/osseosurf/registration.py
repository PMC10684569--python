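"""Rigid transforms, point-to-plane ICP, and six-degree-of-freedom reporting.

Best-fit superimposition of repeatedly segmented (or segmented vs
gold-standard) surface models uses an iterative-closest-point variant
with the study's settings: 100% estimated overlap, matching point to
plane, exact nearest-neighbour search, 100% point sampling, 50
iterations.  The recovered rigid transform is decomposed into the six
movement components reported clinically: X (lateral), Y (vertical),
Z (anteroposterior) translations in mm and rotations about those axes
in degrees.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_ops import MeasurementArea, TriMesh

__all__ = [
    "RigidTransform",
    "SixDoF",
    "ICPSettings",
    "ICPResult",
    "icp_register",
    "decompose_transform",
    "recompose_transform",
    "compose",
    "invert",
]

#: Euler convention used for SixDoF reporting: fixed (extrinsic) axes,
#: applied X then Y then Z.  Recorded in serialised output.
EULER_CONVENTION = "fixed-axis-XYZ"
_EULER_SEQ = "xyz"  # scipy lowercase = extrinsic


@dataclass
class RigidTransform:
    """Proper rigid transform v' = R v + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (‖RᵀR−I‖ = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1 (improper transform)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation) -> "RigidTransform":
        """Axis-angle rotation (degrees) plus translation."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        sixdof = decompose_transform(self)
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "sixdof": sixdof.as_dict(),
            "euler_convention": EULER_CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def save_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path: str | os.PathLike) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(t: RigidTransform) -> RigidTransform:
    return RigidTransform(t.rotation.T, -t.rotation.T @ t.translation)


@dataclass(frozen=True)
class SixDoF:
    """Movement components: translations in mm, rotations in degrees.

    Axes: X lateral, Y vertical, Z anteroposterior.  Rotations are Euler
    angles under the fixed-axis X→Y→Z convention, reported in
    (−180°, 180°].
    """

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    gimbal_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "tx_mm": self.tx,
            "ty_mm": self.ty,
            "tz_mm": self.tz,
            "rx_deg": self.rx,
            "ry_deg": self.ry,
            "rz_deg": self.rz,
        }

    def max_component(self) -> float:
        """Largest magnitude across all six components (mm or degrees)."""
        return float(max(abs(v) for v in (self.tx, self.ty, self.tz, self.rx, self.ry, self.rz)))


def decompose_transform(t: RigidTransform) -> SixDoF:
    """Split a rigid transform into the six reported movement components."""
    angles = Rotation.from_matrix(t.rotation).as_euler(_EULER_SEQ, degrees=True)
    gimbal = bool(abs(abs(angles[1]) - 90.0) < 1e-6)
    if gimbal:
        warnings.warn("Euler decomposition near gimbal lock (|ry| ≈ 90°)", stacklevel=2)
    return SixDoF(
        tx=float(t.translation[0]),
        ty=float(t.translation[1]),
        tz=float(t.translation[2]),
        rx=float(angles[0]),
        ry=float(angles[1]),
        rz=float(angles[2]),
        gimbal_flag=gimbal,
    )


def recompose_transform(dof: SixDoF) -> RigidTransform:
    rot = Rotation.from_euler(_EULER_SEQ, [dof.rx, dof.ry, dof.rz], degrees=True)
    return RigidTransform(rot.as_matrix(), np.array([dof.tx, dof.ty, dof.tz]))


# ----------------------------------------------------------------------
# ICP
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ICPSettings:
    """Superimposition settings (defaults mirror the study protocol)."""

    estimated_overlap: float = 1.0
    metric: str = "point-to-plane"
    nn_search: str = "exact"
    sampling_fraction: float = 1.0
    iterations: int = 50
    convergence_tol: float = 1e-6  # mm change in RMS residual

    def __post_init__(self) -> None:
        if not (0.0 < self.estimated_overlap <= 1.0):
            raise ValueError("estimated_overlap must be in (0, 1]")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.metric not in ("point-to-plane", "point-to-point"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.nn_search != "exact":
            raise ValueError("only exact nearest-neighbour search is supported")


@dataclass
class ICPResult:
    """Convergence log and conditioning flags for one registration."""

    rms_residuals: list[float]
    n_correspondences: int
    iterations_run: int
    rank: int
    unconstrained: bool
    converged: bool


def _solve_point_to_plane(p, q, n):
    """One linearised point-to-plane step.

    Minimises Σ (nᵢ·(pᵢ + ω×pᵢ + t − qᵢ))² over the screw (ω, t) via
    least squares; rank deficiency (e.g. rotationally symmetric
    geometry) falls back to the minimum-norm solution, which zeroes the
    unobservable directions.
    """
    a = np.hstack([np.cross(p, n), n])
    b = -np.einsum("ij,ij->i", n, p - q)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    # observability diagnostic: normalise the rotation block by the cloud's
    # characteristic radius so the six columns share units, then compare
    # singular values.  Rotationally symmetric geometry (e.g. spheres) makes
    # the rotation directions nearly unobservable even at full numerical rank.
    centroid = p.mean(axis=0)
    char_len = float(np.sqrt(np.mean(np.sum((p - centroid) ** 2, axis=1))))
    scaled = np.hstack([np.cross(p - centroid, n) / max(char_len, 1e-12), n])
    s = np.linalg.svd(scaled, compute_uv=False)
    eff_rank = int(np.sum(s > 0.1 * s[0]))
    return sol[:3], sol[3:], min(rank, eff_rank)


def _solve_point_to_point(p, q):
    """Closed-form rigid alignment (Kabsch/Umeyama, no scaling)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def icp_register(
    moving: TriMesh,
    fixed: TriMesh,
    source_area: MeasurementArea | None = None,
    settings: ICPSettings | None = None,
) -> tuple[RigidTransform, ICPResult]:
    """Best-fit approximate ``moving`` onto ``fixed``.

    Correspondences run from (sampled) vertices of ``source_area`` on the
    moving mesh to the exact closest point on the fixed mesh's triangle
    surface.  With ``estimated_overlap < 1`` the worst (1 − overlap)
    fraction of correspondences by distance is discarded each round.

    Returns the transform mapping ``moving`` into ``fixed``'s frame and
    the per-iteration RMS residual log.
    """
    from .deviation import SurfaceQuery  # local import to avoid a cycle

    settings = settings or ICPSettings()
    if moving.is_empty or fixed.is_empty:
        raise ValueError("ICP requires two non-empty meshes")
    vid = moving.area_vertex_ids(source_area)
    if vid.size == 0:
        raise ValueError("source area selects no vertices on the moving mesh")
    pts = moving.vertices[vid]
    if settings.sampling_fraction < 1.0:
        step = max(1, int(round(1.0 / settings.sampling_fraction)))
        pts = pts[::step]
    if len(pts) < 6:
        raise ValueError(f"only {len(pts)} sample points; at least 6 required")

    query = SurfaceQuery(fixed)
    current = RigidTransform.identity()
    rms_log: list[float] = []
    rank = 6
    unconstrained = False
    converged = False

    for _ in range(settings.iterations):
        moved = current.apply(pts)
        dist, closest, face_idx = query.closest(moved)
        if settings.estimated_overlap < 1.0:
            keep = max(6, int(np.ceil(settings.estimated_overlap * len(moved))))
            sel = np.argsort(dist, kind="stable")[:keep]
            moved_s, closest_s, face_s = moved[sel], closest[sel], face_idx[sel]
        else:
            moved_s, closest_s, face_s = moved, closest, face_idx

        if settings.metric == "point-to-plane":
            normals = query.face_normals[face_s]
            resid = np.einsum("ij,ij->i", normals, moved_s - closest_s)
            rms = float(np.sqrt(np.mean(resid**2)))
        else:
            resid = np.linalg.norm(moved_s - closest_s, axis=1)
            rms = float(np.sqrt(np.mean(resid**2)))
        rms_log.append(rms)
        if len(rms_log) >= 2 and abs(rms_log[-2] - rms_log[-1]) < settings.convergence_tol:
            converged = True
            break

        if settings.metric == "point-to-plane":
            omega, dt, rank = _solve_point_to_plane(moved_s, closest_s, normals)
            if rank < 6:
                unconstrained = True
            r_step = Rotation.from_rotvec(omega).as_matrix()
        else:
            r_step, dt = _solve_point_to_point(moved_s, closest_s)
        # re-orthonormalise to keep the invariant tight across iterations
        u, _, vt = np.linalg.svd(r_step)
        r_step = u @ vt
        step = RigidTransform(r_step, dt)
        current = compose(step, current)

    if unconstrained:
        warnings.warn(
            "ICP normal field is rank-deficient: some movement components are "
            "unconstrained by the geometry and reported as zero",
            stacklevel=2,
        )
    result = ICPResult(
        rms_residuals=rms_log,
        n_correspondences=len(pts),
        iterations_run=len(rms_log),
        rank=int(rank),
        unconstrained=unconstrained,
        converged=converged,
    )
    return current, result
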