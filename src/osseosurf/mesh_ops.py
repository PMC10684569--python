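"""Triangle meshes, mesh I/O, and triangle-count-defined measurement areas.

The deviation protocol summarises distances over *measurement areas*:
fixed sets of triangles grown to an exact count (1000 per circular
patch; bilateral patches are unified into one 2000-triangle area for
reproducibility testing and 4000 triangles for trueness testing).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "MeasurementArea",
    "read_mesh",
    "write_mesh",
    "grow_patch",
    "unify_areas",
    "apply_transform",
    "map_area",
    "nearest_triangle",
    "face_adjacency_graph",
]


@dataclass
class TriMesh:
    """Indexed triangle mesh with vertices in millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face with a repeated vertex")
        if self.vertices.size and not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")

    # -- basic queries -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return self.n_faces == 0

    def triangle_corners(self, face_ids: np.ndarray | None = None) -> np.ndarray:
        """(m, 3, 3) corner coordinates of the selected triangles."""
        f = self.faces if face_ids is None else self.faces[np.asarray(face_ids)]
        return self.vertices[f]

    def face_centroids(self, face_ids: np.ndarray | None = None) -> np.ndarray:
        return self.triangle_corners(face_ids).mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit normals following the winding order (right-hand rule)."""
        tri = self.triangle_corners()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.triangle_corners()
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def area_vertex_ids(self, area: "MeasurementArea | None") -> np.ndarray:
        """Vertex ids incident to an area's triangles (whole mesh if None)."""
        if area is None:
            return np.arange(self.n_vertices)
        return np.unique(self.faces[np.asarray(area.triangle_ids)])

    # -- conversions ---------------------------------------------------
    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    @classmethod
    def empty(cls) -> "TriMesh":
        return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))


@dataclass
class MeasurementArea:
    """A set of triangles on a named mesh region.

    Areas are defined by triangle ids on one specific mesh (``mesh_id``)
    so that they can be serialised, unified bilaterally, and transferred
    to differently triangulated meshes with :func:`map_area`.
    """

    mesh_id: str
    name: str
    triangle_ids: np.ndarray
    patch_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.triangle_ids = np.unique(np.asarray(self.triangle_ids, dtype=np.int64))

    @property
    def n_triangles(self) -> int:
        return len(self.triangle_ids)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "mesh_id": self.mesh_id,
            "name": self.name,
            "triangle_ids": self.triangle_ids.tolist(),
            "patch_seeds": list(self.patch_seeds),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "MeasurementArea":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mesh_id=payload["mesh_id"],
            name=payload["name"],
            triangle_ids=np.asarray(payload["triangle_ids"], dtype=np.int64),
            patch_seeds=list(payload.get("patch_seeds", [])),
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_FORMATS = {"stl", "obj", "ply"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return fmt


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> TriMesh:
    """Read an STL/OBJ/PLY mesh.

    STL stores free triangles; duplicated corner coordinates are re-welded
    by exact coordinate match so indexed topology round-trips.
    """
    path = os.fspath(path)
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise FileNotFoundError(f"mesh file does not exist: {path}")
    try:
        loaded = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:
        raise IOError(f"failed to parse {fmt.upper()} file {path!r}: {exc}") from exc
    if not isinstance(loaded, _trimesh.Trimesh) or len(loaded.faces) == 0 and len(loaded.vertices) == 0:
        raise IOError(f"failed to parse {fmt.upper()} file {path!r}: no mesh content")
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if fmt == "stl":
        verts, faces = _weld_exact(verts, faces)
    return TriMesh(verts, faces)


def _weld_exact(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices with bitwise-identical coordinates."""
    if len(vertices) == 0:
        return vertices, faces
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    uniq, first_idx, inverse = np.unique(
        vertices.view([("", vertices.dtype)] * 3), return_index=True, return_inverse=True
    )
    # preserve first-appearance order for stability
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(first_idx)], rank[inverse.ravel()][faces]


def write_mesh(mesh: TriMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    path = os.fspath(path)
    fmt = _infer_format(path, fmt)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"destination directory does not exist: {parent}")
    mesh.as_trimesh().export(path, file_type=fmt)


# ----------------------------------------------------------------------
# adjacency and patch growth
# ----------------------------------------------------------------------

def _face_adjacency_pairs(faces: np.ndarray) -> np.ndarray:
    """(k, 2) pairs of face ids sharing an edge."""
    if len(faces) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    owner = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    return np.column_stack([owner[:-1][same], owner[1:][same]])


def face_adjacency_graph(mesh: TriMesh):
    """Sparse symmetric edge-adjacency graph over faces."""
    pairs = _face_adjacency_pairs(mesh.faces)
    n = mesh.n_faces
    data = np.ones(len(pairs) * 2, dtype=np.int8)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def connected_face_components(mesh: TriMesh) -> np.ndarray:
    """Component label per face (edge connectivity)."""
    if mesh.n_faces == 0:
        return np.zeros(0, dtype=np.int64)
    _, labels = connected_components(face_adjacency_graph(mesh), directed=False)
    return labels


def grow_patch(
    mesh: TriMesh,
    seed_triangle: int,
    n_triangles: int,
    mesh_id: str = "",
    name: str = "custom",
) -> MeasurementArea:
    """Grow an approximately circular patch of exactly ``n_triangles``.

    Growth is breadth-first over edge adjacency from the seed triangle,
    ring by ring; within the final (partial) ring, triangles closest to
    the seed centroid are admitted first, which keeps the patch disc-like
    on smooth surfaces regardless of triangulation density.
    """
    if n_triangles < 1:
        raise ValueError("n_triangles must be >= 1")
    if n_triangles > mesh.n_faces:
        raise ValueError(
            f"requested {n_triangles} triangles but the mesh has only {mesh.n_faces}"
        )
    if not (0 <= seed_triangle < mesh.n_faces):
        raise ValueError(f"seed triangle {seed_triangle} out of range")

    graph = face_adjacency_graph(mesh)
    centroids = mesh.face_centroids()
    seed_c = centroids[seed_triangle]

    selected: list[int] = []
    in_patch = np.zeros(mesh.n_faces, dtype=bool)
    frontier = np.array([seed_triangle])
    in_patch[seed_triangle] = True
    while len(selected) < n_triangles:
        need = n_triangles - len(selected)
        if len(frontier) == 0:
            raise ValueError(
                f"reachable component holds only {len(selected)} triangles, "
                f"requested {n_triangles}"
            )
        if len(frontier) <= need:
            selected.extend(frontier.tolist())
        else:
            d = np.linalg.norm(centroids[frontier] - seed_c, axis=1)
            selected.extend(frontier[np.argsort(d, kind="stable")][:need].tolist())
            break
        nxt = np.unique(graph[frontier].indices)
        nxt = nxt[~in_patch[nxt]]
        in_patch[nxt] = True
        frontier = nxt
    return MeasurementArea(
        mesh_id=mesh_id,
        name=name,
        triangle_ids=np.asarray(selected, dtype=np.int64),
        patch_seeds=[int(seed_triangle)],
    )


def unify_areas(areas: list[MeasurementArea]) -> MeasurementArea:
    """Union of areas on one mesh (e.g. bilateral patches as one area)."""
    if not areas:
        raise ValueError("no areas to unify")
    mesh_ids = {a.mesh_id for a in areas}
    if len(mesh_ids) > 1:
        raise ValueError(f"areas live on different meshes: {sorted(mesh_ids)}")
    names = {a.name for a in areas}
    return MeasurementArea(
        mesh_id=areas[0].mesh_id,
        name=names.pop() if len(names) == 1 else "custom",
        triangle_ids=np.concatenate([a.triangle_ids for a in areas]),
        patch_seeds=[s for a in areas for s in a.patch_seeds],
    )


def apply_transform(mesh: TriMesh, transform) -> TriMesh:
    """Rigidly move a mesh: v' = R v + t. Topology is untouched."""
    return TriMesh(transform.apply(mesh.vertices), mesh.faces.copy())


def nearest_triangle(mesh: TriMesh, point) -> int:
    """Triangle whose centroid is closest to a world-coordinate anchor."""
    if mesh.n_faces == 0:
        raise ValueError("empty mesh has no triangles")
    d = np.linalg.norm(mesh.face_centroids() - np.asarray(point, dtype=float), axis=1)
    return int(np.argmin(d))


def map_area(
    area: MeasurementArea,
    source_mesh: TriMesh,
    target_mesh: TriMesh,
    target_mesh_id: str = "",
    gate_mm: float = 2.0,
) -> MeasurementArea:
    """Transfer an area to a differently triangulated, aligned mesh.

    The match is a deduplicated bidirectional centroid transfer: each
    source triangle centroid in the area admits its nearest target
    triangle, and every target triangle whose nearest source triangle
    belongs to the area is admitted too — so the region keeps its extent
    whether the target triangulation is coarser or finer than the
    source.  A median forward centroid distance above ``gate_mm``
    indicates the meshes are not actually aligned and is flagged with a
    warning.
    """
    if area.n_triangles == 0:
        raise ValueError("cannot map an empty measurement area")
    src_c = source_mesh.face_centroids(area.triangle_ids)
    tgt_c = target_mesh.face_centroids()
    dists, forward = cKDTree(tgt_c).query(src_c)
    if np.median(dists) > gate_mm:
        warnings.warn(
            f"area transfer gate exceeded: median centroid distance "
            f"{np.median(dists):.3f} mm > {gate_mm} mm — meshes may be misaligned",
            stacklevel=2,
        )
    _, nearest_src = cKDTree(source_mesh.face_centroids()).query(tgt_c)
    in_area = np.zeros(source_mesh.n_faces, dtype=bool)
    in_area[area.triangle_ids] = True
    reverse = np.nonzero(in_area[nearest_src])[0]
    return MeasurementArea(
        mesh_id=target_mesh_id,
        name=area.name,
        triangle_ids=np.union1d(forward, reverse),
        patch_seeds=[],
    )
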