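"""Single-threshold iso-surface segmentation of bone from a volume.

The clinical workflow extracts the facial skeletal surface as the level
set of one visually chosen grey value, via marching cubes with per-edge
linear interpolation.  The visual choice itself is *never* computed
here — the threshold is always an input (its operator variability is
simulated by :func:`osseosurf.phantom.sample_operator_thresholds`; for
phantoms the optimal value is the bone/water midpoint).  No smoothing
or decimation is applied after extraction: deviation metrics must see
the raw dense mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .mesh_ops import TriMesh, connected_face_components
from .volume_io import IntensityRange, Volume

__all__ = ["ThresholdRecord", "extract_isosurface", "keep_main_components"]


@dataclass(frozen=True)
class ThresholdRecord:
    """One recorded visual threshold selection (for reproducibility logs)."""

    volume_id: str
    operator_id: str
    session_index: int
    threshold: float
    full_range: float

    def __post_init__(self) -> None:
        if self.full_range <= 0:
            raise ValueError("full_range must be positive")


def extract_isosurface(
    volume: Volume,
    threshold: float,
    value_range: IntensityRange | None = None,
) -> TriMesh:
    """Triangle mesh of the level set {value = threshold} in world mm.

    Vertices are located by per-edge linear interpolation of the voxel
    grid (voxel-centre convention, spacing and origin applied), with
    consistent outward orientation: triangle normals point from
    higher-value bone toward the lower-value background.

    ``value_range``, when given (the scanner's declared grey range),
    gates the threshold; a threshold that simply misses the data (empty
    level set) yields an empty mesh with a warning rather than an error.
    """
    if value_range is not None and not (
        value_range.vmin < threshold < value_range.vmax
    ):
        raise ValueError(
            f"threshold {threshold} outside the value range "
            f"({value_range.vmin}, {value_range.vmax})"
        )
    data = volume.voxels
    if not (float(data.min()) < threshold < float(data.max())):
        warnings.warn(
            f"threshold {threshold} crosses no voxel values: empty level set",
            stacklevel=2,
        )
        return TriMesh.empty()
    verts, faces, _, _ = measure.marching_cubes(
        data.astype(np.float64),
        level=float(threshold),
        spacing=volume.spacing,
        gradient_direction="ascent",  # winding gives outward normals for high-value bone
    )
    verts = verts + np.asarray(volume.origin)
    return TriMesh(verts, faces.astype(np.int64))


def keep_main_components(mesh: TriMesh, min_triangle_fraction: float = 0.01) -> TriMesh:
    """Suppress noise speckle: keep only sufficiently large components.

    Retains every edge-connected component whose triangle count is at
    least ``min_triangle_fraction`` times the largest component's count;
    unreferenced vertices are compacted away.  ``min_triangle_fraction=0``
    is the identity.
    """
    if not (0.0 <= min_triangle_fraction <= 1.0):
        raise ValueError("min_triangle_fraction must be in [0, 1]")
    if mesh.is_empty:
        return TriMesh.empty()
    labels = connected_face_components(mesh)
    counts = np.bincount(labels)
    keep_labels = np.nonzero(counts >= min_triangle_fraction * counts.max())[0]
    keep = np.isin(labels, keep_labels)
    if keep.all():
        return mesh
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], remap[faces])
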