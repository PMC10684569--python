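"""Digital bone-in-water phantoms with analytic ground-truth surfaces.

Physical validation studies of CT/CBCT bone segmentation scan dry
skulls inside water-filled head shells (water emulates soft tissue) and
compare the segmented models against optical-scanner reference models.
This module provides the digital stand-in: a closed bone-density
surface embedded in a water-density background, rasterised with
partial-volume mixing, degraded by scanner-like blur and noise, plus a
ground-truth mesh sampled exactly from the analytic surface and a
simulator of operator-to-operator threshold variability.

All shapes are star-shaped around the origin: the surface is the set
``{ R(u)·u : ‖u‖ = 1 }`` for a smooth radius function ``R``.  The
``face-like`` family perturbs an ellipsoid with fixed low-order
sinusoidal terms, giving convex (zygoma-like) and concave
(maxilla-like) curvature without anatomical data.

The grey-value scale defaults to a 0–4000 full range with bone at 1500
and water at 0, so that a threshold difference of 10 grey values is
0.25% of the full range — the granularity at which operator threshold
variability is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
import yaml
from scipy import ndimage

from .mesh_ops import TriMesh
from .volume_io import IntensityRange, Volume

__all__ = [
    "PhantomSpec",
    "sphere_spec",
    "ellipsoid_spec",
    "face_like_spec",
    "surface_radius",
    "radial_signed_distance",
    "rasterize_phantom",
    "simulate_acquisition",
    "ground_truth_mesh",
    "degrade",
    "sample_operator_thresholds",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548

_FAMILIES = ("sphere", "ellipsoid", "face-like")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic acquisition.

    ``psf_fwhm`` (mm) and ``noise_sigma`` (grey values) describe the
    scanner-like degradation applied by :func:`simulate_acquisition`;
    they are engineering choices, not calibrated to any physical unit.
    """

    shape_family: str
    shape_params: dict
    bone_intensity: float = 1500.0
    water_intensity: float = 0.0
    intensity_full_range: float = 4000.0
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    grid_shape: tuple[int, int, int] | None = None
    psf_fwhm: float = 0.6
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_family not in _FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}; expected {_FAMILIES}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.bone_intensity <= self.water_intensity:
            raise ValueError("bone_intensity must exceed water_intensity")
        if self.intensity_full_range <= 0:
            raise ValueError("intensity_full_range must be positive")
        if self.psf_fwhm < 0 or self.noise_sigma < 0:
            raise ValueError("psf_fwhm and noise_sigma must be non-negative")
        amps = self.shape_params.get("perturb_amplitudes", ())
        min_axis = min(self._semi_axes())
        if sum(abs(a) for a in amps) > 0.5 * min_axis:
            raise ValueError(
                "perturbation amplitudes too large: surface may self-intersect "
                f"(sum |amp| > half the smallest semi-axis {min_axis} mm)"
            )

    def _semi_axes(self) -> tuple[float, float, float]:
        if self.shape_family == "sphere":
            r = float(self.shape_params["radius"])
            return (r, r, r)
        a, b, c = (float(v) for v in self.shape_params["semi_axes"])
        return (a, b, c)

    @property
    def midpoint_threshold(self) -> float:
        """Midpoint of the bone/water plateaus — the phantom's optimal threshold."""
        return 0.5 * (self.bone_intensity + self.water_intensity)

    @property
    def intensity_range(self) -> IntensityRange:
        return IntensityRange(self.water_intensity, self.water_intensity + self.intensity_full_range)

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return {
            "shape_family": self.shape_family,
            "shape_params": {
                k: (list(v) if isinstance(v, (list, tuple)) else v)
                for k, v in self.shape_params.items()
            },
            "bone_intensity": self.bone_intensity,
            "water_intensity": self.water_intensity,
            "intensity_full_range": self.intensity_full_range,
            "spacing": list(self.spacing),
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
            "psf_fwhm": self.psf_fwhm,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["spacing"] = tuple(d["spacing"])
        if d.get("grid_shape"):
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sphere_spec(radius: float = 25.0, **kwargs) -> PhantomSpec:
    return PhantomSpec("sphere", {"radius": float(radius)}, **kwargs)


def ellipsoid_spec(semi_axes=(25.0, 30.0, 20.0), **kwargs) -> PhantomSpec:
    return PhantomSpec("ellipsoid", {"semi_axes": [float(a) for a in semi_axes]}, **kwargs)


def face_like_spec(
    semi_axes=(24.0, 28.0, 22.0),
    perturb_amplitudes=(1.5, 2.0, 1.2),
    **kwargs,
) -> PhantomSpec:
    """Ellipsoid with fixed sinusoidal perturbations and concave recesses.

    The default 24/28/22 mm semi-axes give a desk-scale face analogue
    (frontal height ≈ 56 mm); the three amplitudes (mm) weight the fixed
    low-order harmonics below.
    """
    return PhantomSpec(
        "face-like",
        {
            "semi_axes": [float(a) for a in semi_axes],
            "perturb_amplitudes": [float(a) for a in perturb_amplitudes],
        },
        **kwargs,
    )


# ----------------------------------------------------------------------
# analytic surface
# ----------------------------------------------------------------------

def surface_radius(spec: PhantomSpec, directions: np.ndarray) -> np.ndarray:
    """Radius R(u) of the analytic surface along unit directions (n, 3)."""
    u = np.asarray(directions, dtype=np.float64).reshape(-1, 3)
    a, b, c = spec._semi_axes()
    if spec.shape_family == "sphere":
        return np.full(len(u), a)
    r_ell = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
    if spec.shape_family == "ellipsoid":
        return r_ell
    a1, a2, a3 = spec.shape_params["perturb_amplitudes"]
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    pert = (
        a1 * np.cos(2.0 * theta)
        + a2 * np.sin(3.0 * theta) * np.cos(2.0 * phi)
        + a3 * np.sin(4.0 * theta) * np.sin(3.0 * phi)
    )
    return r_ell + pert


def radial_signed_distance(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Radial signed distance to the analytic surface (negative inside).

    Exact for spheres; for star shapes this is ``‖p‖ − R(p/‖p‖)``, which
    approximates the Euclidean signed distance to first order near the
    surface (the approximation used by the partial-volume ramp).
    """
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    r = np.linalg.norm(p, axis=1)
    safe = np.where(r > 0, r, 1.0)
    u = p / safe[:, None]
    u[r == 0] = (0.0, 0.0, 1.0)
    return r - surface_radius(spec, u)


def _axis_extents(spec: PhantomSpec) -> np.ndarray:
    """Per-axis maximum |coordinate| of the surface (sampled)."""
    dirs = _trimesh.creation.icosphere(subdivisions=4, radius=1.0).vertices
    pts = surface_radius(spec, dirs)[:, None] * dirs
    return np.abs(pts).max(axis=0)


# ----------------------------------------------------------------------
# rasterisation and degradation
# ----------------------------------------------------------------------

def rasterize_phantom(spec: PhantomSpec) -> Volume:
    """Noise-free partial-volume rasterisation of the analytic surface.

    Each voxel takes a mixture of bone and water intensity weighted by
    the estimated fraction of the voxel inside the surface: a clamped
    linear ramp of one-voxel width on the radial signed distance at the
    voxel centre.  Deterministic; blur and noise are applied separately
    by :func:`degrade`.
    """
    spacing = np.asarray(spec.spacing)
    extents = _axis_extents(spec)
    if spec.grid_shape is None:
        half = extents + 4.0 * spacing
        shape = tuple(int(2 * math.ceil(h / s) + 1) for h, s in zip(half, spacing))
    else:
        shape = tuple(int(n) for n in spec.grid_shape)
        half_extent = (np.asarray(shape) - 1) / 2.0 * spacing
        needed = extents + 2.0 * spacing
        if np.any(half_extent < needed):
            raise ValueError(
                f"grid {shape} too small: needs half-extents ≥ {np.round(needed, 2)} mm "
                f"(shape + 2-voxel margin), has {np.round(half_extent, 2)} mm"
            )
    origin = tuple((-(n - 1) / 2.0 * s) for n, s in zip(shape, spacing))

    ramp_width = float(np.mean(spacing))
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    voxels = np.empty(shape, dtype=np.float64)
    # slab-wise along z to bound peak memory on fine grids
    slab = max(1, int(4e6 // (shape[0] * shape[1])))
    for z0 in range(0, shape[2], slab):
        z1 = min(z0 + slab, shape[2])
        gx, gy, gz = np.meshgrid(xs, ys, zs[z0:z1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d = radial_signed_distance(spec, pts).reshape(gx.shape)
        frac = np.clip(0.5 - d / ramp_width, 0.0, 1.0)
        voxels[:, :, z0:z1] = spec.water_intensity + (
            spec.bone_intensity - spec.water_intensity
        ) * frac
    return Volume(voxels=voxels, spacing=tuple(spacing), origin=origin)


def degrade(volume: Volume, psf_fwhm: float, noise_sigma: float, seed: int) -> Volume:
    """Apply scanner-like degradation: Gaussian PSF blur, then noise.

    ``psf_fwhm`` is the isotropic full width at half maximum in mm
    (converted to per-axis sigmas in voxels); ``noise_sigma`` is the
    standard deviation of additive white Gaussian noise in grey values.
    Identical (volume, parameters, seed) give bit-identical output.
    """
    if psf_fwhm < 0 or noise_sigma < 0:
        raise ValueError("psf_fwhm and noise_sigma must be non-negative")
    out = volume.voxels.astype(np.float64, copy=True)
    if psf_fwhm > 0:
        sigmas = [psf_fwhm / _FWHM_TO_SIGMA / s for s in volume.spacing]
        out = ndimage.gaussian_filter(out, sigma=sigmas)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return Volume(voxels=out, spacing=volume.spacing, origin=volume.origin,
                  axis_labels=volume.axis_labels)


def simulate_acquisition(spec: PhantomSpec) -> Volume:
    """Rasterise and degrade in one step using the spec's own parameters."""
    return degrade(rasterize_phantom(spec), spec.psf_fwhm, spec.noise_sigma, spec.seed)


# ----------------------------------------------------------------------
# ground truth and operator simulation
# ----------------------------------------------------------------------

def ground_truth_mesh(spec: PhantomSpec, target_edge_mm: float) -> TriMesh:
    """Closed mesh sampled exactly from the analytic surface.

    Stands in for the optical-scanner gold-standard model: a subdivided
    icosahedron is projected radially onto the surface, so every vertex
    lies on the analytic surface to floating-point precision and the
    median edge length approximates ``target_edge_mm``.
    """
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    coarse = _trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    r_med = float(np.median(surface_radius(spec, coarse.vertices)))
    base_edge = 1.0514622242382672  # icosahedron edge at unit circumradius
    subdivisions = max(0, math.ceil(math.log2(base_edge * r_med / target_edge_mm)))
    subdivisions = min(subdivisions, 9)
    unit = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(unit.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    verts = surface_radius(spec, dirs)[:, None] * dirs
    return TriMesh(verts, np.asarray(unit.faces))


def sample_operator_thresholds(
    base: float,
    spread_fraction: float,
    full_range: float,
    n: int,
    seed: int,
    value_range: IntensityRange | None = None,
) -> np.ndarray:
    """Simulated visually selected thresholds around a base value.

    Draws ``n`` thresholds uniformly from ``base ± spread_fraction ·
    full_range``, emulating intra-/inter-operator variability (observed
    threshold differences stay below ~2% of the scanner's full grey
    range).  Rejects draws that leave the volume's value range.
    """
    if spread_fraction < 0:
        raise ValueError("spread_fraction must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = spread_fraction * full_range
    rng = np.random.default_rng(seed)
    thresholds = rng.uniform(base - half, base + half, size=n)
    if spread_fraction == 0:
        thresholds = np.full(n, float(base))
    if value_range is not None:
        bad = (thresholds < value_range.vmin) | (thresholds > value_range.vmax)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} sampled thresholds fall outside the volume's value "
                f"range [{value_range.vmin}, {value_range.vmax}]"
            )
    return thresholds
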