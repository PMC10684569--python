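"""Radiographic volume container and I/O.

A :class:`Volume` is a 3D scalar grid with physical geometry attached.
Axes follow the craniofacial frame used throughout the package:
index axis 0 = X (lateral), axis 1 = Y (vertical), axis 2 = Z
(anteroposterior).  World coordinates use the voxel-centre convention::

    world(i, j, k) = origin + (i, j, k) * spacing

Grey values are kept exactly as stored (beyond the format's own
rescale slope/intercept): CBCT grey values are not standardised, so no
Hounsfield conversion is attempted.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "IntensityRange",
    "read_volume",
    "write_volume",
    "clip_display_range",
    "threshold_percent_of_range",
]

#: anatomical meaning of the three index axes
DEFAULT_AXIS_LABELS = ("lateral", "vertical", "anteroposterior")


@dataclass
class Volume:
    """3D radiographic image with voxel-centre world geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def value_range(self) -> "IntensityRange":
        """Observed min/max grey values of the data."""
        return IntensityRange(float(self.voxels.min()), float(self.voxels.max()))

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """World coordinates of the voxel centres along one index axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass(frozen=True)
class IntensityRange:
    """Grey-value window, e.g. a display window or a scanner's full range."""

    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.vmax < self.vmin:
            raise ValueError(f"vmax ({self.vmax}) < vmin ({self.vmin})")

    @property
    def full_range(self) -> float:
        return self.vmax - self.vmin

    def contains(self, value: float) -> bool:
        return self.vmin <= value <= self.vmax


def _sitk_to_volume(img: sitk.Image) -> Volume:
    # SimpleITK arrays are indexed (z, y, x); transpose into (x, y, z)
    arr = sitk.GetArrayFromImage(img)
    voxels = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return Volume(voxels=voxels, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def _volume_to_sitk(volume: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0))))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    return img


def read_volume(path: str | os.PathLike, dialect: str = "mha") -> Volume:
    """Read a radiographic volume.

    Parameters
    ----------
    path:
        File (``mha`` dialect) or directory containing a DICOM series
        (``dicom-series`` dialect).
    dialect:
        ``"mha"`` (MetaImage ``.mha``/``.mhd``+raw, used for fixtures) or
        ``"dicom-series"``.

    Returns
    -------
    Volume
        Grid, spacing (including anisotropic interslice spacing) and
        origin round-trip losslessly with :func:`write_volume`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume path does not exist: {path}")
    if dialect == "mha":
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:  # pragma: no cover - message passthrough
            raise IOError(f"failed to read volume {path!r}: {exc}") from exc
        return _sitk_to_volume(img)
    if dialect == "dicom-series":
        if not os.path.isdir(path):
            raise IOError(f"dicom-series dialect expects a directory, got {path!r}")
        reader = sitk.ImageSeriesReader()
        names = reader.GetGDCMSeriesFileNames(path)
        if not names:
            raise IOError(f"no DICOM series found under {path!r}")
        reader.SetFileNames(names)
        try:
            img = reader.Execute()
        except RuntimeError as exc:
            raise IOError(f"failed to read DICOM series under {path!r}: {exc}") from exc
        vol = _sitk_to_volume(img)
        _check_uniform_slice_spacing(names, vol)
        return vol
    raise ValueError(f"unknown dialect {dialect!r}; expected 'mha' or 'dicom-series'")


def _check_uniform_slice_spacing(names: list[str], vol: Volume, tol_mm: float = 1e-3) -> None:
    """Reject series whose slice positions are not uniformly spaced."""
    positions = []
    for name in names:
        fr = sitk.ImageFileReader()
        fr.SetFileName(name)
        fr.ReadImageInformation()
        try:
            ipp = fr.GetMetaData("0020|0032")
            positions.append(float(ipp.split("\\")[-1]))
        except RuntimeError:
            return  # position tags absent; trust the reader's geometry
    if len(positions) < 3:
        return
    steps = np.diff(np.asarray(positions))
    if steps.size and (np.max(steps) - np.min(steps)) > tol_mm:
        raise IOError(
            f"inconsistent DICOM slice spacing: steps range "
            f"{np.min(steps):.4f}..{np.max(steps):.4f} mm (tolerance {tol_mm} mm)"
        )


def write_volume(volume: Volume, path: str | os.PathLike, dialect: str = "mha") -> None:
    """Write a volume; only the MHA/MHD fixture dialect is writable."""
    path = os.fspath(path)
    if dialect != "mha":
        raise ValueError(f"write_volume supports only the 'mha' dialect, got {dialect!r}")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"destination directory does not exist: {parent}")
    sitk.WriteImage(_volume_to_sitk(volume), path, useCompression=False)


def clip_display_range(
    volume: Volume, low_quantile: float = 0.0, high_quantile: float = 1.0
) -> IntensityRange:
    """Display window after clipping irrelevant extreme grey values.

    Mirrors the contrast-enhancement step of the visual threshold
    workflow: the returned window ``[q_low, q_high]`` of the voxel-value
    distribution is a *view* contract — the voxel data are never mutated.
    A constant (degenerate) volume yields a zero-width window with a
    warning.
    """
    if not (0.0 <= low_quantile < high_quantile <= 1.0):
        raise ValueError(
            f"require 0 <= low_quantile < high_quantile <= 1, got "
            f"({low_quantile}, {high_quantile})"
        )
    lo, hi = np.quantile(volume.voxels, [low_quantile, high_quantile])
    rng = IntensityRange(float(lo), float(hi))
    if rng.full_range == 0.0:
        warnings.warn(
            "degenerate (constant) volume: display window has zero width",
            stacklevel=2,
        )
    return rng


def threshold_percent_of_range(threshold_diff: float, intensity_range: IntensityRange) -> float:
    """Express a threshold difference as a percentage of the full grey range.

    E.g. a difference of 10 grey values on a 4000-wide CT range is 0.25%.
    """
    if intensity_range.full_range <= 0:
        raise ValueError("intensity range has zero width; percentage undefined")
    return 100.0 * threshold_diff / intensity_range.full_range
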