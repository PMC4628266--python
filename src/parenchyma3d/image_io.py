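"""Voxel stack I/O, geometric calibration, and cropping.

All images are 3D arrays in (z, y, x) axis order with an isotropic voxel
pitch in micrometres.  Physical outputs follow a single unit convention:
volumes in mm^3, surfaces in mm^2, lengths in um.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelImage",
    "PhaseMasks",
    "read_stack",
    "write_stack",
    "write_mask",
    "crop_margins",
]


@dataclass
class VoxelImage:
    """A 3D grayscale voxel grid with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values (typically 8- or 16-bit attenuation grayscale).
    pitch_um : float
        Isotropic voxel edge length in micrometres (e.g. 5.14 for a
        typical desktop micro-CT scan of fruit tissue).
    name : str
        Free-text sample identifier.
    """

    data: np.ndarray
    pitch_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.pitch_um > 0:
            raise ValueError("pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3: (pitch_um / 1000)^3."""
        return (self.pitch_um / 1000.0) ** 3

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extents in micrometres."""
        return tuple(n * self.pitch_um for n in self.data.shape)


@dataclass
class PhaseMasks:
    """Disjoint binary masks of the cell and void phases on one grid."""

    cells: np.ndarray
    voids: np.ndarray
    pitch_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        self.voids = np.asarray(self.voids, dtype=bool)
        if self.cells.shape != self.voids.shape:
            raise ValueError("cells and voids must share a shape")
        if not self.pitch_um > 0:
            raise ValueError("pitch_um must be positive")

    def validate(self) -> None:
        """Check that the phases are disjoint and cover the domain."""
        if np.any(self.cells & self.voids):
            raise ValueError("cell and void phases overlap")
        if not np.all(self.cells | self.voids):
            raise ValueError("cell and void phases do not cover the domain")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cells.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.pitch_um / 1000.0) ** 3


_SLICE_SUFFIXES = (".tif", ".tiff", ".png")


def read_stack(path: str | os.PathLike, pitch_um: float, name: str | None = None) -> VoxelImage:
    """Read a multi-page TIFF or a directory of 2D slice images.

    Directory slices are stacked in lexicographic filename order; all
    slices must share one shape.  Intensities are preserved bit-exact.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise IOError(f"no slice images found in {path}")
        slices = []
        for f in files:
            if f.suffix.lower() in (".tif", ".tiff"):
                sl = tifffile.imread(f)
            else:
                import imageio.v3 as iio

                sl = iio.imread(f)
            if sl.ndim != 2:
                raise ValueError(f"slice {f.name} is not a 2D image (ndim={sl.ndim})")
            if slices and sl.shape != slices[0].shape:
                raise ValueError(
                    f"slice {f.name} shape {sl.shape} mismatches first slice {slices[0].shape}"
                )
            slices.append(sl)
        data = np.stack(slices, axis=0)
    else:
        if not path.exists():
            raise IOError(f"no such file: {path}")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
    return VoxelImage(data=data, pitch_um=pitch_um, name=name or path.stem)


def write_stack(path: str | os.PathLike, img: VoxelImage) -> None:
    """Write a VoxelImage as a multi-page TIFF."""
    tifffile.imwrite(Path(path), img.data)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit 0/255 multi-page TIFF."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def _crop_slices(
    shape: tuple[int, int, int], pitch_um: float, lateral_um: float, axial_um: float
) -> tuple[slice, slice, slice]:
    """Centered crop slices removing the given physical margins.

    ``axial_um`` is removed from each z face, ``lateral_um`` from each
    y and x face.  The retained extent is the physical extent minus
    twice the margin, rounded down to a whole number of voxels; the
    crop is centered (odd remainders favour the low side by one voxel).
    """
    margins_um = (axial_um, lateral_um, lateral_um)
    out = []
    for n, m_um in zip(shape, margins_um):
        if m_um < 0:
            raise ValueError("margins must be non-negative")
        keep = int(np.floor((n * pitch_um - 2.0 * m_um) / pitch_um + 1e-9))
        if keep < 1:
            raise ValueError(
                f"margin {m_um} um too large for extent {n * pitch_um} um (must be < half)"
            )
        left = (n - keep) // 2
        out.append(slice(left, left + keep))
    return tuple(out)


def crop_margins(img: VoxelImage, lateral_um: float, axial_um: float = 0.0) -> VoxelImage:
    """Trim the stack symmetrically, e.g. to discard mounting foam and
    cut-damaged edge cell layers before analysis.

    Lateral margins apply to the y/x faces, axial to the z faces.  The
    output is the centered prism whose physical size is the input size
    minus twice each margin, rounded down to whole voxels.
    """
    sl = _crop_slices(img.shape, img.pitch_um, lateral_um, axial_um)
    return VoxelImage(data=img.data[sl], pitch_um=img.pitch_um, name=img.name)
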