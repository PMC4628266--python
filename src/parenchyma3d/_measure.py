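"""Shared per-object 3D measurement primitives.

Surface areas use a triangulated isosurface (marching cubes) by default,
which is close to unbiased for objects more than a few voxels across;
simple face counting (which overestimates smooth surfaces by up to ~50 %)
is retained as a cross-check option.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

# 13 canonical digital directions: 3 axes, 6 face diagonals, 4 space diagonals.
_DIRECTIONS_13 = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, -1, 0),
        (1, 0, 1),
        (1, 0, -1),
        (0, 1, 1),
        (0, 1, -1),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (1, -1, -1),
    ],
    dtype=float,
)
_DIRECTIONS_13 /= np.linalg.norm(_DIRECTIONS_13, axis=1, keepdims=True)


def surface_area_um2(mask: np.ndarray, pitch_um: float, method: str = "mesh") -> float:
    """Surface area of a binary object in um^2.

    method='mesh' triangulates the 0.5-isosurface (low bias);
    method='faces' counts exposed voxel faces (biased high, kept for
    cross-checks against voxel-native tools).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0.0
    if method == "faces":
        padded = np.pad(mask, 1).astype(np.int8)
        n_faces = sum(
            int(np.abs(np.diff(padded, axis=ax)).sum()) for ax in range(3)
        )
        return n_faces * pitch_um**2
    if method != "mesh":
        raise ValueError(f"unknown surface method {method!r}")
    # mild Gaussian smoothing before isosurface extraction removes the
    # voxel staircase, which otherwise inflates smooth surfaces by ~9 %
    padded = np.pad(mask, 2).astype(np.float32)
    smooth = ndimage.gaussian_filter(padded, sigma=1.0)
    if smooth.max() <= 0.5:  # object too thin to survive smoothing
        smooth = padded
    verts, faces, _, _ = measure.marching_cubes(
        smooth, level=0.5, spacing=(pitch_um,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


def esd_um(volume_mm3: float) -> float:
    """Equivalent spherical diameter in um from a volume in mm^3."""
    return 1000.0 * (6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0)


def sphericity(volume_mm3: float, surface_mm2: float) -> float:
    """Surface of the equal-volume sphere over the object surface (1 for a ball)."""
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / surface_mm2)


def shape_factor(volume_mm3: float, surface_mm2: float) -> float:
    """Object surface over the lateral surface 4V/d_eq of the equal-volume,
    equal-ESD cylinder; 1.5 for a ball, larger for branched shapes."""
    d_eq_mm = esd_um(volume_mm3) / 1000.0
    return float(surface_mm2 * d_eq_mm / (4.0 * volume_mm3))


def elongation_from_coords(coords_vox: np.ndarray, pitch_um: float) -> float:
    """sqrt(lambda_max / lambda_min) of the voxel second-moment tensor.

    Each voxel is treated as a cube, contributing pitch^2/12 per axis to
    the central second moments, so single-voxel and planar objects stay
    finite (a voxel cube has elongation exactly 1).
    """
    pts = np.asarray(coords_vox, float) * pitch_um
    cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov) + (pitch_um**2 / 12.0) * np.eye(3)
    evals = np.linalg.eigvalsh(cov)
    return float(np.sqrt(evals[-1] / evals[0]))


def max_caliper_um(coords_vox: np.ndarray, pitch_um: float) -> float:
    """Maximum extent over the 13 canonical digital directions in um.

    Approximates the 3D Feret length of convex bodies to within ~3 %.
    One voxel pitch is added to the center-to-center extent to account
    for the finite voxel size.
    """
    pts = np.asarray(coords_vox, float) * pitch_um
    proj = pts @ _DIRECTIONS_13.T
    extents = proj.max(axis=0) - proj.min(axis=0) + pitch_um
    return float(extents.max())


def touches_border(slc: tuple[slice, ...], shape: tuple[int, ...]) -> bool:
    """Whether a label bounding box touches any of the 6 domain faces."""
    return any(s.start == 0 or s.stop == n for s, n in zip(slc, shape))


def label_coords(labels: np.ndarray, lab: int, slc: tuple[slice, ...]) -> np.ndarray:
    """(n, 3) voxel coordinates of one label, in full-grid indices."""
    sub = labels[slc] == lab
    coords = np.argwhere(sub)
    coords += [s.start for s in slc]
    return coords


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)
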