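"""Synthetic parenchyma phantoms with known ground truth.

Real fruit cortex tissue is a wall-to-wall packing of roughly convex cells
of ~150-250 um with the intercellular air space concentrated in narrow
channels along the cell-cell interfaces.  The generator emulates exactly
that: cells are the Voronoi regions of a Poisson-disk point process, and
voids are slabs of controllable thickness along the Voronoi faces.  The
face-slab thickness is calibrated by bisection so the voxelized phantom
hits a target porosity; deleting a (seeded, nested) random subset of faces
fragments the channel network, and an anisotropic distance metric
elongates cells and channels along a chosen axis.

Analytic fixtures (digital balls and tubes) with closed-form volume,
surface and length are provided for estimator validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from parenchyma3d.image_io import PhaseMasks, VoxelImage

__all__ = ["PhantomTruth", "generate_tissue", "generate_ball", "generate_tube"]


@dataclass
class PhantomTruth:
    """Ground truth of a generated tissue phantom.

    cell_centers/cell_radii are in um; channel_graph lists the kept
    cell-pair channels as ((center_i, center_j), half_thickness_um)
    segments.  cell_labels is the voxel-level Voronoi partition of the
    whole domain (label = center index + 1), the reference against which
    watershed separation is scored.
    """

    cell_centers: np.ndarray
    cell_radii: np.ndarray
    channel_graph: list
    porosity_target: float
    porosity_realized: float
    seed: int
    cell_labels: np.ndarray = field(repr=False, default=None)
    fragmentation: float = 0.0


def _hash_uniform(keys: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic uniform(0,1) scores from integer keys (splitmix64 mix)."""
    with np.errstate(over="ignore"):
        x = keys.astype(np.uint64) + np.uint64(seed + 1) * np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return (x >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))


def _poisson_disk(shape_um: np.ndarray, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing Poisson-disk sample filling the box at spacing ~min_dist."""
    # expected count for a saturated packing; cap attempts generously
    target = int(np.prod(shape_um) / (min_dist**3) * 2.5) + 8
    pts: list[np.ndarray] = []
    tree_pts = np.empty((0, 3))
    attempts = 0
    max_attempts = target * 40
    while attempts < max_attempts:
        cand = rng.uniform(0, shape_um, size=3)
        attempts += 1
        if len(pts) == 0:
            pts.append(cand)
            continue
        d = np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1))
        if d >= min_dist:
            pts.append(cand)
    return np.asarray(pts)


def generate_tissue(
    shape_um: tuple[float, float, float] = (1000.0, 1000.0, 1000.0),
    pitch_um: float = 8.0,
    mean_cell_diam_um: float = 200.0,
    porosity: float = 0.15,
    fragmentation: float = 0.2,
    anisotropy_axis: int | None = None,
    anisotropy_stretch: float = 2.0,
    snr: float = 5.0,
    seed: int = 0,
    channel_halfwidth_um: float | None = None,
) -> tuple[VoxelImage, PhaseMasks, PhantomTruth]:
    """Generate a parenchyma-like phantom with known ground truth.

    Parameters
    ----------
    shape_um : physical (z, y, x) extents of the domain.
    pitch_um : isotropic voxel pitch; cells must span >= 10 voxels.
    mean_cell_diam_um : nominal cell diameter (sets the Poisson-disk
        spacing; realized Voronoi cell sizes scatter around it).
    porosity : target void volume fraction; the channel thickness is
        calibrated so the realized value is within +-0.02.
    fragmentation : fraction in [0, 1] of cell-pair channels deleted.
        Deleted sets are nested in this parameter under a fixed seed, so
        raising it fragments the network monotonically.
    anisotropy_axis : 0, 1 or 2 to elongate cells/channels along that
        axis by ``anisotropy_stretch``; None for isotropic tissue.
    snr : contrast-to-noise ratio of the rendered grayscale image.
    seed : RNG seed; identical inputs give identical voxel data.
    channel_halfwidth_um : if given, fixes the channel half-thickness
        directly instead of calibrating it to ``porosity`` (the realized
        porosity is then whatever the geometry yields) — useful for
        studying porosity effects at constant channel radius.

    Returns
    -------
    (VoxelImage, PhaseMasks, PhantomTruth)
    """
    shape_um = np.asarray(shape_um, float)
    if mean_cell_diam_um < 10 * pitch_um:
        raise ValueError("mean_cell_diam_um must be >= 10 * pitch_um to resolve cells")
    if not 0.0 <= fragmentation <= 1.0:
        raise ValueError("fragmentation must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # metric stretch for anisotropic cells: shrink coordinates along the
    # axis before the nearest-center query, elongating Voronoi regions
    scale = np.ones(3)
    if anisotropy_axis is not None:
        scale[anisotropy_axis] = 1.0 / anisotropy_stretch

    centers = _poisson_disk(shape_um, 0.9 * mean_cell_diam_um, rng)
    nvox = np.maximum((shape_um / pitch_um).astype(int), 1)

    # slab-chunked nearest-two-centers query keeps peak memory flat
    tree = cKDTree(centers * scale)
    n_total = int(np.prod(nvox))
    margin = np.empty(n_total, np.float32)  # d2 - d1: 0 on Voronoi faces
    lab1 = np.empty(n_total, np.int32)
    lab2 = np.empty(n_total, np.int32)
    pair_score = np.empty(n_total, np.float32)
    ys = (np.arange(nvox[1]) + 0.5) * pitch_um
    xs = (np.arange(nvox[2]) + 0.5) * pitch_um
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    slab_n = nvox[1] * nvox[2]
    for iz in range(nvox[0]):
        z = (iz + 0.5) * pitch_um
        vox = np.column_stack([np.full(slab_n, z), yy.ravel(), xx.ravel()])
        dist, idx = tree.query(vox * scale, k=2)
        sl = slice(iz * slab_n, (iz + 1) * slab_n)
        margin[sl] = dist[:, 1] - dist[:, 0]
        lab1[sl] = idx[:, 0]
        lab2[sl] = idx[:, 1]
        key = np.minimum(idx[:, 0], idx[:, 1]) * len(centers) + np.maximum(
            idx[:, 0], idx[:, 1]
        )
        pair_score[sl] = _hash_uniform(key.astype(np.uint64), seed)

    # nested channel deletion: each unordered cell pair carries a fixed
    # uniform score; pairs with score < fragmentation are walled off, so
    # the deleted set only grows as the parameter is raised
    kept_pair = pair_score >= fragmentation

    def void_mask(t: float) -> np.ndarray:
        return (margin < t) & kept_pair

    if channel_halfwidth_um is not None:
        t_star = float(channel_halfwidth_um)
    else:
        # bisect the face-slab half-thickness to hit the porosity target
        t_lo, t_hi = 0.0, mean_cell_diam_um
        achievable = void_mask(t_hi).mean()
        if porosity > achievable + 0.02:
            raise ValueError(
                f"porosity {porosity} unreachable; achievable range is [0, {achievable:.3f}]"
            )
        for _ in range(40):
            t_mid = 0.5 * (t_lo + t_hi)
            if void_mask(t_mid).mean() < porosity:
                t_lo = t_mid
            else:
                t_hi = t_mid
        t_star = 0.5 * (t_lo + t_hi)
    voids = void_mask(t_star).reshape(tuple(nvox))
    realized = float(voids.mean())
    cells = ~voids
    cell_labels = (lab1 + 1).reshape(tuple(nvox)).astype(np.int32)

    # grayscale rendering: cells bright, air dark, additive Gaussian noise
    img = np.where(cells, 170.0, 60.0)
    sigma = (170.0 - 60.0) / snr
    img = img + rng.normal(0.0, sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    # ground-truth channel list: unique kept cell pairs realized as voids
    void_flat = voids.ravel()
    kept_keys = np.unique(
        np.minimum(lab1[void_flat], lab2[void_flat]).astype(np.int64) * len(centers)
        + np.maximum(lab1[void_flat], lab2[void_flat])
    )
    channel_graph = []
    for key in kept_keys:
        i, j = int(key // len(centers)), int(key % len(centers))
        channel_graph.append(((centers[i].copy(), centers[j].copy()), t_star))

    truth = PhantomTruth(
        cell_centers=centers,
        cell_radii=np.full(len(centers), mean_cell_diam_um / 2.0),
        channel_graph=channel_graph,
        porosity_target=float(porosity),
        porosity_realized=realized,
        seed=seed,
        cell_labels=cell_labels,
        fragmentation=float(fragmentation),
    )
    image = VoxelImage(data=img, pitch_um=pitch_um, name=f"phantom-seed{seed}")
    masks = PhaseMasks(cells=cells, voids=voids, pitch_um=pitch_um, name=image.name)
    return image, masks, truth


def generate_ball(diameter_um: float, pitch_um: float, pad_vox: int = 2) -> PhaseMasks:
    """Digital ball (as the void phase) with analytic volume pi*d^3/6."""
    r_vox = diameter_um / (2.0 * pitch_um)
    if 2 * r_vox < 4:
        raise ValueError("ball diameter must span >= 4 voxels")
    n = int(np.ceil(2 * r_vox)) + 2 * pad_vox + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.indices((n, n, n))
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r_vox**2
    return PhaseMasks(cells=~ball, voids=ball, pitch_um=pitch_um, name=f"ball-{diameter_um}um")


def generate_tube(
    length_um: float, diameter_um: float, axis: int, pitch_um: float, pad_vox: int = 2
) -> PhaseMasks:
    """Straight circular cylinder (as the void phase) along one axis."""
    r_vox = diameter_um / (2.0 * pitch_um)
    if 2 * r_vox < 4:
        raise ValueError("tube diameter must span >= 4 voxels")
    n_len = int(round(length_um / pitch_um))
    n_cross = int(np.ceil(2 * r_vox)) + 2 * pad_vox + 1
    shape = [n_cross, n_cross, n_cross]
    shape[axis] = n_len + 2 * pad_vox
    c = (n_cross - 1) / 2.0
    idx = np.indices(shape).astype(float)
    cross_axes = [a for a in range(3) if a != axis]
    radial2 = (idx[cross_axes[0]] - c) ** 2 + (idx[cross_axes[1]] - c) ** 2
    along = idx[axis]
    tube = (radial2 <= r_vox**2) & (along >= pad_vox) & (along < pad_vox + n_len)
    return PhaseMasks(
        cells=~tube, voids=tube, pitch_um=pitch_um, name=f"tube-{length_um}x{diameter_um}um"
    )
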