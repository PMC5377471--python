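"""Micro-CT burrow morphometrics.

In a reconstructed CT volume of a sediment core, gray level tracks bulk
density: bright voxels are sediment, dark voxels are burrow lumen (void).
Burrows are segmented by threshold-based seed-point region growing — every
voxel at or below a gray threshold that is connected (6- or 26-neighbour)
to a seed belongs to that seed's burrow system — and three morphometrics
are computed per aquarium:

``B_vol``  lumen volume, cm^3 (labelled voxel count x voxel volume; exact).
``B_SA``   burrow wall surface area, cm^2, from a marching-cubes iso-surface
           of the labelled set.  Voxel-face counting overestimates smooth
           surfaces by tens of percent (staircase artifact), so the binary
           indicator is Gaussian-smoothed (sigma = 1 voxel) before meshing;
           this brings analytic test shapes within ~1%.  Faces capping the
           burrow openings at the sediment surface are excluded by default
           (an opening is water, not burrow wall).
``B_max``  maximum depth of any labelled voxel below the local sediment
           surface, cm.

The volume's first axis is depth (slice index increases downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelVolume",
    "BurrowSegmentation",
    "BurrowMetrics",
    "grow_regions",
    "auto_seed",
    "auto_threshold",
    "burrow_metrics",
    "analyze_volume",
]

#: default physical voxel size of the scanner, cm (81 um)
DEFAULT_VOXEL_SIZE_CM = 81e-4


@dataclass
class VoxelVolume:
    """A 3D grayscale reconstruction (8-bit), axis 0 pointing down into the bed."""

    voxels: np.ndarray  # (Z, Y, X) uint8
    voxel_size_cm: float = DEFAULT_VOXEL_SIZE_CM
    up_axis: str = "z"
    aquarium_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 2:
            raise ValueError("VoxelVolume.voxels must be 3D and non-degenerate on every axis")
        if not self.voxel_size_cm > 0:
            raise ValueError("voxel_size_cm must be positive")
        if v.dtype != np.uint8:
            # linear rescale of higher-bit data to 0..255
            v = v.astype(float)
            lo, hi = v.min(), v.max()
            v = np.zeros_like(v) if hi == lo else (v - lo) * (255.0 / (hi - lo))
            v = np.round(v).astype(np.uint8)
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BurrowSegmentation:
    """Labelled burrow systems: 0 = matrix, 1..k = components in seed order."""

    labels: np.ndarray  # (Z, Y, X) int
    components: list  # [(id, voxel_count, seed_point), ...]
    threshold: int
    connectivity: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class BurrowMetrics:
    B_max_cm: float
    B_SA_cm2: float
    B_vol_cm3: float
    n_components: int
    aquarium_id: str = ""

    def as_dict(self) -> dict:
        return {
            "aquarium_id": self.aquarium_id,
            "B_max_cm": self.B_max_cm,
            "B_SA_cm2": self.B_SA_cm2,
            "B_vol_cm3": self.B_vol_cm3,
            "n_components": self.n_components,
        }


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def grow_regions(
    volume: VoxelVolume,
    seeds: list[tuple[int, int, int]],
    threshold: int,
    connectivity: int = 26,
) -> BurrowSegmentation:
    """Threshold-based seed-point region growing.

    Each output component is the maximal connected set of voxels with
    gray <= ``threshold`` reachable from its seed.  Seeds falling in the
    same connected component merge into one id; ids are assigned in seed
    order, so labelling is deterministic.
    """
    if not seeds:
        raise ValueError("empty seed list (use auto_seed to generate seeds)")
    v = volume.voxels
    sub = v <= threshold
    for s in seeds:
        s = tuple(int(c) for c in s)
        if any(c < 0 or c >= n for c, n in zip(s, v.shape)):
            raise ValueError(f"seed {s} outside volume of shape {v.shape}")
        if not sub[s]:
            raise ValueError(f"seed {s} has gray {int(v[s])} > threshold {threshold}")
    comp, _ = ndimage.label(sub, structure=_structure(connectivity))
    labels = np.zeros_like(comp, dtype=np.int32)
    components = []
    next_id = 0
    seen: dict[int, int] = {}
    for s in seeds:
        s = tuple(int(c) for c in s)
        cid = int(comp[s])
        if cid in seen:
            continue
        next_id += 1
        seen[cid] = next_id
        sel = comp == cid
        labels[sel] = next_id
        components.append((next_id, int(sel.sum()), s))
    return BurrowSegmentation(
        labels=labels, components=components, threshold=int(threshold), connectivity=connectivity
    )


def auto_threshold(volume: VoxelVolume, surface_elevation: np.ndarray | int = 0) -> int:
    """Otsu's bimodal split of the below-interface gray histogram."""
    below = _below_surface_mask(volume.shape, surface_elevation)
    return int(round(threshold_otsu(volume.voxels[below])))


def _below_surface_mask(shape: tuple[int, int, int], surface_elevation) -> np.ndarray:
    z = np.arange(shape[0])[:, None, None]
    e = np.asarray(surface_elevation)
    if e.ndim == 0:
        return np.broadcast_to(z >= int(e), shape)
    if e.shape != shape[1:]:
        raise ValueError("surface_elevation map must have shape (Y, X)")
    return z >= e[None, :, :]


def auto_seed(
    volume: VoxelVolume,
    threshold: int,
    min_component_voxels: int = 50,
    connectivity: int = 26,
    surface_elevation: np.ndarray | int = 0,
) -> list[tuple[int, int, int]]:
    """One seed per sub-threshold component that reaches below the surface.

    Components whose voxels lie entirely above the sediment surface (the
    overlying water) are excluded, as are components smaller than
    ``min_component_voxels``.  The returned seed for each component is its
    first below-surface voxel in scan order.  May return an empty list.
    """
    sub = volume.voxels <= threshold
    comp, n = ndimage.label(sub, structure=_structure(connectivity))
    if n == 0:
        return []
    below = _below_surface_mask(volume.shape, surface_elevation)
    counts = np.bincount(comp.ravel(), minlength=n + 1)
    seeds = []
    comp_below = np.where(below, comp, 0)
    for cid in range(1, n + 1):
        if counts[cid] < min_component_voxels:
            continue
        idx = np.argwhere(comp_below == cid)
        if idx.size == 0:  # touches only the water region
            continue
        seeds.append(tuple(int(c) for c in idx[0]))
    return seeds


def _mesh_area_vox(
    mask: np.ndarray,
    surface_elevation,
    include_openings: bool,
    smooth_sigma: float,
    extend: int = 4,
) -> float:
    """Iso-surface area of ``mask`` in voxel^2 units."""
    if include_openings:
        f = np.pad(mask.astype(float), 2)
        if smooth_sigma > 0:
            g = ndimage.gaussian_filter(f, smooth_sigma)
            # tiny components can be smoothed below the iso level; fall
            # back to the unsmoothed indicator for them
            f = g if g.max() > 0.5 else f
        verts, faces, _, _ = measure.marching_cubes(f, level=0.5)
        return float(measure.mesh_surface_area(verts, faces))
    # Openings excluded: replicate each surface-layer void voxel upward so the
    # mesh never caps an opening, then drop triangles above the local surface.
    e = np.broadcast_to(np.asarray(surface_elevation), mask.shape[1:]).astype(int)
    ext = np.zeros((extend,) + mask.shape[1:], dtype=bool)
    m = np.concatenate([ext, mask], axis=0)
    Y, X = np.indices(mask.shape[1:])
    ez = np.clip(e, 0, mask.shape[0] - 1)
    open_yx = mask[ez, Y, X]
    for k in range(1, extend + 1):
        zk = ez - k + extend  # row in extended array, k voxels above the surface
        inside = zk >= 0
        m[zk[inside & open_yx], Y[inside & open_yx], X[inside & open_yx]] = True
    f = np.pad(m.astype(float), ((0, 2), (2, 2), (2, 2)))
    if smooth_sigma > 0:
        g = ndimage.gaussian_filter(f, smooth_sigma)
        f = g if g.max() > 0.5 else f
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5)
    verts = verts - np.array([extend, 2.0, 2.0])  # back to original voxel coords
    tri = verts[faces]
    cz = tri[:, :, 0].mean(axis=1)
    cy = np.clip(np.round(tri[:, :, 1].mean(axis=1)).astype(int), 0, mask.shape[1] - 1)
    cx = np.clip(np.round(tri[:, :, 2].mean(axis=1)).astype(int), 0, mask.shape[2] - 1)
    keep = cz >= e[cy, cx] - 0.25
    tri = tri[keep]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def burrow_metrics(
    seg: BurrowSegmentation,
    volume: VoxelVolume,
    surface_elevation: np.ndarray | int = 0,
    include_openings: bool = False,
    smooth_sigma: float = 1.0,
) -> BurrowMetrics:
    """Compute B_max, B_SA and B_vol from a segmentation.

    ``surface_elevation`` is the slice index of the sediment surface, either
    a scalar (flat-plane) or a per-(y, x) map; a voxel at slice z has depth
    ``(z - elevation + 1) * voxel_size`` (its lower face).  An empty
    segmentation returns all-zero metrics.
    """
    if seg.labels.shape != volume.shape:
        raise ValueError("segmentation is not aligned to the volume")
    vs = volume.voxel_size_cm
    mask = seg.mask
    count = int(mask.sum())
    if count == 0:
        return BurrowMetrics(0.0, 0.0, 0.0, 0, volume.aquarium_id)
    b_vol = count * vs**3
    e = np.broadcast_to(np.asarray(surface_elevation), mask.shape[1:]).astype(float)
    zz, yy, xx = np.nonzero(mask)
    b_max = float(np.max(zz - e[yy, xx] + 1.0)) * vs
    area_vox = _mesh_area_vox(mask, surface_elevation, include_openings, smooth_sigma)
    return BurrowMetrics(
        B_max_cm=b_max,
        B_SA_cm2=area_vox * vs**2,
        B_vol_cm3=b_vol,
        n_components=seg.n_components,
        aquarium_id=volume.aquarium_id,
    )


def analyze_volume(
    volume: VoxelVolume,
    threshold: int | None = None,
    connectivity: int = 26,
    min_component_voxels: int = 50,
    surface_elevation: np.ndarray | int = 0,
    include_openings: bool = False,
) -> BurrowMetrics:
    """Full CT chain: threshold -> seeds -> region growing -> morphometrics."""
    if threshold is None:
        threshold = auto_threshold(volume, surface_elevation)
    seeds = auto_seed(volume, threshold, min_component_voxels, connectivity, surface_elevation)
    if not seeds:
        empty = BurrowSegmentation(
            labels=np.zeros(volume.shape, dtype=np.int32),
            components=[],
            threshold=int(threshold),
            connectivity=connectivity,
        )
        return burrow_metrics(empty, volume, surface_elevation, include_openings)
    seg = grow_regions(volume, seeds, threshold, connectivity)
    return burrow_metrics(seg, volume, surface_elevation, include_openings)
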