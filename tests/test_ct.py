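"""CT chain: region growing, auto-seeding, burrow morphometrics."""

import numpy as np
import pytest

from bioturbaton import (
    BurrowSegmentation,
    VoxelVolume,
    archetype,
    auto_seed,
    auto_threshold,
    burrow_metrics,
    grow_regions,
    make_burrow_volume,
)
from conftest import flood_fill_oracle

MATRIX, VOID = 200, 25


def volume_with(mask, voxel_size_cm=0.05):
    gray = np.full(mask.shape, MATRIX, dtype=np.uint8)
    gray[mask] = VOID
    return VoxelVolume(gray, voxel_size_cm)


class TestGrowRegions:
    def test_isolated_cube(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        seg = grow_regions(volume_with(mask), [(4, 4, 4)], threshold=112)
        assert seg.components == [(1, 27, (4, 4, 4))]
        assert np.array_equal(seg.labels > 0, mask)

    def test_noise_free_shaft_equals_ground_truth(self, shaft_volume_clean):
        vol, gt = shaft_volume_clean
        seeds = auto_seed(vol, 112, min_component_voxels=10)
        seg = grow_regions(vol, seeds, 112)
        assert np.array_equal(seg.mask, gt.burrow_mask)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(10):
            shape = tuple(rng.integers(6, 20, size=3))
            gray = rng.integers(0, 256, size=shape).astype(np.uint8)
            sub = np.argwhere(gray <= 100)
            if sub.size == 0:
                continue
            seed = tuple(int(c) for c in sub[rng.integers(len(sub))])
            vol = VoxelVolume(gray, 0.01)
            seg = grow_regions(vol, [seed], 100, connectivity)
            mine = set(map(tuple, np.argwhere(seg.labels == 1)))
            assert mine == flood_fill_oracle(gray, seed, 100, connectivity)

    def test_seeds_in_same_component_merge(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 5, 5] = True
        seg = grow_regions(volume_with(mask), [(2, 5, 5), (7, 5, 5)], 112)
        assert seg.n_components == 1

    def test_deterministic_label_order(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:9, 6:9, 6:9] = True
        seg = grow_regions(volume_with(mask), [(7, 7, 7), (1, 1, 1)], 112)
        assert seg.labels[7, 7, 7] == 1  # first seed gets label 1
        assert seg.labels[1, 1, 1] == 2

    def test_bad_seeds_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2, 2] = True
        vol = volume_with(mask)
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            grow_regions(vol, [(0, 0, 0)], 112)  # matrix voxel above threshold
        with pytest.raises(ValueError, match="outside"):
            grow_regions(vol, [(99, 0, 0)], 112)
        with pytest.raises(ValueError, match="seed"):
            grow_regions(vol, [], 112)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        gray = rng.integers(0, 256, size=(12, 12, 12)).astype(np.uint8)
        seed = tuple(int(c) for c in np.argwhere(gray <= 60)[0])
        vol = VoxelVolume(gray, 0.01)
        lo = set(map(tuple, np.argwhere(grow_regions(vol, [seed], 60).labels == 1)))
        hi = set(map(tuple, np.argwhere(grow_regions(vol, [seed], 140).labels == 1)))
        assert lo <= hi

    def test_connectivity_ordering(self):
        rng = np.random.default_rng(2)
        gray = rng.integers(0, 256, size=(12, 12, 12)).astype(np.uint8)
        seed = tuple(int(c) for c in np.argwhere(gray <= 100)[0])
        vol = VoxelVolume(gray, 0.01)
        c6 = set(map(tuple, np.argwhere(grow_regions(vol, [seed], 100, 6).labels == 1)))
        c26 = set(map(tuple, np.argwhere(grow_regions(vol, [seed], 100, 26).labels == 1)))
        assert c6 <= c26


class TestAutoSeed:
    def test_empty_volume_no_seeds(self):
        vol = volume_with(np.zeros((10, 10, 10), dtype=bool))
        assert auto_seed(vol, 112) == []

    def test_two_separate_tubes_two_seeds(self):
        mask = np.zeros((30, 20, 20), dtype=bool)
        mask[0:20, 4:7, 4:7] = True
        mask[0:10, 13:16, 13:16] = True
        seeds = auto_seed(volume_with(mask), 112, min_component_voxels=5)
        assert len(seeds) == 2

    def test_seed_count_matches_ground_truth_systems(self):
        vol, gt = make_burrow_volume(archetype("gallery_diffuser"), (160, 70, 70), seed=2)
        thr = auto_threshold(vol)
        seeds = auto_seed(vol, thr, min_component_voxels=50)
        assert len(seeds) == gt.n_burrow_systems

    def test_min_component_filters_specks(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[0:10, 4:7, 4:7] = True  # 90 voxels
        mask[15, 15, 15] = True  # single speck
        seeds = auto_seed(volume_with(mask), 112, min_component_voxels=5)
        assert len(seeds) == 1

    def test_water_only_components_excluded(self):
        # dark water layer above the surface, plus a burrow below it
        gray = np.full((30, 12, 12), MATRIX, dtype=np.uint8)
        gray[:4] = 10  # water above surface at slice 4
        gray[8:20, 5:7, 5:7] = VOID  # burrow not connected to the water
        vol = VoxelVolume(gray, 0.05)
        seeds = auto_seed(vol, 112, min_component_voxels=5, surface_elevation=4)
        assert len(seeds) == 1
        assert seeds[0][0] >= 4


class TestBurrowMetrics:
    def test_single_voxel_unit_cube(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        vol = volume_with(mask, voxel_size_cm=0.1)
        seg = grow_regions(vol, [(2, 2, 2)], 112)
        m = burrow_metrics(seg, vol)
        assert m.B_vol_cm3 == pytest.approx(0.001)

    def test_empty_segmentation_all_zero(self):
        vol = volume_with(np.zeros((6, 6, 6), dtype=bool))
        seg = BurrowSegmentation(np.zeros((6, 6, 6), np.int32), [], 112, 26)
        m = burrow_metrics(seg, vol)
        assert (m.B_vol_cm3, m.B_SA_cm2, m.B_max_cm, m.n_components) == (0.0, 0.0, 0.0, 0)

    def test_cylinder_volume_and_area_analytic(self):
        r, h = 15, 40
        zz, yy, xx = np.mgrid[0:50, 0:40, 0:40]
        cyl = ((yy - 20) ** 2 + (xx - 20) ** 2 <= r * r) & (zz < h)
        vol = volume_with(cyl, voxel_size_cm=0.0081)
        seg = grow_regions(vol, [(0, 20, 20)], 112)
        m = burrow_metrics(seg, vol)
        vs = 0.0081
        assert m.B_vol_cm3 == cyl.sum() * vs**3  # voxel-count identity, exact
        assert m.B_vol_cm3 == pytest.approx(np.pi * r * r * h * vs**3, rel=0.02)
        lateral_base = (2 * np.pi * r * h + np.pi * r * r) * vs**2
        assert m.B_SA_cm2 == pytest.approx(lateral_base, rel=0.03)
        assert m.B_max_cm == pytest.approx(h * vs)

    def test_sphere_mesh_area_convergence(self):
        r = 15
        zz, yy, xx = np.mgrid[-20:21, -20:21, -20:21]
        sph = zz * zz + yy * yy + xx * xx <= r * r
        vol = volume_with(sph, voxel_size_cm=0.01)
        seg = grow_regions(vol, [(20, 20, 20)], 112)
        m = burrow_metrics(seg, vol, include_openings=True)
        assert m.B_SA_cm2 == pytest.approx(4 * np.pi * (r * 0.01) ** 2, rel=0.03)

    def test_gallery_deeper_than_u_tube(self):
        maxima = {}
        for name in ("gallery_diffuser", "u_tube"):
            vol, _ = make_burrow_volume(archetype(name), (160, 70, 70), seed=4)
            thr = auto_threshold(vol)
            seg = grow_regions(vol, auto_seed(vol, thr, 30), thr)
            maxima[name] = burrow_metrics(seg, vol).B_max_cm
        assert maxima["gallery_diffuser"] > maxima["u_tube"]

    def test_higher_bit_input_rescaled(self):
        v16 = (np.random.default_rng(0).integers(0, 4096, size=(8, 8, 8))).astype(np.uint16)
        vol = VoxelVolume(v16, 0.01)
        assert vol.voxels.dtype == np.uint8
        assert vol.voxels.max() == 255 and vol.voxels.min() == 0
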