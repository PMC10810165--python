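"""Delineation, splitting and stain detection against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from islet3d import PipelineConfig, delineate_islets, detect_stain, islet_volume, split_touching
from islet3d.imageio import MarkerParams

from conftest import ball, bfs_label_26, make_grid


class TestDelineate:
    def test_sphere_volume_within_two_percent(self, sphere_grid, half_config):
        grid, _ = sphere_grid
        lab = delineate_islets(grid, half_config)
        assert lab.n_islets == 1
        analytic = 4.0 / 3.0 * np.pi * 75.0**3
        assert abs(islet_volume(lab, 1) - analytic) / analytic < 0.02

    def test_all_zero_grid_yields_no_islets(self):
        grid = make_grid({"nuclei": np.zeros((20, 20, 20), np.uint16)})
        lab = delineate_islets(grid, PipelineConfig(islet_threshold=10.0))
        assert lab.n_islets == 0

    def test_two_separated_spheres_match_bfs_oracle(self):
        shape = (40, 40, 120)
        m = ball(shape, (20, 20, 30), 12) | ball(shape, (20, 20, 90), 10)
        grid = make_grid({"nuclei": np.where(m, 1000, 0).astype(np.uint16)})
        cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0,
                             min_islet_volume_um3=100.0, split_touching=False)
        lab = delineate_islets(grid, cfg)
        assert lab.n_islets == 2
        oracle = bfs_label_26(m)
        # labels sorted by decreasing size; match components as voxel sets
        for k in (1, 2):
            ours = lab.labels == k
            matched = oracle == oracle[tuple(np.argwhere(ours)[0])]
            assert np.array_equal(ours, matched)

    def test_internal_cavities_are_filled(self):
        shape = (40, 40, 40)
        shell = ball(shape, (20, 20, 20), 15) & ~ball(shape, (20, 20, 20), 6)
        grid = make_grid({"nuclei": np.where(shell, 1000, 0).astype(np.uint16)})
        cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0, min_islet_volume_um3=10.0)
        lab = delineate_islets(grid, cfg)
        assert lab.n_islets == 1
        assert lab.mask(1)[20, 20, 20]  # cavity belongs to the islet

    def test_channel_order_invariance(self, rng):
        a = rng.integers(0, 3000, size=(15, 15, 15), dtype=np.uint16)
        b = rng.integers(0, 3000, size=(15, 15, 15), dtype=np.uint16)
        cfg = PipelineConfig(islet_threshold=2000.0, min_islet_volume_um3=50.0)
        lab1 = delineate_islets(make_grid({"nuclei": a, "laminin": b}), cfg)
        lab2 = delineate_islets(make_grid({"laminin": b, "nuclei": a}), cfg)
        assert np.array_equal(lab1.labels, lab2.labels)

    def test_min_volume_monotonicity(self):
        shape = (30, 30, 60)
        m = ball(shape, (15, 15, 15), 10) | ball(shape, (15, 15, 45), 5)
        grid = make_grid({"nuclei": np.where(m, 1000, 0).astype(np.uint16)})
        ks = []
        for mv in (10.0, 1000.0, 10000.0):
            cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0, min_islet_volume_um3=mv)
            ks.append(delineate_islets(grid, cfg).n_islets)
        assert ks == sorted(ks, reverse=True)


class TestSplitTouching:
    def test_overlapping_spheres_split_near_planted_centers(self):
        shape = (40, 40, 70)
        c1, c2 = (20, 20, 22), (20, 20, 44)  # r=12 spheres overlapping
        m = ball(shape, c1, 12) | ball(shape, c2, 12)
        grid = make_grid({"nuclei": np.where(m, 1000, 0).astype(np.uint16)})
        cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0,
                             min_islet_volume_um3=500.0, split_min_separation_um=10.0)
        lab = delineate_islets(grid, cfg)
        assert lab.n_islets == 1  # touching: one component before splitting
        split = split_touching(lab, grid, cfg)
        assert split.n_islets == 2
        cents = ndimage.center_of_mass(np.ones(shape), split.labels, [1, 2])
        found = sorted(c[2] for c in cents)
        for f, c in zip(found, sorted([c1[2], c2[2]])):
            assert abs(f - c) < 5.0  # µm (unit voxels)
        # voxel conservation
        assert (split.labels > 0).sum() == (lab.labels > 0).sum()

    def test_single_sphere_is_idempotent(self):
        shape = (40, 40, 40)
        m = ball(shape, (20, 20, 20), 13)
        grid = make_grid({"nuclei": np.where(m, 1000, 0).astype(np.uint16)})
        cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0, min_islet_volume_um3=500.0)
        lab = delineate_islets(grid, cfg)
        split = split_touching(lab, grid, cfg)
        assert np.array_equal(split.labels, lab.labels)

    def test_rejected_split_keeps_original_label(self):
        # two tiny lobes: any split would create parts under the volume floor
        shape = (30, 30, 40)
        m = ball(shape, (15, 15, 14), 5) | ball(shape, (15, 15, 23), 5)
        grid = make_grid({"nuclei": np.where(m, 1000, 0).astype(np.uint16)})
        cfg = PipelineConfig(sigma_islet_um=0.0, islet_threshold=500.0,
                             min_islet_volume_um3=2000.0, split_min_separation_um=5.0)
        lab = delineate_islets(grid, cfg)
        if lab.n_islets == 1:  # joined dumbbell
            split = split_touching(lab, grid, cfg)
            assert split.n_islets == 1


class TestDetectStain:
    def test_embedded_cube_detected_exactly(self):
        img = np.full((20, 20, 20), 100, np.uint16)
        img[5:10, 5:10, 5:10] = 1000
        grid = make_grid({"laminin": img})
        st = detect_stain(grid, "laminin", MarkerParams(sigma_um=0.0, threshold=500.0))
        expect = np.zeros((20, 20, 20), bool)
        expect[5:10, 5:10, 5:10] = True
        assert np.array_equal(st.mask, expect)

    def test_threshold_above_max_gives_empty_mask(self):
        grid = make_grid({"laminin": np.full((8, 8, 8), 100, np.uint16)})
        st = detect_stain(grid, "laminin", MarkerParams(sigma_um=0.0, threshold=1e6))
        assert not st.mask.any()

    def test_threshold_monotonicity(self, rng):
        img = rng.integers(0, 5000, size=(16, 16, 16), dtype=np.uint16)
        grid = make_grid({"laminin": img})
        prev = None
        for thr in (500.0, 1500.0, 3000.0):
            m = detect_stain(grid, "laminin", MarkerParams(sigma_um=1.0, threshold=thr)).mask
            if prev is not None:
                assert not np.any(m & ~prev)  # raising threshold never adds voxels
            prev = m

    def test_background_subtracted_matches_independent_oracle(self, rng):
        # linear intensity ramp plus a blob
        z, y, x = np.mgrid[0:24, 0:24, 0:24]
        img = (50 + 10 * x).astype(np.float64)
        img[8:14, 8:14, 8:14] += 2000
        grid = make_grid({"laminin": img.astype(np.uint16)})
        p = MarkerParams(sigma_um=1.0, threshold=800.0, mode="background_subtracted",
                         background_sigma_um=8.0)
        st = detect_stain(grid, "laminin", p)
        # oracle: independently coded subtract-then-threshold
        sm = ndimage.gaussian_filter(img, 1.0)
        bg = ndimage.gaussian_filter(img, 8.0)
        oracle = np.clip(sm - bg, 0, None) >= 800.0
        assert np.array_equal(st.mask, oracle)

    def test_unknown_marker_rejected(self):
        grid = make_grid({"laminin": np.zeros((4, 4, 4), np.uint16)})
        with pytest.raises(KeyError):
            detect_stain(grid, "insulin", MarkerParams(threshold=1.0))

    def test_stored_parameters_reproduce_mask(self, rng):
        img = rng.integers(0, 4000, size=(12, 12, 12), dtype=np.uint16)
        grid = make_grid({"laminin": img})
        st = detect_stain(grid, "laminin", MarkerParams(sigma_um=1.0, threshold=None))
        assert st.recompute_check(grid)


@pytest.mark.parametrize("seed", range(10))
def test_26_connectivity_agrees_with_bfs_oracle(seed):
    rng = np.random.default_rng(seed)
    m = rng.random((20, 20, 20)) < 0.25
    ours, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
    oracle = bfs_label_26(m)
    assert n == oracle.max()
    # same partition: component of every voxel has identical voxel set
    for c in range(1, n + 1):
        sel = ours == c
        ref = oracle == oracle[tuple(np.argwhere(sel)[0])]
        assert np.array_equal(sel, ref)
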