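"""Morphometric measures against voxel-counting and flood-fill oracles."""

import numpy as np
import pytest
from scipy import ndimage

from islet3d import (
    IsletLabeling,
    NoStainedAreaError,
    PhantomSpec,
    ca9_fraction,
    count_nodes,
    generate_islet_phantom,
    generate_viability_image,
    islet_volume,
    mean_intensity,
    quantify_holes,
    viability_ratio,
    volume_fraction,
)
from islet3d.imageio import MarkerParams
from islet3d.morphometry import MorphometryRecord
from islet3d.segmentation import StainMask

from conftest import ball, make_grid, oracle_holes_pct


def labeling_from(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> IsletLabeling:
    return IsletLabeling(labels=mask.astype(np.int32), voxel_size=voxel_size)


def stain_from(mask: np.ndarray, marker="laminin") -> StainMask:
    return StainMask(mask=mask, marker=marker, params=MarkerParams(), threshold_used=0.0)


class TestIsletVolume:
    def test_unit_voxels(self):
        m = np.zeros((10, 10, 10), bool)
        m.flat[:1000] = True
        assert islet_volume(labeling_from(m), 1) == pytest.approx(1000.0)

    def test_anisotropic_voxels(self):
        m = np.zeros((10, 10, 10), bool)
        m.flat[:1000] = True
        lab = labeling_from(m, voxel_size=(2.0, 0.5, 0.5))
        assert islet_volume(lab, 1) == pytest.approx(500.0)

    def test_unknown_id_rejected(self):
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(KeyError):
            islet_volume(labeling_from(m), 2)


class TestVolumeFraction:
    def test_simple_ratio(self, rng):
        islet = np.zeros((25, 25, 25), bool)
        islet[2:22, 2:22, 2:22] = True  # 8000 voxels
        stain = np.zeros_like(islet)
        stain[2:7, 2:22, 2:22] = True  # 2000 voxels inside
        assert volume_fraction(stain_from(stain), labeling_from(islet), 1) == pytest.approx(25.0)

    def test_stain_superset_gives_100(self):
        islet = ball((20, 20, 20), (10, 10, 10), 6)
        assert volume_fraction(stain_from(np.ones_like(islet)), labeling_from(islet), 1) == 100.0

    def test_outside_stain_ignored_and_matches_oracle(self, rng):
        islet = ball((24, 24, 24), (12, 12, 12), 8)
        stain = rng.random(islet.shape) < 0.3
        got = volume_fraction(stain_from(stain), labeling_from(islet), 1)
        expect = 100.0 * np.count_nonzero(stain & islet) / np.count_nonzero(islet)
        assert got == pytest.approx(expect)

    def test_scale_invariance(self):
        islet = ball((20, 20, 20), (10, 10, 10), 7)
        stain = ball((20, 20, 20), (10, 10, 10), 4)
        f1 = volume_fraction(stain_from(stain), labeling_from(islet, (1, 1, 1)), 1)
        f2 = volume_fraction(stain_from(stain), labeling_from(islet, (3, 0.4, 0.4)), 1)
        assert f1 == pytest.approx(f2)  # a pure ratio; volume scales, fraction does not


class TestCountNodes:
    def test_empty_stain_is_zero_nodes(self):
        islet = ball((16, 16, 16), (8, 8, 8), 6)
        n, vols = count_nodes(stain_from(np.zeros_like(islet)), labeling_from(islet), 1)
        assert (n, vols) == (0, [])

    def test_face_adjacent_spheres_are_one_component(self):
        shape = (20, 20, 40)
        islet = np.ones(shape, bool)
        m = ball(shape, (10, 10, 12), 4) | ball(shape, (10, 10, 20), 4)
        m[10, 10, 16] = True  # bridge voxel face-adjacent to both
        n, _ = count_nodes(stain_from(m), labeling_from(islet), 1, min_node_volume_um3=10.0)
        assert n == 1

    def test_min_volume_filter(self):
        shape = (20, 20, 40)
        islet = np.ones(shape, bool)
        m = ball(shape, (10, 10, 10), 5) | ball(shape, (10, 10, 30), 1)
        n, vols = count_nodes(stain_from(m), labeling_from(islet), 1, min_node_volume_um3=50.0)
        assert n == 1
        assert len(vols) == 1 and vols[0] > 400

    def test_planted_nodes_recovered_exactly(self, marker_params_half):
        spec = PhantomSpec(islet_radius_um=45, n_nodes=7, node_radius_um=5, seed=11,
                           voxel_size=(2.0, 2.0, 2.0))
        grid, truth = generate_islet_phantom(spec)
        from islet3d import detect_stain

        st = detect_stain(grid, "laminin", marker_params_half(truth.intensities["laminin"]))
        lab = labeling_from(truth.islet_mask, spec.voxel_size)
        n, vols = count_nodes(st, lab, 1)
        assert n == truth.node_count == len(vols)


class TestQuantifyHoles:
    def test_concentric_shell_analytic_fraction(self):
        shape = (110, 110, 110)
        islet = ball(shape, (55, 55, 55), 50)
        hole = ball(shape, (55, 55, 55), 20)
        st = stain_from(islet & ~hole, "ecadherin")
        got = quantify_holes(st, labeling_from(islet), 1)
        quantized = 100.0 * hole.sum() / islet.sum()
        assert got == pytest.approx(quantized)
        assert got == pytest.approx(100.0 * 20**3 / 50**3, abs=0.2)  # 6.4% analytic

    def test_fully_stained_islet_scores_zero(self):
        islet = ball((20, 20, 20), (10, 10, 10), 7)
        assert quantify_holes(stain_from(islet, "ecadherin"), labeling_from(islet), 1) == 0.0

    def test_surface_wedge_excluded_matches_flood_oracle(self):
        shape = (40, 40, 40)
        islet = ball(shape, (20, 20, 20), 15)
        stain = islet.copy()
        stain[18:23, 18:23, 20:] = False  # channel open to the surface
        stain &= islet
        hole = ball(shape, (20, 20, 8), 0)  # no enclosed cavity
        st = stain_from(stain, "ecadherin")
        lab = labeling_from(islet)
        got = quantify_holes(st, lab, 1, min_hole_volume_um3=5.0, boundary_margin_um=1.5)
        oracle = oracle_holes_pct(islet, stain, (1, 1, 1), 5.0, 1.5)
        assert got == pytest.approx(oracle)
        assert got == 0.0  # the wedge reaches the boundary shell

    def test_enclosed_cavity_plus_open_wedge(self):
        shape = (46, 46, 46)
        islet = ball(shape, (23, 23, 23), 18)
        cavity = ball(shape, (23, 23, 23), 6)
        stain = islet & ~cavity
        stain[21:26, 21:26, 36:] = False  # separate open wedge
        stain &= islet
        st = stain_from(stain, "ecadherin")
        got = quantify_holes(st, labeling_from(islet), 1, min_hole_volume_um3=5.0,
                             boundary_margin_um=1.5)
        oracle = oracle_holes_pct(islet, stain, (1, 1, 1), 5.0, 1.5)
        assert got == pytest.approx(oracle)
        assert got == pytest.approx(100.0 * cavity.sum() / islet.sum())


class TestMeanIntensity:
    def test_constant_channel(self):
        islet = ball((12, 12, 12), (6, 6, 6), 4)
        grid = make_grid({"ecadherin": np.full(islet.shape, 100, np.uint16)})
        assert mean_intensity(grid, "ecadherin", labeling_from(islet), 1) == 100.0

    def test_half_and_half(self):
        islet = np.zeros((10, 10, 10), bool)
        islet[2:4, :, :] = True
        img = np.zeros(islet.shape, np.uint16)
        img[3, :, :] = 200
        grid = make_grid({"ecadherin": img})
        assert mean_intensity(grid, "ecadherin", labeling_from(islet), 1) == pytest.approx(100.0)

    def test_random_channel_matches_sum_over_count(self, rng):
        islet = ball((15, 15, 15), (7, 7, 7), 5)
        img = rng.integers(0, 60000, size=islet.shape, dtype=np.uint16)
        grid = make_grid({"ecadherin": img})
        got = mean_intensity(grid, "ecadherin", labeling_from(islet), 1)
        assert got == pytest.approx(img[islet].sum() / islet.sum())


class TestViability:
    def test_disjoint_areas_give_paper_style_ratio(self):
        img = np.full((2, 20, 20), 10, np.uint16)
        img[0, :11, :16] = 1000  # green 176 px
        img[1, 15:18, :8] = 1000  # red 24 px, disjoint
        res = viability_ratio(img, green_threshold=500, red_threshold=500)
        assert res["viability"] == pytest.approx(176 / 200)

    def test_red_empty_means_fully_viable(self):
        img = np.full((2, 10, 10), 10, np.uint16)
        img[0, 2:8, 2:8] = 1000
        res = viability_ratio(img, green_threshold=500, red_threshold=500)
        assert res["viability"] == 1.0

    def test_no_stained_area_is_a_distinct_outcome(self):
        img = np.full((2, 10, 10), 10, np.uint16)
        with pytest.raises(NoStainedAreaError):
            viability_ratio(img, green_threshold=500, red_threshold=500)

    def test_phantom_recovery_with_otsu_defaults(self):
        img, truth = generate_viability_image(0.62, seed=5)
        res = viability_ratio(img)  # per-channel Otsu
        assert abs(res["viability"] - truth.viable_fraction) <= 0.03

    def test_physical_areas_reported(self):
        img = np.full((2, 10, 10), 10, np.uint16)
        img[0, :5, :10] = 1000
        res = viability_ratio(img, 500, 500, pixel_size_um=2.0)
        assert res["green_area_um2"] == pytest.approx(50 * 4.0)


def test_ca9_fraction_delegates_to_volume_fraction():
    islet = ball((20, 20, 20), (10, 10, 10), 7)
    rim = islet & ~ball((20, 20, 20), (10, 10, 10), 5)
    lab = labeling_from(islet)
    st = stain_from(rim, "ca9")
    assert ca9_fraction(st, lab, 1) == volume_fraction(st, lab, 1)
    assert ca9_fraction(stain_from(np.zeros_like(islet), "ca9"), lab, 1) == 0.0
    assert ca9_fraction(stain_from(islet, "ca9"), lab, 1) == 100.0


def test_record_invariants():
    with pytest.raises(ValueError, match="node_count"):
        MorphometryRecord(1, "ND5", "laminin", 100.0, 5.0, 10.0, node_count=2, node_volumes_um3=[1.0])
    with pytest.raises(ValueError, match="fraction"):
        MorphometryRecord(1, "ND5", "laminin", 100.0, 120.0, 10.0)
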