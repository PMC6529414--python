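import numpy as np
import pytest

from ctmorph import morphometry as mm
from ctmorph.exceptions import EmptyDomainError
from ctmorph.phantom import rasterize_tube

from conftest import random_test_mask


def exhaustive_distance_to_set(target, spacing):
    """Independent nearest-target search over all voxel pairs."""
    spacing = np.asarray(spacing, float)
    out = np.empty(target.shape)
    tgt = np.argwhere(target).astype(float)
    for idx in np.ndindex(target.shape):
        d2 = ((tgt - np.asarray(idx, float)) * spacing) ** 2
        out[idx] = np.sqrt(d2.sum(axis=1).min())
    return out


def exhaustive_edt_to_background(mask, spacing):
    """Independent nearest-background search including the one-voxel pad."""
    spacing = np.asarray(spacing, float)
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded).astype(float) - 1.0
    out = np.zeros(mask.shape)
    for idx in np.argwhere(mask):
        d2 = ((bg - idx.astype(float)) * spacing) ** 2
        out[tuple(idx)] = np.sqrt(d2.sum(axis=1).min())
    return out


class TestEDT:
    def test_face_edge_corner_distances(self):
        # distances to a single reference voxel: 1, sqrt(2), sqrt(3) for
        # face-, edge-, and corner-neighbors (no padding in distance_to_set)
        t = np.zeros((3, 3, 3), dtype=bool)
        t[1, 1, 1] = True
        d = mm.distance_to_set(t, 1.0).values
        assert d[1, 1, 1] == 0.0
        assert d[0, 1, 1] == pytest.approx(1.0)
        assert d[0, 0, 1] == pytest.approx(np.sqrt(2))
        assert d[0, 0, 0] == pytest.approx(np.sqrt(3))

    def test_pad_dominates_in_small_volume(self):
        # with the one-layer padding convention the boundary is background,
        # so in a 3x3x3 all-foreground cube every non-center voxel is 1.0
        m = np.ones((3, 3, 3), dtype=bool)
        m[1, 1, 1] = False
        d = mm.edt_to_background(m, 1.0).values
        assert d[1, 1, 1] == 0.0
        assert np.all(d[m] == pytest.approx(1.0))

    def test_isolated_voxel_distance_one(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert mm.edt_to_background(m, 1.0).values[2, 2, 2] == pytest.approx(1.0)

    def test_boundary_counts_as_background(self):
        m = np.ones((3, 3, 3), dtype=bool)
        assert mm.edt_to_background(m, 1.0).values[0, 0, 0] == pytest.approx(1.0)
        assert mm.edt_to_background(m, 1.0).values[1, 1, 1] == pytest.approx(2.0)

    def test_anisotropic_voxels(self):
        # background one step along a 2 µm axis and two steps along 1 µm axes
        m = np.ones((5, 5, 5), dtype=bool)
        m[3, 1, 1] = False  # one z-step from (2,1,1)
        m[2, 1, 3] = False  # two x-steps from (2,1,1)
        d = mm.edt_to_background(m[:, :3, :], (2.0, 1.0, 1.0))
        # both candidates are 2.0 µm away; interior voxel (2,1,1)
        assert d.values[2, 1, 1] == pytest.approx(2.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        m = rng.random((8, 8, 8)) < 0.6
        got = mm.edt_to_background(m, (1.0, 0.876, 1.148)).values
        want = exhaustive_edt_to_background(m, (1.0, 0.876, 1.148))
        assert np.allclose(got, want, atol=1e-9)


class TestDistanceToSet:
    def test_3_4_5_triangle(self):
        t = np.zeros((8, 8, 8), dtype=bool)
        t[0, 0, 0] = True
        d = mm.distance_to_set(t, 1.0).values
        assert d[3, 4, 0] == pytest.approx(5.0)

    def test_full_target_all_zero(self):
        t = np.ones((4, 4, 4), dtype=bool)
        assert np.all(mm.distance_to_set(t, 1.0).values == 0)

    def test_empty_target_raises(self):
        with pytest.raises(EmptyDomainError):
            mm.distance_to_set(np.zeros((3, 3, 3), bool), 1.0)

    def test_plane_lattice_median(self):
        # vessel planes perpendicular to x, period 20 µm: per period the
        # distance multiset is {0 x1, 1 x2, ..., 9 x2, 10 x1}, median 5 µm
        n = 60
        t = np.zeros((4, 4, n), dtype=bool)
        t[:, :, 10::20] = True
        d = mm.distance_to_set(t, 1.0)
        dom = np.ones_like(t)
        assert mm.median_of_map(d, dom) == pytest.approx(5.0)
        period = d.values[0, 0, :20]
        counts = np.bincount(period.astype(int))
        assert counts[0] == 1 and counts[10] == 1
        assert np.all(counts[1:10] == 2)

    def test_adding_targets_never_increases_distance(self):
        rng = np.random.default_rng(11)
        t1 = rng.random((10, 10, 10)) < 0.05
        t1[0, 0, 0] = True
        extra = rng.random((10, 10, 10)) < 0.05
        d1 = mm.distance_to_set(t1, 1.0).values
        d2 = mm.distance_to_set(t1 | extra, 1.0).values
        assert np.all(d2 <= d1 + 1e-12)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        t = rng.random((8, 8, 8)) < 0.1
        t[4, 4, 4] = True
        got = mm.distance_to_set(t, (1.0, 1.0, 2.0)).values
        want = exhaustive_distance_to_set(t, (1.0, 1.0, 2.0))
        assert np.allclose(got, want, atol=1e-9)


class TestLocalThickness:
    def test_isolated_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        t = mm.local_thickness(m, 1.0)
        assert t.values[2, 2, 2] == pytest.approx(2.0)
        assert np.count_nonzero(t.values) == 1

    def test_slab_reports_n_plus_one(self):
        # 5-voxel slab at 1 µm: the padded-background convention makes the
        # mid-layer EDT 3.0, whose open sphere covers all five layers
        m = np.zeros((5, 21, 21), dtype=bool)
        m[:, 4:17, 4:17] = True
        t = mm.local_thickness(m, 1.0)
        assert np.all(t.values[:, 8:13, 8:13] == pytest.approx(6.0))

    def test_digital_ball_center(self):
        zz, yy, xx = np.indices((11, 11, 11))
        m = (zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 16
        edt_center = exhaustive_edt_to_background(m, 1.0)[5, 5, 5]
        t = mm.local_thickness(m, 1.0)
        assert t.values[5, 5, 5] == pytest.approx(2 * edt_center)

    def test_thickness_at_least_twice_edt(self):
        m = random_test_mask(0, 16)
        t = mm.local_thickness(m, 1.0).values
        e = mm.edt_to_background(m, 1.0).values
        assert np.all(t[m] >= 2 * e[m] - 1e-12)

    def test_monotone_under_dilation(self):
        from scipy import ndimage as ndi

        m = random_test_mask(1, 16)
        bigger = ndi.binary_dilation(m)
        t1 = mm.local_thickness(m, 1.0).values
        t2 = mm.local_thickness(bigger, 1.0).values
        assert np.all(t2[m] >= t1[m] - 1e-12)

    def test_empty_mask(self):
        t = mm.local_thickness(np.zeros((4, 4, 4), bool), 1.0)
        assert np.all(t.values == 0)

    def test_matches_bruteforce_on_random_masks(self):
        for seed in range(5):
            m = random_test_mask(seed, 16)
            fast = mm.local_thickness(m, 1.0).values
            slow = mm.local_thickness_bruteforce(m, 1.0).values
            assert np.array_equal(fast, slow), f"seed {seed}"

    def test_matches_bruteforce_anisotropic(self):
        m = random_test_mask(7, 12)
        fast = mm.local_thickness(m, (2.0, 1.0, 1.0)).values
        slow = mm.local_thickness_bruteforce(m, (2.0, 1.0, 1.0)).values
        assert np.allclose(fast, slow, atol=1e-9)

    def test_bruteforce_covers_itself(self):
        m = random_test_mask(2, 12)
        t = mm.local_thickness_bruteforce(m, 1.0)
        e = exhaustive_edt_to_background(m, 1.0)
        assert np.all(t.values[m] >= 2 * e[m] - 1e-12)


class TestTubeDiameterRecovery:
    @pytest.mark.parametrize("d", [4.0, 8.0, 12.0])
    def test_modal_thickness_within_one_voxel_bias(self, d):
        n = int(d) + 12
        mask = rasterize_tube([(4, n / 2, n / 2), (44, n / 2, n / 2)], d, (48, n, n), 1.0)
        t = mm.local_thickness(mask, 1.0)
        vals = np.round(t.values[mask], 9)
        uniq, cnt = np.unique(vals, return_counts=True)
        mode = uniq[cnt.argmax()]
        assert d <= mode <= d + 2


class TestSummaries:
    def test_structure_volume(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:1000] = True
        assert mm.structure_volume(m, 1.0) == pytest.approx(1000.0)
        assert mm.structure_volume(m, 0.876) == pytest.approx(1000 * 0.876**3)
        assert mm.structure_volume(np.zeros((2, 2, 2), bool), 1.0) == 0.0

    def test_volume_fraction(self):
        dom = np.zeros((5, 5, 5), bool)
        dom.ravel()[:125] = True
        s = np.zeros_like(dom)
        s.ravel()[:8] = True
        assert mm.volume_fraction(s, dom) == pytest.approx(0.064)
        assert mm.volume_fraction(dom, dom) == pytest.approx(1.0)
        with pytest.raises(EmptyDomainError):
            mm.volume_fraction(s, np.zeros_like(dom))

    def test_histogram_counts_conserved(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 30, (6, 6, 6))
        dom = rng.random((6, 6, 6)) < 0.5
        h = mm.map_histogram(vals, dom, 1.0)
        assert h.total == np.count_nonzero(dom)
        assert np.all(np.diff(h.edges) > 0)

    def test_histogram_all_zero_values(self):
        h = mm.map_histogram(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool), 2.0)
        assert h.counts[0] == 27 and h.total == 27

    def test_histogram_empty_domain(self):
        h = mm.map_histogram(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 1.0)
        assert h.total == 0

    def test_median_even_count_rule(self):
        vals = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        dom = np.ones_like(vals, bool)
        assert mm.median_of_map(vals, dom) == pytest.approx(2.5)
        assert mm.median_of_map(vals[..., :3], dom[..., :3]) == pytest.approx(2.0)
        with pytest.raises(EmptyDomainError):
            mm.median_of_map(vals, np.zeros_like(dom))
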