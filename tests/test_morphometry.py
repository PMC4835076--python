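import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (boundary_pixel_rd_oracle, random_convex_polygon,
                      rasterize_convex_polygon)
from cordmorph import (AtrophyField, CordMask, PhantomSpec, make_phantom,
                       cross_sectional_areas, label_levels, radial_distances)
from cordmorph.morphometry import N_ANGLES, VertebralLevelMap


def _tube_mask(ap, rl, voxel=0.3, n_slices=3, fov=24.0):
    spec = PhantomSpec(voxel_mm=voxel, cord_length_mm=n_slices * voxel,
                       n_slices_acq=n_slices, fov_mm=fov,
                       ap_semiaxis_mm=[(0.0, ap), (1.0, ap)],
                       rl_semiaxis_mm=[(0.0, rl), (1.0, rl)], seed=0)
    _, mask, truth = make_phantom(spec, render_volume=False)
    return mask, truth


class TestRadialDistances:
    def test_circle_radius_recovered_within_half_voxel(self):
        mask, _ = _tube_mask(4.0, 4.0)
        rd = radial_distances(mask)
        assert rd.values.shape[1] == N_ANGLES
        assert (rd.values >= 3.85).all() and (rd.values <= 4.15).all()

    def test_ellipse_axes_recovered(self):
        mask, _ = _tube_mask(3.0, 4.0)  # a=3 A-P, b=4 R-L
        rd = radial_distances(mask).values
        assert rd[:, 0] == pytest.approx(3.0, abs=0.15)    # anterior
        assert rd[:, 36] == pytest.approx(3.0, abs=0.15)   # posterior
        assert rd[:, 18] == pytest.approx(4.0, abs=0.15)   # left
        assert rd[:, 54] == pytest.approx(4.0, abs=0.15)   # right

    def test_matches_boundary_pixel_oracle_on_convex_polygons(self):
        rng = np.random.default_rng(42)
        voxel = 0.3
        diag = voxel * np.sqrt(2.0)
        for _ in range(10):
            verts = random_convex_polygon(rng, center=(40, 40),
                                          radius_range=(10, 22))
            sl = rasterize_convex_polygon(verts, (80, 80))
            mask = CordMask(sl[:, :, None], voxel)
            rd = radial_distances(mask).values[0]
            oracle, valid = boundary_pixel_rd_oracle(sl, voxel)
            assert valid.sum() > 60
            assert np.abs(rd[valid] - oracle[valid]).max() <= diag

    def test_translation_invariance_exact(self):
        mask, _ = _tube_mask(3.0, 4.0)
        rd0 = radial_distances(mask).values
        shifted = CordMask(np.roll(mask.data, (7, -5), axis=(0, 1)),
                           mask.voxel_mm)
        assert np.array_equal(radial_distances(shifted).values, rd0)

    def test_quarter_rotation_permutes_columns(self):
        mask, _ = _tube_mask(3.0, 4.0)
        rot = CordMask(np.rot90(mask.data, k=1, axes=(0, 1)).copy(),
                       mask.voxel_mm)
        rd0 = radial_distances(mask).values
        rd90 = radial_distances(rot).values
        assert any(np.allclose(rd90, np.roll(rd0, s, axis=1), atol=1e-12)
                   for s in (18, -18))
        assert np.array_equal(cross_sectional_areas(mask).values,
                              cross_sectional_areas(rot).values)

    def test_empty_slice_rejected(self):
        data = np.zeros((10, 10, 1), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            radial_distances(CordMask(data, 0.3))

    def test_crescent_slice_flagged_with_fallback(self):
        # crescent: ring minus a bite; center of mass lands in the void
        ii, jj = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        r = np.hypot(ii - 30, jj - 30)
        ring = (r <= 20) & (r >= 14) & (jj < 34)
        mask = CordMask(ring[:, :, None], 0.3)
        rd = radial_distances(mask)
        assert 0 in rd.qc_flags
        assert (rd.values > 0).all()

    def test_polygon_area_from_rd_approximates_csa(self):
        mask, _ = _tube_mask(3.5, 5.5)
        rd = radial_distances(mask).values[0]
        csa = cross_sectional_areas(mask).values[0]
        dtheta = 2 * np.pi / N_ANGLES
        poly_area = 0.5 * np.sum(rd * np.roll(rd, -1) * np.sin(dtheta))
        assert poly_area == pytest.approx(csa, rel=0.05)

    def test_anterior_atrophy_shifts_com_posteriorly_and_lowers_both_sides(self):
        spec = PhantomSpec(voxel_mm=0.3, cord_length_mm=9.0, fov_mm=24.0, seed=0)
        atro = AtrophyField(direction="anterior", peak=0.4,
                            extent=(0.0, 1.0), transition=0.0)
        _, base_mask, _ = make_phantom(spec, render_volume=False)
        _, atro_mask, _ = make_phantom(spec, atro, render_volume=False)

        from scipy import ndimage

        com_base = ndimage.center_of_mass(base_mask.data[:, :, 1])
        com_atro = ndimage.center_of_mass(atro_mask.data[:, :, 1])
        assert com_atro[1] > com_base[1]  # toward posterior (increasing j)

        rd_base = radial_distances(base_mask).values.mean(axis=0)
        rd_atro = radial_distances(atro_mask).values.mean(axis=0)
        assert rd_atro[0] < rd_base[0]      # anterior radius decreases
        assert rd_atro[36] < rd_base[36]    # posterior radius decreases too


class TestCSA:
    def test_voxel_count_arithmetic(self):
        data = np.zeros((40, 40, 1), dtype=bool)
        data.ravel()[:559] = True
        csa = cross_sectional_areas(CordMask(data.reshape(40, 40, 1), 0.3))
        assert csa.values[0] == pytest.approx(559 * 0.09)

    def test_circle_within_two_percent_of_analytic(self):
        mask, truth = _tube_mask(4.0, 4.0)
        csa = cross_sectional_areas(mask)
        assert np.allclose(csa.values, np.pi * 16.0, rtol=0.02)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        mask, _ = _tube_mask(3.0, 4.0, n_slices=1)
        di, dj = rng.integers(-8, 9, size=2)
        shifted = CordMask(np.roll(mask.data, (di, dj), axis=(0, 1)),
                           mask.voxel_mm)
        assert cross_sectional_areas(shifted).values[0] == \
            cross_sectional_areas(mask).values[0]


class TestLabelLevels:
    def test_default_equal_sixths_covers_413(self):
        lm = label_levels(413)
        sizes = [stop - start for start, stop in lm.intervals.values()]
        assert sum(sizes) == 413
        assert set(sizes) <= {68, 69}

    def test_c4_overlies_c5_c6_segments(self):
        assert VertebralLevelMap.segments_for("C4") == ("C5", "C6")

    def test_c3_to_c6_span_overlies_c4_to_c7(self):
        assert VertebralLevelMap.segments_for_span("C3", "C6") == ("C4", "C7")

    def test_c2_is_most_superior_interval(self):
        lm = label_levels(413)
        assert lm.intervals["C2"][1] == 413
        assert lm.intervals["C7"][0] == 0

    def test_span_slices(self):
        lm = label_levels(412)
        sl = lm.span_slices("C3", "C6")
        # C3-C6 = middle four sixths
        assert sl[0] == lm.intervals["C6"][0]
        assert sl[-1] == lm.intervals["C3"][1] - 1

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError):
            label_levels(413, [0.2, 0.1, 0.5, 0.6, 0.8])
        with pytest.raises(ValueError):
            label_levels(413, [0.0, 0.2, 0.5, 0.6, 0.8])
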