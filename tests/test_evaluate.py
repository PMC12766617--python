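"""Error metrics, cohort summaries, and clinical-validation analyses."""

import numpy as np
import pytest

from cdtikit import evaluate as ev
from cdtikit import maps, phantom


def maps_from(md, fa, ha, e2a, mask):
    return maps.CDTIMaps(md=md, fa=fa, ha=ha, e2a=e2a, mask=mask,
                         flagged=np.zeros_like(mask))


class TestMAAE:
    @pytest.mark.parametrize("x,y,expected", [
        (10, 30, 20),        # small-difference branch
        (80, -80, 20),       # wraparound: 180 - 160
        (0, 90, 90),         # maximum directional difference
        (45, 45, 0),
        (-90, 90, 0),        # same axis
    ])
    def test_examples(self, x, y, expected):
        assert ev.maae(x, y) == pytest.approx(expected)

    def test_exhaustive_degree_grid(self):
        # symmetry, range [0, 90], zero diagonal over the whole 1-degree grid
        g = np.arange(-90, 91)
        xx, yy = np.meshgrid(g, g)
        err = ev.maae(xx, yy)
        assert err.min() >= 0 and err.max() <= 90
        np.testing.assert_array_equal(err, err.T)
        np.testing.assert_array_equal(np.diag(err), np.zeros(181))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-90, 90\]"):
            ev.maae(120.0, 0.0)


class TestMapErrors:
    def test_identical_maps_zero_error(self, small_geometry):
        m = small_geometry.myo_mask
        md = np.where(m, 1e-3, np.nan)
        fa = np.where(m, 0.4, np.nan)
        ha = np.where(m, 30.0, np.nan)
        e2a = np.where(m, 20.0, np.nan)
        a = maps_from(md, fa, ha, e2a, m)
        entry = ev.map_errors(a, a, m)
        assert (entry.ha_maae, entry.e2a_mae, entry.md_mae, entry.fa_mae) \
            == (0, 0, 0, 0)

    def test_single_voxel_reduces_to_maae(self):
        m = np.zeros((2, 2), dtype=bool)
        m[0, 0] = True
        zero = np.zeros((2, 2))
        pred = maps_from(zero, zero, np.full((2, 2), 30.0), zero, m)
        ref = maps_from(zero, zero, np.full((2, 2), 50.0), zero, m)
        assert ev.map_errors(pred, ref, m).ha_maae == pytest.approx(20.0)

    def test_e2a_compared_on_absolute_angles(self):
        m = np.ones((1, 1), dtype=bool)
        zero = np.zeros((1, 1))
        pred = maps_from(zero, zero, zero, np.full((1, 1), -30.0), m)
        ref = maps_from(zero, zero, zero, np.full((1, 1), 30.0), m)
        assert ev.map_errors(pred, ref, m).e2a_mae == pytest.approx(0.0)

    def test_md_error_reported_in_milli_units(self):
        m = np.ones((1, 1), dtype=bool)
        zero = np.zeros((1, 1))
        pred = maps_from(np.full((1, 1), 1.2e-3), zero, zero, zero, m)
        ref = maps_from(np.full((1, 1), 1.0e-3), zero, zero, zero, m)
        assert ev.map_errors(pred, ref, m).md_mae == pytest.approx(0.2)

    def test_empty_mask_rejected(self):
        m = np.zeros((2, 2), dtype=bool)
        zero = np.zeros((2, 2))
        a = maps_from(zero, zero, zero, zero, m)
        with pytest.raises(ValueError, match="empty"):
            ev.map_errors(a, a, m)


class TestCohortSummary:
    def _entries(self, ha_values):
        return [ev.ErrorEntry(ha_maae=v, e2a_mae=v, md_mae=v, fa_mae=v)
                for v in ha_values]

    def test_median_and_iqr_linear_interpolation(self):
        s = ev.cohort_summary(self._entries([1, 2, 3, 4, 5]))
        assert s.median["ha_maae"] == 3
        assert s.iqr["ha_maae"] == 2        # Q3 - Q1 = 4 - 2
        assert s.n_subjects == 5

    def test_single_subject_iqr_zero(self):
        s = ev.cohort_summary(self._entries([7.0]))
        assert s.iqr["fa_mae"] == 0

    def test_permutation_invariant(self, rng):
        vals = list(rng.uniform(0, 20, 9))
        a = ev.cohort_summary(self._entries(vals))
        b = ev.cohort_summary(self._entries(vals[::-1]))
        assert a.median == b.median and a.iqr == b.iqr

    def test_no_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.cohort_summary([])


class TestTransmuralProfile:
    def test_linear_prescription_recovered(self, small_geometry):
        o = phantom.prescribe_orientation(small_geometry, 60.0, -60.0, 20.0)
        prof = ev.transmural_profiles(np.nan_to_num(o.ha_true),
                                      small_geometry, n_positions=15)
        expected = 60.0 - 120.0 * prof.positions
        interior = slice(1, -1)
        assert np.abs(prof.median_ha[interior] - expected[interior]).max() < 2.0

    def test_linear_recovery_with_off_center_ventricle(self):
        geom = phantom.make_lv_geometry((64, 64), (29.0, 34.5), 9.0, 18.0)
        o = phantom.prescribe_orientation(geom, 50.0, -70.0, 20.0)
        prof = ev.transmural_profiles(np.nan_to_num(o.ha_true), geom,
                                      n_positions=15)
        expected = 50.0 - 120.0 * prof.positions
        assert np.abs(prof.median_ha[1:-1] - expected[1:-1]).max() < 2.0

    def test_constant_map_constant_profile(self, small_geometry):
        ha = np.where(small_geometry.myo_mask, 25.0, 0.0)
        prof = ev.transmural_profiles(ha, small_geometry, n_positions=10)
        np.testing.assert_allclose(prof.median_ha, 25.0, atol=1e-9)

    def test_positions_normalized(self, small_geometry):
        ha = np.where(small_geometry.myo_mask, 10.0, 0.0)
        prof = ev.transmural_profiles(ha, small_geometry)
        assert prof.positions[0] == 0 and prof.positions[-1] == 1
        assert np.all(np.diff(prof.positions) > 0)


class TestFAZones:
    def test_constant_fa(self, small_geometry):
        fa = np.where(small_geometry.myo_mask, 0.4, np.nan)
        assert ev.fa_zones(fa, small_geometry) == (0.4, 0.4, 0.4)

    def test_meso_elevated_prescription(self, small_geometry):
        # parabolic profile peaking mid-wall
        d = small_geometry.depth
        fa = 0.3 + 0.3 * (1 - (2 * d - 1) ** 2)
        endo, meso, epi = ev.fa_zones(np.nan_to_num(fa), small_geometry)
        assert meso > endo and meso > epi

    def test_zone_masks_partition(self, small_geometry):
        d = small_geometry.depth
        m = small_geometry.myo_mask
        z1 = m & (d < 1 / 3)
        z2 = m & (d >= 1 / 3) & (d < 2 / 3)
        z3 = m & (d >= 2 / 3)
        np.testing.assert_array_equal(z1 | z2 | z3, m)
        assert not (z1 & z2).any() and not (z2 & z3).any()


class TestDeltaMD:
    def test_identical_distributions_zero(self, rng):
        md = rng.normal(1e-3, 1e-5, (10, 10))
        lesion = np.zeros((10, 10), dtype=bool)
        remote = np.zeros((10, 10), dtype=bool)
        lesion[:5] = True
        remote[5:] = True
        md[remote] = md[lesion]
        assert ev.delta_md(md, lesion, remote) == pytest.approx(0.0)

    def test_prescribed_contrast_on_infarct_phantom(self, orientation):
        base = phantom.build_tensor_field(orientation, 1.05e-3, 0.45)
        spec = phantom.LesionSpec(angular_range=(30.0, 120.0),
                                  md_lesion=1.25e-3, fa_lesion=0.3)
        field, lesion, remote = phantom.add_infarct(base, orientation, spec)
        md = field.d[..., :3].sum(axis=-1) / 3
        assert ev.delta_md(md, lesion, remote) == pytest.approx(0.20e-3,
                                                                abs=1e-12)

    def test_antisymmetric_under_mask_swap(self, rng):
        md = rng.normal(1e-3, 1e-4, (8, 8))
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4], b[4:] = True, True
        assert ev.delta_md(md, a, b) == pytest.approx(-ev.delta_md(md, b, a))

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            ev.delta_md(np.ones((4, 4)), m, m)


class TestPatchwiseComparison:
    mask = np.ones((10, 10), dtype=bool)

    def test_equal_errors_fraction_zero(self):
        a = np.ones((10, 10))
        assert ev.patchwise_comparison(a, a, self.mask, 5) == 0.0

    def test_uniform_halving_fraction_one(self):
        b = np.ones((10, 10))
        assert ev.patchwise_comparison(b / 2, b, self.mask, 5) == 1.0

    def test_mixed_tiles_fraction_half(self):
        mask = np.ones((5, 10), dtype=bool)
        a = np.ones((5, 10))
        b = np.ones((5, 10))
        a[:, :5] = 0.5   # a wins left tile
        b[:, 5:] = 0.5   # b wins right tile
        assert ev.patchwise_comparison(a, b, mask, 5) == 0.5

    def test_tiles_anchored_at_mask_bounding_box(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:8, 3:8] = True
        a = np.zeros((12, 12))
        b = np.ones((12, 12))
        assert ev.patchwise_comparison(a, b, mask, 5) == 1.0

    def test_no_qualifying_tiles_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            ev.patchwise_comparison(np.ones((5, 5)), np.ones((5, 5)),
                                    np.zeros((5, 5), dtype=bool), 5)
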