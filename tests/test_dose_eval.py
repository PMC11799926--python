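"""DVH curves and dose indices on constructed dose distributions."""

import numpy as np
import pytest

import adaptct as a
from adaptct.dose_eval import DEFAULT_BIN_GY
from adaptct.errors import DegenerateInputError


def _dose(values, spacing=(1.0, 1.0, 1.0), prescription=60.0):
    return a.DoseGrid(np.asarray(values, dtype=float), spacing, prescription_gy=prescription)


def _mask(arr):
    return a.Volume(np.asarray(arr, dtype=bool), (1.0, 1.0, 1.0))


@pytest.fixture
def uniform_60():
    shape = (4, 4, 4)
    return _dose(np.full(shape, 60.0)), _mask(np.ones(shape))


@pytest.fixture
def two_level():
    """Half the structure at 60 Gy, half at 30 Gy."""
    vals = np.full((4, 4, 4), 30.0)
    vals[:2] = 60.0
    return _dose(vals), _mask(np.ones((4, 4, 4)))


class TestDVH:
    def test_uniform_dose_is_step_function(self, uniform_60):
        dose, mask = uniform_60
        dvh = a.compute_dvh(dose, mask)
        assert np.all(dvh.cum_volume[dvh.dose_bins <= 60.0 - 1e-9] == 1.0)
        assert dvh.cum_volume[-1] == 0.0
        assert dvh.volume_cm3 == pytest.approx(64 * 1e-3)

    def test_two_level_midpoint(self, two_level):
        dose, mask = two_level
        dvh = a.compute_dvh(dose, mask)
        idx = np.searchsorted(dvh.dose_bins, 45.0)
        assert dvh.cum_volume[idx] == pytest.approx(0.5)

    def test_cum_volume_monotone_nonincreasing(self, two_level):
        dose, mask = two_level
        dvh = a.compute_dvh(dose, mask)
        assert np.all(np.diff(dvh.cum_volume) <= 0.0)
        assert dvh.cum_volume[0] == 1.0

    def test_refining_bins_changes_d50_by_less_than_coarse_bin(self):
        rng = np.random.default_rng(0)
        dose = _dose(rng.uniform(0, 70, size=(6, 6, 6)))
        mask = _mask(np.ones((6, 6, 6)))
        coarse = a.dose_at_volume(a.compute_dvh(dose, mask, bin_gy=0.5), 50.0)
        fine = a.dose_at_volume(a.compute_dvh(dose, mask, bin_gy=0.05), 50.0)
        assert abs(coarse - fine) < 0.5

    def test_dvh_dmean_equals_voxel_mean(self, two_level):
        dose, mask = two_level
        dvh = a.compute_dvh(dose, mask)
        assert dvh.d_mean() == pytest.approx(dose.values.mean(), abs=DEFAULT_BIN_GY)

    def test_empty_mask_rejected(self, uniform_60):
        dose, _ = uniform_60
        with pytest.raises(DegenerateInputError):
            a.compute_dvh(dose, _mask(np.zeros((4, 4, 4))))


class TestDoseAtVolume:
    def test_flat_dvh(self, uniform_60):
        dose, mask = uniform_60
        dvh = a.compute_dvh(dose, mask)
        for q in (2.0, 50.0, 98.0):
            assert a.dose_at_volume(dvh, q) == pytest.approx(60.0, abs=DEFAULT_BIN_GY)

    def test_two_level_extremes(self, two_level):
        dose, mask = two_level
        dvh = a.compute_dvh(dose, mask)
        assert a.dose_at_volume(dvh, 98.0) == pytest.approx(30.0, abs=DEFAULT_BIN_GY)
        assert a.dose_at_volume(dvh, 2.0) == pytest.approx(60.0, abs=DEFAULT_BIN_GY)

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(1)
        dose = _dose(rng.uniform(0, 70, size=(5, 5, 5)))
        dvh = a.compute_dvh(dose, _mask(np.ones((5, 5, 5))))
        d2, d50, d98 = (a.dose_at_volume(dvh, q) for q in (2.0, 50.0, 98.0))
        assert d2 >= d50 >= d98

    def test_out_of_range_rejected(self, uniform_60):
        dose, mask = uniform_60
        dvh = a.compute_dvh(dose, mask)
        for q in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                a.dose_at_volume(dvh, q)


class TestHomogeneity:
    def test_uniform_dose_gives_zero(self, uniform_60):
        dose, mask = uniform_60
        assert a.homogeneity_index(a.compute_dvh(dose, mask)) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_constructed_three_level_value(self):
        # D2=63, D98=57, D50=60 -> HI = (63-57)/60 = 0.100
        vals = np.full((10, 10, 10), 60.0)
        flat = vals.reshape(-1)
        flat[:25] = 63.0   # top 2.5% of voxels
        flat[-25:] = 57.0  # bottom 2.5%
        dvh = a.compute_dvh(_dose(vals), _mask(np.ones((10, 10, 10))))
        assert a.homogeneity_index(dvh) == pytest.approx(0.100, abs=2e-3)

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(40, 70, size=(6, 6, 6))
        mask = _mask(np.ones((6, 6, 6)))
        h1 = a.homogeneity_index(a.compute_dvh(_dose(vals), mask, bin_gy=0.001))
        h2 = a.homogeneity_index(a.compute_dvh(_dose(2 * vals), mask, bin_gy=0.002))
        assert h1 == pytest.approx(h2, abs=1e-3)


class TestConformity:
    def test_perfect_conformity(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2:4] = 60.0
        gtv = np.zeros((6, 6, 6), dtype=bool)
        gtv[2:4, 2:4, 2:4] = True
        assert a.conformity_index(_dose(vals), _mask(gtv), 60.0) == pytest.approx(1.0)

    def test_voxel_count_example(self):
        # V_GTV = 100, V_ref = 200, overlap 50 -> 50²/(100·200) = 0.125
        vals = np.zeros((1, 20, 20))
        vals[0, :10, :20] = 60.0          # 200 covered voxels
        gtv = np.zeros((1, 20, 20), dtype=bool)
        gtv[0, 5:10, :10] = True           # overlap 50
        gtv[0, 10:15, :10] = True          # 50 uncovered GTV voxels
        assert a.conformity_index(_dose(vals), _mask(gtv), 60.0) == pytest.approx(0.125)

    def test_disjoint_is_zero_and_bounded(self):
        vals = np.zeros((4, 4, 4))
        vals[0] = 60.0
        gtv = np.zeros((4, 4, 4), dtype=bool)
        gtv[3] = True
        ci = a.conformity_index(_dose(vals), _mask(gtv), 60.0)
        assert ci == 0.0
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0, 70, size=(4, 4, 4))
            gtv = rng.random((4, 4, 4)) > 0.5
            if not gtv.any() or not (vals >= 60).any():
                continue
            ci = a.conformity_index(_dose(vals), _mask(gtv), 60.0)
            assert 0.0 <= ci <= 1.0

    def test_ratio_form_can_exceed_one(self):
        vals = np.full((4, 4, 4), 60.0)
        gtv = np.zeros((4, 4, 4), dtype=bool)
        gtv[0, 0, 0] = True
        assert a.conformity_index(_dose(vals), _mask(gtv), 60.0, form="ratio") == 64.0


class TestGradientIndex:
    def test_nested_block_value(self):
        # 10³ voxels at 60 Gy inside a 20³ region at 30 Gy: V50% = 8000 -> GI = 8
        vals = np.zeros((24, 24, 24))
        vals[2:22, 2:22, 2:22] = 30.0
        vals[7:17, 7:17, 7:17] = 60.0
        assert a.gradient_index(_dose(vals), 60.0) == pytest.approx(8.0)

    def test_lower_bound_one(self):
        vals = np.full((4, 4, 4), 65.0)
        assert a.gradient_index(_dose(vals), 60.0) == 1.0

    def test_monotone_in_falloff_distance(self):
        case = a.generate_dataset(1, seed=4)[0]
        gis = []
        for falloff in (12.0, 8.0, 5.0):
            dose = a.generate_synthetic_dose(case, 60.0, falloff)
            gis.append(a.gradient_index(dose, 60.0))
        assert gis[0] > gis[1] > gis[2] >= 1.0

    def test_no_coverage_rejected(self):
        with pytest.raises(DegenerateInputError):
            a.gradient_index(_dose(np.full((3, 3, 3), 10.0)), 60.0)


class TestOARMetrics:
    def test_uniform_dose_row(self):
        vals = np.full((4, 4, 4), 10.0)
        table = a.oar_metrics(_dose(vals), {"lungs": _mask(np.ones((4, 4, 4)))})
        row = table.iloc[0]
        assert row["d_mean_gy"] == pytest.approx(10.0, abs=1e-9)
        assert row["d_max_gy"] == pytest.approx(10.0, abs=1e-9)
        assert row["v5_pct"] == 100.0
        assert row["v20_pct"] == 0.0

    def test_one_row_per_structure_and_v_monotonicity(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 40, size=(6, 6, 6))
        structures = {
            "lungs": _mask(rng.random((6, 6, 6)) > 0.3),
            "heart": _mask(rng.random((6, 6, 6)) > 0.5),
            "spinal_cord": _mask(rng.random((6, 6, 6)) > 0.7),
        }
        table = a.oar_metrics(_dose(vals), structures)
        assert list(table["structure"]) == ["lungs", "heart", "spinal_cord"]
        for _, row in table.iterrows():
            assert row["v5_pct"] >= row["v20_pct"] >= row["v30_pct"]

    def test_indices_invariant_to_axis_permutation(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 70, size=(5, 5, 5))
        gtv = rng.random((5, 5, 5)) > 0.6
        ci0 = a.conformity_index(_dose(vals), _mask(gtv), 60.0)
        gi0 = a.gradient_index(_dose(vals), 60.0)
        perm = (2, 0, 1)
        ci1 = a.conformity_index(
            _dose(vals.transpose(perm)), _mask(gtv.transpose(perm)), 60.0
        )
        gi1 = a.gradient_index(_dose(vals.transpose(perm)), 60.0)
        assert ci0 == ci1 and gi0 == gi1


class TestOverlay:
    def test_identity_same_grid_is_bitwise(self):
        rng = np.random.default_rng(7)
        dose = _dose(rng.uniform(0, 60, size=(6, 6, 6)))
        out = a.overlay_dose(dose, a.RigidTransform(), _dose(np.zeros((6, 6, 6))))
        np.testing.assert_array_equal(out.values, dose.values)

    def test_uniform_dose_stays_uniform(self):
        dose = _dose(np.full((6, 6, 6), 42.0))
        t = a.RigidTransform(translation_mm=(0.5, 0.5, 0.5))
        target = a.Volume(np.zeros((5, 5, 5)), (1.0, 1.0, 1.0))
        out = a.overlay_dose(dose, t, target)
        # sample strictly interior target voxels: constant interpolates exactly
        np.testing.assert_allclose(out.values[1:4, 1:4, 1:4], 42.0, atol=1e-12)

    def test_round_trip_shift_error_small(self):
        # smooth dose: 4 mm shift there and back stays within 2% of max
        z, y, x = np.meshgrid(*(np.arange(24),) * 3, indexing="ij")
        vals = 60.0 * np.exp(-((z - 12.0) ** 2 + (y - 12.0) ** 2 + (x - 12.0) ** 2) / 80.0)
        dose = _dose(vals, spacing=(2.0, 2.0, 2.0))
        target = dose.as_volume()
        t = a.RigidTransform(translation_mm=(0.0, 4.0, 0.0))
        shifted = a.overlay_dose(dose, t, target)
        back = a.overlay_dose(shifted, t.inverse(), target)
        core = np.s_[4:20, 4:20, 4:20]
        assert np.abs(back.values[core] - vals[core]).max() < 0.02 * vals.max()
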