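"""Gamma-index analysis: closed forms, oracle equivalence, resampling."""

import numpy as np
import pytest

import adaptct as a
from adaptct.errors import DegenerateInputError

# coarse-but-exact search settings used for oracle comparisons: the two
# implementations must agree on the SAME lattice, whatever its step
FAST = dict(search_radius_mm=6.0, interp_step_mm=1.0)


def _dose(values, spacing=(2.0, 2.0, 2.0)):
    return a.DoseGrid(np.asarray(values, dtype=float), spacing)


def _random_pair(rng, shape=(16, 16, 16)):
    z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = np.asarray(shape) / 2.0
    base = 60.0 * np.exp(-(((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) / 60.0))
    ref = base * rng.uniform(0.95, 1.05) + rng.normal(0, 0.4, size=shape)
    ev = base * rng.uniform(0.95, 1.05) + rng.normal(0, 0.4, size=shape)
    return _dose(np.clip(ref, 0, None)), _dose(np.clip(ev, 0, None))


class TestClosedForms:
    def test_identity_gives_zero_gamma(self):
        rng = np.random.default_rng(0)
        ref, _ = _random_pair(rng)
        res = a.gamma_map(ref, ref, a.GammaParams(**FAST))
        evaluated = ~np.isnan(res.gamma_map)
        assert np.nanmax(res.gamma_map) == 0.0
        assert res.pass_rate_pct == 100.0
        assert res.n_evaluated == int(evaluated.sum()) > 0

    @pytest.mark.parametrize(
        "scale,expected_gamma,expected_pass",
        [(1.02, 2.0 / 3.0, 100.0), (1.05, 5.0 / 3.0, 0.0)],
    )
    def test_uniform_scaling_closed_form(self, scale, expected_gamma, expected_pass):
        # spatially uniform dose at Dmax: the DTA term cannot help, so
        # γ = ΔD% / DT exactly
        ref = _dose(np.full((8, 8, 8), 50.0))
        ev = _dose(np.full((8, 8, 8), 50.0 * scale))
        res = a.gamma_map(ref, ev, a.GammaParams(**FAST))
        np.testing.assert_allclose(res.gamma_map, expected_gamma, atol=1e-9)
        assert res.pass_rate_pct == expected_pass

    def test_low_dose_threshold_excludes_voxels(self):
        vals = np.full((6, 6, 6), 2.0)
        vals[2:4, 2:4, 2:4] = 60.0  # only these exceed 10% of max
        ref = _dose(vals)
        res = a.gamma_map(ref, ref, a.GammaParams(**FAST))
        assert res.n_evaluated == 8
        with pytest.raises(DegenerateInputError):
            a.gamma_map(
                _dose(np.zeros((4, 4, 4))), _dose(np.zeros((4, 4, 4))),
                a.GammaParams(**FAST),
            )


class TestOracleEquivalence:
    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        params = a.GammaParams(**FAST)
        for _ in range(25):
            ref, ev = _random_pair(rng)
            fast = a.gamma_map(ref, ev, params)
            slow = a.gamma_brute_force(ref, ev, params)
            np.testing.assert_allclose(
                fast.gamma_map, slow.gamma_map, atol=1e-6, equal_nan=True
            )
            assert fast.pass_rate_pct == pytest.approx(slow.pass_rate_pct, abs=1e-9)

    def test_brute_force_guard_rail(self):
        big = _dose(np.ones((40, 8, 8)))
        with pytest.raises(ValueError):
            a.gamma_brute_force(big, big, a.GammaParams(**FAST))

    def test_refining_interp_step_converges(self):
        # linear-gradient dose (trilinear interpolation is exact for it, so
        # the only discretization left is the displacement lattice): halving
        # the evaluation step near the fine limit barely changes gamma
        y = np.arange(12) * 2.0
        base = np.broadcast_to(30.0 + 0.5 * y[None, :, None], (12, 12, 12)).copy()
        ref = _dose(base)
        ev = _dose(base * 1.02)
        coarse = a.gamma_map(ref, ev, a.GammaParams(search_radius_mm=3.0, interp_step_mm=0.15))
        fine = a.gamma_map(ref, ev, a.GammaParams(search_radius_mm=3.0, interp_step_mm=0.075))
        diff = np.nanmax(np.abs(coarse.gamma_map - fine.gamma_map))
        assert diff < 5e-3


class TestInvariances:
    def test_invariant_under_joint_rescaling(self):
        rng = np.random.default_rng(9)
        ref, ev = _random_pair(rng, shape=(10, 10, 10))
        params = a.GammaParams(**FAST)
        r1 = a.gamma_map(ref, ev, params)
        r2 = a.gamma_map(
            _dose(ref.values * 3.0, ref.spacing), _dose(ev.values * 3.0, ev.spacing), params
        )
        np.testing.assert_allclose(r1.gamma_map, r2.gamma_map, atol=1e-9, equal_nan=True)

    def test_subcriterion_shift_in_flat_region_passes(self):
        # uniform dose shifted by less than DTA: γ stays 0 (no gradient)
        ref = _dose(np.full((8, 8, 8), 40.0))
        ev = a.DoseGrid(np.full((8, 8, 8), 40.0), ref.spacing, origin=(0.0, 1.5, 0.0))
        res = a.gamma_map(ref, ev, a.GammaParams(**FAST))
        # rows whose world position the shifted evaluated grid still covers
        np.testing.assert_allclose(np.nan_to_num(res.gamma_map[:, 1:, :]), 0.0, atol=1e-9)

    def test_linear_gradient_shifted_by_dta_stays_within_one(self):
        # dose values match after a 3 mm shift: DTA term saturates at 1
        y = np.arange(16) * 2.0
        vals = np.broadcast_to(30.0 + 1.0 * y[None, :, None], (8, 16, 8)).copy()
        ref = _dose(vals)
        ev = a.DoseGrid(vals.copy(), ref.spacing, origin=(0.0, 3.0, 0.0))
        params = a.GammaParams(search_radius_mm=9.0, interp_step_mm=0.5)
        res = a.gamma_map(ref, ev, params)
        core = res.gamma_map[:, 4:12, :]
        assert np.nanmax(core) <= 1.0 + 1e-6

    def test_pass_status_monotone_in_criteria(self):
        rng = np.random.default_rng(11)
        ref, ev = _random_pair(rng, shape=(10, 10, 10))
        tight = a.gamma_map(ref, ev, a.GammaParams(dose_tolerance_pct=2.0, **FAST))
        loose = a.gamma_map(ref, ev, a.GammaParams(dose_tolerance_pct=4.0, **FAST))
        t = tight.gamma_map <= 1.0
        l = loose.gamma_map <= 1.0
        assert np.all(l[t & ~np.isnan(tight.gamma_map)])
        assert loose.pass_rate_pct >= tight.pass_rate_pct


class TestResampling:
    def test_own_spacing_is_identity(self):
        rng = np.random.default_rng(12)
        dose = _dose(rng.uniform(0, 60, size=(9, 9, 9)), spacing=(2.5, 2.5, 2.5))
        out = a.resample_dose_grid(dose, 2.5)
        np.testing.assert_allclose(out.values, dose.values, atol=1e-9)

    def test_constant_resamples_exactly(self):
        dose = _dose(np.full((9, 9, 9), 17.0), spacing=(1.0, 1.0, 1.0))
        out = a.resample_dose_grid(dose, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out.values, 17.0, atol=1e-12)

    def test_round_trip_error_small_for_smooth_dose(self):
        z, y, x = np.meshgrid(*(np.arange(33),) * 3, indexing="ij")
        vals = 60.0 * np.exp(-(((z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2) / 1200.0))
        dose = _dose(vals, spacing=(1.0, 1.0, 1.0))
        down = a.resample_dose_grid(dose, 4.0)
        back = a.resample_dose_grid(down, 1.0)
        assert back.shape == dose.shape
        assert np.abs(back.values - vals).max() < 0.02 * vals.max()


class TestReport:
    def test_single_identity_comparison(self):
        ref = _dose(np.full((6, 6, 6), 50.0))
        res = a.gamma_map(ref, ref, a.GammaParams(**FAST))
        table = a.pass_rate_report([res], ["2.5 mm"])
        row = table.iloc[0]
        assert row["mean_pass_rate_pct"] == 100.0
        assert row["sd_pass_rate_pct"] == 0.0

    def test_mean_of_two_results(self):
        r1 = a.GammaResult(np.array([[[0.5]]]), 100.0, 1)
        r2 = a.GammaResult(np.array([[[1.5]]]), 98.0, 1)
        table = a.pass_rate_report([r1, r2], ["g", "g"])
        assert table.iloc[0]["mean_pass_rate_pct"] == pytest.approx(99.0)
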