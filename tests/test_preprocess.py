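"""Preprocessing: clipping, normalization round trips, body delineation,
rigid registration, 2.5-D stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adaptct as a
from adaptct.errors import DegenerateInputError
from adaptct.preprocess import resample_rigid


def _vol(arr, spacing=(2.0, 2.0, 2.0)):
    return a.Volume(np.asarray(arr, dtype=np.float32), spacing)


STATS = a.NormStats(mean=0.0, sd=1.0)


class TestClipAndZscore:
    def test_clip_bounds(self):
        v = _vol(np.array([[[5000.0, -1500.0, 40.0, 3000.0]]]))
        out = a.clip_hu(v, STATS)
        np.testing.assert_array_equal(out.data.ravel(), [3000.0, -1000.0, 40.0, 3000.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_clip_is_a_clamp(self, seed):
        rng = np.random.default_rng(seed)
        v = _vol(rng.uniform(-5000, 8000, size=(2, 3, 3)))
        out = a.clip_hu(v, STATS)
        assert out.data.max() <= 3000.0 and out.data.min() >= -1000.0
        inside = (v.data >= -1000) & (v.data <= 3000)
        np.testing.assert_array_equal(out.data[inside], v.data[inside])

    def test_zscore_round_trip_is_exact(self):
        rng = np.random.default_rng(0)
        v = a.Volume(rng.uniform(-1200, 3500, size=(4, 8, 8)), (2.0, 2.0, 2.0))
        stats = a.NormStats(mean=12.5, sd=310.0)
        clipped = a.clip_hu(v, stats)
        back = a.inverse_zscore(a.zscore(v, stats), stats)
        assert np.abs(back.data - clipped.data).max() < 1e-4

    def test_identity_stats_leave_volume_unchanged(self):
        v = _vol(np.random.default_rng(1).normal(size=(2, 4, 4)))
        out = a.zscore(v, a.NormStats(mean=0.0, sd=1.0))
        np.testing.assert_allclose(out.data, v.data, atol=1e-6)

    def test_constant_volume_rejected(self):
        v = _vol(np.full((2, 4, 4), 40.0))
        with pytest.raises(DegenerateInputError):
            a.estimate_norm_stats([v])
        with pytest.raises(DegenerateInputError):
            a.NormStats(mean=0.0, sd=0.0)


class TestBodyMask:
    def test_recovers_simulator_ground_truth(self, phantom_case):
        ct, masks = phantom_case
        cbct = a.degrade_to_cbct(ct, a.ArtifactSpec(seed=3))
        est = a.body_mask(cbct).data
        truth = masks["body"].data
        from scipy import ndimage

        # compare away from a 2-voxel boundary band
        interior = ndimage.binary_erosion(truth, iterations=2)
        exterior = ~ndimage.binary_dilation(truth, iterations=2)
        core = interior | exterior
        dice = (
            2.0 * np.sum(est[core] & truth[core])
            / (np.sum(est[core]) + np.sum(truth[core]))
        )
        assert dice > 0.98

    def test_cbct_and_pct_outlines_agree(self, phantom_case):
        ct, _ = phantom_case
        cbct = a.degrade_to_cbct(ct, a.ArtifactSpec(seed=4))
        m1 = a.body_mask(ct).data
        m2 = a.body_mask(cbct).data
        dice = 2.0 * np.sum(m1 & m2) / (m1.sum() + m2.sum())
        assert dice > 0.95

    def test_idempotent(self, phantom_case):
        ct, _ = phantom_case
        m = a.body_mask(ct)
        masked = ct.data.copy()
        masked[~m.data] = -1000.0
        m2 = a.body_mask(a.Volume(masked, ct.spacing))
        np.testing.assert_array_equal(m.data, m2.data)

    def test_all_air_rejected(self):
        with pytest.raises(DegenerateInputError):
            a.body_mask(_vol(np.full((4, 8, 8), -1000.0)))


class TestRigidRegistration:
    def test_self_registration_is_identity(self, phantom_case):
        ct, _ = phantom_case
        t, res = a.rigid_register(ct, ct)
        assert np.abs(np.asarray(t.translation_mm)).max() < 0.1
        np.testing.assert_allclose(res.data, ct.data, atol=1e-2)

    def test_recovers_known_offset(self, phantom_case):
        ct, _ = phantom_case
        offset = (2.0, -4.0, 6.0)  # mm along (slice, row, column)
        shifted = resample_rigid(ct, a.RigidTransform(translation_mm=offset), ct)
        t, res = a.rigid_register(shifted, ct)
        # aligning the shifted volume back must undo the injected offset
        recovered = -np.asarray(t.translation_mm)
        for rec, true, sp in zip(recovered, offset, ct.spacing):
            assert abs(rec - true) <= sp
        # intensity MAE is noise-limited (double interpolation of a noisy
        # phantom), but alignment must still cut it several-fold
        body = a.body_mask(ct).data
        assert a.mae(res, ct, body) < 0.35 * a.mae(shifted, ct, body)

    @pytest.mark.parametrize("mag", [2.0, 6.0, 10.0])
    def test_recovery_error_below_voxel_up_to_10mm(self, phantom_case, mag):
        ct, _ = phantom_case
        offset = (0.0, mag, -mag)
        shifted = resample_rigid(ct, a.RigidTransform(translation_mm=offset), ct)
        t, _ = a.rigid_register(shifted, ct)
        err = np.abs(-np.asarray(t.translation_mm) - np.asarray(offset))
        assert np.all(err <= np.asarray(ct.spacing))

    def test_transform_composes_with_inverse(self):
        t = a.RigidTransform((3.0, -2.0, 1.5), (2.0, -1.0, 3.0), (10.0, 20.0, 30.0))
        pts = np.random.default_rng(0).uniform(-50, 50, size=(20, 3))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)


class TestSliceStack:
    def test_interior_slices(self, phantom_case):
        ct, _ = phantom_case
        s = a.stack_adjacent_slices(ct, 5)
        np.testing.assert_array_equal(s.channels[0], ct.data[4])
        np.testing.assert_array_equal(s.channels[1], ct.data[5])
        np.testing.assert_array_equal(s.channels[2], ct.data[6])

    def test_edge_replication(self, phantom_case):
        ct, _ = phantom_case
        first = a.stack_adjacent_slices(ct, 0)
        np.testing.assert_array_equal(first.channels[0], first.channels[1])
        last = a.stack_adjacent_slices(ct, ct.shape[0] - 1)
        np.testing.assert_array_equal(last.channels[1], ct.data[-1])
        np.testing.assert_array_equal(last.channels[2], ct.data[-1])

    def test_single_slice_volume(self):
        v = _vol(np.random.default_rng(0).normal(size=(1, 4, 4)))
        s = a.stack_adjacent_slices(v, 0)
        np.testing.assert_array_equal(s.channels[0], s.channels[1])
        np.testing.assert_array_equal(s.channels[1], s.channels[2])

    def test_out_of_range_index(self, phantom_case):
        ct, _ = phantom_case
        with pytest.raises(IndexError):
            a.stack_adjacent_slices(ct, ct.shape[0])
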