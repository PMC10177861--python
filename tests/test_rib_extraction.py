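"""Gradient-domain bone-shadow extraction: stage oracles and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from ribsuppress.phantom import PhantomSpec, generate
from ribsuppress.rib_extraction import (
    BoneImage, ExtractionParams, RibExtractionError,
    centerline_knn_smooth, extract_bone, gaussian_smooth_t,
    partial_derivative_s, reintegrate_s,
)
from ribsuppress.st_transform import Contour, STImage


def make_st(values, valid=None, ds=1.0, dt=1.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return STImage(values=values, valid=np.asarray(valid, dtype=bool),
                   ds=ds, dt=dt, s_max=values.shape[0] - 1.0)


# ---------------------------------------------------------------------------
# independent brute-force stage oracles (plain loops, no vectorisation)

def brute_derivative(values, valid):
    S, T = values.shape
    out = np.zeros((S, T))
    ok = valid.copy()
    for j in range(T):
        for i in range(1, S):
            out[i, j] = values[i, j] - values[i - 1, j]
            ok[i, j] = valid[i, j] and valid[i - 1, j]
    return out, ok


def brute_trapezoid(g):
    S, T = g.shape
    out = np.zeros((S, T))
    for j in range(T):
        for i in range(1, S):
            out[i, j] = out[i - 1, j] + (g[i, j] + g[i - 1, j]) / 2.0
    return out


def brute_knn(values, valid, tau, k):
    S, T = values.shape
    out = values.copy()
    for j in range(T):
        for i in range(1, S):
            if not valid[i, j]:
                continue
            denom = values[i - 1, j]
            with np.errstate(over="ignore"):
                keep = True if denom == 0 else values[i, j] / denom > tau
            if not keep:
                m0 = max(0, i - k + 1)
                window = [values[m, j] for m in range(m0, i + 1)]
                out[i, j] = math.fsum(window) / len(window)
    return out


grids = hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                min_side=2, max_side=16),
                   elements=hst.floats(-10, 10, allow_nan=False))


class TestPartialDerivative:
    def test_constant_is_zero(self):
        d = partial_derivative_s(make_st(np.full((6, 9), 4.2)))
        assert np.all(d.values == 0.0)

    def test_ramp_gives_slope(self):
        a = 0.7
        st = make_st(a * np.arange(5)[:, None] * np.ones((1, 8)))
        d = partial_derivative_s(st)
        assert np.allclose(d.values[1:], a)
        assert np.all(d.values[0] == 0.0)

    @given(grids)
    def test_matches_brute_force(self, v):
        d = partial_derivative_s(make_st(v))
        ref, _ = brute_derivative(v, np.ones_like(v, dtype=bool))
        assert np.array_equal(d.values, ref)

    def test_invalid_predecessor_invalidates_cell(self):
        valid = np.ones((4, 3), dtype=bool)
        valid[1, 1] = False
        d = partial_derivative_s(make_st(np.ones((4, 3)), valid))
        assert not d.valid[1, 1] and not d.valid[2, 1]
        assert d.valid[3, 1]


class TestGaussianSmoothT:
    def test_constant_row_unchanged(self):
        g = gaussian_smooth_t(make_st(np.full((3, 64), 2.5)), sigma=6.0)
        assert np.allclose(g.values, 2.5, atol=1e-9)

    def test_impulse_mass_conserved(self):
        v = np.zeros((1, 128))
        v[0, 50] = 1.0
        g = gaussian_smooth_t(make_st(v), sigma=5.0)
        assert g.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert g.values[0, 50] == g.values.max()

    def test_sinusoid_attenuation_matches_transfer_function(self):
        T, P, sigma = 256, 32.0, 4.0
        t = np.arange(T)
        v = np.sin(2 * np.pi * t / P)[None, :]
        g = gaussian_smooth_t(make_st(v), sigma=sigma)
        # projection onto the input sinusoid gives the surviving amplitude
        amp = 2.0 * np.mean(g.values[0] * v[0])
        expected = np.exp(-2 * np.pi ** 2 * sigma ** 2 / P ** 2)
        assert amp == pytest.approx(expected, rel=0.02)

    def test_masked_cells_do_not_bleed(self):
        v = np.zeros((1, 64))
        valid = np.ones((1, 64), dtype=bool)
        v[0, 10] = 1e6          # garbage hidden behind the mask
        valid[0, 10] = False
        g = gaussian_smooth_t(make_st(v, valid), sigma=3.0)
        assert np.abs(g.values[0, valid[0]]).max() < 1e-9


class TestReintegrate:
    def test_zero_gradients_stay_zero(self):
        r = reintegrate_s(make_st(np.zeros((5, 7))))
        assert np.all(r.values == 0.0)

    def test_hand_trapezoid_column(self):
        r = reintegrate_s(make_st(np.array([[0.0], [1.0], [3.0]])))
        assert np.allclose(r.values[:, 0], [0.0, 0.5, 2.5])

    @given(grids)
    def test_trapezoid_matches_loop_oracle(self, g):
        r = reintegrate_s(make_st(g), method="trapezoid")
        assert np.allclose(r.values, brute_trapezoid(g), atol=1e-10)

    def test_cumsum_mode_recovers_smooth_column_exactly(self):
        s = np.linspace(0, 3, 12)
        col = np.sin(s) + 0.3 * s ** 2
        st = make_st(col[:, None])
        rec = reintegrate_s(partial_derivative_s(st), method="cumsum")
        assert np.abs(rec.values[:, 0] - (col - col[0])).max() < 1e-10

    def test_trapezoid_mode_recovers_half_lagged_column(self):
        s = np.linspace(0, 3, 12)
        col = np.sin(s) + 0.3 * s ** 2
        st = make_st(col[:, None])
        rec = reintegrate_s(partial_derivative_s(st), method="trapezoid")
        lagged = 0.5 * (col + np.concatenate([[col[0]], col[:-1]])) - col[0]
        assert np.abs(rec.values[:, 0] - lagged).max() < 1e-10


class TestCenterlineKNN:
    def test_constant_positive_column_kept_for_small_tau(self):
        v = np.full((6, 4), 3.0)
        out = centerline_knn_smooth(make_st(v), ExtractionParams(tau=0.5))
        assert np.array_equal(out.values, v)

    def test_k_one_replacement_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 5))
        out = centerline_knn_smooth(make_st(v),
                                    ExtractionParams(tau=100.0, k_center=1))
        assert np.allclose(out.values, v)

    def test_printed_rule_on_hand_column(self):
        v = np.array([2.0, 2.0, 2.0, 6.0])[:, None]
        out = centerline_knn_smooth(make_st(v),
                                    ExtractionParams(tau=2.0, k_center=2))
        # ratios: rows 1,2 give 1 <= tau -> averaged (still 2); row 3: 3 > tau -> kept
        assert np.allclose(out.values[:, 0], [2.0, 2.0, 2.0, 6.0])
        assert out.values[3, 0] == 6.0

    @given(grids, hst.floats(0.2, 3.0), hst.integers(1, 6))
    def test_matches_direct_rule_evaluation(self, v, tau, k):
        params = ExtractionParams(tau=tau, k_center=k)
        out = centerline_knn_smooth(make_st(v), params)
        ref = brute_knn(v, np.ones_like(v, dtype=bool), tau, k)
        assert np.allclose(out.values, ref, atol=1e-12)

    def test_inverted_branch_switch(self):
        v = np.array([1.0, 2.0, 8.0])[:, None]   # ratios 2, 4
        kept = centerline_knn_smooth(make_st(v), ExtractionParams(tau=1.5))
        inv = centerline_knn_smooth(
            make_st(v), ExtractionParams(tau=1.5, keep_if_ratio_gt=False))
        assert np.allclose(kept.values[:, 0], v[:, 0])
        assert not np.allclose(inv.values[:, 0], v[:, 0])


class TestExtractBone:
    def test_no_structure_along_s_gives_zero_bone(self):
        """A field constant along every inward normal leaves no bone signal."""
        contour = Contour([(10, 6), (170, 6), (170, 22), (10, 22)])
        mask = np.zeros((40, 180), dtype=bool)
        mask[6:23, 10:171] = True
        x = np.arange(180.0)
        img = np.tile(0.4 + 0.2 * np.sin(x / 9.0), (40, 1))
        bone = extract_bone(img, contour, mask,
                            ExtractionParams(kernel_sigma_t=3.0))
        core = mask.copy()
        core[:, :40] = core[:, 141:] = False   # clear of the end-edge bands
        assert np.abs(bone.values[core]).max() < 1e-6 * 0.4

    def test_phantom_bone_recovered_within_tolerance(self, single_rib_phantom):
        s = single_rib_phantom
        bone = extract_bone(s.input, s.contours[0], s.masks[0],
                            ExtractionParams(), ds=0.5, dt=0.5)
        band = s.masks[0]
        err = np.sqrt(np.mean((bone.values[band] - s.bone[band]) ** 2))
        assert err <= 0.05 * s.spec.rib_amplitude

    def test_decreasing_profile_clamps_to_zero(self, single_rib_phantom):
        s = single_rib_phantom
        img = 1.0 - s.bone     # shadow dips instead of rising: all-negative field
        bone = extract_bone(img, s.contours[0], s.masks[0], ExtractionParams())
        assert np.all(bone.values == 0.0)

    def test_output_nonnegative_and_zero_outside_support(self, single_rib_phantom):
        s = single_rib_phantom
        bone = extract_bone(s.input, s.contours[0], s.masks[0])
        assert bone.values.min() >= 0.0
        assert np.all(bone.values[~bone.support] == 0.0)

    def test_linearity_up_to_clamp(self, single_rib_phantom):
        s = single_rib_phantom
        a = 2.5
        b1 = extract_bone(s.bone, s.contours[0], s.masks[0],
                          ExtractionParams(), ds=0.5, dt=0.5)
        b2 = extract_bone(a * s.bone, s.contours[0], s.masks[0],
                          ExtractionParams(), ds=0.5, dt=0.5)
        assert np.allclose(b2.values, a * b1.values, atol=1e-9)

    def test_empty_band_raises_with_label(self):
        contour = Contour([(200, 200), (210, 200), (210, 210), (200, 210)],
                          label="R9")
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:30, 20:30] = True
        with pytest.raises((RibExtractionError, Exception)):
            extract_bone(np.zeros((50, 50)), contour, mask)

    def test_bone_image_validates_shapes(self):
        with pytest.raises(ValueError):
            BoneImage(values=np.zeros((4, 4)), support=np.zeros((5, 5), dtype=bool))
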