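"""Filter-bank construction and 2-D DWT correctness.

The independent oracle used throughout is explicit 1-D circular
convolution y[n] = sum_k f[k] x[(2n + L/2 - k) mod N] applied to rows then
columns, which pins down the package's phase convention.
"""

import numpy as np
import pytest

from wavepool.wavelets import (FilterBank, SubbandSet, dwt2, idwt2,
                               make_symlet, max_levels, wavedec2, waverec2)

ORDERS = (2, 4, 6)

# published orthonormal Symlet-2 scaling coefficients
SYM2_DEC_LO = (-0.12940952255092145, 0.22414386804185735,
               0.836516303737469, 0.48296291314469025)


def conv_downsample_1d(row, filt):
    """Oracle: circular convolution + downsample-by-2, offset L/2."""
    n, L = len(row), len(filt)
    return np.array([
        sum(filt[k] * row[(2 * i + L // 2 - k) % n] for k in range(L))
        for i in range(n // 2)
    ])


def dwt2_oracle(image, fb):
    """Rows-then-columns separable transform built from the 1-D oracle.

    LH = high-pass along the vertical (H) axis, low-pass along W;
    HL the converse -- the convention of the package's SubbandSet.
    """
    lo = np.array([conv_downsample_1d(r, fb.dec_lo) for r in image])
    hi = np.array([conv_downsample_1d(r, fb.dec_hi) for r in image])
    ll = np.array([conv_downsample_1d(c, fb.dec_lo) for c in lo.T]).T
    lh = np.array([conv_downsample_1d(c, fb.dec_hi) for c in lo.T]).T
    hl = np.array([conv_downsample_1d(c, fb.dec_lo) for c in hi.T]).T
    hh = np.array([conv_downsample_1d(c, fb.dec_hi) for c in hi.T]).T
    return ll, lh, hl, hh


class TestFilterBank:
    @pytest.mark.parametrize("order,taps", [(2, 4), (4, 8), (6, 12)])
    def test_tap_count(self, order, taps):
        fb = make_symlet(order)
        assert len(fb.dec_lo) == len(fb.dec_hi) == taps

    @pytest.mark.parametrize("order", ORDERS)
    def test_orthonormality(self, order):
        lo = np.array(make_symlet(order).dec_lo)
        assert abs(lo.sum() - np.sqrt(2)) < 1e-10
        assert abs((lo ** 2).sum() - 1.0) < 1e-10

    @pytest.mark.parametrize("order", ORDERS)
    def test_qmf_relation_and_reversal(self, order):
        fb = make_symlet(order)
        lo, hi = np.array(fb.dec_lo), np.array(fb.dec_hi)
        L = len(lo)
        expected = np.array([(-1) ** k * lo[L - 1 - k] for k in range(L)])
        np.testing.assert_allclose(hi, expected, atol=1e-14)
        np.testing.assert_allclose(fb.rec_lo, lo[::-1], atol=1e-14)
        np.testing.assert_allclose(fb.rec_hi, hi[::-1], atol=1e-14)

    @pytest.mark.parametrize("order", ORDERS)
    def test_vanishing_moments_equal_order(self, order):
        # normalize by the k^m weight scale: raw sums inherit the published
        # coefficients' ~1e-13 precision amplified by (2N-1)^m
        hi = np.array(make_symlet(order).dec_hi)
        k = np.arange(len(hi))
        for m in range(order):
            scale = max(1.0, float((k ** m).max()))
            assert abs(np.sum(hi * k ** m)) / scale < 1e-8, f"moment {m} should vanish"
        scale = float((k ** order).max())
        assert abs(np.sum(hi * k ** order)) / scale > 1e-4

    def test_sym2_matches_published_table(self):
        np.testing.assert_allclose(make_symlet(2).dec_lo, SYM2_DEC_LO, atol=1e-12)

    @pytest.mark.parametrize("bad", [0, 3, 8, -2])
    def test_unsupported_order_names_allowed(self, bad):
        with pytest.raises(ValueError, match=r"2, 4, 6"):
            make_symlet(bad)


class TestDwt2:
    @pytest.mark.parametrize("order", ORDERS)
    def test_constant_image(self, order):
        sub = dwt2(np.full((16, 20), 0.7), make_symlet(order))
        np.testing.assert_allclose(sub.ll, 1.4, atol=1e-10)
        for band in (sub.lh, sub.hl, sub.hh):
            np.testing.assert_allclose(band, 0.0, atol=1e-10)

    def test_subband_shapes_halve(self):
        sub = dwt2(np.zeros((224, 224)), make_symlet(2))
        assert all(b.shape == (112, 112) for b in sub.subbands)

    @pytest.mark.parametrize("order", ORDERS)
    def test_matches_convolution_oracle(self, order):
        fb = make_symlet(order)
        rng = np.random.default_rng(100 + order)
        for _ in range(20):
            x = rng.standard_normal((16, 16))
            sub = dwt2(x, fb)
            for got, want in zip(sub.subbands, dwt2_oracle(x, fb)):
                np.testing.assert_allclose(got, want, atol=1e-8)

    @pytest.mark.parametrize("order", ORDERS)
    def test_energy_conservation(self, order):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((32, 32))
        sub = dwt2(x, make_symlet(order))
        assert abs(np.sum(x ** 2) - sum(np.sum(b ** 2) for b in sub.subbands)) < 1e-8

    def test_rejects_bad_input(self):
        fb = make_symlet(2)
        with pytest.raises(ValueError):
            dwt2(np.zeros((1, 8)), fb)
        with pytest.raises(ValueError):
            dwt2(np.array([[np.nan, 1], [2, 3]]), fb)


class TestIdwt2:
    @pytest.mark.parametrize("order", ORDERS)
    def test_perfect_reconstruction(self, order):
        fb = make_symlet(order)
        x = np.random.default_rng(order).standard_normal((32, 32))
        np.testing.assert_allclose(idwt2(dwt2(x, fb), fb), x, atol=1e-8)

    def test_constant_inverse(self):
        fb = make_symlet(2)
        sub = SubbandSet(ll=np.full((8, 8), 1.0), lh=np.zeros((8, 8)),
                         hl=np.zeros((8, 8)), hh=np.zeros((8, 8)),
                         source_shape=(16, 16))
        np.testing.assert_allclose(idwt2(sub, fb), 0.5, atol=1e-10)

    def test_isometry_on_random_subbands(self):
        fb = make_symlet(4)
        rng = np.random.default_rng(11)
        bands = [rng.standard_normal((8, 8)) for _ in range(4)]
        sub = SubbandSet(*bands, source_shape=(16, 16))
        rec = idwt2(sub, fb)
        assert abs(np.sum(rec ** 2) - sum(np.sum(b ** 2) for b in bands)) < 1e-8

    def test_mismatched_subbands_error(self):
        with pytest.raises(ValueError, match="differ"):
            SubbandSet(ll=np.zeros((4, 4)), lh=np.zeros((4, 4)),
                       hl=np.zeros((4, 4)), hh=np.zeros((3, 4)),
                       source_shape=(8, 8))


class TestMultilevel:
    def test_two_level_shapes(self):
        dec = wavedec2(np.zeros((224, 224)), make_symlet(2), 2)
        assert dec.ll_final.shape == (56, 56)
        assert dec.details[0][0].shape == (112, 112)
        assert dec.details[1][0].shape == (56, 56)

    def test_single_level_equals_dwt2(self):
        x = np.random.default_rng(3).standard_normal((16, 16))
        fb = make_symlet(2)
        dec = wavedec2(x, fb, 1)
        sub = dwt2(x, fb)
        np.testing.assert_allclose(dec.ll_final, sub.ll, atol=1e-12)
        for got, want in zip(dec.details[0], (sub.lh, sub.hl, sub.hh)):
            np.testing.assert_allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("order", ORDERS)
    def test_round_trip(self, order):
        fb = make_symlet(order)
        x = np.random.default_rng(order).standard_normal((64, 64))
        np.testing.assert_allclose(waverec2(wavedec2(x, fb, 2), fb), x, atol=1e-8)

    def test_round_trip_odd_dims(self):
        fb = make_symlet(2)
        x = np.random.default_rng(9).standard_normal((30, 34))
        np.testing.assert_allclose(waverec2(wavedec2(x, fb, 2), fb), x, atol=1e-8)

    def test_too_many_levels_states_maximum(self):
        with pytest.raises(ValueError, match="maximum"):
            wavedec2(np.zeros((16, 16)), make_symlet(2), 10)
        assert max_levels((16, 16)) == 4
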