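"""Core combination machinery: thresholds, weights, blur-and-shift, and the
weighted geometric mean, checked against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scosfire.core import (
    BlurParams,
    CosfireTuple,
    ParameterError,
    blur_shift,
    gaussian_max_filter,
    sigma_prime,
    threshold_fraction,
    translate,
    tuple_weight,
    weighted_geometric_mean,
)

from .oracles import oracle_blur_shift, oracle_weighted_gmean


class TestWeights:
    def test_endpoints_at_50(self):
        sp = sigma_prime(50.0)
        assert tuple_weight(0.0, sp) == pytest.approx(1.0, abs=1e-12)
        assert tuple_weight(50.0, sp) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_endpoints_any_rho_max(self, rho_max):
        sp = sigma_prime(rho_max)
        assert tuple_weight(0.0, sp) == pytest.approx(1.0, abs=1e-12)
        assert tuple_weight(rho_max, sp) == pytest.approx(0.5, abs=1e-12)

    def test_formula(self):
        assert sigma_prime(50.0) == pytest.approx(
            math.sqrt(-(50.0**2) / (2.0 * math.log(0.5))), abs=1e-12
        )

    def test_zero_rho_max_gives_equal_weights(self):
        sp = sigma_prime(0.0)
        assert math.isinf(sp)
        assert tuple_weight(0.0, sp) == 1.0
        assert tuple_weight(123.0, sp) == 1.0

    def test_monotone_decay(self):
        sp = sigma_prime(10.0)
        w = [tuple_weight(r, sp) for r in (0.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_errors(self):
        with pytest.raises(ParameterError):
            sigma_prime(-1.0)
        with pytest.raises(ParameterError):
            tuple_weight(-1.0, 5.0)
        with pytest.raises(ParameterError):
            tuple_weight(1.0, 0.0)


class TestBlurParams:
    def test_linear_sigma(self):
        b = BlurParams(0.1, 0.0853)
        assert b.sigma(0.0) == pytest.approx(0.1)
        assert b.sigma(50.0) == pytest.approx(0.1 + 0.0853 * 50.0)

    def test_validation(self):
        with pytest.raises(ParameterError):
            BlurParams(0.0, 0.1)
        with pytest.raises(ParameterError):
            BlurParams(-1.0, 0.1)
        with pytest.raises(ParameterError):
            BlurParams(1.0, -0.1)


class TestCosfireTuple:
    def test_phi_normalized(self):
        t = CosfireTuple("c", 5.0, -math.pi / 2)
        assert t.phi == pytest.approx(3 * math.pi / 2)
        assert CosfireTuple("c", 0.0, 2 * math.pi).phi == 0.0

    def test_negative_rho_rejected(self):
        with pytest.raises(ParameterError):
            CosfireTuple("c", -1.0, 0.0)


class TestThresholdFraction:
    def test_zero_is_identity(self):
        m = np.array([[0.1, 0.5], [0.9, 0.0]])
        out = threshold_fraction(m, 0.0)
        assert np.array_equal(out, m)
        assert out is not m

    def test_soft_threshold(self):
        m = np.array([[0.1, 0.5], [1.0, 0.74]])
        out = threshold_fraction(m, 0.75)
        assert np.array_equal(out, [[0.0, 0.0], [1.0, 0.0]])

    def test_kept_values_unchanged(self):
        m = np.array([[0.2, 0.8, 1.0]])
        out = threshold_fraction(m, 0.5)
        assert out[0, 1] == 0.8 and out[0, 2] == 1.0

    def test_all_zero_map(self):
        m = np.zeros((4, 4))
        assert np.array_equal(threshold_fraction(m, 0.5), m)

    def test_invalid_fraction(self):
        with pytest.raises(ParameterError):
            threshold_fraction(np.ones((2, 2)), 1.5)
        with pytest.raises(ParameterError):
            threshold_fraction(np.ones((2, 2)), -0.1)


class TestTranslate:
    def test_definition(self):
        a = np.arange(12, dtype=float).reshape(3, 4)
        out = translate(a, 1, -1)
        # out(x, y) = a(x - 1, y + 1)
        for iy in range(3):
            for ix in range(4):
                sy, sx = iy + 1, ix - 1
                want = a[sy, sx] if 0 <= sy < 3 and 0 <= sx < 4 else 0.0
                assert out[iy, ix] == want

    def test_shift_out_of_frame(self):
        a = np.ones((3, 3))
        assert translate(a, 5, 0).sum() == 0.0
        assert translate(a, 0, -3).sum() == 0.0


class TestGaussianMaxFilter:
    def test_constant_map_unchanged(self):
        m = np.full((9, 9), 0.7)
        out = gaussian_max_filter(m, 1.5)
        assert np.allclose(out, 0.7, rtol=0, atol=0)

    def test_impulse_becomes_gaussian(self):
        m = np.zeros((15, 15))
        m[7, 7] = 1.0
        sigma = 1.2
        out = gaussian_max_filter(m, sigma)
        k = int(math.ceil(3 * sigma))
        for iy in range(15):
            for ix in range(15):
                dx, dy = ix - 7, iy - 7
                if abs(dx) <= k and abs(dy) <= k:
                    want = math.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma))
                    assert out[iy, ix] == pytest.approx(want, rel=1e-12)
                else:
                    assert out[iy, ix] == 0.0

    def test_errors(self):
        with pytest.raises(ParameterError):
            gaussian_max_filter(np.ones((3, 3)), 0.0)
        with pytest.raises(ParameterError):
            gaussian_max_filter(np.array([[1.0, -0.1]]), 1.0)


class TestBlurShiftOracle:
    @settings(max_examples=12)
    @given(
        seed=st.integers(0, 2**31 - 1),
        rho=st.floats(min_value=0.0, max_value=6.0),
        phi=st.floats(min_value=0.0, max_value=2 * math.pi - 1e-9),
        sigma0=st.floats(min_value=0.4, max_value=2.0),
        alpha=st.floats(min_value=0.0, max_value=0.2),
        t1=st.sampled_from([0.0, 0.2]),
    )
    def test_random_maps_match_brute_force(self, seed, rho, phi, sigma0, alpha, t1):
        rng = np.random.default_rng(seed)
        m = rng.random((16, 16))
        got = blur_shift(m, CosfireTuple("c", rho, phi),
                         BlurParams(sigma0, alpha), t1)
        want = oracle_blur_shift(m, rho, phi, sigma0, alpha, t1)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-300)

    def test_impulse_moves_to_filter_center(self):
        # a subunit response at its preferred position (rho, phi) from the
        # center must land on the center after the shift
        m = np.zeros((21, 21))
        rho, phi = 6.0, math.pi / 3
        cx = cy = 10
        sx = cx + int(round(rho * math.cos(phi)))
        sy = cy + int(round(rho * math.sin(phi)))
        m[sy, sx] = 1.0
        out = blur_shift(m, CosfireTuple("c", rho, phi), BlurParams(0.5, 0.0))
        iy, ix = np.unravel_index(out.argmax(), out.shape)
        assert (iy, ix) == (cy, cx)
        assert out[cy, cx] == 1.0


class TestWeightedGeometricMean:
    def test_zero_factor_zeroes_output(self):
        a = np.full((5, 5), 0.8)
        b = np.zeros((5, 5))
        out = weighted_geometric_mean([a, b], [0.0, 10.0])
        assert np.array_equal(out, np.zeros((5, 5)))

    def test_identical_maps_fixed_point(self):
        rng = np.random.default_rng(7)
        m = rng.random((8, 8))
        out = weighted_geometric_mean([m, m, m], [0.0, 5.0, 9.0])
        assert np.allclose(out, m, rtol=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(3)
        maps = [rng.random((10, 10)) for _ in range(3)]
        rhos = [0.0, 4.0, 9.0]
        sp = sigma_prime(max(rhos))
        got = weighted_geometric_mean(maps, rhos, t3=0.2)
        want = oracle_weighted_gmean(maps, rhos, sp, t3=0.2)
        assert np.allclose(got, want, rtol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        maps = [rng.random((6, 6)) for _ in range(3)]
        rhos = [1.0, 4.0, 9.0]
        sp = sigma_prime(9.0)
        a = weighted_geometric_mean(maps, rhos, sp=sp)
        b = weighted_geometric_mean(maps[::-1], rhos[::-1], sp=sp)
        assert np.allclose(a, b, rtol=1e-12)

    def test_errors(self):
        with pytest.raises(ParameterError):
            weighted_geometric_mean([], [])
        with pytest.raises(ParameterError):
            weighted_geometric_mean([np.ones((2, 2))], [1.0, 2.0])
        with pytest.raises(ParameterError):
            weighted_geometric_mean([np.ones((2, 2)), np.ones((3, 3))], [1.0, 2.0])
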