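"""Shape layer: configuration, response, AND behavior, perceptual ranking,
geometric transforms, and equivalence with a hand-composed evaluation."""

import math

import numpy as np
import pytest

import scosfire as sc
from scosfire.core import (
    BlurParams,
    CosfireTuple,
    ParameterError,
    sigma_prime,
    threshold_fraction,
    tuple_weight,
)
from scosfire.vertex import ConfigurationError, ResponseContext, VCosfireFilter
from scosfire.shape import strict_local_maxima

from .conftest import CENTER_512, SQUARE_HALF_SIDE, SQUARE_ORIENTATION
from .oracles import oracle_blur_shift, oracle_weighted_gmean


def center_response(resp, cx=CENTER_512[0], cy=CENTER_512[1], halo=4):
    iy, ix = int(round(cy)), int(round(cx))
    return float(resp[iy - halo : iy + halo + 1, ix - halo : ix + halo + 1].max())


class TestStrictLocalMaxima:
    def test_single_peak(self):
        m = np.zeros((8, 8))
        m[3, 5] = 1.0
        assert strict_local_maxima(m) == [(3, 5)]

    def test_plateau_keeps_lexicographic_representative(self):
        m = np.zeros((8, 8))
        m[4, 4] = m[4, 5] = 1.0
        assert strict_local_maxima(m) == [(4, 4)]

    def test_sorted_by_descending_value(self):
        m = np.zeros((10, 10))
        m[2, 2] = 0.5
        m[7, 7] = 1.0
        assert strict_local_maxima(m) == [(7, 7), (2, 2)]

    def test_all_zero(self):
        assert strict_local_maxima(np.zeros((5, 5))) == []


class TestConfigure:
    def test_triangle_worked_example(self, tri_filter):
        assert len(tri_filter.tuples) == 3
        want_phis = (math.pi / 2, 7 * math.pi / 6, 11 * math.pi / 6)
        seen = set()
        for vf, rho, phi in tri_filter.tuples:
            assert rho == pytest.approx(50.0, abs=2.0)
            assert vf.spec.gamma == pytest.approx(math.pi / 3)
            best = min(want_phis,
                       key=lambda p: abs((phi - p + math.pi) % (2 * math.pi) - math.pi))
            assert abs((phi - best + math.pi) % (2 * math.pi) - math.pi) \
                < math.radians(5.0)
            seen.add(best)
        assert len(seen) == 3

    def test_square_corner_representation(self, square_filter):
        # corner bisectors of the pi/12-rotated square fall on the bank's
        # orientation grid, so exactly the four right-angle corners configure
        assert len(square_filter.tuples) == 4
        half_diag = SQUARE_HALF_SIDE * math.sqrt(2.0)
        corners = [math.pi / 4 + SQUARE_ORIENTATION + k * math.pi / 2
                   for k in range(4)]
        seen = set()
        for vf, rho, phi in square_filter.tuples:
            assert vf.spec.gamma == pytest.approx(math.pi / 2)
            assert rho == pytest.approx(half_diag, abs=2.0)
            best = min(corners,
                       key=lambda p: abs((phi - p + math.pi) % (2 * math.pi) - math.pi))
            assert abs((phi - best + math.pi) % (2 * math.pi) - math.pi) \
                < math.radians(5.0)
            seen.add(round(best, 6))
        assert len(seen) == 4

    def test_blank_image_is_error(self, vbank):
        with pytest.raises(ConfigurationError):
            sc.configure_s_cosfire(np.zeros((64, 64)), (31.5, 31.5), vbank)

    def test_center_outside(self, vbank, triangle512):
        with pytest.raises(ParameterError):
            sc.configure_s_cosfire(triangle512, (600.0, 10.0), vbank)

    def test_empty_bank(self, triangle512):
        with pytest.raises(ParameterError):
            sc.configure_s_cosfire(triangle512, CENTER_512, [])

    def test_sigma_prime_consistency(self, tri_filter):
        assert tuple_weight(tri_filter.rho_max, tri_filter.sigma_prime) \
            == pytest.approx(0.5, abs=1e-12)


class TestApply:
    def test_self_match_peaks_at_center(self, triangle512, tri_filter):
        resp = sc.apply_s_cosfire(triangle512, tri_filter)
        iy, ix = np.unravel_index(resp.argmax(), resp.shape)
        assert math.hypot(ix - CENTER_512[0], iy - CENTER_512[1]) <= 3.0
        assert resp.max() > 0.5

    def test_and_property_erasing_any_vertex_zeroes_center(
        self, triangle512, tri_filter
    ):
        # "fully erased" must cover the vertex filters' spatial support:
        # tuple radius (<= 20) + blur window (~6) + Gabor kernel reach,
        # evaluated anywhere inside the shape-level blur window of the
        # corner (~13), so a 40 px disk around the corner suffices
        ys, xs = np.mgrid[0:512, 0:512]
        for vf, rho, phi in tri_filter.tuples:
            vx = CENTER_512[0] + rho * math.cos(phi)
            vy = CENTER_512[1] + rho * math.sin(phi)
            img = triangle512.copy()
            img[(xs - vx) ** 2 + (ys - vy) ** 2 < 40.0**2] = 0.0
            resp = sc.apply_s_cosfire(img, tri_filter)
            assert center_response(resp) == 0.0

    def test_perceptual_ranking(self, square_filter, square512):
        partial = sc.make_fig1_variant(
            "partial", SQUARE_HALF_SIDE, canvas=(512, 512),
            orientation=SQUARE_ORIENTATION,
        )
        scrambled = sc.make_fig1_variant(
            "scrambled", SQUARE_HALF_SIDE, canvas=(512, 512),
            orientation=SQUARE_ORIENTATION, seed=0,
        )
        full = center_response(sc.apply_s_cosfire(square512, square_filter))
        part = center_response(sc.apply_s_cosfire(partial, square_filter))
        scram = float(sc.apply_s_cosfire(scrambled, square_filter).max())
        # the corners carry the representation: the 25%-contour variant
        # scores close to the full square, the scrambled parts score nothing
        assert part > 0.5 * full
        assert scram == 0.0
        assert part > scram

    def test_t3_thresholds_output(self, triangle512, tri_filter):
        from dataclasses import replace

        resp = sc.apply_s_cosfire(triangle512, tri_filter)
        gated = sc.apply_s_cosfire(triangle512, replace(tri_filter, t3=0.5))
        assert np.array_equal(gated, threshold_fraction(resp, 0.5))


class TestTransforms:
    def test_rotation_adds_to_phi(self, tri_filter):
        rot = sc.rotate_s(tri_filter, math.pi / 3)
        for (v0, r0, p0), (v1, r1, p1) in zip(tri_filter.tuples, rot.tuples):
            assert r1 == r0
            assert p1 == pytest.approx((p0 + math.pi / 3) % (2 * math.pi))

    def test_rotations_compose(self, tri_filter):
        a = sc.rotate_s(sc.rotate_s(tri_filter, 0.4), 0.5)
        b = sc.rotate_s(tri_filter, 0.9)
        for (va, ra, pa), (vb, rb, pb) in zip(a.tuples, b.tuples):
            assert pa == pytest.approx(pb)
            for ta, tb in zip(va.tuples, vb.tuples):
                assert ta.phi == pytest.approx(tb.phi)
                assert ta.subunit[1] == pytest.approx(tb.subunit[1], abs=1e-8)

    def test_scale_rescales_sigma_prime(self, tri_filter):
        sca = sc.scale_s(tri_filter, 2.0)
        assert sca.rho_max == pytest.approx(2.0 * tri_filter.rho_max)
        assert sca.sigma_prime == pytest.approx(2.0 * tri_filter.sigma_prime)
        assert tuple_weight(sca.rho_max, sca.sigma_prime) \
            == pytest.approx(0.5, abs=1e-12)

    def test_scale_rotate_commute(self, tri_filter):
        a = sc.rotate_s(sc.scale_s(tri_filter, 1.5), 0.7)
        b = sc.scale_s(sc.rotate_s(tri_filter, 0.7), 1.5)
        for (va, ra, pa), (vb, rb, pb) in zip(a.tuples, b.tuples):
            assert ra == pytest.approx(rb)
            assert pa == pytest.approx(pb)

    def test_reflect_twice_identity(self, tri_filter):
        back = sc.reflect_s(sc.reflect_s(tri_filter))
        for (v0, r0, p0), (v1, r1, p1) in zip(tri_filter.tuples, back.tuples):
            assert r1 == pytest.approx(r0)
            assert abs((p1 - p0 + math.pi) % (2 * math.pi) - math.pi) < 1e-9

    def test_invalid_scale(self, tri_filter):
        with pytest.raises(ParameterError):
            sc.scale_s(tri_filter, -1.0)


class TestInvariance:
    def test_trivial_spec_equals_plain_apply(self, triangle512, tri_filter):
        spec = sc.InvarianceSpec()
        resp, label_idx, labels = sc.invariant_response(
            triangle512, tri_filter, spec
        )
        plain = sc.apply_s_cosfire(triangle512, tri_filter)
        assert np.array_equal(resp, plain)
        assert labels == [sc.TransformLabel(0.0, 1.0, False)]

    def test_validation(self):
        with pytest.raises(ParameterError):
            sc.InvarianceSpec(rotations=())
        with pytest.raises(ParameterError):
            sc.InvarianceSpec(scales=(0.0,))

    def test_constructors(self):
        spec = sc.InvarianceSpec.rotations_equidistant(4)
        assert spec.rotations == pytest.approx(
            (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)
        )
        grid = sc.InvarianceSpec.scale_grid((-1, 0, 1))
        assert grid.scales == pytest.approx(
            (2 ** -0.5, 1.0, 2 ** 0.5)
        )


class TestHandComposedEquivalence:
    def test_apply_equals_manual_composition_64x64(self):
        # two tiny vertex filters built by hand, one S filter on top;
        # every stage recomputed with the brute-force oracles
        blur_v = BlurParams(0.5, 0.05)
        blur_s = BlurParams(0.5, 0.05)
        vf1 = VCosfireFilter(
            (CosfireTuple((4.0, 0.0), 0.0, 0.0),
             CosfireTuple((4.0, math.pi / 2), 3.0, math.pi / 4)),
            blur_v, t1=0.1,
        )
        vf2 = VCosfireFilter(
            (CosfireTuple((4.0, math.pi / 2), 2.0, math.pi),),
            blur_v, t1=0.2,
        )
        filt = sc.SCosfireFilter(
            ((vf1, 6.0, 0.0), (vf2, 9.0, math.pi / 2)),
            blur_s, t1=0.15, t3=0.1,
        )
        rng = np.random.default_rng(11)
        img = rng.random((64, 64)) * sc.make_triangle(20.0, canvas=(64, 64))

        got = sc.apply_s_cosfire(img, filt)

        bank = filt.frontend.bank_for(filt.wavelengths)
        stack = sc.gabor_energy(img, bank)
        v_maps = []
        for vf in (vf1, vf2):
            parts = [
                oracle_blur_shift(
                    threshold_fraction(stack.channel(*t.subunit), vf.t1),
                    t.rho, t.phi, blur_v.sigma0, blur_v.alpha, t1=0.0,
                )
                for t in vf.tuples
            ]
            v_maps.append(
                oracle_weighted_gmean(
                    parts, [t.rho for t in vf.tuples],
                    sigma_prime(max(t.rho for t in vf.tuples)),
                )
            )
        s_parts = [
            oracle_blur_shift(
                threshold_fraction(v, filt.t1), rho, phi,
                blur_s.sigma0, blur_s.alpha, t1=0.0,
            )
            for v, (_, rho, phi) in zip(v_maps, filt.tuples)
        ]
        want = oracle_weighted_gmean(
            s_parts, [rho for _, rho, _ in filt.tuples],
            filt.sigma_prime, t3=filt.t3,
        )
        assert np.allclose(got, want, rtol=1e-10, atol=1e-300)
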