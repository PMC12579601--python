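"""Afterimage prediction models: oracles, invariants, limiting cases."""

import math

import numpy as np
import pytest

from afterimage.colorimetry import (
    ConeFundamentals,
    DKLSpace,
    GamutError,
    LMS_to_XYZ,
    MonitorModel,
    XYZ_to_LMS,
    circular_signed_difference,
)
from afterimage.models import (
    AdaptationConfig,
    HeringPrototypes,
    add_response_noise,
    cone_contrast,
    effective_adapting_colour,
    predict_appearance_model,
    predict_cone_adaptation,
    predict_cone_opponent,
    predict_hering,
)
from afterimage.stimuli import InducerSpec


class TestConeContrast:
    def test_zero_at_adapting_point(self):
        assert np.allclose(cone_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), 0.0)

    def test_arithmetic(self):
        assert np.allclose(
            cone_contrast([1.0, 1.0, 1.0], [0.5, 1.0, 2.0]), [1.0, 0.0, -0.5]
        )

    def test_ratio_cancellation(self):
        a = np.array([0.7, 1.1, 0.4])
        b = np.array([0.5, 0.9, 0.8])
        scaled = cone_contrast(a * [3, 1, 1], b * [3, 1, 1])
        assert np.allclose(scaled, cone_contrast(a, b))

    def test_degenerate_adapting(self):
        with pytest.raises(GamutError):
            cone_contrast([1.0, 1.0, 1.0], [0.0, 1.0, 1.0])


class TestEffectiveAdaptingColour:
    def test_partial_strength(self, monitor, cfg):
        lms = effective_adapting_colour(InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg)
        L, c, h = monitor.luv_polar_of_XYZ(LMS_to_XYZ(lms, monitor.fundamentals))
        assert (c, h) == pytest.approx((27.0, 60.0), abs=1e-9)
        assert L == pytest.approx(70.0, abs=1e-9)

    def test_complete_adaptation_variant(self, monitor):
        cfg = AdaptationConfig(adapt_chroma_luv=50.0)
        ind = InducerSpec("CIELUV", 60.0, 50.0)
        lms = effective_adapting_colour(ind, monitor, cfg)
        assert np.allclose(
            LMS_to_XYZ(lms, monitor.fundamentals), ind.to_XYZ(monitor), atol=1e-9
        )

    def test_zero_strength_is_background(self, monitor):
        cfg = AdaptationConfig(adapt_chroma_luv=0.0)
        lms = effective_adapting_colour(InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg)
        assert np.allclose(
            LMS_to_XYZ(lms, monitor.fundamentals), monitor.background_XYZ, atol=1e-9
        )

    def test_strength_beyond_gamut(self, monitor):
        cfg = AdaptationConfig(adapt_chroma_luv=500.0)
        with pytest.raises(GamutError):
            effective_adapting_colour(InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg)


class TestConeAdaptation:
    def test_independent_oracle_and_frozen_regression(self, monitor, cfg):
        """Step-by-step oracle with a different matrix path (raw
        unscaled cone matrix, own CIELUV algebra)."""
        prediction = predict_cone_adaptation(InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg)

        # --- fully independent re-derivation -------------------------
        W = np.array([0.3304 * 101.1 / 0.3526, 101.1,
                      (1 - 0.3304 - 0.3526) * 101.1 / 0.3526])
        bgXYZ = W * ((70 + 16) / 116) ** 3
        M = np.array(
            [[0.210576, 0.855098, -0.0396983],
             [-0.417076, 1.17726, 0.0786283],
             [0.0, 0.0, 0.516835]]
        )  # raw published matrix: per-channel scaling differs from package

        def uv(p):
            d = p[0] + 15 * p[1] + 3 * p[2]
            return 4 * p[0] / d, 9 * p[1] / d

        upw, vpw = uv(W)

        def xyz_of(Lst, C, h):
            u, v = C * math.cos(math.radians(h)), C * math.sin(math.radians(h))
            Y = W[1] * ((Lst + 16) / 116) ** 3
            up, vp = u / (13 * Lst) + upw, v / (13 * Lst) + vpw
            return np.array(
                [Y * 9 * up / (4 * vp), Y, Y * (12 - 3 * up - 20 * vp) / (4 * vp)]
            )

        iLMS = M @ xyz_of(70.0, 27.0, 60.0)
        after = (M @ bgXYZ) ** 2 / iLMS
        aXYZ = np.linalg.solve(M, after)
        aXYZ *= bgXYZ[1] / aXYZ[1]
        Lst = 116 * (aXYZ[1] / W[1]) ** (1 / 3) - 16
        up, vp = uv(aXYZ)
        u, v = 13 * Lst * (up - upw), 13 * Lst * (vp - vpw)
        oracle_hue = math.degrees(math.atan2(v, u)) % 360
        oracle_chroma = math.hypot(u, v)

        assert prediction.hue_azimuth == pytest.approx(oracle_hue, abs=1e-3)
        assert prediction.chroma == pytest.approx(oracle_chroma, abs=1e-3)
        # frozen regression values
        assert prediction.hue_azimuth == pytest.approx(251.0053, abs=1e-3)
        assert prediction.chroma == pytest.approx(34.6277, abs=1e-3)

    def test_identity_when_no_adaptation(self, monitor):
        cfg0 = AdaptationConfig(adapt_chroma_luv=0.0)
        p = predict_cone_adaptation(InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg0)
        assert p.chroma == pytest.approx(0.0, abs=1e-9)
        assert not p.hue_defined

    def test_subtractive_limit(self, monitor):
        """Deviation from opponency shrinks strictly with adapting chroma
        and vanishes in the weak-adaptation (linearized) limit."""
        for hue in np.arange(0.0, 360.0, 45.0):
            ind = InducerSpec("CIELUV", hue, 50.0)
            devs = []
            for strength in (27.0, 9.0, 3.0, 1.0):
                p = predict_cone_adaptation(
                    ind, monitor, AdaptationConfig(adapt_chroma_luv=strength)
                )
                devs.append(abs(circular_signed_difference(p.hue_azimuth, hue + 180)))
            assert all(a > b for a, b in zip(devs, devs[1:])), (hue, devs)
            p = predict_cone_adaptation(
                ind, monitor, AdaptationConfig(adapt_chroma_luv=0.01)
            )
            assert abs(circular_signed_difference(p.hue_azimuth, hue + 180)) < 0.1

    def test_scale_invariance_of_fundamentals(self, monitor, cfg):
        rng = np.random.default_rng(3)
        base = predict_cone_adaptation(InducerSpec("CIELUV", 100.0, 50.0), monitor, cfg)
        for _ in range(5):
            scales = rng.uniform(0.1, 10.0, size=3)
            m2 = MonitorModel(
                primaries=monitor.primaries,
                gamma=monitor.gamma,
                white=monitor.white,
                background_Lstar=monitor.background_Lstar,
                fundamentals=monitor.fundamentals.rescaled(scales),
            )
            p = predict_cone_adaptation(InducerSpec("CIELUV", 100.0, 50.0), m2, cfg)
            assert p.hue_azimuth == pytest.approx(base.hue_azimuth, abs=1e-9)
            assert p.chroma == pytest.approx(base.chroma, abs=1e-9)

    def test_three_peaks_and_six_zero_crossings(self, monitor, cfg, dkl):
        hues = np.arange(0.0, 360.0, 5.0)
        preds = [
            predict_cone_adaptation(InducerSpec("CIELUV", h, 50.0), monitor, cfg, dkl)
            for h in hues
        ]
        chroma = np.array([p.chroma for p in preds])
        dev = np.array(
            [circular_signed_difference(p.hue_azimuth, h + 180) for p, h in zip(preds, hues)]
        )
        n_max = int(np.sum((chroma > np.roll(chroma, 1)) & (chroma >= np.roll(chroma, -1))))
        assert n_max == 3
        sign = np.sign(dev)
        assert int(np.sum(sign != np.roll(sign, 1))) == 6

    def test_not_reciprocal(self, monitor, cfg):
        """The afterimage of the afterimage is not the original inducer."""
        worst = 0.0
        for hue in np.arange(0.0, 360.0, 15.0):
            p1 = predict_cone_adaptation(InducerSpec("CIELUV", hue, 50.0), monitor, cfg)
            p2 = predict_cone_adaptation(
                InducerSpec("CIELUV", p1.hue_azimuth, 50.0), monitor, cfg
            )
            worst = max(worst, abs(circular_signed_difference(p2.hue_azimuth, hue)))
        assert worst > 2.0


class TestConeOpponent:
    def test_dkl_opposite(self, monitor, cfg, dkl):
        p = predict_cone_opponent(InducerSpec("DKL", 60.0, 0.5), monitor, cfg, dkl)
        assert p.native["dkl_azimuth"] == pytest.approx(240.0, abs=1e-9)

    def test_radius_proportional_to_k(self, monitor, dkl):
        cfg = AdaptationConfig(k=0.5)
        p = predict_cone_opponent(InducerSpec("DKL", 10.0, 0.5), monitor, cfg, dkl)
        assert p.native["dkl_radius"] == pytest.approx(0.25, abs=1e-9)

    def test_luv_hue_independent_of_k(self, monitor, dkl):
        hues = [
            predict_cone_opponent(
                InducerSpec("DKL", 33.0, 0.5), monitor, AdaptationConfig(k=k), dkl
            ).hue_azimuth
            for k in (0.2, 0.5, 0.9)
        ]
        assert np.ptp(hues) < 1e-6

    def test_default_k_matches_strength(self, monitor, cfg, dkl):
        p = predict_cone_opponent(InducerSpec("DKL", 60.0, 0.5), monitor, cfg, dkl)
        assert p.native["k"] == pytest.approx(0.47 / 0.5, abs=1e-6)

    def test_halfwave_rectification_is_noop(self, monitor, dkl):
        for hue in np.arange(0.0, 360.0, 5.0):
            ind = InducerSpec("CIELUV", hue, 50.0)
            a = predict_cone_opponent(ind, monitor, AdaptationConfig(), dkl)
            b = predict_cone_opponent(
                ind, monitor, AdaptationConfig(halfwave_rectify=True), dkl
            )
            assert abs(circular_signed_difference(a.hue_azimuth, b.hue_azimuth)) < 1e-6
            assert a.chroma == pytest.approx(b.chroma, abs=1e-6)

    def test_isoluminant_cone_contrast_identity(self, monitor, cfg, dkl):
        """With k = 1 the subtractive opponent prediction equals the
        negated inducer cone contrasts expressed on the DKL axes."""
        bg = monitor.background_LMS
        for hue in (0.0, 60.0, 145.0, 260.0):
            ind = InducerSpec("CIELUV", hue, 50.0)
            i_lms = XYZ_to_LMS(ind.to_XYZ(monitor), monitor.fundamentals)
            icc = (i_lms - bg) / bg
            pred = predict_cone_opponent(
                ind, monitor, AdaptationConfig(k=1.0), dkl
            )
            # un-scale the gamut-normalized coordinates
            lm_raw = pred.native["dkl"][0] * dkl.lm_unit
            s_raw = pred.native["dkl"][1] * dkl.s_unit
            assert s_raw == pytest.approx(-icc[2], abs=1e-9)
            assert lm_raw == pytest.approx(-(icc[0] - icc[1]), abs=1e-9)


class TestAppearanceModels:
    def test_identity_at_zero_strength(self, monitor):
        cfg0 = AdaptationConfig(adapt_chroma_luv=0.0)
        for which in ("cieluv", "cielab", "ciecam02"):
            p = predict_appearance_model(
                InducerSpec("CIELUV", 60.0, 50.0), monitor, cfg0, which
            )
            assert p.chroma == pytest.approx(0.0, abs=1e-6)

    def test_cieluv_hue_equals_opponent_hue(self, monitor, cfg, dkl):
        for hue in np.arange(0.0, 360.0, 15.0):
            ind = InducerSpec("CIELUV", hue, 50.0)
            a = predict_appearance_model(ind, monitor, cfg, "cieluv")
            b = predict_cone_opponent(ind, monitor, cfg, dkl)
            assert abs(circular_signed_difference(a.hue_azimuth, b.hue_azimuth)) < 1e-6

    def test_cat02_against_reference_implementation(self, monitor, cfg):
        """Cross-check the CAT02 corresponding-colour step against a
        direct transcription of the published transform."""
        M = np.array(
            [[0.7328, 0.4296, -0.1624],
             [-0.7036, 1.6975, 0.0061],
             [0.0030, 0.0136, 0.9834]]
        )
        La = monitor.background_XYZ[1] / 5.0
        D = 1.0 * (1.0 - (1.0 / 3.6) * math.exp((-La - 42.0) / 92.0))
        for hue in np.arange(0.0, 360.0, 45.0):
            ind = InducerSpec("CIELUV", hue, 50.0)
            p = predict_appearance_model(ind, monitor, cfg, "ciecam02")
            wa = p.native["adapting_white_XYZ"]
            wr = monitor.white_XYZ
            rgb = M @ monitor.background_XYZ
            rgb_c = rgb * (D * (M @ wr) / (M @ wa) + (1 - D))
            xyz_c = np.linalg.solve(M, rgb_c)
            xyz_c *= monitor.background_XYZ[1] / xyz_c[1]
            _, c, h = monitor.luv_polar_of_XYZ(xyz_c)
            assert abs(circular_signed_difference(p.hue_azimuth, h)) < 0.1
            assert p.chroma == pytest.approx(c, rel=1e-6)

    def test_unknown_label(self, monitor, cfg):
        with pytest.raises(ValueError):
            predict_appearance_model(InducerSpec("CIELUV", 0.0, 50.0), monitor, cfg, "hsv")


class TestHering:
    def test_prototype_maps_to_opponent_prototype(self, prototypes):
        p = predict_hering(InducerSpec("CIELUV", prototypes.red, 50.0), prototypes)
        assert p.hue_azimuth == pytest.approx(prototypes.green)
        assert p.chroma is None

    def test_midpoint(self, prototypes):
        mid = prototypes.red + 0.5 * ((prototypes.yellow - prototypes.red) % 360)
        p = predict_hering(InducerSpec("CIELUV", mid, 50.0), prototypes)
        expect = prototypes.green + 0.5 * ((prototypes.blue - prototypes.green) % 360)
        assert p.hue_azimuth == pytest.approx(expect % 360)

    def test_quarter_against_parametric_oracle(self, prototypes):
        # brute-force parametric interpolation oracle on the yellow->green arc
        t = 0.25
        start, end = prototypes.yellow, prototypes.green
        ind_hue = (start + t * ((end - start) % 360)) % 360
        o_start, o_end = prototypes.blue, prototypes.red
        oracle = (o_start + t * ((o_end - o_start) % 360)) % 360
        p = predict_hering(InducerSpec("CIELUV", ind_hue, 50.0), prototypes)
        assert p.hue_azimuth == pytest.approx(oracle, abs=1e-9)

    def test_invalid_cyclic_order(self):
        with pytest.raises(ValueError):
            HeringPrototypes(red=10, yellow=200, green=100, blue=300)


class TestResponseNoise:
    def test_sigma_zero_and_determinism(self):
        hues = [10.0, 200.0]
        s0 = add_response_noise(hues, 0.0, 5, seed=1)
        assert np.allclose(s0, np.array(hues)[:, None])
        a = add_response_noise(hues, 15.0, 100, seed=42)
        b = add_response_noise(hues, 15.0, 100, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, add_response_noise(hues, 15.0, 100, seed=43))

    def test_wrapped_gaussian_moments(self):
        samples = add_response_noise([90.0], 15.0, 100_000, seed=7)[0]
        rad = np.radians(samples)
        R = np.hypot(np.cos(rad).mean(), np.sin(rad).mean())
        circ_sd = np.degrees(np.sqrt(-2 * np.log(R)))
        assert circ_sd == pytest.approx(15.0, rel=0.01)
        mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360
        assert mean == pytest.approx(90.0, abs=0.5)

    def test_negative_sigma(self):
        with pytest.raises(ValueError):
            add_response_noise([0.0], -1.0, 10, seed=0)
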