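"""TIE Poisson and WOTF-deconvolution phase recovery."""

import numpy as np
import pytest

from aitie import (ComplexObject, FocalStack, ImagingConfig, PhaseMap,
                   ReconSettings, SourceSpec, axial_derivative,
                   gaussian_bumps, ideal_lowpass_reference,
                   multi_distance_combine, rmse, siemens_star,
                   through_focus_stack, tie_poisson_solve, wotf_deconvolve)

EPS = float(np.finfo(float).eps)


@pytest.fixture(scope="module")
def weak_stack(cfg128, annulus):
    star = siemens_star(128, 0.13, n_spokes=16, peak_phase=0.05)
    sm = ideal_lowpass_reference(star, cfg128, 1.4)
    obj = ComplexObject.from_phase(sm)
    stack = through_focus_stack(obj, cfg128, annulus, [-0.5, 0.0, 0.5],
                                method="weak_object")
    return stack, sm


class TestAxialDerivative:
    def test_identical_planes_zero(self):
        imgs = np.ones((2, 16, 16))
        stack = FocalStack(imgs, (-0.5, 0.5), 0.13)
        assert np.all(axial_derivative(stack) == 0)

    def test_constant_offset_planes(self):
        c = 0.04
        stack = FocalStack(np.stack([(1 - c) * np.ones((16, 16)),
                                     (1 + c) * np.ones((16, 16))]),
                           (-0.5, 0.5), 0.13)
        assert np.allclose(axial_derivative(stack), c / 0.5)

    def test_missing_pair_raises(self):
        stack = FocalStack(np.ones((2, 8, 8)) , (0.0, 0.5), 0.13)
        with pytest.raises(ValueError, match="symmetric"):
            axial_derivative(stack)

    def test_derivative_spectrum_matches_wotf_prediction(self, cfg128, annulus,
                                                         weak_stack):
        from scipy import fft as sfft
        from aitie import wotf
        stack, sm = weak_stack
        didz = axial_derivative(stack)
        M = wotf(cfg128, annulus, 0.5).values.imag
        pred = sfft.ifft2(-2.0 / 0.5 * M * sfft.fft2(sm.values)).real
        assert np.linalg.norm(didz - pred) / np.linalg.norm(pred) < 0.05


class TestTiePoisson:
    def test_cosine_phase_recovered_in_weak_defocus(self):
        """Single-frequency weak phase: TIE recovers the amplitude within
        2% when the transfer sin(πλzf²) ≈ πλzf²."""
        cfg = ImagingConfig(0.8, 0.55, 0.13, 128)
        fcyc = 6 / (128 * 0.13)  # 6 periods across the field
        x = np.arange(128) * 0.13
        phi = 0.05 * np.cos(2 * np.pi * fcyc * x)[None, :] * np.ones((128, 1))
        obj = ComplexObject.from_phase(PhaseMap(phi, 0.13))
        stack = through_focus_stack(obj, cfg, SourceSpec.delta(),
                                    [-0.1, 0.0, 0.1], method="weak_object")
        rec = tie_poisson_solve(stack, cfg)
        scale = np.dot(rec.values.ravel(), phi.ravel()) / np.dot(
            phi.ravel() - phi.mean(), phi.ravel())
        assert scale == pytest.approx(1.0, abs=0.02)

    def test_zero_derivative_gives_flat_phase(self, cfg128):
        stack = FocalStack(np.ones((3, 32, 32)), (-0.5, 0.0, 0.5), 0.13)
        rec = tie_poisson_solve(stack, cfg128)
        assert np.abs(rec.values).max() < 1e-12

    def test_nonpositive_intensity_rejected(self, cfg128):
        imgs = np.ones((3, 16, 16))
        imgs[1, 3, 3] = 0.0
        stack = FocalStack(imgs, (-0.5, 0.0, 0.5), 0.13)
        with pytest.raises(ValueError, match="strictly positive"):
            tie_poisson_solve(stack, cfg128)

    def test_agrees_with_wotf_deconvolution_in_coherent_weak_defocus(self, cfg128):
        bumps = gaussian_bumps(128, 0.13, [(40, 40), (88, 80)], sigma_px=12,
                               peak_phase=0.05)
        obj = ComplexObject.from_phase(bumps)
        stack = through_focus_stack(obj, cfg128, SourceSpec.delta(),
                                    [-0.1, 0.0, 0.1], method="weak_object")
        pt = tie_poisson_solve(stack, cfg128)
        pw = wotf_deconvolve(stack, cfg128, SourceSpec.delta(),
                             settings=ReconSettings(alpha=EPS), band_floor=0.0)
        assert rmse(pt, pw) / np.std(pw.values) < 0.03


class TestWotfDeconvolve:
    def test_noise_free_weak_phase_round_trip(self, cfg128, annulus, weak_stack):
        stack, sm = weak_stack
        rec = wotf_deconvolve(stack, cfg128, annulus)
        ref = sm.values - sm.values.mean()
        assert rmse(rec.values, ref) < 1e-3
        assert rmse(rec.values, ref) < 0.02 * 0.05  # < 2% of the peak phase

    def test_abbe_simulated_round_trip(self, cfg128, annulus):
        star = siemens_star(128, 0.13, n_spokes=16, peak_phase=0.05)
        sm = ideal_lowpass_reference(star, cfg128, 1.4)
        obj = ComplexObject.from_phase(sm)
        stack = through_focus_stack(obj, cfg128, annulus, [-0.5, 0.0, 0.5])
        rec = wotf_deconvolve(stack, cfg128, annulus)
        assert rmse(rec.values, sm.values - sm.values.mean(),
                    exclude_border=4) < 1e-3

    def test_recovered_sign_matches_input(self, cfg128, annulus):
        """Round-trip sign convention: a positive phase bump comes back
        positive."""
        bump = gaussian_bumps(128, 0.13, [(64, 64)], sigma_px=10, peak_phase=0.1)
        obj = ComplexObject.from_phase(bump)
        stack = through_focus_stack(obj, cfg128, annulus, [-0.5, 0.0, 0.5])
        rec = wotf_deconvolve(stack, cfg128, annulus)
        assert rec.values[64, 64] > 0.5 * (0.1 - bump.values.mean())

    def test_linearity_in_the_weak_regime(self, cfg128, annulus):
        star = siemens_star(128, 0.13, n_spokes=16, peak_phase=1.0)
        base = ideal_lowpass_reference(star, cfg128, 1.4)
        base_vals = 0.02 * base.values / np.abs(base.values).max()
        recs = {}
        for c in (0.5, 1.0, 2.0):
            obj = ComplexObject.from_phase(PhaseMap(c * base_vals, 0.13))
            stack = through_focus_stack(obj, cfg128, annulus, [-0.5, 0.0, 0.5])
            recs[c] = wotf_deconvolve(stack, cfg128, annulus).values
        for c in (0.5, 2.0):
            dev = np.linalg.norm(recs[c] - c * recs[1.0]) / np.linalg.norm(c * recs[1.0])
            assert dev < 0.01

    def test_infinite_regularization_kills_phase(self, cfg128, annulus, weak_stack):
        stack, _ = weak_stack
        rec = wotf_deconvolve(stack, cfg128, annulus,
                              settings=ReconSettings(alpha=1e12))
        assert np.abs(rec.values).max() < 1e-10

    def test_negative_alpha_rejected(self, cfg128, annulus, weak_stack):
        stack, _ = weak_stack
        with pytest.raises(ValueError):
            wotf_deconvolve(stack, cfg128, annulus,
                            settings=ReconSettings(alpha=-1.0))


@pytest.fixture(scope="module")
def two_pair_stack(cfg128):
    bumps = gaussian_bumps(128, 0.13, [(40, 48), (90, 80)], sigma_px=14,
                           peak_phase=0.08)
    obj = ComplexObject.from_phase(bumps)
    spec = SourceSpec.circular(0.4)
    stack = through_focus_stack(obj, cfg128, spec, [-3.0, -0.5, 0.0, 0.5, 3.0],
                                method="weak_object")
    return stack, bumps, spec


class TestMultiDistance:

    def test_single_pair_reduces_to_deconvolve(self, cfg128, two_pair_stack):
        stack, _, spec = two_pair_stack
        a = multi_distance_combine(stack, cfg128, spec, distances=[0.5])
        b = wotf_deconvolve(stack, cfg128, spec, dz=0.5)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_combined_error_bounded_by_worst_single_in_expectation(
            self, cfg128, two_pair_stack):
        """Least-squares property over 20 noise draws: the band-averaged
        expected error of the combination does not exceed that of the worse
        single-distance reconstruction at any radial frequency bin."""
        from aitie import add_noise, NoiseModel
        stack, bumps, spec = two_pair_stack
        ref = bumps.values - bumps.values.mean()
        alpha = ReconSettings(alpha=1e-4)
        f = np.fft.fftfreq(128, 0.13)
        fr = np.hypot(*np.meshgrid(f, f, indexing="ij")) * 0.55 / 0.8
        bins = np.digitize(fr.ravel(), np.linspace(0, 1.8, 10))
        err = {k: np.zeros(11) for k in ("s", "l", "c")}
        for draw in range(20):
            noisy = FocalStack(
                np.stack([np.clip(add_noise(im, NoiseModel(0.01, 1000 + 7 * draw + i)),
                                  0, None)
                          for i, im in enumerate(stack.images)]),
                stack.defocus_um, 0.13)
            recs = {
                "s": wotf_deconvolve(noisy, cfg128, spec, dz=0.5, settings=alpha),
                "l": wotf_deconvolve(noisy, cfg128, spec, dz=3.0, settings=alpha),
                "c": multi_distance_combine(noisy, cfg128, spec,
                                            settings=ReconSettings(alpha=1e-4)),
            }
            for k, r in recs.items():
                e = np.abs(np.fft.fft2(r.values - ref)).ravel()
                err[k] += np.bincount(bins, weights=e, minlength=11)
        worst = np.maximum(err["s"], err["l"])
        used = worst > 0
        assert np.all(err["c"][used] <= 1.05 * worst[used])
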