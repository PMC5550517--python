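"""Transfer-function construction: sources, pupils, WOTFs and metrics."""

import numpy as np
import pytest

from aitie import (ImagingConfig, SourceSpec, coherent_wotf_paraxial,
                   make_pupil, make_source, phase_transfer, wotf, wotf_radial)
from aitie.grids import FrequencyGrid
from aitie.transfer import (contrast_area, gain_at, phase_contrast_cutoff,
                            support_cutoff)


@pytest.fixture(scope="module")
def grid512():
    return FrequencyGrid.from_config(
        ImagingConfig(0.8, 0.55, 0.13, 512))


class TestMakeSource:
    def test_circular_disk_of_normalized_radius(self, grid512):
        src = make_source(SourceSpec.circular(1.0), grid512)
        assert set(np.unique(src)) <= {0.0, 1.0}
        assert np.array_equal(src == 1, grid512.norm_radius <= 1.0)

    def test_annular_ring_area_fraction(self, grid512):
        """Ring [0.9, 1] holds ~19% of the full-disk sample count."""
        ring = make_source(SourceSpec.annular(0.9, 1.0), grid512).sum()
        disk = make_source(SourceSpec.circular(1.0), grid512).sum()
        assert ring / disk == pytest.approx(0.19, rel=0.02)

    def test_delta_is_single_dc_sample(self, grid512):
        src = make_source(SourceSpec.delta(), grid512)
        assert src.sum() == 1.0 and src[0, 0] == 1.0

    def test_empty_discretized_annulus_raises(self):
        coarse = FrequencyGrid.from_config(ImagingConfig(0.8, 0.55, 0.16, 16))
        with pytest.raises(ValueError, match="finer grid|wider annulus"):
            make_source(SourceSpec.annular(0.900, 0.901), coarse)


class TestMakePupil:
    def test_in_focus_pupil_is_real_binary(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        pup = make_pupil(cfg128, 0.0, grid)
        assert np.all(pup.values.imag == 0)
        assert set(np.unique(pup.values.real)) <= {0.0, 1.0}

    def test_piston_phase_at_dc(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        pup = make_pupil(cfg128, 0.5, grid)
        assert pup.values[0, 0] == pytest.approx(
            np.exp(1j * cfg128.wavenumber * 0.5), abs=1e-12)

    def test_defocus_phase_closed_form_at_pupil_edge(self, cfg128):
        # k z sqrt(1 - NA^2) for lambda=0.55, z=0.5, NA=0.8 -> 3.4272 rad
        grid = FrequencyGrid.from_config(cfg128)
        pup = make_pupil(cfg128, 0.5, grid)
        i, j = np.unravel_index(
            np.argmin(np.abs(grid.norm_radius - 1.0) + 1e6 * (grid.norm_radius > 1)),
            grid.shape)
        r = grid.norm_radius[i, j]
        expected = cfg128.wavenumber * 0.5 * np.sqrt(1 - (0.8 * r) ** 2)
        assert np.angle(pup.values[i, j]) % (2 * np.pi) == pytest.approx(
            expected % (2 * np.pi), abs=1e-10)
        # and the exact closed form at normalized radius exactly 1:
        assert (2 * np.pi / 0.55) * 0.5 * np.sqrt(1 - 0.8 ** 2) == pytest.approx(
            3.4272, abs=5e-4)


class TestWotf:
    def test_coherent_limit_matches_closed_form(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        tf = wotf(cfg128, SourceSpec.delta(), 0.5, grid=grid)
        lam_u = grid.f_radius * cfg128.wavelength_um
        inside = (grid.norm_radius <= 1.0) & (lam_u <= 1.0)
        ref = np.where(
            inside,
            np.exp(1j * cfg128.wavenumber * 0.5
                   * (np.sqrt(np.clip(1 - lam_u ** 2, 0, None)) - 1.0)),
            0.0)
        assert np.abs(tf.values - ref).max() < 1e-12

    def test_in_focus_wotf_is_real(self, cfg128, annulus):
        for spec in (annulus, SourceSpec.circular(0.6)):
            p = wotf_radial(cfg128, spec, 0.0)
            assert np.abs(p.im).max() == 0.0
            assert p.values[0] == pytest.approx(1.0)

    def test_incoherent_source_has_no_phase_transfer(self, cfg128):
        p = wotf_radial(cfg128, SourceSpec.circular(1.5), 0.7, du=2 / 256)
        assert np.abs(p.im).max() / np.abs(p.re).max() < 1e-10

    def test_defocus_hermitian_symmetry(self, cfg128, annulus):
        for spec in (annulus, SourceSpec.circular(0.75)):
            pp = wotf_radial(cfg128, spec, 0.5, du=2 / 256)
            pm = wotf_radial(cfg128, spec, -0.5, du=2 / 256)
            assert np.abs(pp.re - pm.re).max() < 1e-10
            assert np.abs(pp.im + pm.im).max() < 1e-10

    def test_matched_annulus_inverse_contrast_no_zero_crossing(self, cfg128, annulus):
        """In the pass-band the annular phase WOTF is single-signed and of
        the sign opposite to circular illumination (inverse contrast)."""
        pa = wotf_radial(cfg128, annulus, 0.5)
        pc = wotf_radial(cfg128, SourceSpec.circular(0.3), 0.5, u_max=pa.u[-1])
        band = (pa.u > 0.05) & (pa.u < 1.85)
        assert np.all(pa.im[band] > 0) or np.all(pa.im[band] < 0)
        band_c = (pc.u > 0.05) & (pc.u < 0.9)
        assert np.sign(pa.im[band].mean()) == -np.sign(pc.im[band_c].mean())

    def test_cutoff_law(self, cfg128):
        for s in (0.3, 0.5, 0.75):
            p = wotf_radial(cfg128, SourceSpec.circular(s), 0.5, u_max=2.0)
            assert support_cutoff(p) == pytest.approx(1 + s, abs=2 * (2 / 1024))
        pa = wotf_radial(cfg128, SourceSpec.annular(0.8, 0.95), 0.5, u_max=2.0)
        assert support_cutoff(pa) == pytest.approx(1.95, abs=2 * (2 / 1024))

    def test_source_outside_pupil_raises(self, cfg128):
        with pytest.raises(ValueError, match="outside pupil"):
            wotf_radial(cfg128, SourceSpec.annular(1.05, 1.2), 0.5)

    def test_grid_refinement_convergence_of_contrast_area(self, cfg128, annulus):
        a1 = contrast_area(wotf_radial(cfg128, annulus, 0.5, du=2 / 512, u_max=2.0))
        a2 = contrast_area(wotf_radial(cfg128, annulus, 0.5, du=2 / 1024, u_max=2.0))
        assert abs(a2 - a1) / a2 < 0.01


class TestParaxialAndTransfers:
    def test_paraxial_closed_form(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        tf = coherent_wotf_paraxial(cfg128, 0.5, grid)
        chirp = np.pi * 0.55 * 0.5 * grid.f_radius ** 2
        inside = grid.norm_radius <= 1.0
        assert np.allclose(tf.values[inside],
                           np.cos(chirp[inside]) - 1j * np.sin(chirp[inside]))
        assert np.all(tf.values[~inside] == 0)
        assert np.all(tf.values[grid.norm_radius < 1e-9] == 1.0)

    def test_paraxial_agrees_with_angular_spectrum_at_low_freq(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        tfp = coherent_wotf_paraxial(cfg128, 0.5, grid)
        tfd = wotf(cfg128, SourceSpec.delta(), 0.5, grid=grid)
        m = grid.norm_radius <= 0.5
        rel = np.abs(tfp.values[m] - tfd.values[m]) / np.abs(tfd.values[m])
        assert rel.max() < 0.025  # closed-form deviation at u=0.5 is 1.98e-2

    def test_phase_transfer_odd_in_defocus_and_zero_in_focus(self, cfg128, annulus):
        grid = FrequencyGrid.from_config(cfg128)
        tp = wotf(cfg128, annulus, 0.4, grid=grid)
        tm = wotf(cfg128, annulus, -0.4, grid=grid)
        assert np.allclose(phase_transfer(tp), -phase_transfer(tm), atol=1e-12)
        t0 = wotf(cfg128, annulus, 0.0, grid=grid)
        assert np.abs(phase_transfer(t0)).max() == 0.0

    def test_phase_transfer_coherent_paraxial_is_sine(self, cfg128):
        grid = FrequencyGrid.from_config(cfg128)
        tf = coherent_wotf_paraxial(cfg128, 0.5, grid)
        inside = grid.norm_radius <= 1.0
        chirp = np.pi * 0.55 * 0.5 * grid.f_radius ** 2
        assert np.allclose(phase_transfer(tf)[inside], np.sin(chirp[inside]))


class TestContrastMetrics:
    def test_gain_requires_common_axis(self, cfg128, annulus):
        p1 = wotf_radial(cfg128, annulus, 0.5, u_max=2.0)
        p2 = wotf_radial(cfg128, SourceSpec.circular(0.75), 0.5, u_max=1.8)
        with pytest.raises(ValueError, match="different frequency axes"):
            gain_at(p1, p2, 1.0)

    def test_annular_phase_cutoff_is_one_plus_inner_radius(self, cfg128):
        # Im WOTF cancels identically beyond 1 + s1 = 2 - width
        p = wotf_radial(cfg128, SourceSpec.matched_annulus(0.1), 0.5, u_max=2.0)
        assert phase_contrast_cutoff(p, floor=1e-6) == pytest.approx(
            1.9, abs=2 * (2 / 1024))
        assert np.abs(p.im[p.u > 1.905]).max() < 1e-14

    def test_contrast_area_positive_and_scale(self, cfg128, annulus):
        p = wotf_radial(cfg128, annulus, 0.5)
        area = contrast_area(p)
        assert 0 < area < 2.0
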