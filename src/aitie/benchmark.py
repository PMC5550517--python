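"""Reference studies: aperture optimization metrics and the Siemens-star
simulation comparison between annular and circular illumination TIE.

These are the quantitative experiments the package is validated against;
both the test suite and ``scripts/acceptance.py`` run them.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import ImagingConfig, NoiseModel, ReconSettings, SourceSpec
from .grids import FrequencyGrid
from .phantoms import PhaseMap, rmse, siemens_star
from .reconstruct import multi_distance_combine, wotf_deconvolve
from .simulate import ComplexObject, through_focus_stack
from .transfer import (DEFAULT_DU, contrast_area, gain_at, phase_contrast_cutoff,
                   wotf, wotf_radial)


def _wotf_im(cfg: ImagingConfig, spec: SourceSpec, dz: float) -> np.ndarray:
    return wotf(cfg, spec, dz, grid=FrequencyGrid.from_config(cfg)).values.imag

__all__ = [
    "wotf_optimization_summary",
    "star_study",
    "spoke_resolution_radius",
    "lowfreq_rmse",
]


def wotf_optimization_summary(
    na_obj: float = 0.8,
    wavelength_um: float = 0.55,
    defocus_um: float = 0.5,
    du: float = DEFAULT_DU,
) -> dict:
    """Phase-contrast comparison of matched annuli vs circular apertures.

    Computes the radial phase WOTF for matched annular illumination of
    widths 0.01 and 0.10 and circular illumination with coherence parameters
    0.75 and 0.1, all at the same defocus, and summarizes: total contrast
    area ratios vs s = 0.75, pointwise |Im WOTF| gains at ū = 1.6/1.7 vs
    s = 0.75, percentage of the s = 0.1 contrast area retained, and the
    phase-contrast cutoff of the width-0.10 annulus (in units of NA_obj).
    """
    cfg = ImagingConfig(na_obj=na_obj, wavelength_um=wavelength_um,
                        pixel_pitch_um=0.13, grid_size=256)
    profiles = {
        "annular_0.01": wotf_radial(cfg, SourceSpec.matched_annulus(0.01), defocus_um,
                                    du=du, u_max=2.0),
        "annular_0.10": wotf_radial(cfg, SourceSpec.matched_annulus(0.10), defocus_um,
                                    du=du, u_max=2.0),
        "circular_0.75": wotf_radial(cfg, SourceSpec.circular(0.75), defocus_um,
                                     du=du, u_max=2.0),
        "circular_0.10": wotf_radial(cfg, SourceSpec.circular(0.1), defocus_um,
                                     du=du, u_max=2.0),
    }
    areas = {k: contrast_area(p) for k, p in profiles.items()}
    out = {
        "profiles": profiles,
        "areas": areas,
        "area_ratio_w001_vs_s075": areas["annular_0.01"] / areas["circular_0.75"],
        "area_ratio_w010_vs_s075": areas["annular_0.10"] / areas["circular_0.75"],
        "area_pct_w001_vs_s010": 100.0 * areas["annular_0.01"] / areas["circular_0.10"],
        "area_pct_w010_vs_s010": 100.0 * areas["annular_0.10"] / areas["circular_0.10"],
        "gain_u1.6_w010": gain_at(profiles["annular_0.10"], profiles["circular_0.75"], 1.6),
        "gain_u1.6_w001": gain_at(profiles["annular_0.01"], profiles["circular_0.75"], 1.6),
        "gain_u1.7_w010": gain_at(profiles["annular_0.10"], profiles["circular_0.75"], 1.7),
        "gain_u1.7_w001": gain_at(profiles["annular_0.01"], profiles["circular_0.75"], 1.7),
        "cutoff_factor_w010": phase_contrast_cutoff(profiles["annular_0.10"]),
        "n_radial": int(profiles["annular_0.10"].u.size),
    }
    return out


def _star_masks(grid_size: int, n_spokes: int, radius_frac: float):
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size]
    dx, dy = x - c, y - c
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    period = 2 * np.pi / n_spokes
    bright = np.mod(theta, period) < period / 2
    inside = r <= radius_frac * grid_size / 2.0
    return r, bright, inside


def spoke_resolution_radius(
    phase: PhaseMap,
    n_spokes: int = 40,
    peak_phase: float = 1.0,
    radius_frac: float = 0.9,
    threshold: float = 0.1,
    ring_width_px: float = 2.0,
) -> float:
    """Innermost radius (µm) at which the star's spokes are resolved.

    For each radius ring, the modulation depth between the known bright-
    and dark-sector pixels — (mean_bright − mean_dark)/peak_phase, after
    referencing the map to its outside-the-star background level — is
    compared with ``threshold``; the innermost radius of the contiguous
    resolved run ending at the star edge is returned (the local spoke pitch
    decreases toward the centre, so resolution maps to radius).
    """
    n = phase.values.shape[0]
    r, bright, inside = _star_masks(n, n_spokes, radius_frac)
    background = float(phase.values[~inside].mean())
    vals = phase.values - background
    r_outer = radius_frac * n / 2.0
    edges = np.arange(2 * ring_width_px, r_outer, ring_width_px)
    resolved_inner = r_outer
    for r_hi in edges[::-1]:
        ring = (r >= r_hi - ring_width_px) & (r < r_hi) & inside
        b = float(vals[ring & bright].mean())
        d = float(vals[ring & ~bright].mean())
        if (b - d) / abs(peak_phase) <= threshold:
            break
        resolved_inner = r_hi - ring_width_px
    return resolved_inner * phase.pixel_pitch_um


def lowfreq_rmse(phase: PhaseMap, reference: PhaseMap, cfg: ImagingConfig,
                 band: float = 0.2, exclude_border: int = 4) -> float:
    """RMSE of the reconstruction error restricted to ū < ``band``."""
    err = phase.values - phase.values.mean() - (reference.values - reference.values.mean())
    f = np.fft.fftfreq(err.shape[0], d=phase.pixel_pitch_um)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    keep = np.hypot(fx, fy) * cfg.wavelength_um / cfg.na_obj < band
    low = np.fft.ifft2(np.fft.fft2(err) * keep).real
    s = np.s_[exclude_border:-exclude_border, exclude_border:-exclude_border]
    return float(np.sqrt(np.mean(low[s] ** 2)))


def star_study(
    seed: int = 0,
    grid_size: int = 256,
    pixel_pitch_um: float = 0.13,
    na_obj: float = 0.8,
    wavelength_um: float = 0.55,
    sigma: float = 0.01,
    dz_small: float = 0.5,
    dz_large: float = 3.0,
    annulus_width: float = 0.1,
    circular_s: float = 0.4,
    n_spokes: int = 40,
    peak_phase: float = 1.0,
) -> dict:
    """Siemens-star phase-retrieval comparison across illumination settings.

    Simulates noisy through-focus stacks by Abbe summation for (a) matched
    annular illumination at a single small defocus, (b) nearly matched
    circular illumination s = 0.99, and (c) circular illumination at both a
    small and a large defocus; reconstructs phase by WOTF deconvolution
    (plus the two-distance least-squares combination for (c)); and reports
    RMSEs against the ideal star, low-frequency-band RMSEs, defocused-image
    contrast and spoke-resolution radii.
    """
    cfg = ImagingConfig(na_obj=na_obj, wavelength_um=wavelength_um,
                        pixel_pitch_um=pixel_pitch_um, grid_size=grid_size)
    star = siemens_star(grid_size, pixel_pitch_um, n_spokes=n_spokes,
                        peak_phase=peak_phase)
    obj = ComplexObject.from_phase(star)
    ref = PhaseMap(star.values - star.values.mean(), pixel_pitch_um)

    annular = SourceSpec.matched_annulus(annulus_width)
    circ99 = SourceSpec.circular(0.99)
    circ = SourceSpec.circular(circular_s)

    stack_ann = through_focus_stack(
        obj, cfg, annular, [-dz_small, 0.0, dz_small],
        noise=NoiseModel(sigma=sigma, seed=seed))
    stack_c99 = through_focus_stack(
        obj, cfg, circ99, [-dz_small, 0.0, dz_small],
        noise=NoiseModel(sigma=sigma, seed=seed + 100))
    stack_circ = through_focus_stack(
        obj, cfg, circ, [-dz_large, -dz_small, 0.0, dz_small, dz_large],
        noise=NoiseModel(sigma=sigma, seed=seed + 200))

    phi_ann = wotf_deconvolve(stack_ann, cfg, annular)
    phi_c99 = wotf_deconvolve(stack_c99, cfg, circ99)
    # one regularizer for all three circular reconstructions so the
    # small/large/combined comparison is controlled; Wiener-matched to the
    # noise level: alpha ~ var(noise in D)/var(phase signal)
    if sigma > 0:
        alpha_circ = (sigma * np.sqrt(2.0) / 4.0) ** 2 / (peak_phase / 2.0) ** 2
    else:
        alpha_circ = 1e-3 * float(np.abs(_wotf_im(cfg, circ, dz_small)).max()) ** 2
    circ_settings = ReconSettings(alpha=alpha_circ)
    phi_small = wotf_deconvolve(stack_circ, cfg, circ, dz=dz_small,
                                settings=circ_settings)
    phi_large = wotf_deconvolve(stack_circ, cfg, circ, dz=dz_large,
                                settings=circ_settings)
    phi_comb = multi_distance_combine(
        stack_circ, cfg, circ,
        settings=ReconSettings(combine="least_squares", alpha=alpha_circ))

    def _rmse(p):
        return rmse(PhaseMap(p.values - p.values.mean(), pixel_pitch_um), ref,
                    exclude_border=4)

    # negative-contrast check on the over-focused annular raw image
    _, bright, inside = _star_masks(grid_size, n_spokes, 0.9)
    over = stack_ann.plane(dz_small)
    star_mask = inside & bright
    bg_mask = ~inside

    res = {
        "config": cfg,
        "rmse_annular": _rmse(phi_ann),
        "rmse_circular_s099": _rmse(phi_c99),
        "rmse_circular_small": _rmse(phi_small),
        "rmse_circular_large": _rmse(phi_large),
        "rmse_circular_combined": _rmse(phi_comb),
        "lowfreq_rmse_circular_small": lowfreq_rmse(phi_small, ref, cfg),
        "lowfreq_rmse_circular_large": lowfreq_rmse(phi_large, ref, cfg),
        "lowfreq_rmse_circular_combined": lowfreq_rmse(phi_comb, ref, cfg),
        "overfocus_star_mean": float(over[star_mask].mean()),
        "overfocus_background_mean": float(over[bg_mask].mean()),
        "resolution_um_annular": spoke_resolution_radius(phi_ann, n_spokes, peak_phase),
        "resolution_um_circular_small": spoke_resolution_radius(phi_small, n_spokes, peak_phase),
        "resolution_um_circular_large": spoke_resolution_radius(phi_large, n_spokes, peak_phase),
        "resolution_um_circular_s099": spoke_resolution_radius(phi_c99, n_spokes, peak_phase),
        "phase_maps": {
            "annular": phi_ann, "circular_s099": phi_c99,
            "circular_small": phi_small, "circular_large": phi_large,
            "circular_combined": phi_comb,
        },
    }
    return res
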