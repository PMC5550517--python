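"""Quantitative phase recovery from through-focus intensity stacks.

Two inversion routes are provided:

* ``tie_poisson_solve`` — the classical transport-of-intensity route: the
  axial intensity derivative feeds an FFT Poisson solve for the auxiliary
  potential, the gradient is divided by the in-focus intensity and a second
  Poisson solve integrates back to phase.
* ``wotf_deconvolve`` — Tikhonov-regularized Fourier deconvolution of the
  antisymmetric defocus difference by the imaginary (phase) part of the
  WOTF.  With matched annular illumination the phase WOTF has no
  zero-crossings in its pass-band so the regularizer can be essentially
  zero; circular illumination needs a finite α at its transfer nulls.

Both return mean-free phase (the global offset is unobservable).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft

from .config import ImagingConfig, ReconSettings, SourceSpec
from .grids import FrequencyGrid
from .phantoms import PhaseMap
from .simulate import FocalStack
from . import transfer as _wotf

__all__ = [
    "axial_derivative",
    "tie_poisson_solve",
    "wotf_deconvolve",
    "multi_distance_combine",
]


def _pair(stack: FocalStack, dz: Optional[float] = None):
    pairs = stack.symmetric_pairs()
    if not pairs:
        raise ValueError("stack has no symmetric ±Δz defocus pair")
    if dz is None:
        dz = pairs[0]
    elif not any(np.isclose(dz, p) for p in pairs):
        raise ValueError(f"no symmetric pair at Δz = {dz} µm (have {pairs})")
    return stack.plane(+dz), stack.plane(-dz), float(dz)


def axial_derivative(stack: FocalStack, dz: Optional[float] = None) -> np.ndarray:
    """Central-difference ∂I/∂z from a ±Δz plane pair (intensity/µm)."""
    ip, im, dz = _pair(stack, dz)
    return (ip - im) / (2.0 * dz)


def _inv_laplacian(rhs: np.ndarray, pixel_pitch_um: float) -> np.ndarray:
    """Solve ∇²ψ = rhs on a periodic domain; DC of ψ set to zero."""
    n = rhs.shape[0]
    f = np.fft.fftfreq(n, d=pixel_pitch_um)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    lap = -4.0 * np.pi ** 2 * (fx ** 2 + fy ** 2)
    lap[0, 0] = 1.0
    psi_hat = sfft.fft2(rhs) / lap
    psi_hat[0, 0] = 0.0
    return sfft.ifft2(psi_hat).real


def tie_poisson_solve(
    stack: FocalStack,
    cfg: ImagingConfig,
    dz: Optional[float] = None,
    assume_uniform: bool = False,
) -> PhaseMap:
    """Classical TIE inversion  −k·∂I/∂z = ∇·[I∇φ]  via FFT Poisson solves.

    With ``assume_uniform`` the intensity is treated as constant and the
    two-step solution collapses to a single inverse Laplacian divided by the
    mean intensity.  The in-focus image must be strictly positive.
    """
    didz = axial_derivative(stack, dz)
    i0 = stack.plane(0.0) if any(np.isclose(z, 0.0) for z in stack.defocus_um) \
        else np.full_like(didz, 1.0)
    if i0.min() <= 0:
        raise ValueError("in-focus intensity must be strictly positive")
    k = cfg.wavenumber
    p = stack.pixel_pitch_um
    if assume_uniform:
        phi = _inv_laplacian(-k * didz / float(i0.mean()), p)
        return PhaseMap(phi - phi.mean(), p)
    psi = _inv_laplacian(-k * didz, p)
    n = psi.shape[0]
    f = np.fft.fftfreq(n, d=p)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    psi_hat = sfft.fft2(psi)
    gx = sfft.ifft2(2j * np.pi * fx * psi_hat).real / i0
    gy = sfft.ifft2(2j * np.pi * fy * psi_hat).real / i0
    div = sfft.ifft2(
        2j * np.pi * (fx * sfft.fft2(gx) + fy * sfft.fft2(gy))
    ).real
    phi = _inv_laplacian(div, p)
    return PhaseMap(phi - phi.mean(), p)


def default_alpha(spec: SourceSpec, im_map: np.ndarray) -> float:
    """Tikhonov default: ~machine epsilon for annular illumination (no
    transfer nulls in the pass-band), 1e-3·max|Im WOTF|² otherwise."""
    if spec.shape == "annular":
        return float(np.finfo(float).eps)
    return float(1e-3 * np.max(np.abs(im_map)) ** 2)


def _phase_im_map(cfg, spec, dz, grid, du) -> np.ndarray:
    tf = _wotf.wotf(cfg, spec, dz, grid=grid, du=du)
    return tf.values.imag


#: pass-band floor: Fourier modes where |Im WOTF| falls below this fraction
#: of its peak carry essentially no phase signal and are excluded from the
#: deconvolution instead of being amplified by 1/Im WOTF; 1e-2 bounds the
#: inverse-filter gain at ~100/peak, matched to percent-level camera noise
BAND_FLOOR = 1e-2


def wotf_deconvolve(
    stack: FocalStack,
    cfg: ImagingConfig,
    spec: SourceSpec,
    settings: Optional[ReconSettings] = None,
    dz: Optional[float] = None,
    du: float = _wotf.DEFAULT_DU,
    band_floor: float = BAND_FLOOR,
) -> PhaseMap:
    """One-step Fourier deconvolution of the defocus difference by Im[WOTF].

    The antisymmetric difference of the ±Δz images, normalized by 4× the
    mean in-focus (background) intensity, is linearly related to the phase
    spectrum through Im[WOTF]; a Tikhonov-regularized division inverts it:

        φ = F⁻¹{ F[(I₊ − I₋)/(4·mean I₀)] · (−Im W) / (Im W² + α) }

    (the sign follows this package's FFT conventions; see the module note
    in :mod:`aitie.transfer`).  The filter is applied only inside the phase
    pass-band (|Im W| ≥ ``band_floor`` × its peak); outside it the data hold
    no phase information and the estimate is 0.
    """
    if spec is None:
        raise ValueError("wotf_deconvolve requires a source specification")
    alpha = settings.alpha if settings is not None else None
    if settings is not None and settings.distances_used and dz is None:
        dz = max(settings.distances_used)
    ip, im_img, dz = _pair(stack, dz)
    try:
        i0 = stack.plane(0.0)
    except KeyError:
        i0 = 0.5 * (ip + im_img)
    grid = FrequencyGrid.from_config(cfg)
    M = _phase_im_map(cfg, spec, dz, grid, du)
    if alpha is None:
        alpha = default_alpha(spec, M)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    d = (ip - im_img) / (4.0 * float(i0.mean()))
    filt = -M / (M ** 2 + alpha)
    filt[np.abs(M) < band_floor * np.abs(M).max()] = 0.0
    phi = sfft.ifft2(sfft.fft2(d) * filt).real
    return PhaseMap(phi - phi.mean(), stack.pixel_pitch_um)


def multi_distance_combine(
    stack: FocalStack,
    cfg: ImagingConfig,
    spec: SourceSpec,
    settings: Optional[ReconSettings] = None,
    distances: Optional[Sequence[float]] = None,
    du: float = _wotf.DEFAULT_DU,
    band_floor: float = BAND_FLOOR,
) -> PhaseMap:
    """Least-squares fusion of reconstructions at several defocus distances.

    Per Fourier coefficient the phase is the least-squares solution over all
    symmetric pairs:  φ̂ = −Σ_j Im W_j · D̂_j / (Σ_j Im W_j² + α), where D̂_j
    is the normalized difference spectrum at Δz_j.  Frequencies where a
    short-distance transfer is weak are carried by the long distance and
    vice versa, which suppresses the low-frequency noise amplification of
    single-distance TIE.  Reduces to ``wotf_deconvolve`` for one pair.
    """
    if distances is None:
        distances = settings.distances_used if settings is not None and \
            settings.distances_used else stack.symmetric_pairs()
    if not distances:
        raise ValueError("no symmetric defocus pairs available")
    try:
        i0 = stack.plane(0.0)
    except KeyError:
        i0 = None
    grid = FrequencyGrid.from_config(cfg)
    num = np.zeros(grid.shape, dtype=complex)
    den = np.zeros(grid.shape)
    max_im = 0.0
    for dz in distances:
        ip, im_img, dzv = _pair(stack, float(dz))
        bg = float(i0.mean()) if i0 is not None else float((0.5 * (ip + im_img)).mean())
        d_hat = sfft.fft2((ip - im_img) / (4.0 * bg))
        M = _phase_im_map(cfg, spec, dzv, grid, du)
        num += -M * d_hat
        den += M ** 2
        max_im = max(max_im, float(np.abs(M).max()))
    alpha = settings.alpha if settings is not None else None
    if alpha is None:
        alpha = float(np.finfo(float).eps) if spec.shape == "annular" \
            else 1e-3 * max_im ** 2
    filt = num / (den + alpha)
    filt[den < (band_floor * max_im) ** 2] = 0.0
    phi = sfft.ifft2(filt).real
    return PhaseMap(phi - phi.mean(), stack.pixel_pitch_um)
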