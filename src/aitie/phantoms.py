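"""Synthetic phase objects, noise, references and error metrics.

Everything downstream (forward simulation, reconstruction, cell analysis) is
validated on these phantoms, so no measured data is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ImagingConfig, NoiseModel

__all__ = [
    "PhaseMap",
    "siemens_star",
    "disk",
    "lens_profile",
    "gaussian_bumps",
    "ideal_lowpass_reference",
    "add_noise",
    "rmse",
]


@dataclass
class PhaseMap:
    """2D quantitative phase in radians with its object-space pixel pitch."""

    values: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("phase map must be square 2D")
        if not np.all(np.isfinite(v)):
            raise ValueError("phase map contains non-finite values")
        self.values = v

    @property
    def shape(self):
        return self.values.shape


def siemens_star(
    grid_size: int = 256,
    pixel_pitch_um: float = 0.13,
    n_spokes: int = 40,
    peak_phase: float = 1.0,
    radius_frac: float = 0.9,
) -> PhaseMap:
    """Siemens-star resolution target as a binary phase object.

    ``n_spokes`` bright sectors alternate with dark ones (angular period
    2π/n_spokes) inside a disk of radius ``radius_frac`` × half the field,
    so the local spoke pitch shrinks linearly toward the centre.  Values are
    0 or ``peak_phase`` (radians).
    """
    if n_spokes < 2 or n_spokes % 2:
        raise ValueError("n_spokes must be even and >= 2")
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size]
    dx, dy = x - c, y - c
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    period = 2.0 * np.pi / n_spokes
    bright = np.mod(theta, period) < period / 2.0
    inside = r <= radius_frac * grid_size / 2.0
    vals = np.where(bright & inside, float(peak_phase), 0.0)
    return PhaseMap(values=vals, pixel_pitch_um=pixel_pitch_um)


def disk(
    grid_size: int,
    pixel_pitch_um: float,
    radius_um: float,
    peak_phase: float = 1.0,
) -> PhaseMap:
    """Flat-top circular phase disk centred in the field."""
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size]
    r = np.hypot(x - c, y - c) * pixel_pitch_um
    return PhaseMap(np.where(r <= radius_um, float(peak_phase), 0.0), pixel_pitch_um)


def lens_profile(
    grid_size: int,
    pixel_pitch_um: float,
    radius_um: float,
    peak_phase: float = 1.0,
) -> PhaseMap:
    """Plano-convex lenslet: spherical-cap phase profile, zero outside."""
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size]
    r = np.hypot(x - c, y - c) * pixel_pitch_um
    cap = np.clip(1.0 - (r / radius_um) ** 2, 0.0, None)
    return PhaseMap(float(peak_phase) * np.sqrt(cap), pixel_pitch_um)


def gaussian_bumps(
    grid_size: int,
    pixel_pitch_um: float,
    centers_px,
    sigma_px: float,
    peak_phase: float = 1.0,
) -> PhaseMap:
    """Sum of isotropic Gaussian phase bumps (synthetic 'cells')."""
    y, x = np.mgrid[0:grid_size, 0:grid_size]
    vals = np.zeros((grid_size, grid_size))
    for (cx, cy) in centers_px:
        vals += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma_px ** 2))
    return PhaseMap(float(peak_phase) * vals, pixel_pitch_um)


def ideal_lowpass_reference(
    phase: PhaseMap, cfg: ImagingConfig, cutoff_na: float
) -> PhaseMap:
    """Best diffraction-limited image of a phase map for an effective NA.

    Applies an ideal circular low-pass at cutoff_na/λ in frequency space;
    energy outside the cutoff is exactly zero.
    """
    if cutoff_na <= 0:
        raise ValueError("cutoff_na must be positive")
    n = phase.values.shape[0]
    f = np.fft.fftfreq(n, d=phase.pixel_pitch_um)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    keep = np.hypot(fx, fy) <= cutoff_na / cfg.wavelength_um
    filt = np.fft.ifft2(np.fft.fft2(phase.values) * keep).real
    return PhaseMap(filt, phase.pixel_pitch_um)


def add_noise(image: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Additive i.i.d. Gaussian noise, reproducible for a fixed seed."""
    if model.sigma == 0.0:
        return np.array(image, dtype=float, copy=True)
    rng = np.random.default_rng(model.seed)
    return image + rng.normal(0.0, model.sigma, size=image.shape)


def rmse(a, b, exclude_border: int = 0) -> float:
    """Root-mean-square difference between two equally shaped maps.

    ``exclude_border`` trims that many pixels from each edge before
    comparing (Fourier solvers assume periodic boundaries, so edges carry
    wrap-around artifacts).
    """
    av = a.values if isinstance(a, PhaseMap) else np.asarray(a)
    bv = b.values if isinstance(b, PhaseMap) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch {av.shape} vs {bv.shape}")
    if exclude_border:
        s = np.s_[exclude_border:-exclude_border, exclude_border:-exclude_border]
        av, bv = av[s], bv[s]
    return float(np.sqrt(np.mean((av - bv) ** 2)))
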