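"""Forward simulation of partially coherent through-focus brightfield images.

The reference model is Abbe's source-point superposition: each point of the
condenser aperture produces a coherent sub-image

    I_s(x) = |F⁻¹[ F[t](ν) · P_z(ν + u_s) ]|²

(pupil evaluated at the true, unwrapped frequency ν + u_s, with the
angular-spectrum defocus phase), and the partially coherent image is the
incoherent sum over source points, normalized so an empty object (t ≡ 1)
gives unit mean intensity.  A linearized weak-object alternative applies the
WOTF directly and costs a single FFT instead of a source-point loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft

from .config import ImagingConfig, NoiseModel, SourceSpec
from .grids import FrequencyGrid
from .phantoms import PhaseMap, add_noise
from . import transfer as _wotf

__all__ = [
    "ComplexObject",
    "FocalStack",
    "source_points",
    "abbe_image",
    "weak_object_image",
    "through_focus_stack",
]

_CHUNK = 64  # source points per FFT batch; bounds memory at ~64 MB for 256²


@dataclass
class ComplexObject:
    """Complex transmittance t(x) sampled at the object pixel pitch."""

    transmittance: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transmittance, dtype=complex)
        if np.abs(t).max() > 1.0 + 1e-9:
            raise ValueError("|t| must not exceed 1")
        self.transmittance = t

    @classmethod
    def from_phase(cls, phase: PhaseMap, absorption: float = 1.0) -> "ComplexObject":
        """Pure-phase object t = a·exp(iφ) from a phase map."""
        return cls(absorption * np.exp(1j * phase.values), phase.pixel_pitch_um)


@dataclass
class FocalStack:
    """Ordered through-focus intensity images with signed defocus (µm)."""

    images: np.ndarray  # (n, N, N)
    defocus_um: Sequence[float]
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 3:
            raise ValueError("images must be a (n, N, N) array")
        if len(self.defocus_um) != imgs.shape[0]:
            raise ValueError("one defocus value per image required")
        if len(set(float(z) for z in self.defocus_um)) != imgs.shape[0]:
            raise ValueError("defocus values must be distinct")
        if imgs.min() < 0:
            raise ValueError("intensities must be nonnegative")
        self.images = imgs
        self.defocus_um = tuple(float(z) for z in self.defocus_um)

    def plane(self, z_um: float) -> np.ndarray:
        for img, z in zip(self.images, self.defocus_um):
            if np.isclose(z, z_um):
                return img
        raise KeyError(f"no plane at z = {z_um} µm")

    def symmetric_pairs(self) -> list:
        """Sorted positive defocus values z for which both ±z are present."""
        zs = set(self.defocus_um)
        return sorted(z for z in zs if z > 0 and any(np.isclose(-z, w) for w in zs))


def _check_sampling(cfg: ImagingConfig, spec: SourceSpec) -> None:
    span = (1.0 + spec.outer_radius) * cfg.coherent_cutoff
    if span > cfg.nyquist + 1e-12:
        need = 0.5 / span
        raise ValueError(
            f"grid undersampled: source+pupil support {span:.3f} cyc/µm exceeds "
            f"Nyquist {cfg.nyquist:.3f}; use pixel_pitch_um <= {need:.4f}"
        )


def source_points(
    cfg: ImagingConfig,
    spec: SourceSpec,
    grid: Optional[FrequencyGrid] = None,
    supersample: int = 1,
) -> np.ndarray:
    """Source sample frequencies (cycles/µm) on the image frequency lattice.

    ``supersample`` refines the lattice by that integer factor (used to check
    convergence of the Abbe sum); the default lattice is the FFT grid itself,
    which keeps the simulation bit-reproducible.
    """
    if spec.shape == "delta":
        return np.zeros((1, 2))
    if grid is None:
        grid = FrequencyGrid.from_config(cfg)
    df = 1.0 / (cfg.grid_size * cfg.pixel_pitch_um * supersample)
    n = int(np.floor(spec.outer_radius * cfg.coherent_cutoff / df)) + 1
    ax = np.arange(-n, n + 1) * df
    fx, fy = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(fx, fy) * cfg.wavelength_um / cfg.na_obj
    mask = _wotf._source_mask(spec, r)
    pts = np.column_stack([fx[mask], fy[mask]])
    if pts.shape[0] == 0:
        raise ValueError("discretized source has no samples; refine the grid")
    return pts


def abbe_image(
    obj: ComplexObject,
    cfg: ImagingConfig,
    spec: SourceSpec,
    z_um: float,
    supersample: int = 1,
) -> np.ndarray:
    """Partially coherent intensity image at defocus ``z_um`` by Abbe summation."""
    _check_sampling(cfg, spec)
    grid = FrequencyGrid.from_config(cfg)
    t = obj.transmittance
    if t.shape != grid.shape:
        raise ValueError("object shape does not match config grid_size")
    T = sfft.fft2(t)
    pts = source_points(cfg, spec, grid, supersample=supersample)
    na2 = cfg.na_obj ** 2
    lam = cfg.wavelength_um
    k = cfg.wavenumber
    cutoff = cfg.coherent_cutoff

    intensity = np.zeros(grid.shape)
    background = 0.0
    for start in range(0, pts.shape[0], _CHUNK):
        chunk = pts[start:start + _CHUNK]
        # true (unwrapped) frequencies of the shifted pupil per source point
        sx = grid.fx[None] + chunk[:, 0, None, None]
        sy = grid.fy[None] + chunk[:, 1, None, None]
        rr = np.hypot(sx, sy)
        inside = rr <= cutoff
        if z_um == 0.0:
            P = inside.astype(complex)
        else:
            ph = k * z_um * np.sqrt(np.clip(1.0 - (lam * rr) ** 2, 0.0, None))
            P = np.where(inside, np.exp(1j * ph), 0.0)
        fields = sfft.ifft2(T[None] * P, axes=(-2, -1))
        intensity += np.sum(np.abs(fields) ** 2, axis=0)
        background += float(np.sum(np.hypot(chunk[:, 0], chunk[:, 1]) <= cutoff + 1e-12))
    if background == 0.0:
        raise ValueError("source outside pupil: empty background")
    return intensity / background


def weak_object_image(
    obj: ComplexObject,
    cfg: ImagingConfig,
    spec: SourceSpec,
    z_um: float,
    tf: Optional[_wotf.TransferFunction] = None,
) -> np.ndarray:
    """Linearized weak-object image via the WOTF.

    The object is decomposed as t ≈ a0 + Δa + i·a0·φ and the normalized
    intensity is 1 + (2/a0)·Re F⁻¹{WOTF·[Δã + i·a0·φ̃]}, exact to first
    order in the scattered field.
    """
    t = obj.transmittance
    a = np.abs(t)
    phi = np.angle(t)
    a0 = float(a.mean())
    if tf is None:
        tf = _wotf.wotf(cfg, spec, z_um)
    spec_obj = sfft.fft2(a - a0) + 1j * a0 * sfft.fft2(phi)
    pert = sfft.ifft2(tf.values * spec_obj)
    return a0 ** 2 + 2.0 * a0 * np.real(pert)  # normalized: background a0²·WOTF(0)/WOTF(0)


def through_focus_stack(
    obj: ComplexObject,
    cfg: ImagingConfig,
    spec: SourceSpec,
    defocus_um: Sequence[float],
    noise: Optional[NoiseModel] = None,
    method: str = "abbe",
    supersample: int = 1,
) -> FocalStack:
    """Simulate one image per defocus distance and optionally add noise.

    Noise is applied after normalization (σ in normalized intensity units)
    with a per-plane seed ``noise.seed + index`` so planes are independent
    but the stack is reproducible.
    """
    if not len(defocus_um):
        raise ValueError("defocus_um must be nonempty")
    imgs = []
    for idx, z in enumerate(defocus_um):
        if method == "abbe":
            img = abbe_image(obj, cfg, spec, float(z), supersample=supersample)
        elif method == "weak_object":
            img = weak_object_image(obj, cfg, spec, float(z))
        else:
            raise ValueError(f"unknown method {method!r}")
        if noise is not None and noise.sigma > 0:
            img = add_noise(img, replace(noise, seed=noise.seed + idx))
        imgs.append(np.clip(img, 0.0, None))
    return FocalStack(np.stack(imgs), tuple(float(z) for z in defocus_um),
                      obj.pixel_pitch_um)
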