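"""Weak-object transfer functions for partially coherent brightfield imaging.

The imaging model is a Köhler-illuminated microscope: an extended incoherent
source S(u') in the condenser aperture, an aberration-free objective pupil
P(u) of normalized radius 1, and defocus applied as the angular-spectrum
phase factor exp(ikz·sqrt(1 − λ²|u|²)) inside the pupil.  The weak-object
transfer function is the linear part of the transmission cross-coefficient,

    WOTF(u) = ∫∫ S(u') |P(u')| |P(u'+u)|
              · exp{ikz[sqrt(1 − λ²|u'+u|²) − sqrt(1 − λ²|u'|²)]} du' ,

normalized by the background WOTF(0) (source intensity integrated over the
pupil).  Its real part transfers absorption and its imaginary part transfers
phase; defocus is what turns phase into measurable intensity contrast.

Frequencies are handled in pupil-normalized units ū = |u|·λ/NA_obj, in which
the pupil edge sits at ū = 1 and the incoherent limit at ū = 2.

Sign convention: with numpy's FFT conventions the coherent-limit WOTF is
|P|²·exp(ikz[sqrt(1 − λ²u²) − 1]), whose imaginary part is negative at small
defocus (≈ −sin(πλz|u|²)).  Matched annular illumination produces an
imaginary part of the *opposite*, single sign — the "inverse contrast"
regime in which optically thick structures appear dark on over-focus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ImagingConfig, SourceSpec
from .grids import FrequencyGrid

__all__ = [
    "Pupil",
    "RadialWOTF",
    "TransferFunction",
    "make_source",
    "make_pupil",
    "wotf_radial",
    "wotf",
    "coherent_wotf_paraxial",
    "phase_transfer",
    "amplitude_transfer",
    "contrast_area",
    "phase_contrast_cutoff",
    "gain_at",
    "contrast_metrics",
]

#: default radial sampling step in normalized frequency (also the source
#: quadrature lattice step); 2/1024 gives >= 512 samples over [0, 2]
DEFAULT_DU = 2.0 / 1024.0


@dataclass
class Pupil:
    """Complex objective pupil sampled on a frequency grid."""

    values: np.ndarray
    defocus_um: float
    cutoff: float = 1.0


@dataclass
class RadialWOTF:
    """Radial profile of a normalized WOTF.

    ``u`` is the normalized frequency axis (lattice-aligned with the source
    quadrature so that exact symmetry cancellations survive discretization),
    ``values`` the complex WOTF with values[0] == 1 after normalization.
    """

    u: np.ndarray
    values: np.ndarray
    defocus_um: float
    source: SourceSpec
    config: ImagingConfig

    @property
    def im(self) -> np.ndarray:
        return self.values.imag

    @property
    def re(self) -> np.ndarray:
        return self.values.real


@dataclass
class TransferFunction:
    """2D sampled WOTF plus the radial profile it was synthesized from."""

    grid: FrequencyGrid
    values: np.ndarray
    defocus_um: float
    normalization: float
    radial: Optional[RadialWOTF] = None


def _source_mask(spec: SourceSpec, norm_radius: np.ndarray) -> np.ndarray:
    if spec.shape == "circular":
        return norm_radius <= spec.s
    if spec.shape == "annular":
        return (norm_radius >= spec.s1) & (norm_radius <= spec.s2)
    raise ValueError("delta source has no extended support")


def make_source(spec: SourceSpec, grid: FrequencyGrid) -> np.ndarray:
    """Binary source map on ``grid`` (1 inside the aperture, 0 outside).

    The annular support is the closed ring [s1, s2]; a delta source is a
    single unit sample at DC.  Raises if the discretized support is empty
    (annulus thinner than one grid sample).
    """
    out = np.zeros(grid.shape, dtype=float)
    if spec.shape == "delta":
        out[0, 0] = 1.0
        return out
    mask = _source_mask(spec, grid.norm_radius)
    if not mask.any():
        raise ValueError(
            "discretized source support is empty; use a finer grid "
            "(smaller pixel pitch or larger grid_size) or a wider annulus"
        )
    out[mask] = 1.0
    return out


def _defocus_phase(cfg: ImagingConfig, z_um: float, lam_u_sq: np.ndarray) -> np.ndarray:
    """k·z·sqrt(1 − λ²|u|²) with the evanescent argument clipped at zero."""
    return cfg.wavenumber * z_um * np.sqrt(np.clip(1.0 - lam_u_sq, 0.0, None))


def make_pupil(cfg: ImagingConfig, z_um: float, grid: FrequencyGrid) -> Pupil:
    """Ideal circular pupil with angular-spectrum defocus phase.

    Unit modulus inside normalized radius 1 (and inside the evanescent
    cutoff |u| <= 1/λ), zero outside; at z = 0 the pupil is purely real.
    """
    if not np.isfinite(z_um):
        raise ValueError("defocus must be finite")
    lam_u = grid.f_radius * cfg.wavelength_um
    inside = (grid.norm_radius <= 1.0) & (lam_u <= 1.0)
    vals = np.zeros(grid.shape, dtype=complex)
    if z_um == 0.0:
        vals[inside] = 1.0
    else:
        vals[inside] = np.exp(1j * _defocus_phase(cfg, z_um, lam_u[inside] ** 2))
    return Pupil(values=vals, defocus_um=z_um)


def _source_quadrature(spec: SourceSpec, du: float):
    """Cartesian quadrature points (px, py, weights) of the source inside the
    pupil, folded onto py >= 0.

    The lattice is aligned with the radial evaluation axis (both are integer
    multiples of ``du``) so that the pairwise symmetry p -> (−px−ū, py),
    which makes Im WOTF vanish identically beyond ū = 1 + s1 for an annular
    source, cancels exactly in the discrete sum as well.
    """
    outer = min(spec.outer_radius, 1.0)
    n = int(np.floor(outer / du)) + 1
    ax = np.arange(-n, n + 1) * du
    ay = np.arange(0, n + 1) * du
    px, py = np.meshgrid(ax, ay, indexing="ij")
    r = np.hypot(px, py)
    mask = _source_mask(spec, r) & (r <= 1.0)
    if not mask.any():
        if spec.shape == "annular" and spec.s1 >= 1.0:
            raise ValueError("source outside pupil: the annulus does not "
                             "overlap the objective aperture")
        raise ValueError(
            "source quadrature support is empty; decrease du or widen the annulus"
        )
    w = np.where(py == 0.0, 1.0, 2.0)  # fold py<0 by symmetry
    return px[mask], py[mask], w[mask]


def wotf_radial(
    cfg: ImagingConfig,
    spec: SourceSpec,
    z_um: float,
    du: float = DEFAULT_DU,
    u_max: Optional[float] = None,
) -> RadialWOTF:
    """Radial WOTF profile by direct quadrature of the source integral.

    For axisymmetric sources the WOTF is radially symmetric, so it is
    evaluated along one frequency axis only; each radial sample is still a
    full 2D integral over the source.  The result is normalized by WOTF(0).
    """
    if u_max is None:
        u_max = 1.0 + spec.outer_radius + 2 * du
    n_rad = int(round(u_max / du)) + 1
    u = np.arange(n_rad) * du
    k = cfg.wavenumber
    na2 = cfg.na_obj ** 2

    if spec.shape == "delta":
        lam_u_sq = np.clip(na2 * u ** 2, 0.0, 1.0)
        vals = np.where(
            u <= 1.0,
            np.exp(1j * k * z_um * (np.sqrt(1.0 - lam_u_sq) - 1.0)),
            0.0,
        )
        return RadialWOTF(u=u, values=vals, defocus_um=z_um, source=spec, config=cfg)

    px, py, w = _source_quadrature(spec, du)
    sq0 = np.sqrt(np.clip(1.0 - na2 * (px ** 2 + py ** 2), 0.0, None))
    vals = np.zeros(n_rad, dtype=complex)
    for i, uu in enumerate(u):
        rr2 = (px + uu) ** 2 + py ** 2
        inp = rr2 <= 1.0
        if not inp.any():
            continue
        ph = k * z_um * (np.sqrt(np.clip(1.0 - na2 * rr2[inp], 0.0, None)) - sq0[inp])
        vals[i] = np.sum(w[inp] * np.exp(1j * ph))
    w0 = vals[0].real
    if w0 <= 0:
        raise ValueError("source outside pupil: WOTF(0) = 0")
    return RadialWOTF(u=u, values=vals / w0, defocus_um=z_um, source=spec, config=cfg)


def radial_to_grid(profile: RadialWOTF, grid: FrequencyGrid) -> np.ndarray:
    """Synthesize the 2D WOTF map from a radial profile by interpolation."""
    r = grid.norm_radius.ravel()
    re = np.interp(r, profile.u, profile.re, right=0.0)
    im = np.interp(r, profile.u, profile.im, right=0.0)
    return (re + 1j * im).reshape(grid.shape)


def wotf(
    cfg: ImagingConfig,
    spec: SourceSpec,
    z_um: float,
    grid: Optional[FrequencyGrid] = None,
    du: float = DEFAULT_DU,
) -> TransferFunction:
    """Normalized WOTF sampled on the image frequency grid.

    Delta (coherent) sources are evaluated pointwise on the grid — the
    source integral collapses to the angular-spectrum kernel, so the result
    equals |P(u)|²·exp(ikz[sqrt(1 − λ²|u|²) − 1]) to rounding.  Extended
    axisymmetric sources use the radial quadrature plus interpolation.
    """
    if grid is None:
        grid = FrequencyGrid.from_config(cfg)
    if spec.shape == "delta":
        lam_u = grid.f_radius * cfg.wavelength_um
        inside = (grid.norm_radius <= 1.0) & (lam_u <= 1.0)
        vals = np.zeros(grid.shape, dtype=complex)
        vals[inside] = np.exp(
            1j * (_defocus_phase(cfg, z_um, lam_u[inside] ** 2) - cfg.wavenumber * z_um)
        )
        radial = wotf_radial(cfg, spec, z_um, du=du)
        return TransferFunction(grid=grid, values=vals, defocus_um=z_um,
                                normalization=1.0, radial=radial)
    radial = wotf_radial(cfg, spec, z_um, du=du)
    vals = radial_to_grid(radial, grid)
    return TransferFunction(grid=grid, values=vals, defocus_um=z_um,
                            normalization=1.0, radial=radial)


def coherent_wotf_paraxial(
    cfg: ImagingConfig, z_um: float, grid: Optional[FrequencyGrid] = None
) -> TransferFunction:
    """Paraxial coherent WOTF: |P|²·[cos(πλz|u|²) − i·sin(πλz|u|²)]."""
    if grid is None:
        grid = FrequencyGrid.from_config(cfg)
    chirp = np.pi * cfg.wavelength_um * z_um * grid.f_radius ** 2
    inside = grid.norm_radius <= 1.0
    vals = np.where(inside, np.cos(chirp) - 1j * np.sin(chirp), 0.0)
    return TransferFunction(grid=grid, values=vals, defocus_um=z_um, normalization=1.0)


def phase_transfer(tf, a0: float = 1.0) -> np.ndarray:
    """Phase-contrast transfer −a0²·Im[WOTF] (identically 0 in focus)."""
    vals = tf.values if hasattr(tf, "values") else tf
    return -(a0 ** 2) * np.imag(vals)


def amplitude_transfer(tf, a0: float = 1.0) -> np.ndarray:
    """Absorption-contrast transfer a0·Re[WOTF]."""
    vals = tf.values if hasattr(tf, "values") else tf
    return a0 * np.real(vals)


# ---------------------------------------------------------------------------
# scalar contrast metrics on radial profiles

def _check_same_axis(p: RadialWOTF, q: RadialWOTF) -> None:
    if p.u.shape != q.u.shape or not np.allclose(p.u, q.u):
        raise ValueError("profiles are sampled on different frequency axes")


def contrast_area(profile: RadialWOTF) -> float:
    """Total phase contrast: ∫ |Im WOTF| dū over the radial profile."""
    return float(np.trapezoid(np.abs(profile.im), profile.u))


def phase_contrast_cutoff(profile: RadialWOTF, floor: float = 1e-6) -> float:
    """Largest ū with |Im WOTF| above ``floor`` × its peak."""
    a = np.abs(profile.im)
    peak = a.max()
    if peak == 0.0:
        return 0.0
    idx = np.nonzero(a > floor * peak)[0]
    return float(profile.u[idx[-1]]) if idx.size else 0.0


def support_cutoff(profile: RadialWOTF, floor: float = 1e-6) -> float:
    """Largest ū with |WOTF| above ``floor`` × its peak (Re and Im)."""
    a = np.abs(profile.values)
    idx = np.nonzero(a > floor * a.max())[0]
    return float(profile.u[idx[-1]]) if idx.size else 0.0


def gain_at(num: RadialWOTF, den: RadialWOTF, u_norm: float) -> float:
    """|Im WOTF| ratio of two profiles at a normalized frequency
    (linear interpolation between radial samples)."""
    _check_same_axis(num, den)
    a = np.interp(u_norm, num.u, np.abs(num.im))
    b = np.interp(u_norm, den.u, np.abs(den.im))
    return float(a / b)


def cutoff_factor(spec: SourceSpec) -> float:
    """Phase-contrast frequency cutoff in units of NA_obj/λ.

    Circular illumination extends the pass-band to 1 + s; an annulus to
    1 + s1 (= 2 − Δs when the outer radius matches the pupil), because the
    antisymmetric phase response cancels identically beyond that radius; a
    delta source stops at the coherent limit 1.
    """
    if spec.shape == "circular":
        return 1.0 + float(spec.s)
    if spec.shape == "annular":
        return 1.0 + float(spec.s1)
    return 1.0


def resolution_limit(spec: SourceSpec, na_obj: float, wavelength_um: float) -> float:
    """Minimum resolvable pitch λ/(cutoff_factor·NA_obj) in µm."""
    return wavelength_um / (cutoff_factor(spec) * na_obj)


def contrast_metrics(profile: RadialWOTF, floor: float = 1e-6) -> dict:
    """Summary scalars used to compare illumination apertures."""
    return {
        "area": contrast_area(profile),
        "cutoff": phase_contrast_cutoff(profile, floor=floor),
        "peak": float(np.abs(profile.im).max()),
    }
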