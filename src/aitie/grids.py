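"""Frequency-space coordinates in the FFT layout."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ImagingConfig

__all__ = ["FrequencyGrid"]


@dataclass
class FrequencyGrid:
    """2D spatial-frequency coordinates matching ``numpy.fft`` layout.

    ``fx``/``fy`` are in cycles/µm; ``norm_radius`` is |u|·λ/NA_obj, the
    frequency in units of the coherent diffraction limit, so the objective
    pupil edge sits at 1 and the incoherent limit at 2.
    """

    fx: np.ndarray
    fy: np.ndarray
    norm_radius: np.ndarray
    pixel_pitch_um: float
    wavelength_um: float
    na_obj: float

    @classmethod
    def from_config(cls, cfg: ImagingConfig) -> "FrequencyGrid":
        f = np.fft.fftfreq(cfg.grid_size, d=cfg.pixel_pitch_um)
        fx, fy = np.meshgrid(f, f, indexing="ij")
        rad = np.hypot(fx, fy) * cfg.wavelength_um / cfg.na_obj
        return cls(fx=fx, fy=fy, norm_radius=rad,
                   pixel_pitch_um=cfg.pixel_pitch_um,
                   wavelength_um=cfg.wavelength_um, na_obj=cfg.na_obj)

    @property
    def shape(self):
        return self.fx.shape

    @property
    def f_radius(self) -> np.ndarray:
        """Radial frequency |u| in cycles/µm."""
        return np.hypot(self.fx, self.fy)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.pixel_pitch_um

    @property
    def nyquist_norm(self) -> float:
        """Nyquist frequency in pupil-normalized units."""
        return self.nyquist * self.wavelength_um / self.na_obj
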