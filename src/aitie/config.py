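"""Configuration objects shared across the toolkit.

All lengths are micrometres, phases are radians and numerical apertures are
dimensionless.  A single-unit discipline is enforced here because mixed nm/µm
conventions are the classic source of error in quantitative phase work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "ImagingConfig",
    "SourceSpec",
    "NoiseModel",
    "ReconSettings",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Optical parameters of the microscope.

    Parameters
    ----------
    na_obj : float
        Objective numerical aperture, in (0, 1.5].
    wavelength_um : float
        Centre wavelength of the quasi-monochromatic illumination (µm).
    pixel_pitch_um : float
        Object-space sampling pitch (µm); camera pitch divided by the
        magnification.
    grid_size : int
        Pixels per side of the (square) computation grid; even, >= 16.
    """

    na_obj: float
    wavelength_um: float
    pixel_pitch_um: float
    grid_size: int

    def __post_init__(self) -> None:
        if not (0.0 < self.na_obj <= 1.5):
            raise ValueError(f"na_obj must be in (0, 1.5], got {self.na_obj}")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.grid_size < 16 or self.grid_size % 2:
            raise ValueError("grid_size must be even and >= 16")

    @property
    def wavenumber(self) -> float:
        """k = 2π/λ in rad/µm."""
        return 2.0 * math.pi / self.wavelength_um

    @property
    def coherent_cutoff(self) -> float:
        """Coherent diffraction limit NA/λ in cycles/µm."""
        return self.na_obj / self.wavelength_um

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the grid in cycles/µm."""
        return 0.5 / self.pixel_pitch_um


@dataclass(frozen=True)
class SourceSpec:
    """Condenser aperture geometry in pupil-normalized coordinates.

    Radii are expressed in units of the coherent cutoff NA_obj/λ, so ``s = 1``
    means an illumination NA equal to the objective NA.  ``circular`` is the
    conventional open diaphragm with coherence parameter ``s``; ``annular`` is
    the ring [s1, s2] (closed interval); ``delta`` is an on-axis point source
    (coherent limit).
    """

    shape: str
    s: Optional[float] = None
    s1: Optional[float] = None
    s2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "annular", "delta"):
            raise ValueError(f"unknown source shape {self.shape!r}")
        if self.shape == "circular":
            if self.s is None or self.s <= 0:
                raise ValueError("circular source requires s > 0")
        elif self.shape == "annular":
            if self.s1 is None or self.s2 is None or not (0 <= self.s1 < self.s2):
                raise ValueError("annular source requires 0 <= s1 < s2")

    @classmethod
    def circular(cls, s: float) -> "SourceSpec":
        return cls(shape="circular", s=s)

    @classmethod
    def annular(cls, s1: float, s2: float) -> "SourceSpec":
        return cls(shape="annular", s1=s1, s2=s2)

    @classmethod
    def matched_annulus(cls, width: float) -> "SourceSpec":
        """Annulus with outer radius matched to the objective pupil (s2 = 1)."""
        return cls(shape="annular", s1=1.0 - width, s2=1.0)

    @classmethod
    def delta(cls) -> "SourceSpec":
        return cls(shape="delta")

    @property
    def outer_radius(self) -> float:
        """Outermost normalized source radius (0 for a delta source)."""
        if self.shape == "circular":
            return float(self.s)
        if self.shape == "annular":
            return float(self.s2)
        return 0.0

    @property
    def width(self) -> float:
        """Annulus width Δs (s2 − s1); the full radius for a circular source."""
        if self.shape == "annular":
            return float(self.s2) - float(self.s1)
        return self.outer_radius


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian intensity noise in normalized units."""

    sigma: float = 0.0
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")


@dataclass(frozen=True)
class ReconSettings:
    """Phase-reconstruction choices.

    ``alpha`` is the Tikhonov regularizer; ``None`` selects the default for
    the source (machine epsilon for annular illumination, whose phase transfer
    has no zero-crossings in its pass-band, and 1e-3·max|Im WOTF|² otherwise).
    """

    method: str = "wotf_deconv"
    alpha: Optional[float] = None
    distances_used: Optional[Sequence[float]] = None
    combine: str = "single"

    def __post_init__(self) -> None:
        if self.method not in ("tie_poisson", "wotf_deconv"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.combine not in ("single", "least_squares"):
            raise ValueError(f"unknown combine mode {self.combine!r}")


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate → reconstruct → analyze)."""

    imaging: ImagingConfig
    source: SourceSpec
    defocus_um: Sequence[float] = (-0.5, 0.0, 0.5)
    noise: NoiseModel = field(default_factory=NoiseModel)
    recon: ReconSettings = field(default_factory=ReconSettings)
    input_path: Optional[str] = None
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if self.recon.method == "wotf_deconv" and self.source is None:
            raise ValueError("wotf_deconv requires a source specification")
        if not self.defocus_um:
            raise ValueError("defocus_um must be nonempty")


def _source_to_dict(src: SourceSpec) -> dict:
    d = {"shape": src.shape}
    if src.shape == "circular":
        d["s"] = src.s
    elif src.shape == "annular":
        d["s1"], d["s2"] = src.s1, src.s2
    return d


def _source_from_dict(d: dict) -> SourceSpec:
    return SourceSpec(shape=d["shape"], s=d.get("s"), s1=d.get("s1"), s2=d.get("s2"))


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        "na_obj": cfg.imaging.na_obj,
        "wavelength_um": cfg.imaging.wavelength_um,
        "pixel_pitch_um": cfg.imaging.pixel_pitch_um,
        "grid_size": cfg.imaging.grid_size,
        "source": _source_to_dict(cfg.source),
        "defocus_um": list(cfg.defocus_um),
        "noise": {"sigma": cfg.noise.sigma, "seed": cfg.noise.seed},
        "recon": {k: v for k, v in asdict(cfg.recon).items() if v is not None},
        "input_path": cfg.input_path,
        "output_dir": cfg.output_dir,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    imaging = ImagingConfig(
        na_obj=doc["na_obj"],
        wavelength_um=doc["wavelength_um"],
        pixel_pitch_um=doc["pixel_pitch_um"],
        grid_size=doc["grid_size"],
    )
    recon_doc = dict(doc.get("recon", {}))
    recon = ReconSettings(**recon_doc)
    noise_doc = doc.get("noise", {})
    cfg = RunConfig(
        imaging=imaging,
        source=_source_from_dict(doc["source"]),
        defocus_um=tuple(doc.get("defocus_um", (-0.5, 0.0, 0.5))),
        noise=NoiseModel(sigma=noise_doc.get("sigma", 0.0), seed=noise_doc.get("seed", 0)),
        recon=recon,
        input_path=doc.get("input_path"),
        output_dir=doc.get("output_dir"),
    )
    cfg.validate()
    return cfg
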