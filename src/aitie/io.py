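"""File I/O: focal stacks (multi-page float TIFF + JSON sidecar), phase maps
and transfer-function exports.

Per-plane defocus is written both into the TIFF page descriptions and into a
``<stack>.meta.json`` sidecar; the sidecar is authoritative because page
description fields are fragile across TIFF tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .phantoms import PhaseMap
from .simulate import FocalStack
from .transfer import RadialWOTF, TransferFunction

__all__ = [
    "write_stack",
    "read_stack",
    "write_phase",
    "read_phase",
    "export_radial_profile",
    "export_transfer_tiff",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_stack(stack: FocalStack, path) -> None:
    """Write a focal stack as multi-page 32-bit float TIFF plus sidecar."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for img, z in zip(stack.images, stack.defocus_um):
            tif.write(
                img.astype(np.float32),
                description=json.dumps({"defocus_um": z}),
                contiguous=False,
            )
    meta = {
        "defocus_um": list(stack.defocus_um),
        "pixel_pitch_um": stack.pixel_pitch_um,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> FocalStack:
    """Read a focal stack written by :func:`write_stack`.

    Defocus metadata is taken from the sidecar when present, otherwise from
    the TIFF page descriptions; a page without defocus metadata is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        descs = [p.description for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"stack pages have inconsistent shapes: {shapes}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        defocus = meta["defocus_um"]
        pitch = meta.get("pixel_pitch_um", 1.0)
    else:
        defocus, pitch = [], 1.0
        for i, d in enumerate(descs):
            try:
                defocus.append(json.loads(d)["defocus_um"])
            except Exception as exc:
                raise ValueError(f"page {i} has no defocus metadata") from exc
    if len(defocus) != len(pages):
        raise ValueError("number of defocus entries does not match pages")
    return FocalStack(np.stack([p.astype(float) for p in pages]), defocus, pitch)


def write_phase(phase: PhaseMap, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, phase.values.astype(np.float32),
                     description=json.dumps({"pixel_pitch_um": phase.pixel_pitch_um}))
    _sidecar(path).write_text(json.dumps({"pixel_pitch_um": phase.pixel_pitch_um}))


def read_phase(path) -> PhaseMap:
    path = Path(path)
    vals = tifffile.imread(path).astype(float)
    pitch = 1.0
    side = _sidecar(path)
    if side.exists():
        pitch = json.loads(side.read_text()).get("pixel_pitch_um", 1.0)
    return PhaseMap(vals, pitch)


def export_radial_profile(profile: RadialWOTF, path) -> None:
    """Two-column-per-part text export: ū, Re WOTF, Im WOTF."""
    data = np.column_stack([profile.u, profile.re, profile.im])
    header = (f"normalized_frequency re_wotf im_wotf "
              f"(defocus_um={profile.defocus_um}, na_obj={profile.config.na_obj}, "
              f"wavelength_um={profile.config.wavelength_um})")
    np.savetxt(path, data, header=header)


def export_transfer_tiff(tf: TransferFunction, path) -> None:
    """2-page float32 TIFF: page 0 = Re WOTF, page 1 = Im WOTF."""
    with tifffile.TiffWriter(Path(path)) as out:
        out.write(tf.values.real.astype(np.float32), description="re_wotf")
        out.write(tf.values.imag.astype(np.float32), description="im_wotf")
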