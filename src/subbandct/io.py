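"""File formats: float TIFF images with JSON provenance sidecars, HDF5 sinograms."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .fbp import ReconImage
from .geometry import FanBeamGeometry, ImageGrid
from .projector import Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
]


def save_image(recon: ReconImage, path: str | Path) -> None:
    """Write a reconstruction as 32-bit float TIFF plus a `.json` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, recon.values.astype(np.float32))
    sidecar = {
        "n_pixels": recon.grid.n_pixels,
        "pixel_mm": recon.grid.pixel_mm,
        "provenance": recon.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_image(path: str | Path) -> ReconImage:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = ImageGrid(sidecar["n_pixels"], sidecar["pixel_mm"])
    return ReconImage(values, grid, sidecar.get("provenance", {}))


_GEOMETRY_ATTRS = (
    "source_isocenter_mm",
    "source_detector_mm",
    "n_channels",
    "channel_pitch_mm",
    "n_views",
)


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    """HDF5 layout: dataset "sinogram" (views × channels, float32) with the
    geometry mirrored in its attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sinogram", data=sino.values.astype(np.float32))
        for name in _GEOMETRY_ATTRS:
            ds.attrs[name] = getattr(sino.geometry, name)


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with h5py.File(path, "r") as f:
        ds = f["sinogram"]
        values = ds[...].astype(float)
        attrs = {k: ds.attrs[k] for k in ds.attrs}
    if not attrs and sidecar.exists():  # JSON sidecar as alternative metadata
        attrs = json.loads(sidecar.read_text())
    geom = FanBeamGeometry(
        source_isocenter_mm=float(attrs["source_isocenter_mm"]),
        source_detector_mm=float(attrs["source_detector_mm"]),
        n_channels=int(attrs["n_channels"]),
        channel_pitch_mm=float(attrs["channel_pitch_mm"]),
        n_views=int(attrs["n_views"]),
    )
    return Sinogram(values, geom)
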