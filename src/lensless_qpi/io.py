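"""Reading and writing images, phase maps and complex fields.

Camera frames come in as 8- or 16-bit grayscale PNG/TIFF and are mapped to
[0, 1]; phase maps go out as 32-bit float TIFF (radians); complex fields are
persisted as a pair of 32-bit float TIFFs (amplitude and phase).  A plain
key-value sidecar file carries geometry metadata alongside an image.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .grid_optics import ComplexField, SimulationGrid
from .phantoms import PhaseMap

__all__ = [
    "FormatError",
    "read_intensity",
    "write_intensity",
    "read_phase",
    "write_phase",
    "read_field",
    "write_field",
]


class FormatError(ValueError):
    """Unsupported image format (wrong bit depth, color, ...)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def read_intensity(path) -> tuple[np.ndarray, dict]:
    """Load a grayscale intensity frame, scaled to [0, 1], plus metadata.

    8-bit input is divided by 255, 16-bit by 65535; float input is passed
    through unchanged.  Color images are rejected (convert to grayscale
    first).  Metadata is read from a ``<name>.meta.yaml`` sidecar when one
    exists.
    """
    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim != 2:
        raise FormatError(
            f"{path.name} is not a single-channel grayscale image "
            f"(shape {img.shape}); convert to grayscale before loading"
        )
    if img.dtype == np.uint8:
        out = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        out = img.astype(float) / 65535.0
    elif np.issubdtype(img.dtype, np.floating):
        out = img.astype(float)
    else:
        raise FormatError(
            f"{path.name}: unsupported bit depth {img.dtype}; expected "
            f"uint8, uint16 or float grayscale"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return out, meta


def write_intensity(path, intensity: np.ndarray, metadata: dict | None = None
                    ) -> Path:
    """Save an intensity frame (expected in [0, 1]) as 16-bit grayscale."""
    path = Path(path)
    arr = np.asarray(intensity, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("intensity must lie in [0, 1] before 16-bit export")
    quantized = np.round(arr * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quantized)
    else:
        iio.imwrite(path, quantized)
    if metadata:
        _sidecar_path(path).write_text(yaml.safe_dump(metadata, sort_keys=True))
    return path


def write_phase(path, phase: PhaseMap) -> Path:
    """Save a phase map as a 32-bit float TIFF in radians."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(phase.values, dtype=np.float32))
    return path


def read_phase(path, pixel: float | None = None) -> PhaseMap:
    """Load a float-TIFF phase map (radians)."""
    values = tifffile.imread(Path(path))
    return PhaseMap(np.asarray(values), pixel=pixel)


def write_field(path, field: ComplexField) -> tuple[Path, Path]:
    """Persist a complex field as paired amplitude/phase float TIFFs.

    ``path`` is a stem; the files written are ``<stem>.amp.tif`` and
    ``<stem>.phase.tif``.
    """
    stem = Path(path)
    amp_path = stem.with_suffix(".amp.tif")
    phase_path = stem.with_suffix(".phase.tif")
    tifffile.imwrite(amp_path, np.abs(field.values).astype(np.float32))
    tifffile.imwrite(phase_path, np.angle(field.values).astype(np.float32))
    return amp_path, phase_path


def read_field(path, grid: SimulationGrid, plane_label: str = "") -> ComplexField:
    """Load a complex field written by :func:`write_field`."""
    stem = Path(path)
    amp = tifffile.imread(stem.with_suffix(".amp.tif")).astype(float)
    phase = tifffile.imread(stem.with_suffix(".phase.tif")).astype(float)
    return ComplexField(values=amp * np.exp(1j * phase), grid=grid,
                        plane_label=plane_label)
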