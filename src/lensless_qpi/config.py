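"""Experiment configuration: a flat key-value file describing a full run.

Lengths are stored internally in meters and written to file with an explicit
``m`` suffix (shortest-repr, so files round-trip losslessly); the parser
also accepts ``cm``/``mm``/``um``/``nm`` suffixes for hand-written configs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .units import parse_length

__all__ = ["ExperimentConfig"]

_LENGTH_FIELDS = ("d1", "d2", "wavelength", "pixel", "thickness", "delta_d")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a simulate-retrieve-analyze run.

    ``mode`` is ``"simulate"`` (generate a phantom and its sensor frame,
    then retrieve) or ``"data"`` (retrieve from a pre-recorded frame at
    ``intensity_path``).  ``use_effective_distance`` applies the spherical
    illumination correction ``(1/d2 - 1/d1)^-1`` to the retrieval distance.
    """

    # geometry
    d1: float = 2.0
    d2: float = 0.2
    wavelength: float = 530e-9
    pixel: float = 4.65e-6
    n1: int = 256
    n2: int = 256
    # retrieval
    iterations: int = 50
    stop_tolerance: float = 0.0
    initial_phase: str = "uniform"
    seed: int = 0
    use_effective_distance: bool = True
    # phantom (simulate mode)
    mode: str = "simulate"
    phantom: str = "disc"
    phantom_size: int = 128
    thickness: float = 530e-9
    refractive_index: float = 1.5
    # second plane: enabled when delta_d > 0
    phantom_b: str = ""
    delta_d: float = 0.0
    # data mode
    intensity_path: str = ""
    output_dir: str = "qpi-run"

    def to_file(self, path) -> Path:
        path = Path(path)
        doc = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name in _LENGTH_FIELDS:
                doc[f.name] = f"{value!r}m"
            else:
                doc[f.name] = value
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in _LENGTH_FIELDS:
            if key in doc:
                doc[key] = parse_length(doc[key])
        return cls(**doc)
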