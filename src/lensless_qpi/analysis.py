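"""Quantitative evaluation of reconstructions and imaging geometry.

Covers the phase-only-filter cross-correlation used to score a retrieved
phase map against a reference, conversion between phase and physical
thickness, two-pass separable phase unwrapping, and the geometric figures of
merit of the lensless configuration (magnification, numerical aperture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_2d

from .phantoms import PhaseMap

__all__ = [
    "ImagingGeometry",
    "CorrelationReport",
    "phase_correlation",
    "phase_similarity",
    "phase_from_thickness",
    "thickness_from_phase",
    "magnification",
    "numerical_aperture",
    "unwrap_phase",
]

TWO_PI = 2.0 * np.pi

#: floor applied to spectral moduli before the phase-only division
POF_FLOOR = 1e-12


@dataclass(frozen=True)
class ImagingGeometry:
    """Source-sample distance d1, sample-sensor distance d2, sensor diameter D."""

    d1: float
    d2: float
    sensor_diameter: float
    pixel: float

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "sensor_diameter", "pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_grid(cls, grid, d1: float, d2: float) -> "ImagingGeometry":
        d = grid.pixel * max(grid.n1, grid.n2)
        return cls(d1=d1, d2=d2, sensor_diameter=d, pixel=grid.pixel)

    @property
    def magnification(self) -> float:
        return magnification(self.d1, self.d2)

    @property
    def numerical_aperture(self) -> float:
        return numerical_aperture(self)


@dataclass
class CorrelationReport:
    """Phase-only-filter correlation of a test map against a reference.

    ``value_at_origin`` is the zero-lag value ``C(0, 0)`` of the squared
    cross-correlation magnitude; ``autocorrelation_reference`` is the same
    quantity for the reference against itself (the attainable maximum), and
    ``normalized_score`` their ratio.  A map correlated with itself scores
    exactly 1.
    """

    value_at_origin: float
    autocorrelation_reference: float
    normalized_score: float
    surface: np.ndarray | None = None


def _as_array(m) -> np.ndarray:
    return np.asarray(getattr(m, "values", m), dtype=float)


def _pof_cross_correlation(reference: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Complex correlation surface with a phase-only filter on the test spectrum."""
    fr = np.fft.fft2(reference)
    ft = np.fft.fft2(test)
    pof = ft / np.maximum(np.abs(ft), POF_FLOOR)
    return np.fft.ifft2(fr * np.conj(pof))


def phase_correlation(reference, test, keep_surface: bool = False) -> CorrelationReport:
    """Score a test phase map against a reference by phase-only correlation.

    Both maps are treated as real-valued images.  The test spectrum is
    normalized to unit modulus (phase-only filter, floor-guarded), the
    cross-correlation evaluated by FFT, and the squared magnitude at zero
    lag reported, normalized by the reference autocorrelation so the score
    is comparable across objects.  With ``keep_surface=True`` the full
    (center-origin) squared-magnitude surface is retained.
    """
    ref = _as_array(reference)
    tst = _as_array(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if not ref.any() or not tst.any():
        raise ValueError("phase correlation of an all-zero map is undefined")
    cross = _pof_cross_correlation(ref, tst)
    auto = _pof_cross_correlation(ref, ref)
    value = float(np.abs(cross[0, 0]) ** 2)
    auto_value = float(np.abs(auto[0, 0]) ** 2)
    surface = np.fft.fftshift(np.abs(cross) ** 2) if keep_surface else None
    return CorrelationReport(
        value_at_origin=value,
        autocorrelation_reference=auto_value,
        normalized_score=value / auto_value,
        surface=surface,
    )


def phase_similarity(reference, test) -> float:
    """Zero-mean normalized cross-correlation of two phase maps at zero lag.

    A smooth companion to :func:`phase_correlation`: the phase-only filter
    makes that score a very sharp (and therefore noise-sensitive) matched
    detector, useful for tracking convergence but close to zero even for
    visually faithful reconstructions.  This Pearson-style score stays
    interpretable (-1 to 1) for judging overall structural agreement.
    """
    ref = _as_array(reference)
    tst = _as_array(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    a = ref - ref.mean()
    b = tst - tst.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("similarity of a constant map is undefined")
    return float((a * b).sum() / denom)


def phase_from_thickness(t, n: float, wavelength: float):
    """Optical phase delay of a relief of thickness ``t`` in air.

    ``phi = 2 pi t (n - 1) / lambda`` — e.g. 800 nm of index-1.5 material at
    530 nm gives about 1.5 pi radians.  Accepts scalars or arrays.
    """
    if n <= 1:
        raise ValueError(f"refractive index must exceed 1, got {n!r}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    out = TWO_PI * t * (n - 1.0) / wavelength
    return float(out) if out.ndim == 0 else out


def thickness_from_phase(phi, n: float, wavelength: float):
    """Invert :func:`phase_from_thickness`: ``t = phi lambda / (2 pi (n - 1))``."""
    if n <= 1:
        raise ValueError(f"refractive index must exceed 1, got {n!r}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    phi = np.asarray(phi, dtype=float)
    out = phi * wavelength / (TWO_PI * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def magnification(d1: float, d2: float) -> float:
    """Geometric-projection magnification ``M = 1 + d2/d1`` (always >= 1)."""
    if d1 <= 0 or d2 < 0:
        raise ValueError("distances must be positive (d2 may be 0)")
    return 1.0 + d2 / d1


def numerical_aperture(geometry: ImagingGeometry) -> float:
    """Collection NA of the lensless geometry: ``D / (2 (d1 + d2))``."""
    return geometry.sensor_diameter / (2.0 * (geometry.d1 + geometry.d2))


def unwrap_phase(wrapped, method: str = "separable") -> PhaseMap:
    """Recover a continuous phase surface from its modulo-2pi representation.

    The default ``"separable"`` method unwraps the first column, then each
    row anchored to it — the classic 1-D-unwrap-in-a-loop construction,
    exact on residue-free (noiseless, adequately sampled) maps.  The
    ``"quality"`` method delegates to the 2-D quality-guided unwrapper for
    noisy data.  Either way, output minus input is a multiple of 2pi at
    every pixel; noisy inputs may unwrap imperfectly but never raise.
    """
    values = _as_array(wrapped)
    if values.ndim != 2:
        raise ValueError("expected a 2-D phase map")
    if method == "separable":
        out = np.unwrap(values, axis=1)
        first_col = np.unwrap(values[:, 0])
        out = out + (first_col - out[:, 0])[:, np.newaxis]
    elif method == "quality":
        out = np.asarray(_unwrap_2d(np.mod(values + np.pi, TWO_PI) - np.pi))
        # re-anchor so the first pixel is congruent with the input
        out = out + (values[0, 0] - out[0, 0])
    else:
        raise ValueError(f"unknown unwrap method {method!r}")
    src = wrapped if isinstance(wrapped, PhaseMap) else None
    return PhaseMap(out, pixel=getattr(src, "pixel", None),
                    n=getattr(src, "n", None),
                    wavelength=getattr(src, "wavelength", None))
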