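"""Synthetic phase and amplitude objects for simulation studies.

Everything downstream of the forward model is exercised on objects generated
here: binary phase steps drawn from procedural masks, a linear modulo-2pi
phase ramp, a phase-only scattering layer designed by a Fourier-plane
Gerchberg-Saxton synthesis, and a thick object composed of two thin phase
objects at different axial positions.  All generation is deterministic
(seeded where random).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from skimage import draw as _draw

from .grid_optics import (
    SimulationGrid,
    apply_phase_object,
    point_source_illumination,
    propagate,
    sensor_intensity,
    spherical_kernel,
)

__all__ = [
    "PhaseMap",
    "ThickObject",
    "ScatterSpec",
    "binary_phase_from_mask",
    "linear_ramp_phase",
    "scattering_layer",
    "fourier_support_power_fraction",
    "two_plane_object",
    "simulate_two_plane_intensity",
    "builtin_phantom",
    "PHANTOM_REGISTRY",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseMap:
    """A 2-D phase distribution in radians.

    Optional material context (refractive index ``n`` and ``wavelength``)
    allows conversion between phase and physical thickness via
    ``phi = 2 pi t (n - 1) / lambda``.  ``wrapped`` declares that values
    live in ``[0, 2 pi)``.
    """

    values: np.ndarray
    pixel: float | None = None
    n: float | None = None
    wavelength: float | None = None
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")
        if self.wrapped and (self.values.min() < 0 or self.values.max() >= TWO_PI):
            raise ValueError("wrapped phase map must lie in [0, 2*pi)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def wrap(self) -> "PhaseMap":
        """Return the modulo-2pi representation of this map."""
        return PhaseMap(np.mod(self.values, TWO_PI), pixel=self.pixel,
                        n=self.n, wavelength=self.wavelength, wrapped=True)

    def to_thickness(self) -> np.ndarray:
        """Convert phase to thickness in meters (requires material context)."""
        if self.n is None or self.wavelength is None:
            raise ValueError("thickness conversion needs refractive index and wavelength")
        return self.values * self.wavelength / (TWO_PI * (self.n - 1.0))


@dataclass
class ThickObject:
    """An axially extended object: thin phase planes at increasing positions.

    Axial positions are measured downstream from the first plane; the
    spacing ``delta_d`` between consecutive planes follows from them.  The
    source sits ``d1`` upstream of the first plane and the sensor ``d2``
    downstream of the last.
    """

    planes: list[tuple[PhaseMap, float]]
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if len(self.planes) < 2:
            raise ValueError("a thick object needs at least two planes")
        positions = [z for _, z in self.planes]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("plane positions must be strictly increasing")

    @property
    def spacings(self) -> list[float]:
        positions = [z for _, z in self.planes]
        return [b - a for a, b in zip(positions, positions[1:])]

    def sensor_distances(self) -> list[float]:
        """Distance from each plane to the sensor, nearest plane last."""
        z_last = self.planes[-1][1]
        return [self.d2 + (z_last - z) for _, z in self.planes]


@dataclass(frozen=True)
class ScatterSpec:
    """Parameters of a designed phase-only scattering layer.

    ``sigma`` is the scattering ratio: the fraction of Fourier-plane samples
    inside the target support (a centered disc) over which the far-field
    power is to be spread.
    """

    size: int
    sigma: float
    iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"size must be positive, got {self.size}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")


def binary_phase_from_mask(mask: np.ndarray, t: float, n: float,
                           wavelength: float) -> PhaseMap:
    """Phase map of a binary relief: step ``2 pi t (n - 1) / lambda`` on the mask.

    ``mask`` must be binary (boolean or {0, 1}); ``t`` is the relief
    thickness in meters and ``n`` the refractive index of the material
    (in air).  A 530 nm step of index 1.5 at 530 nm wavelength gives a
    phase step of exactly pi.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (values 0/1 or boolean)")
    if t < 0:
        raise ValueError(f"thickness must be non-negative, got {t!r}")
    if n <= 1:
        raise ValueError(f"refractive index must exceed 1, got {n!r}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    step = TWO_PI * t * (n - 1.0) / wavelength
    return PhaseMap(step * mask.astype(float), n=n, wavelength=wavelength)


def linear_ramp_phase(size: int, max_phase: float, wrapped: bool = False,
                      ramp_fraction: float = 0.5) -> PhaseMap:
    """Linear phase ramp embedded in a zero-phase surround.

    A centered square block covering ``ramp_fraction`` of the map per side
    ramps linearly from 0 to ``max_phase`` left to right; the surround is
    zero phase (unit amplitude when used as a pure phase object).  With
    ``wrapped=True`` the values are reduced modulo 2pi, producing
    ``max_phase / 2pi`` fringe periods across the ramp.
    """
    if max_phase < 0:
        raise ValueError(f"max_phase must be non-negative, got {max_phase!r}")
    values = np.zeros((size, size), dtype=float)
    side = max(2, int(round(size * ramp_fraction)))
    r0 = (size - side) // 2
    c0 = (size - side) // 2
    ramp = np.linspace(0.0, max_phase, side)
    values[r0:r0 + side, c0:c0 + side] = ramp[np.newaxis, :]
    if wrapped:
        return PhaseMap(np.mod(values, TWO_PI), wrapped=True)
    return PhaseMap(values)


def _fourier_support(size: int, sigma: float) -> np.ndarray:
    """Centered disc occupying (approximately) fraction sigma of Fourier samples."""
    radius = np.sqrt(sigma / np.pi) * size
    ii, jj = np.indices((size, size))
    c = size // 2
    return (ii - c) ** 2 + (jj - c) ** 2 <= radius**2


def scattering_layer(spec: ScatterSpec, return_history: bool = False):
    """Synthesize a phase-only scattering layer by a Fourier-plane GS iteration.

    Starting from seeded random phase on a unit-amplitude layer, the loop
    alternates between imposing the target amplitude in the Fourier plane
    (uniform inside a centered disc covering fraction ``sigma`` of the
    samples, zero outside) and re-imposing unit amplitude in the layer
    plane, carrying phases both ways.  The returned :class:`PhaseMap` holds
    the converged layer phase in ``[0, 2 pi)``; a layer with ``sigma = 0``
    is a uniform (zero) phase.

    With ``return_history=True`` also returns the per-iteration fraction of
    far-field power captured inside the target support.
    """
    if spec.sigma == 0.0:
        layer = PhaseMap(np.zeros((spec.size, spec.size)), wrapped=True)
        return (layer, np.ones(spec.iterations)) if return_history else layer
    rng = np.random.default_rng(spec.seed)
    support = _fourier_support(spec.size, spec.sigma)
    target = support.astype(float)
    field = np.exp(1j * rng.uniform(0.0, TWO_PI, (spec.size, spec.size)))
    history = np.empty(spec.iterations)
    for it in range(spec.iterations):
        F = np.fft.fftshift(np.fft.fft2(field))
        power = np.abs(F) ** 2
        history[it] = power[support].sum() / power.sum()
        F = target * np.exp(1j * np.angle(F))
        field = np.fft.ifft2(np.fft.ifftshift(F))
        field = np.exp(1j * np.angle(field))
    layer = PhaseMap(np.mod(np.angle(field), TWO_PI), wrapped=True)
    return (layer, history) if return_history else layer


def fourier_support_power_fraction(layer: PhaseMap, sigma: float) -> float:
    """Fraction of a layer's far-field power inside the sigma target support."""
    field = np.exp(1j * layer.values)
    F = np.fft.fftshift(np.fft.fft2(field))
    power = np.abs(F) ** 2
    support = _fourier_support(layer.values.shape[0], sigma)
    return float(power[support].sum() / power.sum())


def two_plane_object(phase_a: PhaseMap, phase_b: PhaseMap, d1: float,
                     delta_d: float, d2: float) -> ThickObject:
    """Construct a thick object from two thin phase objects ``delta_d`` apart.

    Plane A sits at axial position 0 (a distance ``d1`` from the point
    source) and plane B at ``delta_d``; the sensor is ``d2`` beyond plane B,
    so A and B are ``d2 + delta_d`` and ``d2`` from the sensor respectively.
    """
    if delta_d <= 0:
        raise ValueError(f"plane spacing delta_d must be positive, got {delta_d!r}")
    return ThickObject(planes=[(phase_a, 0.0), (phase_b, float(delta_d))],
                       d1=float(d1), d2=float(d2))


def simulate_two_plane_intensity(obj: ThickObject, grid: SimulationGrid,
                                 kind: str = "spherical") -> np.ndarray:
    """Forward-simulate the sensor frame of a (two-plane) thick object.

    The illumination is applied at the first plane, then each phase plane is
    applied and the field propagated to the next, finishing with the
    sensor-plane intensity (peak-normalized, sensor-sized).
    """
    field = point_source_illumination(grid, obj.d1)
    for (phase, z), (_, z_next) in zip(obj.planes, obj.planes[1:]):
        field = apply_phase_object(field, phase)
        field = propagate(field, spherical_kernel(grid, z_next - z))
    field = apply_phase_object(field, obj.planes[-1][0])
    return sensor_intensity(field, obj.d2, kind=kind)


def _draw_disc(size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = _draw.disk((size / 2 - 0.5, size / 2 - 0.5), 0.25 * size,
                        shape=mask.shape)
    mask[rr, cc] = 1
    return mask


def _draw_ring(size: int) -> np.ndarray:
    mask = _draw_disc(size)
    inner = np.zeros_like(mask)
    rr, cc = _draw.disk((size / 2 - 0.5, size / 2 - 0.5), 0.15 * size,
                        shape=mask.shape)
    inner[rr, cc] = 1
    return (mask & ~inner).astype(np.uint8)


def _draw_star(size: int, points: int = 5) -> np.ndarray:
    """Five-pointed star polygon, the classic resolution/alignment target."""
    c = size / 2 - 0.5
    r_out, r_in = 0.42 * size, 0.17 * size
    angles = -np.pi / 2 + np.arange(2 * points) * np.pi / points
    radii = np.where(np.arange(2 * points) % 2 == 0, r_out, r_in)
    rows = c + radii * np.sin(angles)
    cols = c + radii * np.cos(angles)
    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = _draw.polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = 1
    return mask


def _draw_silhouette(size: int) -> np.ndarray:
    """Blobby animal-like silhouette: body + head + ear ellipses and a tail."""
    mask = np.zeros((size, size), dtype=np.uint8)
    s = size / 256.0  # drawn at a 256 reference scale
    for cy, cx, ry, rx, rot in (
        (150, 120, 55, 38, 0.2),    # body
        (88, 160, 26, 20, -0.3),    # head
        (62, 150, 16, 6, -0.2),     # ear
        (62, 172, 16, 6, 0.3),      # ear
        (180, 60, 14, 48, 0.5),     # tail
        (205, 100, 26, 10, 0.1),    # leg
        (205, 140, 26, 10, -0.1),   # leg
    ):
        rr, cc = _draw.ellipse(cy * s, cx * s, ry * s, rx * s,
                               shape=mask.shape, rotation=rot)
        mask[rr, cc] = 1
    return mask


def _draw_bars(size: int) -> np.ndarray:
    """Three-bar group, a simple resolution element."""
    mask = np.zeros((size, size), dtype=np.uint8)
    w = max(2, size // 16)
    h0, h1 = int(0.25 * size), int(0.75 * size)
    for k in range(3):
        c0 = int(0.3 * size) + k * 2 * w
        mask[h0:h1, c0:c0 + w] = 1
    return mask


PHANTOM_REGISTRY = {
    "disc": _draw_disc,
    "ring": _draw_ring,
    "star": _draw_star,
    "silhouette": _draw_silhouette,
    "bars": _draw_bars,
}


def builtin_phantom(name: str, size: int = 256) -> np.ndarray:
    """Procedurally drawn binary mask from the built-in registry.

    Synthetic stand-ins for typical lithographic test objects (disc, ring,
    star, animal silhouette, bar group); deterministic for a given name and
    size, values strictly in {0, 1}.
    """
    try:
        fn = PHANTOM_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown phantom {name!r}; available: {sorted(PHANTOM_REGISTRY)}"
        ) from None
    if size <= 0:
        raise ValueError(f"size must be positive, got {size!r}")
    return fn(int(size))
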