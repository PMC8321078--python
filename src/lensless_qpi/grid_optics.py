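"""Computational space, scalar-diffraction kernels and the lensless forward model.

The imaging geometry is a pinhole point source, a (mostly) transparent phase
sample a distance ``d1`` downstream, and a bare image sensor a further ``d2``
away.  All wave propagation is simulated on a computational space twice the
sensor size in each dimension (a zero-padding margin for the circular
convolutions), sampled at the sensor pixel pitch, with the coordinate origin
at the central sample.

Free-space propagation over a distance ``d`` is a 2-D convolution with a
sampled kernel:

* spherical kernel ``S[R(d)] = exp(j 2 pi R(d) / lambda)`` with
  ``R(d) = sqrt(x^2 + y^2 + d^2)`` — exact (non-paraxial) phase;
* quadratic (Fresnel) kernel ``Q(b) = exp(j pi b (x^2 + y^2) / lambda)``
  with ``b = 1/d`` — the paraxial approximation of the spherical kernel.

The convolution is evaluated with three FFTs,
``f (*) S = IFFT[FFT(f) x FFT(S)]``, on the centered grid, and the output is
rescaled so total power is conserved (the physical kernels carry an arbitrary
complex constant which this normalization fixes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SimulationGrid",
    "ComplexField",
    "PropagationKernel",
    "kernel_spectrum",
    "make_grid",
    "spherical_kernel",
    "quadratic_phase",
    "propagate",
    "point_source_illumination",
    "apply_phase_object",
    "sensor_intensity",
    "embed_in_center",
    "crop_center",
]


@dataclass(frozen=True)
class SimulationGrid:
    """Sampling of the computational space.

    ``n1`` x ``n2`` is the sensor size in pixels (rows x columns); the
    computational space holds ``2*n1`` x ``2*n2`` samples at pitch ``pixel``
    (meters).  ``x``/``y`` are integer sample indices running from ``-N`` to
    ``N - 1`` per axis and ``X``/``Y`` are the corresponding metric
    coordinate arrays, symmetric about the origin sample at index
    ``(n1, n2)``.
    """

    n1: int
    n2: int
    pixel: float
    wavelength: float
    x: np.ndarray
    y: np.ndarray
    X: np.ndarray
    Y: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        """Shape of the computational space: ``(2*n1, 2*n2)``."""
        return (2 * self.n1, 2 * self.n2)

    @property
    def sensor_shape(self) -> tuple[int, int]:
        return (self.n1, self.n2)

    @property
    def center_index(self) -> tuple[int, int]:
        """Index of the origin sample (where X = Y = 0)."""
        return (self.n1, self.n2)

    @property
    def central_block(self) -> tuple[slice, slice]:
        """Slices selecting the sensor-sized central region."""
        return (
            slice(self.n1 // 2, 3 * self.n1 // 2),
            slice(self.n2 // 2, 3 * self.n2 // 2),
        )


@dataclass
class ComplexField:
    """A complex optical field sampled on a :class:`SimulationGrid`."""

    values: np.ndarray
    grid: SimulationGrid
    plane_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match the "
                f"computational space {self.grid.shape}"
            )

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass(frozen=True)
class PropagationKernel:
    """A sampled free-space propagation kernel.

    ``kind`` is ``"spherical"`` (exact phase) or ``"quadratic"`` (Fresnel).
    Spherical kernels have unit modulus at every sample and satisfy
    ``K(-d) = conj(K(+d))``.
    """

    values: np.ndarray
    distance: float
    kind: str
    grid: SimulationGrid


def make_grid(n1: int, n2: int, pixel: float, wavelength: float) -> SimulationGrid:
    """Create the centered computational space for an ``n1`` x ``n2`` sensor.

    Parameters
    ----------
    n1, n2 :
        Sensor height and width in pixels.  Must be even and at least 8 so
        the doubled space has a well-defined central block.
    pixel :
        Pixel pitch in meters (also the sampling period of the simulation).
    wavelength :
        Illumination wavelength in meters.
    """
    for name, n in (("n1", n1), ("n2", n2)):
        if int(n) != n or n < 8 or n % 2 != 0:
            raise ValueError(f"{name} must be an even integer >= 8, got {n!r}")
    if pixel <= 0:
        raise ValueError(f"pixel pitch must be positive, got {pixel!r}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    n1, n2 = int(n1), int(n2)
    x = np.arange(-n1, n1)
    y = np.arange(-n2, n2)
    X, Y = np.meshgrid(x * pixel, y * pixel, indexing="ij")
    return SimulationGrid(n1=n1, n2=n2, pixel=float(pixel),
                          wavelength=float(wavelength), x=x, y=y, X=X, Y=Y)


def spherical_kernel(grid: SimulationGrid, d: float) -> PropagationKernel:
    """Exact spherical-wave kernel ``exp(j sign(d) 2 pi R(|d|) / lambda)``.

    Negative ``d`` gives the backward propagator, the elementwise conjugate
    of the forward one.
    """
    if d == 0:
        raise ValueError("propagation distance d must be non-zero")
    R = np.sqrt(grid.X**2 + grid.Y**2 + d**2)
    values = np.exp(1j * np.sign(d) * 2.0 * np.pi * R / grid.wavelength)
    return PropagationKernel(values=values, distance=float(d),
                             kind="spherical", grid=grid)


def quadratic_phase(grid: SimulationGrid, b: float) -> PropagationKernel:
    """Paraxial (Fresnel) kernel ``exp(j pi b (X^2 + Y^2) / lambda)``.

    ``b`` is the inverse propagation distance in 1/m; ``b = 0`` yields the
    all-ones field (no propagation).  Within the paraxial region
    ``X^2 + Y^2 << d^2`` it matches the spherical kernel up to the constant
    phase ``exp(j 2 pi d / lambda)``.
    """
    if not np.isfinite(b):
        raise ValueError(f"curvature b must be finite, got {b!r}")
    values = np.exp(1j * np.pi * b * (grid.X**2 + grid.Y**2) / grid.wavelength)
    d = np.inf if b == 0 else 1.0 / b
    return PropagationKernel(values=values, distance=float(d),
                             kind="quadratic", grid=grid)


def kernel_spectrum(kernel: PropagationKernel, exact: bool = True) -> np.ndarray:
    """Spectrum of a propagation kernel on the grid's FFT frequencies.

    With ``exact=True`` (the recommended mode) the spectrum is evaluated in
    closed form: the spherical kernel's spectrum is the angular-spectrum
    transfer function ``exp(j sign(d) 2 pi |d| sqrt(1/lambda^2 - f^2))`` and
    the quadratic kernel's is the Fresnel transfer function
    ``exp(-j pi lambda (fx^2 + fy^2) / b)``.  Both have unit modulus at
    every frequency, so propagation conserves power exactly and forward and
    backward kernels are exact inverses.  With ``exact=False`` the sampled
    real-space kernel is transformed numerically instead; that spectrum
    carries truncation artifacts of the finite chirp (its modulus collapses
    outside the stationary-phase band), and is kept for comparison against
    direct-summation convolution.
    """
    grid = kernel.grid
    if not exact:
        return np.fft.fft2(np.fft.ifftshift(kernel.values))
    f1 = np.fft.fftfreq(grid.shape[0], grid.pixel)
    f2 = np.fft.fftfreq(grid.shape[1], grid.pixel)
    F1, F2 = np.meshgrid(f1, f2, indexing="ij")
    lam = grid.wavelength
    if kernel.kind == "spherical":
        d = kernel.distance
        # pixel pitch >> lambda/2 keeps all sampled frequencies propagating
        # (no evanescent components), so the root argument stays positive
        arg = np.maximum(1.0 / lam**2 - F1**2 - F2**2, 0.0)
        return np.exp(1j * np.sign(d) * 2.0 * np.pi * abs(d) * np.sqrt(arg))
    if kernel.kind == "quadratic":
        d = kernel.distance  # = 1/b
        if np.isinf(d):
            return np.ones(grid.shape, dtype=complex)
        return np.exp(-1j * np.pi * lam * d * (F1**2 + F2**2))
    raise ValueError(f"unknown kernel kind {kernel.kind!r}")


def propagate(field: ComplexField, kernel: PropagationKernel,
              exact_spectrum: bool = True) -> ComplexField:
    """Free-space propagation as a three-FFT circular convolution.

    Both the field and the kernel live with the origin at the grid center,
    so each is de-centered with ``ifftshift`` around the transforms.  By
    default the kernel's spectrum is evaluated in closed form
    (:func:`kernel_spectrum`), which is unit-modulus at every frequency:
    propagation is then exactly unitary — power is conserved, and a
    ``+d`` / ``-d`` round trip is an identity to machine precision.  With
    ``exact_spectrum=False`` the sampled kernel is transformed numerically
    (the literal three-transform convolution, reproducible by a direct
    double sum) and the output is rescaled to conserve total power.
    """
    if field.values.shape != kernel.values.shape:
        raise ValueError(
            f"field shape {field.values.shape} and kernel shape "
            f"{kernel.values.shape} do not match"
        )
    F = np.fft.fft2(np.fft.ifftshift(field.values))
    K = kernel_spectrum(kernel, exact=exact_spectrum)
    out = np.fft.fftshift(np.fft.ifft2(F * K))
    if not exact_spectrum:
        p_in = np.sum(np.abs(field.values) ** 2)
        p_out = np.sum(np.abs(out) ** 2)
        if p_out > 0:
            out *= np.sqrt(p_in / p_out)
    return ComplexField(values=out, grid=field.grid, plane_label=field.plane_label)


def point_source_illumination(
    grid: SimulationGrid, d1: float, paraxial: bool = False
) -> ComplexField:
    """Unit-amplitude diverging wave at the sample plane.

    A pinhole a distance ``d1`` upstream illuminates the sample with a
    spherical wavefront; far sources (``d1`` much larger than the grid
    extent squared over the wavelength) reduce to a quasi-plane wave.  The
    exact spherical phase is used by default; ``paraxial=True`` selects the
    quadratic approximation ``Q(1/d1)``.
    """
    if d1 <= 0:
        raise ValueError(f"source distance d1 must be positive, got {d1!r}")
    if paraxial:
        k = quadratic_phase(grid, 1.0 / d1)
    else:
        k = spherical_kernel(grid, d1)
    return ComplexField(values=k.values.copy(), grid=grid, plane_label="sample")


def embed_in_center(grid: SimulationGrid, values: np.ndarray) -> np.ndarray:
    """Place a sensor-sized array in the central block of a zero full-space array.

    Full-space input is passed through unchanged.
    """
    values = np.asarray(values)
    if values.shape == grid.shape:
        return values
    if values.shape != grid.sensor_shape:
        raise ValueError(
            f"array shape {values.shape} matches neither the sensor "
            f"{grid.sensor_shape} nor the computational space {grid.shape}"
        )
    full = np.zeros(grid.shape, dtype=values.dtype)
    full[grid.central_block] = values
    return full


def crop_center(grid: SimulationGrid, values: np.ndarray) -> np.ndarray:
    """Extract the sensor-sized central block of a full-space array."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"expected full-space shape {grid.shape}, got {values.shape}")
    return values[grid.central_block]


def apply_phase_object(field: ComplexField, phase) -> ComplexField:
    """Modulate a field by a transparent sample: ``output = field * exp(-j phi)``.

    ``phase`` is a phase map in radians, either sensor-sized (zero outside
    the central block) or covering the full computational space.  The
    modulus is unchanged everywhere (pure phase object).
    """
    values = getattr(phase, "values", phase)
    phi = embed_in_center(field.grid, np.asarray(values, dtype=float))
    return ComplexField(values=field.values * np.exp(-1j * phi),
                        grid=field.grid, plane_label=field.plane_label)


def sensor_intensity(
    field_at_sample: ComplexField, d2: float, kind: str = "spherical"
) -> np.ndarray:
    """Propagate a sample-plane field to the sensor and record its intensity.

    The field is propagated a distance ``d2``, the squared modulus taken,
    the sensor-sized central block cropped out and the peak normalized to 1.
    Returns an ``n1 x n2`` non-negative array, the simulated camera frame.
    """
    if d2 <= 0:
        raise ValueError(f"sensor distance d2 must be positive, got {d2!r}")
    grid = field_at_sample.grid
    if kind == "spherical":
        k = spherical_kernel(grid, d2)
    elif kind == "quadratic":
        k = quadratic_phase(grid, 1.0 / d2)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    at_sensor = propagate(field_at_sample, k)
    intensity = crop_center(grid, at_sensor.intensity)
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return intensity


def simulate_intensity(
    grid: SimulationGrid,
    phase,
    d1: float,
    d2: float,
    kind: str = "spherical",
    paraxial_illumination: bool = False,
) -> np.ndarray:
    """Full forward model: point source -> phase sample -> sensor intensity.

    Convenience composition of :func:`point_source_illumination`,
    :func:`apply_phase_object` and :func:`sensor_intensity`.
    """
    illum = point_source_illumination(grid, d1, paraxial=paraxial_illumination)
    after = apply_phase_object(illum, phase)
    return sensor_intensity(after, d2, kind=kind)


__all__.append("simulate_intensity")
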