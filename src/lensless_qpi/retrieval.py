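"""Iterative phase retrieval from a single lensless intensity frame.

The solver is the two-plane Gerchberg-Saxton scheme: the measured sensor
amplitude (square root of the normalized intensity, zero-padded into the
doubled computational space) is propagated back to the sample plane with the
conjugate spherical kernel, the amplitude there replaced by the assumed unit
function while the phase is carried, the field propagated forward again, the
sensor amplitude re-imposed, and so on.  Alternating the two amplitude
constraints drives the carried phases toward consistency with both planes.

Multi-plane (3-D) imaging is handled by running the same retrieval at a set
of candidate distances and scoring the sharpness of each reconstruction;
each axial plane of a thick object comes into focus at its own distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analysis import phase_correlation
from .grid_optics import (
    ComplexField,
    SimulationGrid,
    crop_center,
    propagate,
    quadratic_phase,
    spherical_kernel,
)
from .phantoms import PhaseMap

__all__ = [
    "RetrievalConfig",
    "RetrievalResult",
    "FocusScan",
    "prepare_sensor_amplitude",
    "gsa_retrieve",
    "refocus_scan",
    "focus_score",
    "effective_distance",
]


@dataclass(frozen=True)
class RetrievalConfig:
    """Settings of a single retrieval run.

    ``distance`` is the sensor-sample propagation distance in meters (use
    the curvature-corrected effective distance when the illumination is a
    nearby point source, see :func:`effective_distance`).  The initial
    sensor-plane phase is uniform zero by default — the faster-converging
    choice — with a seeded-random alternative for robustness studies.  The
    loop stops at ``max_iterations`` or when the monitored convergence
    score changes by less than ``stop_tolerance`` (relative) across
    ``stop_window`` iterations; set ``stop_tolerance=0`` to always run the
    full iteration budget.
    """

    distance: float
    max_iterations: int = 100
    initial_phase: str = "uniform"
    seed: int = 0
    stop_tolerance: float = 1e-3
    stop_window: int = 5
    kernel: str = "spherical"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError(f"distance must be positive, got {self.distance!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stop_tolerance < 0:
            raise ValueError("stop_tolerance must be >= 0")
        if self.initial_phase not in ("uniform", "random"):
            raise ValueError("initial_phase must be 'uniform' or 'random'")
        if self.kernel not in ("spherical", "quadratic"):
            raise ValueError("kernel must be 'spherical' or 'quadratic'")


@dataclass
class RetrievalResult:
    """Outcome of a retrieval run.

    ``phase`` is the sample-phase estimate over the sensor-sized central
    block, in the same sign convention as the forward model (thicker
    regions more positive).  ``sensor_error_history`` holds the
    scale-optimal RMS mismatch between the propagated and measured sensor
    amplitudes per iteration; ``correlation_history`` the normalized
    phase-only correlation against the reference phase when one was
    supplied (empty otherwise).  ``refocus_amplitude`` is the modulus of
    the first back-propagation of the measured sensor amplitude — the
    holographic refocus image used for sharpness-based best-focus
    selection.  ``iterates`` optionally keeps every iteration's phase
    estimate (the reconstruction can transiently improve before amplitude
    constraints redistribute twin-image energy, so inspecting intermediate
    iterates is part of normal practice with this method).
    """

    phase: PhaseMap
    correlation_history: np.ndarray
    sensor_error_history: np.ndarray
    iterations_run: int
    converged: bool
    distance: float
    refocus_amplitude: np.ndarray | None = None
    iterates: list[np.ndarray] | None = None


@dataclass
class FocusScan:
    """Per-distance retrievals and sharpness scores from :func:`refocus_scan`."""

    distances: np.ndarray
    results: list[RetrievalResult]
    scores: np.ndarray  # shape (n_distances,) or (n_distances, n_rois)

    def best_distance(self, roi_index: int | None = None) -> float:
        s = self.scores if self.scores.ndim == 1 else self.scores[:, roi_index or 0]
        return float(self.distances[int(np.argmax(s))])


def prepare_sensor_amplitude(intensity: np.ndarray,
                             grid: SimulationGrid) -> ComplexField:
    """Zero-padded sensor amplitude from a recorded intensity frame.

    The sensor-sized intensity is normalized to peak 1, square-rooted, and
    placed in the central block of an otherwise zero full-space array.
    Invariant under positive rescaling of the input.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != grid.sensor_shape:
        raise ValueError(
            f"intensity shape {intensity.shape} does not match the sensor "
            f"{grid.sensor_shape}"
        )
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    peak = intensity.max()
    if peak == 0:
        raise ValueError("intensity is identically zero; nothing to retrieve")
    a = np.zeros(grid.shape, dtype=float)
    a[grid.central_block] = np.sqrt(intensity / peak)
    return ComplexField(values=a, grid=grid, plane_label="sensor")


def _scale_optimal_rms(amplitude: np.ndarray, target: np.ndarray) -> float:
    """Relative RMS of ``alpha*amplitude - target`` minimized over alpha.

    The forward model carries an arbitrary complex constant, so amplitudes
    are compared up to a global scale.
    """
    denom = np.sum(amplitude**2)
    alpha = np.sum(amplitude * target) / denom if denom > 0 else 0.0
    return float(np.linalg.norm(alpha * amplitude - target)
                 / np.linalg.norm(target))


def gsa_retrieve(
    amplitude_sensor: ComplexField,
    config: RetrievalConfig,
    grid: SimulationGrid | None = None,
    reference_phase: PhaseMap | np.ndarray | None = None,
    keep_iterates: bool = False,
) -> RetrievalResult:
    """Run the alternating-amplitude phase retrieval loop.

    Starting from the prepared sensor amplitude and a uniform (or seeded
    random) initial phase, each iteration back-propagates to the sample
    plane, replaces the amplitude by the assumed unit function keeping the
    phase, forward-propagates, and re-imposes the measured amplitude.  The
    scale-optimal sensor-amplitude RMS error is recorded each iteration;
    when a reference phase is given, so is the normalized phase-only
    correlation of the current reconstruction against it.

    Non-convergent runs never raise: the loop returns the final iterate
    with ``converged=False`` when the iteration budget is exhausted before
    the stopping rule fires.
    """
    grid = grid if grid is not None else amplitude_sensor.grid
    a1 = np.abs(amplitude_sensor.values)
    if config.kernel == "spherical":
        forward = spherical_kernel(grid, config.distance)
        backward = spherical_kernel(grid, -config.distance)
    else:
        forward = quadratic_phase(grid, 1.0 / config.distance)
        backward = quadratic_phase(grid, -1.0 / config.distance)

    if config.initial_phase == "uniform":
        p1 = np.zeros(grid.shape)
    else:
        rng = np.random.default_rng(config.seed)
        p1 = rng.uniform(0.0, 2.0 * np.pi, grid.shape)

    ref = None
    if reference_phase is not None:
        ref = np.asarray(getattr(reference_phase, "values", reference_phase),
                         dtype=float)

    c1 = ComplexField(values=a1 * np.exp(1j * p1), grid=grid,
                      plane_label="sensor")
    errors: list[float] = []
    correlations: list[float] = []
    iterates: list[np.ndarray] = []
    p2 = np.zeros(grid.shape)
    refocus_amplitude: np.ndarray | None = None
    converged = False

    for iteration in range(config.max_iterations):
        c2 = propagate(c1, backward)
        p2 = np.angle(c2.values)
        if iteration == 0:
            refocus_amplitude = crop_center(grid, np.abs(c2.values))
        c2 = ComplexField(values=np.exp(1j * p2), grid=grid,
                          plane_label="sample")
        c1_prop = propagate(c2, forward)
        errors.append(_scale_optimal_rms(np.abs(c1_prop.values), a1))
        if ref is not None:
            est = crop_center(grid, -p2) if ref.shape == grid.sensor_shape else -p2
            correlations.append(phase_correlation(ref, est).normalized_score)
        if keep_iterates:
            iterates.append(crop_center(grid, -p2))
        c1 = ComplexField(values=a1 * np.exp(1j * np.angle(c1_prop.values)),
                          grid=grid, plane_label="sensor")

        monitor = correlations if ref is not None else errors
        w = config.stop_window
        if config.stop_tolerance > 0 and len(monitor) > w:
            prev, last = monitor[-1 - w], monitor[-1]
            if abs(last - prev) < config.stop_tolerance * max(abs(prev), 1e-30):
                converged = True
                break

    # the forward model modulates by exp(-j*phi_s), so the carried sample
    # phase is the negative of the sample phase estimate
    phase = PhaseMap(crop_center(grid, -p2), pixel=grid.pixel,
                     wavelength=grid.wavelength)
    return RetrievalResult(
        phase=phase,
        correlation_history=np.asarray(correlations),
        sensor_error_history=np.asarray(errors),
        iterations_run=len(errors),
        converged=converged,
        distance=config.distance,
        refocus_amplitude=refocus_amplitude,
        iterates=iterates if keep_iterates else None,
    )


def focus_score(image: np.ndarray, roi: tuple[slice, slice] | None = None
                ) -> float:
    """Sharpness of a refocused image: Tamura coefficient of its gradient.

    Computes ``std/mean`` of the gradient-magnitude image.  An in-focus
    reconstruction of a step-like object concentrates its gradients in
    sparse tall edges (high Tamura coefficient); defocus spreads them into
    a dense low-contrast carpet.  Being scale-invariant, the score can be
    compared across reconstruction distances even though the effective
    resolution and noise floor of the reconstruction vary with distance.
    ``roi`` restricts the metric to a sub-region (useful when laterally
    separated objects focus at different depths).
    """
    values = np.asarray(getattr(image, "values", image), dtype=float)
    if roi is not None:
        values = values[roi]
    gy, gx = np.gradient(values)
    gm = np.hypot(gy, gx)
    mean = gm.mean()
    if mean == 0:
        return 0.0
    return float(np.std(gm) / mean)


def refocus_scan(
    amplitude_sensor: ComplexField,
    config: RetrievalConfig,
    distances,
    grid: SimulationGrid | None = None,
    rois: list[tuple[slice, slice]] | None = None,
    reference_phase=None,
) -> FocusScan:
    """Retrieve at each candidate distance and score reconstruction sharpness.

    Runs :func:`gsa_retrieve` independently per distance (the ``config``
    supplies every other setting) and evaluates :func:`focus_score` on each
    run's holographic refocus amplitude (the first back-propagation of the
    measured sensor amplitude) — over the full sensor block, or per entry
    of ``rois``.  For a thick object the score peaks at the distances of
    its planes, enabling best-focus selection plane by plane; for a single
    plane under spherical illumination it peaks at the curvature-corrected
    effective distance rather than the physical one.
    """
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        raise ValueError("refocus_scan needs at least one distance")
    if np.any(distances <= 0):
        raise ValueError("all scan distances must be positive")
    results = []
    scores = []
    for d in distances:
        res = gsa_retrieve(amplitude_sensor, replace(config, distance=float(d)),
                           grid=grid, reference_phase=reference_phase)
        results.append(res)
        if rois is None:
            scores.append(focus_score(res.refocus_amplitude))
        else:
            scores.append([focus_score(res.refocus_amplitude, roi)
                           for roi in rois])
    return FocusScan(distances=distances, results=results,
                     scores=np.asarray(scores))


def effective_distance(d1: float, d2: float) -> float:
    """Curvature-corrected reconstruction distance ``(1/d2 - 1/d1)^-1``.

    With a point source at finite ``d1`` the illumination reaching the
    sample is spherical; the best backward-propagation distance absorbs
    that curvature.  For ``d1 = 200 cm`` and ``d2 = 20 cm`` the corrected
    distance is 22.2 cm; as ``d1 -> inf`` it reduces to ``d2``.
    """
    if d2 <= 0:
        raise ValueError(f"d2 must be positive, got {d2!r}")
    if np.isinf(d1):
        return d2
    if d1 <= d2:
        raise ValueError(
            f"geometry requires d1 > d2 > 0, got d1={d1!r}, d2={d2!r}"
        )
    return 1.0 / (1.0 / d2 - 1.0 / d1)
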