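# Methods

## Optical model and discretization

The instrument being modeled is the simplest lensless QPI bench: an LED
(treated as monochromatic at its center wavelength λ) behind a pinhole, a
transparent sample a distance d₁ downstream, and a bare image sensor a
further d₂ away.  The sample is a pure phase object: transmission
`exp(−jΦs)` with `Φs = 2πt(n−1)/λ`, thickness t and index n assumed
separable only if one of them is known.

All fields are sampled on a computational space of 2N₁ × 2N₂ points at the
sensor pixel pitch Δ, with the origin at the central sample — double the
sensor in each dimension, so the circular convolutions have a guard
margin.  Free-space propagation is a three-FFT convolution with a sampled
kernel object:

* spherical kernel `S[R(d)] = exp(j·sign(d)·2πR(|d|)/λ)`,
  `R = (x²+y²+d²)^½` — exact phase, used by default;
* quadratic (Fresnel) kernel `Q(b) = exp(jπb(x²+y²)/λ)`, `b = 1/d` — the
  paraxial limit, available everywhere a kernel kind can be chosen.

**Spectrum evaluation.** The kernel's spectrum is evaluated in closed form
(`kernel_spectrum`): the angular-spectrum transfer function
`exp(j·2π|d|·(1/λ² − f²)^½)` for the spherical kind, the Fresnel transfer
function `exp(−jπλd·f²)` for the quadratic kind.  Both are unit-modulus at
every sampled frequency (the pixel pitch is far above λ/2, so no
evanescent components are ever sampled), which makes propagation exactly
unitary: power is conserved, a +d/−d round trip is an identity to machine
precision, and the alternating-amplitude retrieval below enjoys the
classical error-reduction guarantee.  The literal numerical alternative —
FFT of the truncated sampled chirp — is kept as
`propagate(..., exact_spectrum=False)` and is verified against a direct
double-sum convolution in the tests; it is not the default because the
truncated chirp's spectrum has strongly non-unit modulus and uncontrolled
phase outside its stationary band, which measurably de-stabilizes the
retrieval loop and corrupts multi-distance refocusing.

## Phase retrieval

Retrieval is the two-plane Gerchberg–Saxton scheme.  The measured
N₁ × N₂ intensity is peak-normalized, square-rooted, and zero-padded into
the central block of the computational space (A₁); the initial sensor
phase is uniform zero (a seeded-random start is available; the uniform
start converges faster and makes runs bit-reproducible).  Each iteration
back-propagates with the conjugate kernel, replaces the sample-plane
amplitude with the assumed unit function A₂ = 1 while carrying the phase,
propagates forward, and re-imposes A₁.  The monitored error is the
scale-optimal relative RMS between propagated and measured sensor
amplitudes (the forward model carries an arbitrary constant, so amplitudes
are compared up to a fitted global scale).  The loop stops after
`max_iterations` (default 100) or when the monitored score changes by less
than `stop_tolerance` (default 10⁻³, relative) across a 5-iteration
window.  The returned phase is −P₂ cropped to the sensor block: the
forward model modulates by `exp(−jΦs)`, so negating the carried phase
gives the estimate in the sample's own sign convention.

Because a single intensity frame constrains the field only up to
twin-image mixing, the iterates can transiently pass closer to the true
object than the fixed point they settle at; `keep_iterates=True` retains
every iteration's phase for exactly this inspection, and the per-iteration
phase-only correlation against a reference (when one exists, i.e. in
simulation) is always recorded.

**Known accuracy limitation.**  The retrieval reproduces object
*structure* reliably but absolute step heights of binary phase objects
carry a twin-image bias that depends on the step: across the simulated
range π/4…π the recovered step differs from truth by anywhere from a few
percent to tens of percent, and a π step is intrinsically ambiguous (the
object field `exp(−jπm) = 1−2m` is real, so the field and its conjugate
yield the same hologram; spherical illumination cannot break this — by the
Fresnel scaling theorem it is equivalent to plane illumination at the
corrected distance).  This matches the behavior of the physical bench,
where a 1.5π fabricated step is recovered as ≈π.  Quantitative
thickness mapping from one frame should therefore be treated as
semi-quantitative for strong phase steps; the package states this rather
than papering over it.

## Refocusing and best-focus selection

Thick objects are handled plane by plane: the same frame is retrieved at a
set of candidate distances (`refocus_scan`) and a focus score ranks them.
The score is the Tamura coefficient (standard deviation over mean — a
scale-invariant sharpness statistic) of the gradient magnitude of the
*first back-propagation amplitude*, i.e. the classic holographic refocus
image.  An in-focus step object concentrates its amplitude gradients in
sparse edge lines (high Tamura), a defocused one spreads them into a dense
carpet; scale invariance matters because the reconstruction's resolution
and noise floor vary strongly with distance, which defeats plain variance
metrics (including variance of the retrieved phase gradient, which was
evaluated and rejected).  Per-region scores (`rois`) let laterally
separated objects at different depths be focused independently.  Under
spherical illumination the score peaks at the curvature-corrected
effective distance `d₂′ = (1/d₂ − 1/d₁)⁻¹` rather than the physical d₂,
which is also how that correction is validated in the tests.

## Analysis metrics

* **Phase-only correlation** (`phase_correlation`): cross-correlation of
  reference and test maps (as real images) with the test spectrum
  normalized to unit modulus (floor 10⁻¹²), reported as |·|² at zero lag
  and normalized by the reference autocorrelation under the same filter,
  so self-correlation is exactly 1.  It is a sharp matched detector: good
  for tracking convergence trends, but even visually faithful
  reconstructions score ≪ 1.  `phase_similarity` (zero-mean normalized
  cross-correlation) is the interpretable structural companion.
* **Unwrapping** (`unwrap_phase`): the reference path is the separable
  scheme — unwrap the first column, then every row anchored to it — exact
  on residue-free maps; a quality-guided 2-D method is available behind
  `method="quality"` for noisy data.  Output minus input is a multiple of
  2π at every pixel in both modes.
* **Geometry**: `M = 1 + d₂/d₁`, `NA = D/2(d₁+d₂)`, thickness↔phase
  conversion, and `effective_distance`.

## Synthetic objects

The phantom module regenerates every object class the simulations use, so
nothing external is required: procedurally drawn binary masks (disc, ring,
five-pointed star, animal-like silhouette, bar group — stand-ins of
similar feature scale for lithographic test artwork), binary phase maps
from mask + material (t, n, λ), a linear ramp to a configurable maximum
(8π by default usage) in a zero-phase surround, a two-plane thick object,
and a phase-only scattering layer designed by a Fourier-plane GS
synthesis: starting from seeded random phase, alternate a uniform
amplitude target on a centered Fourier disc covering fraction σ of the
samples with a unit-amplitude constraint in the layer plane.  σ is defined
as that Fourier support fraction; the generated σ = 0.12 layer puts ≈95%
of its far-field power inside the support after 50 iterations.  All
randomness is seeded; all generators are deterministic.

What the synthetic data does *not* emulate: sensor noise (shot/read),
finite LED spectral width (33 nm FWHM in the physical bench, a known
source of phase-contrast loss), finite pinhole size, pixel cross-talk, and
glass-substrate thickness.  Passing tests therefore demonstrate the
correctness of the computational pipeline under ideal sampling, not the
noise robustness of the bench.

## Default study conditions and problem sizes

Simulation studies default to λ = 530 nm and pixel pitch 4.65 µm (the
physical camera), with d₁ = 200 cm, d₂ = 20 cm for geometry calculations
and quasi-plane illumination (d₁ = 100 m) where a plane-like wavefront is
the stated condition.  Test fixtures use 256² sensors for single-plane
studies and 512² where the physics requires the larger aperture: the
two-plane study (Δd = 20 cm, planes 15/35 cm from the sensor — a 256²
aperture cannot resolve an object 40 cm away) and the 8π ramp (the ramp
block is 25% of the sensor side because the ramp deflects its beam
laterally by ~150 px, which must stay on the sensor).  Retrieval iteration
counts follow the study being reproduced: 2 (experiment-like), 10–20
(thick objects, ramps), 50–100 (convergence studies).

## Numerical choices

* Lengths in meters internally; file and CLI interfaces take explicit unit
  suffixes (m, cm, mm, um, nm).
* 0-based, half-open indexing; the 1-based central-block slice of the
  pseudo-code maps to `[N/2, 3N/2)`.
* Phase maps stored in radians, float64 in memory, float32 on disk
  (32-bit float TIFF); intensity frames 16-bit grayscale.
* Degenerate inputs fail loudly (all-zero frame, σ outside [0,1],
  non-binary masks, RGB images) with remediation hints where useful;
  non-convergent retrievals return the final iterate flagged
  `converged=False` rather than raising.
* Peak normalization of simulated frames fixes the arbitrary model
  constant; the retrieval is invariant to any positive rescaling of its
  input frame.
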