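# Methods

## Forward model and conventions

A thin sample is a complex transmittance t(r); its spectrum is
S = FT(t). A tilted plane wave with direction sines s (|s| = sin θ)
shifts the spectrum by k_i = s/λ; the objective multiplies by the coherent
transfer function (CTF) — unit amplitude on the disk λ|k| ≤ NA, phase
φ_ab(k) — and the camera records

    I(r) = gain · | IFT[ S(k − k_i) · P(k) e^{iφ_ab(k)} ] |² + noise.

All arrays are `[row, col]` = `[y, x]`; real-space and frequency origins
sit at the center pixel `n // 2`; `ft`/`ift` wrap numpy FFTs with the
fftshift bookkeeping (`apic._fft`). Illumination shifts that land on
integer frequency bins are applied as exact spectrum rolls; sub-pixel
shifts use a real-space linear phase ramp (exact for the tilt itself;
the later rasterization of shifted CTF masks to nearest bins is the
documented approximation for off-grid LEDs).

Simulation runs on a fine grid (default 4× the camera tile) whose
frequency step equals the camera's; the camera band is the central block
of the fine spectrum. This keeps the shifted spectra of the outermost
darkfield angles alias-free.

Defaults that set the study conditions: objective NA 0.25 (10×),
wavelength 0.52 µm (green LED; chosen as a typical LED-array value),
8 NA-matching LEDs, darkfield rings out to illumination sine 2·NA so the
synthetic NA is 0.75. The defocus phase is the exact angular-spectrum
form φ(k) = (2πz/λ)(√(1 − (λ|k|)²) − 1) — not the paraxial quadratic —
because only the exact form reproduces the printed magnitudes of a 32 µm
defocus at NA 0.25 (peak-to-valley 3.91π, disk standard deviation 1.13π)
at λ = 0.52 µm.

## Illumination design

The NA-matching condition is what makes the closed form exact: the
shifted spectrum must touch DC from one side. The ring designer therefore
places NA-matching LEDs on integer lattice points of the circle of radius
NA/(λ·Δk) bins whenever such points exist — then the one-sidedness holds
to machine precision for every ring LED. One subtlety is deliberate: if
all selected points share a common integer factor (circles of radius 50
or 60 bins only carry scaled Pythagorean points), all pairwise shift
differences live on a sublattice and the aberration solver's difference
equations decouple into cosets with weakly-determined relative pistons.
The designer then substitutes one LED with a coprime lattice point,
accepting a radius deficit below one frequency step (still inside the
two-step NA-matching tolerance, and inward, so the unscattered beam stays
inside the CTF). Darkfield LEDs are rounded to the nearest bin.

## Kramers–Kronig recovery

For a nonvanishing detected field the demodulated field
ψ = E·e^{−i2πk_i·r} has a one-sided spectrum and log ψ inherits it, so

    ψ = √I · exp(i · H_d[½ log I]),   H_d: multiplier +i·sgn(k·d̂),
    d̂ = k_i/|k_i|,  sgn(0) = 0,

with one free global phase per measurement. Because ψ is already
demodulated, FT(ψ) sits directly in sample-spectrum coordinates:
patch(u) = S(u)·e^{iφ_ab(u + k_i)} on the CTF disk translated by −k_i.
Intensities are floored at 1e−6·max(I) before the log (field zeros
violate the assumptions and are reported as a warning). Exactness on a
finite grid additionally requires the log-field spectrum to decay before
the grid edge; the error scales with the object's scattering strength
(the n-th log-field harmonic carries the n-th power of the contrast), so
weak/band-limited phantoms recover to ~1e−8 while a binary Siemens star
recovers to ~1e−3 — still far below what the aberration and darkfield
stages need. Measurements whose sine is more than two frequency steps
from NA are refused (interior angles have no analytic closed form).

## Aberration retrieval

On the overlap of patches i and j the sample phase cancels:

    Δ_ij(u) = φ_ab(u + k_i) − φ_ab(u + k_j) + (c_i − c_j)   (mod 2π).

Weights are the minimum of the two normalized patch amplitudes, zeroed
below a 1e−3 noise floor; pairs with less than 5% disk overlap are
dropped. Large aberrations wrap Δ, and per-region 2-D unwrapping leaves
one free 2π branch per pair whose cycle sums the per-patch constants
cannot absorb. The solver therefore never unwraps:

1. **Gradient bootstrap** — wrapped first differences of Δ along both
   frequency axes; the constants cancel exactly, and local differences
   stay inside one wrap for any aberration sampled below π per bin.
   Solved by exact sparse normal equations with a Tikhonov damp (1e−4,
   weights median-normalized) plus a weak first-difference smoothness
   penalty (1e−2) between adjacent covered pupil nodes — the smoothing
   also ties together any remaining sublattice cosets.
2. **Gauss–Newton refinement** on the absolute wrapped constraints
   (branch-safe once the model is within ~π); the node-block normal
   matrix is factorized once and the eight dense constant columns are
   eliminated by a Schur complement, so each iteration costs two
   triangular solves. Constraints disagreeing by > 1 rad are zeroed.
3. **2π de-spiking** — wrapped constraints cannot see a 2π offset of a
   node, so small branch-locked clusters can survive; nodes sitting a
   near-multiple of 2π from their 5/9/15-pixel neighborhood median are
   snapped back, followed by two more refinement steps.

Per-patch constants come from weighted circular means given the solved
phase (spanning-tree walk plus one linear refinement). Piston, tip and
tilt — a global phase and a rigid image shift, unobservable from
intensity — are zeroed on the disk and absorbed into the constants; the
same gauge shift later cancels exactly between the stitched spectrum's
linear phase ramp and the re-applied aberration, so the darkfield stage
is gauge-consistent. Pupil nodes never covered by any overlap are filled
by a 21-mode Zernike fit of the covered region. Zernike bases are
discretely re-orthonormalized on the rasterized disk (Cholesky of the
Gram matrix), so one unit coefficient means exactly unit RMS.

Measured recovery (8 NA-matching views of a Siemens star, 200² camera,
50-bin pupil): Noll 4–11 at 1 rad total RMS → 0.010 rad RMSE; 32 µm
defocus (PV 3.9π) → 0.026 rad RMSE and PV within 0.3%; at 40 dB
intensity SNR → 0.032 rad.

## Stitching

Corrected patches (`values · e^{−i(φ̂(u+k_i) + ĉ_i)}`, guarded against
double correction) are combined node-wise by amplitude-weighted mean —
averaging recovery noise rather than last-write-wins — and the global
phase is anchored so the stitched DC is real-positive. With the full
ring the known support reaches 2·NA/λ, the two-fold synthetic aperture.

## Darkfield extension

N²·FT(I) of a darkfield image equals the autocorrelation of the sampled
spectrum G = K + U (K: prior values on the shifted CTF disk with the
retrieved aberration re-applied; U: the rest of the disk). Per
measurement, processed in order of overlap with the known support:

- a scalar gain is calibrated on lags where K⋆K is the only contributor
  (LED brightnesses vary; simulator default 1 calibrates to 1);
- R = FT(I)·N²/gain − K⋆K is formed; exclusive lags are those in
  supp(K⋆U) but outside supp(U⋆U), supp(U⋆K) and supp(K⋆K) (all by
  morphological mask correlation; the K⋆K exclusion guards against
  prior/gain error and makes the returned region slightly smaller than
  the purely geometric K⋆U-separable set), minus lags whose operator row
  norm is below 1e−3 of the maximum;
- the linear system (K⋆U)(q) = Σ_u conj(K(u−q))·U(u) is solved with a
  Tikhonov damp of 1e−2 × the largest row norm — the center of a broad
  stability plateau (1e−3…3e−2) found by a conditioning sweep; below it,
  small errors in the stitched prior's low-amplitude rim amplify through
  the inverse. Dense solve when the matrix fits 4e6 entries, otherwise
  LSMR with FFT-based (zero-padded, non-circular) correlations on the
  disk's bounding box;
- unknown nodes whose operator columns receive no signal from the
  exclusive region (the far tip of the crescent) are left unsolved
  rather than filled with minimum-norm values; the measurement is
  re-queued once after the prior has grown. Deferred/unprocessed
  measurements are always reported, never dropped.

All correlations and supports are computed on the bounding box of each
shifted CTF disk, so per-measurement cost is independent of the output
grid size. With thin unknown crescents (dense rings) the sequential
closed-form extension is exact to machine precision; the default
acceptance geometry (72 darkfield LEDs in four rings out to sine 0.5,
echoing the high-redundancy acquisition used for the full synthetic-NA
experiments at desk scale) reconstructs a 256² Siemens-star tile to
complex correlation 0.9999 with the band-limited truth, and 0.9998 with
a hidden 32 µm defocus.

## Tiling

Large fields of view are split into overlapping tiles; each tile's
illumination sines are recomputed from the 3-D LED positions and its
center (plane-wave illumination is a per-tile approximation). Tiles are
independent, deterministic work units; per-tile global phases (a gauge
of the closed-form recovery) are aligned on the overlap bands before
linear feather blending; tile failures leave a masked hole and are
recorded. Per-tile sub-pixel translation gauge is not re-estimated — a
known limitation for very aberrated tiles.

## What the simulator does and does not emulate

Emulated: plane-wave tilts at arbitrary angles, circular CTF with
arbitrary Zernike/defocus phase, intensity detection, camera-band
downsampling, Poisson shot noise, Gaussian read noise, per-LED gains.
Not emulated: partial coherence, finite LED extent, LED-position
calibration error, multiple scattering, polarization, sensor nonlinearity.
Passing tests therefore validate the reconstruction mathematics and its
noise behavior, not robustness to the systematic errors of a physical
bench (the method is known to need good angle calibration).

## Problem sizes used by tests and the acceptance script

Closed-form defocus magnitudes on a 1024² grid (dense disk); KK
exactness on a 256² camera with a 60-bin pupil radius; aberration
recovery on a 200² camera with a 50-bin pupil; darkfield oracle
equivalence on a 24² camera (5-bin pupil) against an explicitly
enumerated dense least squares; end-to-end runs on one 256² tile with
4× upsampling (1024² reconstruction grid). These sizes make the whole
suite run in minutes on one CPU while keeping every stage in the regime
its contracts describe; the library itself is size-agnostic.
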