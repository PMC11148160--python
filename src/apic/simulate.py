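"""Coherent LED-array imaging simulator and phantom generator.

Forward model
-------------
A thin sample with complex transmittance t(r) is illuminated by a tilted plane
wave with direction sines s = (sx, sy), |s| = sin(theta).  The tilt shifts the
sample spectrum S = FT(t) by k_i = s / wavelength; the objective passes the
shifted spectrum through its coherent transfer function (CTF) — a disk of
radius NA/wavelength with unit amplitude and an aberration phase map — and the
camera records the intensity of the resulting field:

    I(r) = gain * | IFT[ S(k - k_i) * P(k) * exp(i phi_ab(k)) ] |^2  + noise.

Illumination classes follow the acquisition design of NA-matching microscopy:
LEDs on the ring |s| = NA ("NA-matching") place the unscattered beam exactly
on the CTF cutoff, which is the condition enabling closed-form Kramers-Kronig
field recovery; LEDs with |s| > NA give darkfield measurements used for
spectrum extension; interior LEDs are ordinary brightfield.

Grid conventions (used package-wide): arrays are ``[row, col]`` = ``[y, x]``;
real and frequency origins sit at the center pixel ``n // 2``; transforms go
through :mod:`apic._fft`.  Sub-pixel illumination shifts are realized exactly
by a real-space linear phase ramp on the sample field; integer-bin shifts use
an equivalent (and faster) spectrum roll.  The ring designer prefers integer
lattice points that lie *exactly* on the pupil-radius circle so that the
Kramers-Kronig one-sidedness condition holds to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from ._fft import center_index, crop_center, ft, ift
from .zernike import ZernikeBasis, noll_to_nm

__all__ = [
    "FrequencyGrid", "ComplexSample", "Pupil", "IlluminationGeometry",
    "MeasurementStack", "NoiseModel", "BRIGHTFIELD", "NA_MATCHING", "DARKFIELD",
    "make_siemens_star", "make_smooth_phantom",
    "defocus_phase_map", "defocus_pupil_phase",
    "zernike_phase", "simulate_measurement", "simulate_dataset",
    "design_ring_geometry", "write_dataset", "read_dataset",
]

BRIGHTFIELD = "brightfield"
NA_MATCHING = "na_matching"
DARKFIELD = "darkfield"

_EPS = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyGrid:
    """Square sampling grid linking the sample plane and frequency space.

    Parameters
    ----------
    shape : int
        Grid size in pixels (square).
    pixel_size : float
        Sample-plane pixel pitch in micrometres.
    wavelength : float
        Illumination wavelength in micrometres.
    """

    shape: int
    pixel_size: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("shape, pixel_size and wavelength must be positive")

    @classmethod
    def for_pupil_radius(cls, shape: int, na: float, wavelength: float,
                         radius_bins: int) -> "FrequencyGrid":
        """Grid whose pupil cutoff NA/wavelength falls at an integer bin radius."""
        pixel_size = radius_bins * wavelength / (shape * na)
        return cls(shape, pixel_size, wavelength)

    @property
    def dk(self) -> float:
        """Frequency step 1/(shape * pixel_size), in inverse micrometres."""
        return 1.0 / (self.shape * self.pixel_size)

    @property
    def k(self) -> np.ndarray:
        """Centered 1-D frequency coordinates (DC at index shape//2)."""
        return (np.arange(self.shape) - center_index(self.shape)) * self.dk

    @property
    def r(self) -> np.ndarray:
        """Centered 1-D real-space coordinates in micrometres."""
        return (np.arange(self.shape) - center_index(self.shape)) * self.pixel_size

    @property
    def kxx(self) -> np.ndarray:
        return np.broadcast_to(self.k[None, :], (self.shape, self.shape))

    @property
    def kyy(self) -> np.ndarray:
        return np.broadcast_to(self.k[:, None], (self.shape, self.shape))

    @property
    def kr(self) -> np.ndarray:
        """Radial frequency magnitude |k|."""
        return np.hypot(self.kxx, self.kyy)

    def pupil_radius_bins(self, na: float) -> float:
        return na / (self.wavelength * self.dk)

    def disk_mask(self, na: float, center_k=(0.0, 0.0)) -> np.ndarray:
        """Rasterized disk ``wavelength * |k - center_k| <= na`` (inclusive)."""
        cx, cy = center_k
        rr = np.hypot(self.kxx - cx, self.kyy - cy)
        return self.wavelength * rr <= na * (1 + _EPS)


@dataclass(frozen=True)
class ComplexSample:
    """Complex transmittance map: amplitude * exp(i * phase)."""

    field: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.field)):
            raise ValueError("sample field must be finite")


@dataclass(frozen=True)
class Pupil:
    """Unit-amplitude coherent transfer function with an aberration phase.

    ``phase`` is the aberration map in radians on the full frequency grid,
    zero outside the support disk wavelength*|k| <= na.
    """

    grid: FrequencyGrid
    na: float
    phase: np.ndarray

    def __post_init__(self) -> None:
        if not 0 < self.na < 1:
            raise ValueError("na must lie in (0, 1)")
        if self.phase.shape != (self.grid.shape, self.grid.shape):
            raise ValueError("phase map shape does not match the grid")

    @classmethod
    def ideal(cls, grid: FrequencyGrid, na: float) -> "Pupil":
        return cls(grid, na, np.zeros((grid.shape, grid.shape)))

    @property
    def support(self) -> np.ndarray:
        return self.grid.disk_mask(self.na)

    @property
    def ctf(self) -> np.ndarray:
        """Complex CTF: support * exp(i * phase)."""
        return np.where(self.support, np.exp(1j * self.phase), 0.0)

    def with_added_phase(self, extra: np.ndarray) -> "Pupil":
        return replace(self, phase=np.where(self.support, self.phase + extra, 0.0))

    def unit_disk_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, theta) with rho = 1 at the pupil cutoff."""
        g = self.grid
        rho = np.clip(g.wavelength * g.kr / self.na, 0.0, 1.0)
        theta = np.arctan2(g.kyy, g.kxx)
        return rho, theta

    def zernike_basis(self, n_modes: int) -> ZernikeBasis:
        rho, theta = self.unit_disk_coords()
        return ZernikeBasis(self.support, rho, theta, n_modes)


@dataclass
class IlluminationGeometry:
    """Per-LED illumination direction sines, class labels, and gains.

    ``sines`` is (n, 2) ordered (sx, sy); the frequency shift of LED *i* is
    k_i = sines[i] / wavelength.  Labels are assigned by :meth:`classify`.
    """

    sines: np.ndarray
    labels: np.ndarray | None = None
    gains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sines = np.atleast_2d(np.asarray(self.sines, dtype=float))
        if self.sines.shape[1] != 2:
            raise ValueError("sines must be (n, 2)")
        if not np.all(np.isfinite(self.sines)):
            raise ValueError("sines must be finite")
        if self.gains is None:
            self.gains = np.ones(len(self.sines))
        self.gains = np.asarray(self.gains, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)

    def __len__(self) -> int:
        return len(self.sines)

    def k_shifts(self, wavelength: float) -> np.ndarray:
        return self.sines / wavelength

    def classify(self, na: float, tol_match: float) -> "IlluminationGeometry":
        """Label every LED as brightfield / na_matching / darkfield.

        ``tol_match`` is the half-width of the NA-matching band in direction-
        sine units (typically two frequency steps: 2 * dk * wavelength).
        """
        s = np.linalg.norm(self.sines, axis=1)
        labels = np.where(np.abs(s - na) <= tol_match, NA_MATCHING,
                          np.where(s < na, BRIGHTFIELD, DARKFIELD))
        return replace(self, labels=labels)

    def indices(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("geometry has not been classified yet")
        return np.flatnonzero(self.labels == label)

    def subset(self, idx) -> "IlluminationGeometry":
        return IlluminationGeometry(
            self.sines[idx],
            None if self.labels is None else self.labels[idx],
            self.gains[idx],
        )


@dataclass
class MeasurementStack:
    """Intensity images plus the geometry/optics metadata needed to invert them."""

    images: np.ndarray              # (n_led, N, N), nonnegative
    geometry: IlluminationGeometry
    grid: FrequencyGrid             # camera-plane grid (sample-plane units)
    na: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.geometry):
            raise ValueError("need one image per LED, all the same shape")
        if self.images.shape[1] != self.grid.shape or self.images.shape[2] != self.grid.shape:
            raise ValueError("image shape does not match the camera grid")

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise and/or additive Gaussian noise.

    photon_budget
        Expected photon count of a unit-intensity pixel; ``None`` disables
        shot noise.
    read_noise
        Std of additive Gaussian read noise, in intensity units.
    snr_db
        Alternative additive-noise spec: Gaussian with std mean(I)/10^(SNR/20).
    """

    photon_budget: float | None = None
    read_noise: float = 0.0
    snr_db: float | None = None

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = intensity
        if self.photon_budget is not None:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_budget) / self.photon_budget
        if self.snr_db is not None:
            sigma = out.mean() / 10 ** (self.snr_db / 20)
            out = out + rng.normal(0.0, sigma, out.shape)
        if self.read_noise > 0:
            out = out + rng.normal(0.0, self.read_noise, out.shape)
        return out


# ---------------------------------------------------------------------------
# phantoms and pupil phases
# ---------------------------------------------------------------------------

def make_siemens_star(n_spokes: int, shape: int, pixel_size: float,
                      amplitude_contrast: float = 0.25,
                      phase_contrast: float = 0.6,
                      radius_fraction: float = 0.9) -> ComplexSample:
    """Radial spoke (Siemens star) resolution target.

    The star has ``n_spokes`` full on/off cycles per revolution with 50% duty,
    so the local full period at radius r pixels is 2*pi*r/n_spokes pixels —
    spatial frequency increases toward the center, which is what makes the
    target a direct resolution readout.  Spokes modulate amplitude down by
    ``amplitude_contrast`` and phase up by ``phase_contrast`` (radians); the
    background transmittance is 1.  ``n_spokes = 0`` gives a uniform field.
    """
    if shape <= 0 or pixel_size <= 0:
        raise ValueError("shape and pixel_size must be positive")
    if n_spokes < 0:
        raise ValueError("n_spokes must be >= 0")
    if n_spokes == 0:
        return ComplexSample(np.ones((shape, shape), dtype=complex), pixel_size)
    c = center_index(shape)
    y, x = np.mgrid[0:shape, 0:shape]
    y = y - c
    x = x - c
    theta = np.arctan2(y, x)
    rr = np.hypot(x, y)
    spoke = (np.cos(n_spokes * theta) >= 0) & (rr <= radius_fraction * shape / 2)
    spoke = spoke.astype(float)
    fld = (1.0 - amplitude_contrast * spoke) * np.exp(1j * phase_contrast * spoke)
    return ComplexSample(fld, pixel_size)


def make_smooth_phantom(shape: int, pixel_size: float,
                        log_amplitude_rms: float = 0.08,
                        phase_rms: float = 0.3,
                        band_limit_bins: int = 16,
                        seed: int = 0) -> ComplexSample:
    """Weak, smooth, nonvanishing random phantom.

    The log-field is a band-limited Gaussian random field (support
    ``band_limit_bins`` frequency bins), so the transmittance
    ``exp(a + i phi)`` never vanishes and its log-spectrum decays fast —
    the regime in which closed-form Kramers-Kronig recovery is exact to
    numerical precision.  ``log_amplitude_rms``/``phase_rms`` set the RMS
    contrast of log-amplitude (dimensionless) and phase (radians).
    """
    if shape <= 0 or pixel_size <= 0:
        raise ValueError("shape and pixel_size must be positive")
    rng = np.random.default_rng(seed)
    c = center_index(shape)
    b = int(band_limit_bins)
    spec = np.zeros((shape, shape), dtype=complex)
    blk = rng.normal(size=(2 * b + 1, 2 * b + 1)) \
        + 1j * rng.normal(size=(2 * b + 1, 2 * b + 1))
    spec[c - b:c + b + 1, c - b:c + b + 1] = blk
    g = ift(spec)
    a = g.real / g.real.std() * log_amplitude_rms
    ph = g.imag / g.imag.std() * phase_rms
    return ComplexSample(np.exp(a + 1j * ph), pixel_size)


def defocus_phase_map(z: float, grid: FrequencyGrid, na: float) -> np.ndarray:
    """Angular-spectrum defocus phase on the pupil disk.

    phi(k) = (2 pi z / wavelength) * (sqrt(1 - (wavelength |k|)^2) - 1),
    which is exact for propagating waves (no paraxial approximation) and
    vanishes at DC.  ``z`` is the defocus distance in micrometres.
    """
    s = grid.wavelength * grid.kr
    support = grid.disk_mask(na)
    if np.any(s[support] >= 1.0):
        raise ValueError("evanescent frequencies inside the pupil support")
    with np.errstate(invalid="ignore"):
        phi = 2 * np.pi * z / grid.wavelength * (np.sqrt(np.clip(1 - s ** 2, 0, 1)) - 1)
    return np.where(support, phi, 0.0)


def defocus_pupil_phase(z: float, pupil: Pupil) -> Pupil:
    """Return a pupil with the defocus phase for distance ``z`` (µm) added."""
    return pupil.with_added_phase(defocus_phase_map(z, pupil.grid, pupil.na))


def zernike_phase(coeffs, pupil: Pupil) -> Pupil:
    """Pupil with an aberration Sum_j c_j Z_j added (Noll-indexed, radians).

    ``coeffs`` is a mapping or iterable of ``(noll_index, value)`` pairs; the
    basis is the discrete-orthonormal one of :class:`~apic.zernike.ZernikeBasis`,
    so a single unit coefficient has unit RMS over the pupil disk.
    """
    items = list(coeffs.items()) if isinstance(coeffs, dict) else list(coeffs)
    if not items:
        return pupil.with_added_phase(np.zeros_like(pupil.phase))
    for j, _ in items:
        noll_to_nm(int(j))  # raises for invalid indices
    n_modes = max(int(j) for j, _ in items)
    basis = pupil.zernike_basis(n_modes)
    vec = np.zeros(n_modes)
    for j, cval in items:
        vec[int(j) - 1] += cval
    return pupil.with_added_phase(basis.synthesize(vec))


# ---------------------------------------------------------------------------
# forward imaging
# ---------------------------------------------------------------------------

def _shift_spectrum(sample: ComplexSample, k_i: np.ndarray,
                    grid: FrequencyGrid) -> np.ndarray:
    """Spectrum S(k - k_i) on the grid; exact roll for integer-bin shifts,
    real-space phase ramp otherwise."""
    bins = np.asarray(k_i, dtype=float) / grid.dk  # (bx, by)
    if np.allclose(bins, np.round(bins), atol=1e-9):
        S = ft(sample.field)
        bx, by = np.round(bins).astype(int)
        return np.roll(S, (by, bx), axis=(0, 1))
    x = grid.r[None, :]
    y = grid.r[:, None]
    ramp = np.exp(2j * np.pi * (k_i[0] * x + k_i[1] * y))
    return ft(sample.field * ramp)


def simulate_measurement(sample: ComplexSample, k_i, pupil: Pupil,
                         gain: float = 1.0, noise: NoiseModel | None = None,
                         rng: np.random.Generator | None = None,
                         out_shape: int | None = None) -> np.ndarray:
    """Intensity image for one LED: I = gain*|IFT[S(k-k_i) P(k) e^{i phi}]|^2.

    ``out_shape`` (<= simulation grid) emulates a camera that samples the
    field more coarsely than the simulation grid: the field spectrum is
    cropped to the camera band before detection.  The returned intensity is
    normalized so a uniform unit sample under on-axis illumination gives a
    constant image of value ``gain``.
    """
    grid = pupil.grid
    if sample.field.shape != (grid.shape, grid.shape) or not np.isclose(
            sample.pixel_size, grid.pixel_size):
        raise ValueError("sample and pupil must share one grid")
    k_i = np.asarray(k_i, dtype=float)
    spec = _shift_spectrum(sample, k_i, grid) * pupil.ctf
    n_out = grid.shape if out_shape is None else int(out_shape)
    if n_out != grid.shape:
        spec = crop_center(spec, n_out)
    E = ift(spec) * (n_out ** 2 / grid.shape ** 2)
    I = gain * np.abs(E) ** 2
    if noise is not None:
        I = noise.apply(I, rng if rng is not None else np.random.default_rng())
    return I


def simulate_dataset(sample: ComplexSample, pupil: Pupil,
                     geometry: IlluminationGeometry,
                     noise: NoiseModel | None = None,
                     camera_shape: int | None = None,
                     seed: int | None = None,
                     store_truth: bool = True) -> MeasurementStack:
    """One intensity image per LED, in the LED order given.

    With ``camera_shape`` < simulation grid the measurements are recorded on a
    coarser camera grid (same frequency step, reduced band).  Ground truth is
    stashed in ``metadata['truth']`` for fixtures unless ``store_truth=False``.
    """
    if len(geometry) == 0:
        raise ValueError("geometry must contain at least one LED")
    grid = pupil.grid
    n_cam = grid.shape if camera_shape is None else int(camera_shape)
    rng = np.random.default_rng(seed)
    ks = geometry.k_shifts(grid.wavelength)
    images = np.stack([
        simulate_measurement(sample, ks[i], pupil, gain=geometry.gains[i],
                             noise=noise, rng=rng, out_shape=n_cam)
        for i in range(len(geometry))
    ])
    cam_grid = FrequencyGrid(n_cam, grid.pixel_size * grid.shape / n_cam,
                             grid.wavelength)
    meta = {"noise": noise, "seed": seed}
    if store_truth:
        meta["truth"] = {"sample": sample, "pupil": pupil}
    return MeasurementStack(images, geometry, cam_grid, pupil.na, meta)


# ---------------------------------------------------------------------------
# illumination design
# ---------------------------------------------------------------------------

def _lattice_circle_points(radius: int) -> np.ndarray:
    """All integer points with x^2 + y^2 == radius^2, sorted by angle."""
    pts = []
    for x in range(-radius, radius + 1):
        y2 = radius * radius - x * x
        y = int(round(np.sqrt(y2)))
        if y * y == y2:
            pts.append((x, y))
            if y != 0:
                pts.append((x, -y))
    pts = np.array(sorted(set(pts)), dtype=int)
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    return pts[np.argsort(ang)]


def _snap_inward(target: np.ndarray, radius: float) -> np.ndarray:
    """Nearest integer point with norm <= radius (prefers staying close)."""
    best, best_d = None, np.inf
    tx, ty = target
    for dx in (np.floor, np.ceil, np.round):
        for dy in (np.floor, np.ceil, np.round):
            p = np.array([dx(tx), dy(ty)], dtype=int)
            if np.hypot(*p) <= radius + _EPS:
                d = np.hypot(p[0] - tx, p[1] - ty)
                if d < best_d:
                    best, best_d = p, d
    if best is None:  # fall back: scale inside
        scale = (radius - 0.5) / max(np.hypot(tx, ty), 1e-12)
        best = np.round(target * scale).astype(int)
    return best


def _set_gcd(points) -> int:
    """GCD of all pairwise coordinate differences of a point set."""
    import math

    p0 = points[0]
    g = 0
    for p in points[1:]:
        g = math.gcd(g, math.gcd(abs(int(p[0] - p0[0])), abs(int(p[1] - p0[1]))))
    return g


def _break_common_factor(points, lattice, taken) -> list:
    """Swap one ring point so pairwise shift differences generate the full
    integer lattice.

    If every pairwise difference of the selected frequency shifts shares an
    integer factor g > 1, the aberration solver's difference equations only
    couple pupil nodes within cosets of that sublattice and the relative
    coset pistons become weakly determined.  Substituting a single lattice
    point with coprime coordinates breaks the degeneracy at the cost of a
    slightly less uniform ring.  (Some radii, e.g. those whose squares have
    no primitive representations, admit no fix; the selection is returned
    unchanged then.)
    """
    if len(points) < 2 or _set_gcd(points) == 1:
        return points
    R = float(np.linalg.norm(np.asarray(points[0], float)))
    used = {tuple(lattice[i]) for i in taken}
    # candidates: remaining exact-circle points (radius deficit 0), then
    # lattice points just *inside* the ring (still NA-matching within the
    # two-bin tolerance; inward keeps the unscattered beam inside the CTF)
    candidates = [(0.0, tuple(p)) for i, p in enumerate(lattice)
                  if i not in taken]
    rmin = R - 1.5
    for x in range(-int(R), int(R) + 1):
        for y in range(-int(R), int(R) + 1):
            r = np.hypot(x, y)
            if rmin <= r < R - 1e-9:
                candidates.append((R - r, (x, y)))
    best = None
    for deficit, cand in candidates:
        if cand in used:
            continue
        for si in range(len(points)):
            trial = list(points)
            trial[si] = np.asarray(cand, int)
            if len({tuple(p) for p in trial}) < len(trial):
                continue
            if _set_gcd(trial) == 1:
                move = np.linalg.norm(np.asarray(points[si], float)
                                      - np.asarray(cand, float))
                key = (deficit, move)
                if best is None or key < best[0]:
                    best = (key, trial)
    return best[1] if best is not None else points


def design_ring_geometry(grid: FrequencyGrid, na: float, n_na: int = 8,
                         darkfield_rings=((1.5, 12), (2.0, 16)),
                         n_brightfield: int = 0) -> IlluminationGeometry:
    """NA-matching ring + darkfield ring(s) on the discrete frequency grid.

    The NA-matching LEDs are placed on integer lattice points of the circle of
    radius NA/(wavelength*dk) bins when such points exist (exactly on the ring
    — keeps the unscattered beam on the CTF cutoff so Kramers-Kronig recovery
    is exact); otherwise points snap to the nearest lattice node at or inside
    the cutoff.  ``darkfield_rings`` lists ``(sine_ratio, n_leds)`` pairs with
    the ring sine ``ratio * NA``; the default reaches a synthetic NA of 3*NA.
    ``n_brightfield`` interior LEDs are added on a coarse inner grid (they are
    recorded but unused by the reconstruction).
    """
    R = grid.pupil_radius_bins(na)
    R_int = int(round(R))
    points: list[np.ndarray] = []
    use_lattice = abs(R - R_int) < 1e-6
    lattice = _lattice_circle_points(R_int) if use_lattice else np.empty((0, 2))
    targets = 2 * np.pi * np.arange(n_na) / n_na
    if len(lattice) >= n_na:
        ang = np.arctan2(lattice[:, 1], lattice[:, 0]) % (2 * np.pi)
        taken: set[int] = set()
        for t in targets:
            gap = np.abs((ang - t + np.pi) % (2 * np.pi) - np.pi)
            for idx in np.argsort(gap):
                if idx not in taken:
                    taken.add(int(idx))
                    points.append(lattice[idx])
                    break
        points = _break_common_factor(points, lattice, taken)
    else:
        warnings.warn(
            f"no exact lattice ring at radius {R:.2f} bins; snapping NA-matching "
            "LEDs inward (sub-bin Kramers-Kronig residual)", stacklevel=2)
        for t in targets:
            points.append(_snap_inward(R * np.array([np.cos(t), np.sin(t)]), R))
    for ratio, m in darkfield_rings:
        r = ratio * R
        offs = np.pi / m  # stagger against the NA ring
        for t in 2 * np.pi * np.arange(m) / m + offs:
            points.append(np.round(r * np.array([np.cos(t), np.sin(t)])).astype(int))
    if n_brightfield:
        side = int(np.ceil(np.sqrt(n_brightfield)))
        half = 0.5 * R
        coords = np.linspace(-half, half, side)
        bf = [np.round([cx, cy]).astype(int) for cy in coords for cx in coords]
        points.extend(bf[:n_brightfield])
    sines = np.array(points, dtype=float) * grid.dk * grid.wavelength
    geom = IlluminationGeometry(sines)
    return geom.classify(na, tol_match=2 * grid.dk * grid.wavelength)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(stack: MeasurementStack, tiff_path, sidecar_path=None,
                  truth_path=None) -> None:
    """Multi-page float32 TIFF (one page per LED) + YAML sidecar; optional
    HDF5 ground-truth bundle."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.images.astype(np.float32))
    side = {
        "na": float(stack.na),
        "wavelength_um": float(stack.grid.wavelength),
        "pixel_size_um": float(stack.grid.pixel_size),
        "shape": int(stack.grid.shape),
        "sines": stack.geometry.sines.tolist(),
        "gains": stack.geometry.gains.tolist(),
        "labels": None if stack.geometry.labels is None
        else [str(l) for l in stack.geometry.labels],
    }
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".yaml")
    sidecar_path.write_text(yaml.safe_dump(side))
    if truth_path is not None:
        import h5py

        truth = stack.metadata.get("truth")
        if truth is None:
            raise ValueError("stack carries no ground truth to write")
        with h5py.File(truth_path, "w") as f:
            f.create_dataset("sample_field", data=truth["sample"].field)
            f.attrs["sample_pixel_size_um"] = truth["sample"].pixel_size
            f.create_dataset("pupil_phase", data=truth["pupil"].phase)
            f.attrs["na"] = truth["pupil"].na
            f.attrs["sim_shape"] = truth["pupil"].grid.shape
            f.attrs["sim_pixel_size_um"] = truth["pupil"].grid.pixel_size
            f.attrs["wavelength_um"] = truth["pupil"].grid.wavelength


def read_dataset(tiff_path, sidecar_path=None) -> MeasurementStack:
    """Load a measurement stack written by :func:`write_dataset` (or any
    multi-page TIFF plus a conforming YAML sidecar)."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".yaml")
    side = yaml.safe_load(sidecar_path.read_text())
    images = tifffile.imread(tiff_path).astype(float)
    if images.ndim == 2:
        images = images[None]
    geom = IlluminationGeometry(
        np.asarray(side["sines"], dtype=float),
        None if side.get("labels") is None else np.asarray(side["labels"]),
        np.asarray(side["gains"], dtype=float) if side.get("gains") is not None else None,
    )
    grid = FrequencyGrid(int(side["shape"]), float(side["pixel_size_um"]),
                         float(side["wavelength_um"]))
    return MeasurementStack(images, geom, grid, float(side["na"]))
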