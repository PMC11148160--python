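"""Analytic spectrum extension from darkfield measurements.

The Fourier transform of an intensity image is the autocorrelation of the
detected field's spectrum.  Splitting the spectrum sampled by darkfield
measurement *i* (the CTF disk shifted by ``-k_i``) into a *known* part K —
the prior spectrum, with the retrieved aberration re-applied — and an
*unknown* part U, the measured autocorrelation decomposes as

    N^2 FT(I_i) = K*K + K*U + U*K + U*U        ( (A*B)(q) = sum_u conj(A(u)) B(u+q) )

K*K is computable and subtracted.  On correlation lags where, by support
geometry, neither U*U nor the mirrored U*K (nor K*K) can contribute, the
remainder is *linear* in U:  (K*U)(q) = sum_u conj(K(u-q)) U(u).  Solving this
closed-form linear system on that exclusive lag region yields U; removing the
aberration gives new sample-spectrum values, the prior grows, and the next
measurement (processed in order of overlap with the known support) sees a
larger K.  No iteration over the whole dataset is ever needed.

All correlations are evaluated on the bounding box of the shifted CTF disk
with zero-padded (linear, non-circular) FFT convolutions; the lag grid is
(2D-1)^2 for a D^2 box with lag 0 at index (D-1, D-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.sparse.linalg import LinearOperator, lsmr

from ._fft import center_index, crop_center, ft
from .aberration import AberrationEstimate
from .simulate import DARKFIELD, FrequencyGrid, IlluminationGeometry, MeasurementStack, Pupil
from .stitching import PriorSpectrum

__all__ = [
    "KnownUnknownSplit", "CrossCorrRegion", "DarkfieldSolve",
    "order_darkfield", "split_known_unknown", "residual_after_known_autocorr",
    "exclusive_cross_region", "solve_unknown", "update_prior",
    "run_darkfield_stage",
]


# ---------------------------------------------------------------------------
# correlation primitives (lag 0 at index (D-1, D-1) of a (2D-1)^2 lag grid)
# ---------------------------------------------------------------------------

def xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full linear cross-correlation C(q) = sum_u conj(a(u)) b(u+q)."""
    return fftconvolve(b, np.conj(a[::-1, ::-1]), mode="full")


def _mask_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean support of the correlation of two masks."""
    c = fftconvolve(b.astype(float), a[::-1, ::-1].astype(float), mode="full")
    return c > 0.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KnownUnknownSplit:
    """Known/unknown partition of one darkfield measurement's spectrum.

    Arrays live on the D x D bounding box of the CTF disk shifted by
    ``-k_i``; ``origin`` is the (row, col) of the box's first node on the
    prior grid.  ``K`` is the prior spectrum on ``K_support`` with the
    aberration phase ``exp(+i phi_ab(u + k_i))`` re-applied (``phase``
    stores that factor so it can be removed from the solved unknown).
    """

    k_i: np.ndarray
    origin: tuple[int, int]
    box: int
    K: np.ndarray
    K_support: np.ndarray
    U_support: np.ndarray
    phase: np.ndarray
    known_fraction: float
    redundant: bool = False

    @property
    def disk_support(self) -> np.ndarray:
        return self.K_support | self.U_support


@dataclass
class CrossCorrRegion:
    """Lags where only the K*U cross term can contribute."""

    mask: np.ndarray          # (2D-1)^2 bool on the lag grid
    sensitivity: np.ndarray   # row norms of the K*U operator per lag

    @property
    def n_lags(self) -> int:
        return int(self.mask.sum())

    @property
    def lags(self) -> np.ndarray:
        """(n, 2) integer lags (qy, qx) relative to lag 0."""
        d = (self.mask.shape[0] + 1) // 2
        qy, qx = np.nonzero(self.mask)
        return np.column_stack([qy - (d - 1), qx - (d - 1)])


@dataclass
class DarkfieldSolve:
    """Solved unknown spectrum for one measurement (box coordinates).

    ``determined`` marks the subset of the unknown support whose operator
    columns carry signal from the exclusive lag region; only those nodes are
    solved and filled back (the rest stay unknown for neighboring
    measurements or a later pass).
    """

    S_hat: np.ndarray         # aberration-removed values, zero off determined
    determined: np.ndarray    # bool, subset of U_support
    ok: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def order_darkfield(geometry: IlluminationGeometry, prior: PriorSpectrum,
                    na: float, indices=None) -> np.ndarray:
    """Darkfield LED indices sorted by descending overlap with the prior.

    Ties break by ascending |k_i|, then by azimuth — deterministic across
    runs.  ``indices`` restricts the candidate set (default: all LEDs labeled
    darkfield).
    """
    if indices is None:
        indices = geometry.indices(DARKFIELD)
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise ValueError("no darkfield LEDs to order")
    grid = prior.grid
    ks = geometry.k_shifts(grid.wavelength)
    keys = []
    for i in indices:
        disk = grid.disk_mask(na, center_k=(-ks[i, 0], -ks[i, 1]))
        overlap = int((disk & prior.known_mask).sum())
        kn = float(np.hypot(*ks[i]))
        az = float(np.arctan2(ks[i, 1], ks[i, 0]) % (2 * np.pi))
        keys.append((-overlap, kn, az))
    order = sorted(range(len(indices)), key=lambda t: keys[t])
    return indices[order]


def split_known_unknown(prior: PriorSpectrum, k_i, pupil: Pupil,
                        ab: AberrationEstimate | None,
                        camera_grid: FrequencyGrid | None = None) -> KnownUnknownSplit:
    """Crop the prior to the shifted CTF support and re-apply the aberration.

    Raises when the measurement has zero overlap with the known support (it
    cannot be anchored yet and must be deferred); flags it as redundant when
    the whole shifted support is already known.
    """
    grid = prior.grid
    cam = camera_grid if camera_grid is not None else pupil.grid
    k_i = np.asarray(k_i, dtype=float)
    dk = grid.dk
    R = grid.pupil_radius_bins(pupil.na)
    rad = int(np.ceil(R - 1e-9))
    D = 2 * rad + 1
    mc = center_index(grid.shape)
    bx, by = np.round(k_i / dk).astype(int)
    cy, cx = mc - by, mc - bx
    if cy - rad < 0 or cx - rad < 0 or cy + rad >= grid.shape or cx + rad >= grid.shape:
        raise ValueError("shifted CTF support falls outside the prior grid; "
                         "increase the reconstruction grid (upsampling factor)")
    rows = slice(cy - rad, cy + rad + 1)
    cols = slice(cx - rad, cx + rad + 1)
    iy, ix = np.mgrid[0:D, 0:D]
    u_kx = (ix - rad + (cx - mc)) * dk
    u_ky = (iy - rad + (cy - mc)) * dk
    disk = grid.wavelength * np.hypot(u_kx + k_i[0], u_ky + k_i[1]) \
        <= pupil.na * (1 + 1e-9)
    known = prior.known_mask[rows, cols]
    K_support = disk & known
    U_support = disk & ~known
    if not K_support.any():
        raise ValueError("measurement has no overlap with the known spectrum "
                         "(cannot anchor; defer it)")
    # aberration phase at pupil coordinate p = u + k_i (camera-grid indices)
    if ab is not None:
        cc = center_index(cam.shape)
        py = iy - rad + (cy - mc) + by + cc
        px = ix - rad + (cx - mc) + bx + cc
        py = np.clip(py, 0, cam.shape - 1)
        px = np.clip(px, 0, cam.shape - 1)
        phase = np.exp(1j * ab.phase[py, px])
    else:
        phase = np.ones((D, D), dtype=complex)
    K = np.where(K_support, prior.values[rows, cols] * phase, 0.0)
    frac = float(K_support.sum() / disk.sum())
    return KnownUnknownSplit(k_i, (cy - rad, cx - rad), D, K, K_support,
                             U_support, phase, frac,
                             redundant=not U_support.any())


def _corr_supports(split: KnownUnknownSplit):
    Km, Um = split.K_support, split.U_support
    return {
        "KK": _mask_xcorr(Km, Km),
        "KU": _mask_xcorr(Km, Um),
        "UK": _mask_xcorr(Um, Km),
        "UU": _mask_xcorr(Um, Um),
    }


def residual_after_known_autocorr(intensity: np.ndarray,
                                  split: KnownUnknownSplit,
                                  camera_grid: FrequencyGrid,
                                  gain: float | None = None
                                  ) -> tuple[np.ndarray, float]:
    """Measured autocorrelation minus the known-part autocorrelation.

    Returns ``(R, gain)`` on the (2D-1)^2 lag grid; noiselessly R contains
    only U*U + K*U + U*K.  With ``gain=None`` a per-measurement scalar gain
    is calibrated by matching the measurement to K*K on lags where K*K is the
    only contributing term (LED brightness varies in practice; the simulator
    default gain is 1 and calibrates to 1).
    """
    Nc = camera_grid.shape
    D = split.box
    if 2 * D - 1 > Nc:
        raise ValueError("camera band too small for the required lag range")
    FTI = crop_center(ft(np.asarray(intensity, dtype=float)) * Nc ** 2, 2 * D - 1)
    KK = xcorr(split.K, split.K)
    if gain is None:
        sup = _corr_supports(split)
        excl_kk = sup["KK"] & ~sup["KU"] & ~sup["UK"] & ~sup["UU"]
        num = float(np.sum(np.real(np.conj(KK[excl_kk]) * FTI[excl_kk])))
        den = float(np.sum(np.abs(KK[excl_kk]) ** 2))
        if den > 0 and num > 0:
            gain = num / den
        else:
            warnings.warn("gain calibration region empty or degenerate; "
                          "assuming gain 1", stacklevel=2)
            gain = 1.0
    return FTI / gain - KK, float(gain)


def exclusive_cross_region(split: KnownUnknownSplit,
                           sensitivity_floor: float = 1e-3) -> CrossCorrRegion:
    """Lags where the K*U cross-correlation is the sole contributor.

    A lag qualifies when it lies in supp(K*U) but outside supp(U*U),
    supp(K*K) and supp(U*K) (all supports by morphological correlation of
    the masks).  Lags whose operator row norm falls below
    ``sensitivity_floor`` of the maximum are dropped for conditioning.
    An empty region is legal and signals deferral.
    """
    D = split.box
    if not split.U_support.any():
        shape = (2 * D - 1, 2 * D - 1)
        return CrossCorrRegion(np.zeros(shape, bool), np.zeros(shape))
    sup = _corr_supports(split)
    mask = sup["KU"] & ~sup["UU"] & ~sup["KK"] & ~sup["UK"]
    row_norm2 = np.real(xcorr(np.abs(split.K) ** 2,
                              split.U_support.astype(float)))
    sens = np.sqrt(np.clip(row_norm2, 0, None))
    if mask.any():
        mask = mask & (sens >= sensitivity_floor * sens[mask].max())
    return CrossCorrRegion(mask, sens)


def _column_sensitivity(split: KnownUnknownSplit,
                        region: CrossCorrRegion) -> np.ndarray:
    """Column norms of the K*U operator: sqrt(sum_q in region |K(u-q)|^2)."""
    D = split.box
    rmask = np.zeros((2 * D - 1, 2 * D - 1))
    rmask[region.mask] = 1.0
    full = fftconvolve(np.abs(split.K) ** 2, rmask, mode="full")
    cols2 = np.real(full[D - 1: 2 * D - 1, D - 1: 2 * D - 1])
    return np.sqrt(np.clip(cols2, 0, None)) * split.U_support


def _cross_operator(split: KnownUnknownSplit, region: CrossCorrRegion,
                    umask: np.ndarray):
    """Matrix-free K*U operator restricted to the exclusive region and to
    the unknown nodes in ``umask``."""
    D = split.box
    uy, ux = np.nonzero(umask)
    n_u = len(uy)
    qmask = region.mask
    n_q = int(qmask.sum())
    K = split.K

    def matvec(x):
        U = np.zeros((D, D), dtype=complex)
        U[uy, ux] = x
        return xcorr(K, U)[qmask]

    def rmatvec(r):
        rarr = np.zeros((2 * D - 1, 2 * D - 1), dtype=complex)
        rarr[qmask] = r
        full = fftconvolve(K, rarr, mode="full")
        return full[D - 1: 2 * D - 1, D - 1: 2 * D - 1][uy, ux]

    return LinearOperator((n_q, n_u), matvec=matvec, rmatvec=rmatvec,
                          dtype=complex), (uy, ux)


def _dense_matrix(split: KnownUnknownSplit, region: CrossCorrRegion,
                  uy: np.ndarray, ux: np.ndarray) -> np.ndarray:
    D = split.box
    lags = region.lags
    Kp = np.zeros((3 * D, 3 * D), dtype=complex)
    Kp[D:2 * D, D:2 * D] = split.K
    A = np.empty((len(lags), len(uy)), dtype=complex)
    for r, (qy, qx) in enumerate(lags):
        A[r] = np.conj(Kp[uy - qy + D, ux - qx + D])
    return A


def solve_unknown(split: KnownUnknownSplit, region: CrossCorrRegion,
                  R: np.ndarray, regularization: float = 1e-2,
                  maxiter: int = 2000,
                  dense_limit: float = 4e6,
                  determined_floor: float = 1e-3) -> DarkfieldSolve:
    """Closed-form least-squares solve for the unknown spectrum.

    Solves ``A U = R|region`` with ``A(q, u) = conj(K(u-q))`` by Tikhonov-
    damped least squares (damp = ``regularization`` x the largest operator
    row norm), densely when the matrix fits ``dense_limit`` entries and via
    LSMR with FFT-based mat-vecs otherwise, then removes the aberration:
    ``S_hat(u) = U_hat(u) * exp(-i phi_ab(u + k_i))``.

    Unknown nodes whose operator column norm falls below
    ``determined_floor`` of the maximum receive no signal from the exclusive
    region (typically the far tip of the unknown crescent); they are left
    unsolved rather than filled with minimum-norm values, to be picked up by
    a neighboring measurement or a later pass.  Remaining under-determined
    systems are solved in the minimum-norm sense with a warning; solver
    failure flags the measurement for deferral.
    """
    D = split.box
    S_hat = np.zeros((D, D), dtype=complex)
    det = np.zeros((D, D), dtype=bool)
    n_u = int(split.U_support.sum())
    n_q = region.n_lags
    diag = {"n_unknown": n_u, "n_lags": n_q}
    if n_u == 0:
        return DarkfieldSolve(S_hat, det, True, diag | {"note": "nothing unknown"})
    if n_q == 0:
        return DarkfieldSolve(S_hat, det, False,
                              diag | {"note": "empty exclusive region"})
    cols = _column_sensitivity(split, region)
    det = cols >= determined_floor * cols.max()
    n_det = int(det.sum())
    diag["n_determined"] = n_det
    if n_det == 0:
        return DarkfieldSolve(S_hat, det, False,
                              diag | {"note": "no determined unknowns"})
    if n_q < n_u:
        warnings.warn(f"under-determined darkfield solve ({n_q} lags for "
                      f"{n_u} unknowns): minimum-norm solution", stacklevel=2)
    # solve over *all* unknown nodes (weak columns still carry their true
    # contribution into the region; dropping them would bias the rest) but
    # fill back only the determined subset.
    b = R[region.mask]
    smax = float(region.sensitivity[region.mask].max())
    damp = regularization * smax
    op, (uy, ux) = _cross_operator(split, region, split.U_support)
    if n_q * n_u <= dense_limit:
        A = _dense_matrix(split, region, uy, ux)
        Aaug = np.vstack([A, damp * np.eye(n_u, dtype=complex)])
        baug = np.concatenate([b, np.zeros(n_u, dtype=complex)])
        x, *_ = np.linalg.lstsq(Aaug, baug, rcond=None)
        resid = float(np.linalg.norm(A @ x - b))
        diag |= {"solver": "dense", "residual": resid}
        ok = True
    else:
        sol = lsmr(op, b, damp=damp, atol=1e-10, btol=1e-10, maxiter=maxiter)
        x = sol[0]
        diag |= {"solver": "lsmr", "istop": int(sol[1]), "iters": int(sol[2]),
                 "residual": float(sol[3])}
        ok = sol[1] in (0, 1, 2, 4, 5)
    keep = det[uy, ux]
    S_hat[uy[keep], ux[keep]] = x[keep] * np.conj(split.phase[uy[keep], ux[keep]])
    bnorm = float(np.linalg.norm(b))
    diag |= {"rel_residual": diag["residual"] / bnorm if bnorm else 0.0}
    return DarkfieldSolve(S_hat, det, ok, diag)


def update_prior(prior: PriorSpectrum, split: KnownUnknownSplit,
                 solve: DarkfieldSolve) -> PriorSpectrum:
    """Fill the solved unknown spectrum back into the prior (in place).

    The unknown support must be disjoint from the current known mask; the
    known mask and provenance grow accordingly.
    """
    r0, c0 = split.origin
    D = split.box
    rows = slice(r0, r0 + D)
    cols = slice(c0, c0 + D)
    fill = solve.determined
    if (prior.known_mask[rows, cols] & split.U_support).any():
        raise RuntimeError("unknown support overlaps the known mask")
    if not fill.any():
        return prior
    prior.values[rows, cols] = np.where(fill, solve.S_hat,
                                        prior.values[rows, cols])
    prior.known_mask[rows, cols] |= fill
    prior.provenance[rows, cols] += fill
    return prior


def run_darkfield_stage(prior: PriorSpectrum, stack: MeasurementStack,
                        ab: AberrationEstimate | None, pupil: Pupil,
                        regularization: float = 1e-2,
                        sensitivity_floor: float = 1e-3,
                        maxiter: int = 2000,
                        max_passes: int = 2) -> tuple[PriorSpectrum, list[dict]]:
    """Process every darkfield measurement, growing the prior sequentially.

    Measurements are ordered by overlap with the current known support and
    re-ordered at the start of each pass; ones that cannot be solved yet
    (empty exclusive region, no anchor, solver failure) are deferred to the
    next pass and reported — never silently dropped.
    """
    geometry = stack.geometry
    remaining = list(geometry.indices(DARKFIELD))
    records: list[dict] = []
    ks = geometry.k_shifts(stack.grid.wavelength)
    for pass_no in range(max_passes):
        if not remaining:
            break
        order = order_darkfield(geometry, prior, pupil.na, indices=remaining)
        deferred = []
        for led in order:
            rec = {"led": int(led), "pass": pass_no}
            try:
                split = split_known_unknown(prior, ks[led], pupil, ab,
                                            camera_grid=stack.grid)
            except ValueError as err:
                rec |= {"status": "deferred", "reason": str(err)}
                deferred.append(led)
                records.append(rec)
                continue
            if split.redundant:
                rec |= {"status": "redundant", "known_fraction": 1.0}
                records.append(rec)
                continue
            region = exclusive_cross_region(split, sensitivity_floor)
            R, gain = residual_after_known_autocorr(
                stack.images[led], split, stack.grid, gain=None)
            solve = solve_unknown(split, region, R, regularization, maxiter)
            rec |= {"known_fraction": split.known_fraction, "gain": gain,
                    **solve.diagnostics}
            if not solve.ok:
                rec["status"] = "deferred"
                deferred.append(led)
            else:
                update_prior(prior, split, solve)
                if solve.diagnostics.get("n_determined", 0) < \
                        solve.diagnostics.get("n_unknown", 0):
                    rec["status"] = "partial"
                    deferred.append(led)  # leftover nodes: retry after growth
                else:
                    rec["status"] = "ok"
            records.append(rec)
        remaining = deferred
    for led in remaining:
        records.append({"led": int(led), "status": "unprocessed"})
    return prior, records
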