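"""Noll-indexed Zernike polynomials, discretely orthonormalized on a pupil disk.

Continuous Zernike polynomials lose orthogonality once sampled on a finite
pixel grid clipped to a rasterized disk.  For aberration fitting and reporting
we therefore re-orthonormalize the sampled basis with a Cholesky/Gram step so
that, for basis vectors Z_j and disk nodes p,

    (1 / n_nodes) * sum_p Z_i(p) Z_j(p) = delta_ij .

With this normalization a mode with coefficient c has area-weighted RMS |c|
over the disk.  The re-orthonormalized vectors stay within O(pixelization) of
the analytic polynomials, and diag(R) > 0 in the Gram factor keeps their signs
and scales aligned with the textbook definitions (Noll 1976 indexing: j=1
piston, 2/3 tip/tilt, 4 defocus, ...).
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np

__all__ = ["noll_to_nm", "zernike_nm", "ZernikeBasis"]


@lru_cache(maxsize=None)
def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index j >= 1 to radial degree n and azimuthal frequency m."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_nm(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Analytic Zernike Z_n^m with the Noll normalization (RMS 1 on the disk)."""
    if (n - abs(m)) % 2 or abs(m) > n:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    norm = np.sqrt(2.0 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
    r = _radial(n, m, rho)
    if m > 0:
        return norm * r * np.cos(m * theta)
    if m < 0:
        return norm * r * np.sin(-m * theta)
    return norm * r


class ZernikeBasis:
    """Discrete-orthonormal Zernike basis on a boolean disk mask.

    Parameters
    ----------
    support : (H, W) bool array
        Rasterized pupil disk.
    rho, theta : (H, W) float arrays
        Unit-disk polar coordinates of every grid node (rho = 1 at the pupil
        edge); only values inside ``support`` are used.
    n_modes : int
        Number of Noll modes, starting at j = 1 (piston).
    """

    def __init__(self, support: np.ndarray, rho: np.ndarray, theta: np.ndarray,
                 n_modes: int) -> None:
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        self.support = np.asarray(support, dtype=bool)
        self.n_modes = int(n_modes)
        nodes = self.support
        self._n_nodes = int(nodes.sum())
        if self._n_nodes < n_modes:
            raise ValueError("fewer disk nodes than requested modes")
        B = np.empty((self._n_nodes, n_modes))
        r, t = rho[nodes], theta[nodes]
        for col, j in enumerate(range(1, n_modes + 1)):
            B[:, col] = zernike_nm(*noll_to_nm(j), r, t)
        # Gram re-orthonormalization wrt the area-weighted discrete product.
        G = B.T @ B / self._n_nodes
        L = np.linalg.cholesky(G)
        self._B = np.linalg.solve(L, B.T).T  # B @ inv(L).T

    @property
    def matrix(self) -> np.ndarray:
        """(n_nodes, n_modes) orthonormalized basis over the disk nodes."""
        return self._B

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Phase map (full grid, zero outside the disk) from Noll coefficients."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.n_modes,):
            raise ValueError(f"expected {self.n_modes} coefficients")
        out = np.zeros(self.support.shape)
        out[self.support] = self._B @ coeffs
        return out

    def decompose(self, phase: np.ndarray) -> np.ndarray:
        """Least-squares (= orthogonal) projection of a disk phase map."""
        vals = phase[self.support]
        return self._B.T @ vals / self._n_nodes

    def fit(self, phase_values: np.ndarray, node_mask: np.ndarray) -> np.ndarray:
        """LS-fit coefficients from values on a *subset* of disk nodes.

        ``node_mask`` is boolean over the disk nodes (length n_nodes).  Used to
        extrapolate an aberration estimate into uncovered pupil nodes.
        """
        A = self._B[node_mask]
        coeffs, *_ = np.linalg.lstsq(A, phase_values, rcond=None)
        return coeffs

    def residual(self, phase: np.ndarray, coeffs: np.ndarray) -> float:
        """Relative L2 residual of a disk phase map after projection."""
        vals = phase[self.support]
        rec = self._B @ coeffs
        denom = np.linalg.norm(vals)
        return float(np.linalg.norm(vals - rec) / denom) if denom else 0.0
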