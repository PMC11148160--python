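"""Closed-form complex-field recovery for NA-matching measurements.

When the illumination direction sine equals the objective NA, the detected
field ``E`` has a spectrum confined to a disk whose boundary passes through
the unscattered beam's frequency ``k_i``.  Demodulating by the illumination
tilt, ``psi = E * exp(-i 2 pi k_i . r)``, moves that disk so it touches DC and
lies entirely in the half-plane ``k . d <= 0`` (``d = k_i/|k_i|``): ``psi`` is
one-sided (anti-analytic along ``d``).  For a nonvanishing ``psi`` the same is
true of ``log psi``, so its imaginary part (the field phase) follows from its
real part (half the log-intensity) by a directional Hilbert transform — the
spatial Kramers-Kronig relation:

    psi = sqrt(I) * exp(i * H_d[ log(I) / 2 ]),    H_d: multiplier +i sgn(k.d)

with ``sgn(0) = 0`` on the dividing line (standard analytic-signal convention;
keeps the mean of ``psi`` real-positive, which is the per-measurement phase
gauge).  The recovery is exact up to one global phase per measurement — there
is no iteration and no convergence parameter.

Because ``psi`` is the tilt-demodulated field, its Fourier transform already
sits in sample-spectrum coordinates: ``FT(psi)(u) = S(u) e^{i phi_ab(u+k_i)}``
(up to the global phase and the camera scale), supported on the CTF disk
translated by ``-k_i``.  :func:`patch_from_field` masks it to that support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._fft import ft, ift
from .simulate import FrequencyGrid, Pupil

__all__ = ["SpectrumPatch", "kk_field_from_intensity", "patch_from_field"]


@dataclass
class SpectrumPatch:
    """A complex sample-spectrum estimate with its validity support.

    ``values`` lives on ``grid``'s frequency axes in sample-spectrum
    coordinates and is zero outside ``support`` — the CTF disk translated by
    ``-source_k``.  Up to one unknown global phase per patch, the noiseless
    values equal ``S(u) * exp(i * phi_ab(u + source_k))``.
    """

    values: np.ndarray
    support: np.ndarray
    source_k: np.ndarray
    grid: FrequencyGrid
    label: int | None = None
    corrected: bool = False
    phase_const: float | None = None

    def __post_init__(self) -> None:
        self.source_k = np.asarray(self.source_k, dtype=float)
        if self.values.shape != self.support.shape:
            raise ValueError("values/support shape mismatch")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


def _directional_sign(grid: FrequencyGrid, direction: np.ndarray) -> np.ndarray:
    proj = grid.kxx * direction[0] + grid.kyy * direction[1]
    out = np.sign(proj)
    out[np.abs(proj) < 1e-9 * grid.dk] = 0.0
    return out


def kk_field_from_intensity(intensity: np.ndarray, k_i, grid: FrequencyGrid,
                            na: float, tol_steps: float = 2.0,
                            clamp: float = 1e-6) -> np.ndarray:
    """Recover the tilt-demodulated complex field from one NA-matching image.

    Parameters
    ----------
    intensity : (N, N) array
        Nonnegative intensity measurement (gain-normalized).
    k_i : pair of floats
        Illumination frequency shift in inverse micrometres;
        ``wavelength * |k_i|`` must match ``na`` within ``tol_steps``
        frequency steps, otherwise the measurement is refused (interior
        brightfield angles have no analytic closed form, and angles beyond
        the cutoff belong to the darkfield branch).
    clamp : float
        Intensities are floored at ``clamp * max(I)`` before the log to guard
        against zeros of the field; a warning reports how many pixels were
        clamped, since field zeros violate the nonvanishing assumption.

    Returns
    -------
    psi : (N, N) complex array
        Demodulated field with one-sided spectrum, mean-phase gauge fixed.
    """
    k_i = np.asarray(k_i, dtype=float)
    k_norm = float(np.hypot(*k_i))
    if k_norm == 0.0:
        raise ValueError("k_i = 0 has no Kramers-Kronig direction")
    if abs(grid.wavelength * k_norm - na) > tol_steps * grid.dk * grid.wavelength:
        raise ValueError(
            f"illumination sine {grid.wavelength * k_norm:.4f} is not NA-matching "
            f"(na={na}, tol={tol_steps} frequency steps)")
    I = np.asarray(intensity, dtype=float)
    floor = clamp * I.max()
    n_clamped = int(np.count_nonzero(I < floor))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} pixels clamped at {clamp:g}*max(I) before log "
            "(field zeros break the Kramers-Kronig assumptions)", stacklevel=2)
    I = np.maximum(I, floor)
    if floor <= 0 and I.min() <= 0:
        raise FloatingPointError("nonpositive intensities after clamping")
    half_log = 0.5 * np.log(I)
    mult = 1j * _directional_sign(grid, k_i / k_norm)
    hilbert = np.real(ift(mult * ft(half_log)))
    return np.sqrt(I) * np.exp(1j * hilbert)


def patch_from_field(psi: np.ndarray, k_i, pupil: Pupil,
                     grid: FrequencyGrid | None = None,
                     label: int | None = None) -> SpectrumPatch:
    """Place a recovered field into sample-spectrum coordinates.

    The demodulated field's transform is masked to the translated CTF support
    ``{u : wavelength * |u + k_i| <= NA}``; its global phase is still free
    (``phase_const`` unset) until the aberration stage estimates it.

    ``grid`` defaults to a grid with the camera's shape/pixel pitch; it must
    share the pupil's frequency step.
    """
    k_i = np.asarray(k_i, dtype=float)
    if grid is None:
        grid = FrequencyGrid(psi.shape[0], pupil.grid.pixel_size *
                             pupil.grid.shape / psi.shape[0], pupil.grid.wavelength)
    support = grid.disk_mask(pupil.na, center_k=(-k_i[0], -k_i[1]))
    values = np.where(support, ft(psi), 0.0)
    return SpectrumPatch(values, support, k_i, grid, label=label)
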