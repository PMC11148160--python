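"""Aberration correction and Fourier-domain stitching of spectrum patches.

Each recovered patch is divided by its pupil-phase factor and its estimated
per-measurement constant, after which all patches agree (noiselessly) on
their overlaps and can be averaged into a single running sample-spectrum
estimate — the *prior* spectrum.  With a full NA-matching ring the union of
the translated CTF disks reaches twice the CTF radius: the two-fold
resolution-enhanced synthetic aperture of the NA-matching stage.  The prior's
support mask is later grown further by the darkfield stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._fft import center_index, embed_center
from .aberration import AberrationEstimate
from .kk import SpectrumPatch
from .simulate import FrequencyGrid

__all__ = ["PriorSpectrum", "correct_patch", "stitch"]


@dataclass
class PriorSpectrum:
    """Running stitched sample-spectrum estimate with its known support.

    ``values`` is complex on ``grid`` (sample-spectrum coordinates), zero
    outside ``known_mask``; ``provenance`` counts contributing measurements
    per node (patches here, darkfield updates later).
    """

    values: np.ndarray
    known_mask: np.ndarray
    provenance: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        if not (self.values.shape == self.known_mask.shape == self.provenance.shape):
            raise ValueError("values/known_mask/provenance shape mismatch")

    @property
    def support_radius_bins(self) -> float:
        """Maximum |u| over the known support, in frequency bins."""
        if not self.known_mask.any():
            return 0.0
        c = center_index(self.known_mask.shape[0])
        ry, rx = np.nonzero(self.known_mask)
        return float(np.hypot(ry - c, rx - c).max())


def correct_patch(patch: SpectrumPatch, ab: AberrationEstimate) -> SpectrumPatch:
    """Remove the retrieved aberration and per-patch constant from a patch.

    values(u) <- values(u) * exp(-i * (phi_ab(u + k_i) + c_i)); after this all
    patches share a single global phase.  Correcting twice would subtract the
    phase again, so already-corrected patches are refused.
    """
    if patch.corrected:
        raise ValueError("patch is already aberration-corrected")
    key = patch.label
    if key is None or key not in ab.constants:
        raise ValueError(f"no per-patch constant for patch label {key!r}")
    grid = patch.grid
    bins = np.asarray(patch.source_k) / grid.dk
    bx, by = np.round(bins).astype(int)
    # phi_ab sampled at u + k_i == pupil map shifted by -k_i onto patch coords
    phi_shift = np.roll(ab.phase, (-by, -bx), axis=(0, 1))
    vals = np.where(patch.support,
                    patch.values * np.exp(-1j * (phi_shift + ab.constants[key])),
                    0.0)
    return replace(patch, values=vals, corrected=True,
                   phase_const=float(ab.constants[key]))


def stitch(patches: list[SpectrumPatch], out_grid: FrequencyGrid | None = None,
           weighting: str = "amplitude") -> PriorSpectrum:
    """Average corrected, phase-aligned patches into a PriorSpectrum.

    Overlapping nodes combine by amplitude-weighted mean (``weighting=
    'amplitude'``, the default — averages down Kramers-Kronig noise) or plain
    mean (``'uniform'``).  The known mask is the union of patch supports.  The
    global phase is anchored so the stitched DC value is real-positive (every
    NA-matching patch support touches DC).

    ``out_grid`` embeds the result on a larger grid with the same frequency
    step (the upsampled reconstruction grid); default keeps the patch grid.
    """
    if not patches:
        raise ValueError("need at least one patch")
    if weighting not in ("amplitude", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    for p in patches:
        if not p.corrected:
            raise ValueError("stitch requires aberration-corrected patches")
    grid = patches[0].grid
    shape = patches[0].values.shape
    acc = np.zeros(shape, dtype=complex)
    wacc = np.zeros(shape)
    prov = np.zeros(shape, dtype=int)
    for p in patches:
        w = p.amplitude if weighting == "amplitude" else p.support.astype(float)
        acc += w * p.values
        wacc += np.where(p.support, w, 0.0)
        prov += p.support
    mask = prov > 0
    vals = np.zeros_like(acc)
    nz = mask & (wacc > 0)
    vals[nz] = acc[nz] / wacc[nz]
    c = center_index(grid.shape)
    dc = vals[c, c]
    if np.abs(dc) > 0:
        vals = vals * np.exp(-1j * np.angle(dc))
    if out_grid is not None:
        if abs(out_grid.dk - grid.dk) > 1e-9 * grid.dk:
            raise ValueError("output grid must share the patch frequency step")
        vals = embed_center(vals, out_grid.shape)
        mask = embed_center(mask, out_grid.shape)
        prov = embed_center(prov, out_grid.shape)
        grid = out_grid
    return PriorSpectrum(vals, mask, prov, grid)
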