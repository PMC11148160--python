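"""Shared fixtures: small optical setups and simulated measurement stacks.

All fixtures use NA 0.25 and wavelength 0.52 um (green LED).  Grids are
chosen so the pupil cutoff falls on an integer bin radius with exact
lattice points on the NA-matching ring, which keeps the closed-form
recovery exact and the expected values sharp.
"""

from __future__ import annotations

import numpy as np
import pytest

from apic import (FrequencyGrid, Pupil, design_ring_geometry,
                  make_smooth_phantom, simulate_dataset)
from apic._fft import ft
from apic.kk import SpectrumPatch, kk_field_from_intensity, patch_from_field

NA = 0.25
WL = 0.52


@pytest.fixture(scope="session")
def grid100():
    return FrequencyGrid.for_pupil_radius(100, NA, WL, 25)


@pytest.fixture(scope="session")
def pupil100(grid100):
    return Pupil.ideal(grid100, NA)


@pytest.fixture(scope="session")
def ring100(grid100):
    return design_ring_geometry(grid100, NA, n_na=8, darkfield_rings=())


@pytest.fixture(scope="session")
def phantom100(grid100):
    return make_smooth_phantom(100, grid100.pixel_size, seed=5)


@pytest.fixture(scope="session")
def patches100(grid100, pupil100, ring100, phantom100):
    """Kramers-Kronig patches of an aberration-free 8-LED ring dataset."""
    stack = simulate_dataset(phantom100, pupil100, ring100)
    ks = ring100.k_shifts(WL)
    out = []
    for i in range(len(ring100)):
        psi = kk_field_from_intensity(stack.images[i], ks[i], grid100, NA)
        out.append(patch_from_field(psi, ks[i], pupil100, grid100, label=i))
    return out


def exact_patches(grid, pupil, sample, geometry, consts=None):
    """Noise-free analytic spectrum patches S(u)*exp(i*phi(u+k_i))*e^{ic_i}.

    Bypasses the simulator and Kramers-Kronig stage entirely — used to test
    the aberration solver against machine-precision inputs.
    """
    S = ft(sample.field)
    ks = geometry.k_shifts(grid.wavelength)
    out = []
    for i in range(len(geometry)):
        bx, by = np.round(ks[i] / grid.dk).astype(int)
        ctf_shift = np.roll(pupil.ctf, (-by, -bx), axis=(0, 1))
        support = grid.disk_mask(pupil.na, center_k=(-ks[i][0], -ks[i][1]))
        vals = np.where(support, S * ctf_shift, 0.0)
        if consts is not None:
            vals = vals * np.exp(1j * consts[i])
        out.append(SpectrumPatch(vals, support, ks[i], grid, label=i))
    return out


def gauge_free_rmse(estimate, truth, grid, na):
    """RMS phase error on the pupil disk after removing piston/tip/tilt
    from both maps (the components unobservable from intensity)."""
    sup = grid.disk_mask(na)
    P = np.column_stack([np.ones(int(sup.sum())), grid.kxx[sup], grid.kyy[sup]])

    def strip(v):
        v = v[sup]
        return v - P @ np.linalg.lstsq(P, v, rcond=None)[0]

    return float(np.sqrt(np.mean((strip(estimate) - strip(truth)) ** 2)))
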