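"""Analytic pupil-phase retrieval from overlapping spectrum patches.

Two NA-matching measurements sample overlapping regions of the sample
spectrum.  On an overlap frequency ``u`` the two recovered patches are

    patch_i(u) = S(u) e^{i phi_ab(u + k_i)} e^{i c_i},
    patch_j(u) = S(u) e^{i phi_ab(u + k_j)} e^{i c_j},

so the phase of ``patch_i * conj(patch_j)`` cancels the sample term and leaves

    Delta_ij(u) = phi_ab(u + k_i) - phi_ab(u + k_j) + (c_i - c_j)   (mod 2pi),

one *linear* constraint on the pupil phase per overlap node, with one free
constant per patch (the Kramers-Kronig phase gauge).

Large aberrations — e.g. a defocus with a peak-to-valley of several pi —
make the raw differences wrap, and per-region 2-D unwrapping leaves one free
2*pi branch per patch pair whose cycle sums the patch constants cannot
absorb.  The solver therefore works with *wrapped first differences* of the
Delta maps along the two frequency axes: the patch constants drop out
exactly, no unwrapping is needed (local differences stay well inside one
wrap for any aberration sampled below pi per frequency bin), and the
unit-step structure keeps the node graph connected even when the ring shifts
share a common lattice factor.  The pixel-wise pupil phase is the weighted
least-squares solution of those difference equations plus a weak smoothness
penalty; per-patch constants are recovered afterwards by circular averaging.
The gauge (piston/tip/tilt: global phase and rigid image shift, unobservable
from intensity) is zeroed on the pupil disk; pupil nodes never covered by
any overlap are filled by Zernike extrapolation of the fitted modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr, spsolve

from .kk import SpectrumPatch
from .simulate import Pupil
from .zernike import ZernikeBasis

__all__ = [
    "PairOverlap", "OverlapEquationSet", "AberrationEstimate",
    "overlap_phase_difference", "build_overlap_equations",
    "solve_pupil_phase", "zernike_decompose",
]


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2 * np.pi)


@dataclass
class PairOverlap:
    """Wrapped phase-difference constraints from one patch pair.

    ``delta`` is defined on the whole geometric overlap ``overlap`` (the
    lens-shaped support intersection); ``mask`` marks the subset with usable
    amplitude that contributes least-squares constraints (``weight > 0``).
    """

    i: int
    j: int
    k_i: np.ndarray
    k_j: np.ndarray
    overlap: np.ndarray   # geometric support intersection (2-D bool)
    mask: np.ndarray      # overlap nodes with usable amplitude (2-D bool)
    delta: np.ndarray     # wrapped phase difference in (-pi, pi] (2-D)
    weight: np.ndarray    # min-amplitude weights, max-normalized (2-D)

    @property
    def n_constraints(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapEquationSet:
    """All pairwise constraints feeding one pupil-phase solve."""

    pairs: list[PairOverlap]
    n_patches: int
    labels: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AberrationEstimate:
    """Retrieved pupil phase, gauge-fixed, with per-patch constants.

    ``phase`` is the full-grid aberration map (radians, zero outside the
    disk) with piston/tip/tilt removed; ``constants`` maps patch labels to
    the per-measurement global phases; ``covered`` marks pupil nodes that
    were directly constrained (the rest are Zernike extrapolations);
    ``residual_rms`` is the weighted RMS misfit of the original wrapped
    constraints, in radians.
    """

    phase: np.ndarray
    constants: dict
    residual_rms: float
    zernike_coeffs: np.ndarray
    covered: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def phase_at(self, support: np.ndarray) -> np.ndarray:
        return np.where(support, self.phase, 0.0)


def overlap_phase_difference(patch_i: SpectrumPatch, patch_j: SpectrumPatch,
                             noise_floor: float = 1e-3,
                             i: int = 0, j: int = 1) -> PairOverlap:
    """Wrapped phase differences on the overlap of two spectrum patches.

    Nodes where either patch amplitude falls below ``noise_floor`` times that
    patch's peak are dropped (weight 0); remaining weights are the minimum of
    the two normalized amplitudes.  An empty overlap yields an empty mask.
    """
    amp_i, amp_j = patch_i.amplitude, patch_j.amplitude
    overlap = patch_i.support & patch_j.support
    ok = overlap & (amp_i > noise_floor * amp_i.max()) \
                 & (amp_j > noise_floor * amp_j.max())
    prod = patch_i.values * np.conj(patch_j.values)
    delta = np.where(overlap, np.angle(prod), 0.0)
    wmax = max(amp_i.max(), amp_j.max())
    weight = np.where(ok, np.minimum(amp_i, amp_j) / wmax, 0.0)
    return PairOverlap(i, j, patch_i.source_k, patch_j.source_k,
                       overlap, ok, delta, weight)


def build_overlap_equations(patches: list[SpectrumPatch], pupil: Pupil,
                            min_overlap_frac: float = 0.05,
                            noise_floor: float = 1e-3) -> OverlapEquationSet:
    """Constraints from every patch pair whose support overlap covers at
    least ``min_overlap_frac`` of the CTF disk (small overlaps contribute
    ill-conditioned equations)."""
    disk_area = int(patches[0].grid.disk_mask(pupil.na).sum())
    pairs = []
    for a in range(len(patches)):
        for b in range(a + 1, len(patches)):
            ov = patches[a].support & patches[b].support
            if ov.sum() < min_overlap_frac * disk_area:
                continue
            po = overlap_phase_difference(patches[a], patches[b],
                                          noise_floor, i=a, j=b)
            if po.n_constraints:
                pairs.append(po)
    labels = [p.label if p.label is not None else idx
              for idx, p in enumerate(patches)]
    return OverlapEquationSet(pairs, len(patches), labels)


def _connected_components(n: int, edges) -> list[set[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: dict[int, set[int]] = {}
    for x in range(n):
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def _despike_2pi(phase: np.ndarray, support: np.ndarray,
                 sizes=(5, 9, 15)) -> np.ndarray:
    """Snap 2*pi-offset node clusters back toward the local median.

    The wrapped absolute constraints are blind to a 2*pi offset of a node,
    so small clusters pinned on the wrong branch survive the solve (their
    wrapped residual is zero; only the weak smoothness penalty opposes
    them).  The pupil phase is physically smooth at the node scale, so any
    node sitting a near-multiple of 2*pi away from its neighborhood median
    is branch-corrected; increasing window sizes catch clusters larger than
    half the smallest window.
    """
    from scipy.ndimage import distance_transform_edt, median_filter

    out = phase.copy()
    for size in sizes:
        filled = out.copy()
        if (~support).any():
            _, (iy, ix) = distance_transform_edt(~support, return_indices=True)
            filled[~support] = out[iy[~support], ix[~support]]
        med = median_filter(filled, size=size)
        jumps = np.round((out - med) / (2 * np.pi))
        out = out - 2 * np.pi * jumps * support
    return out


def _lsq_solve(A: sp.spmatrix, b: np.ndarray, damp: float) -> np.ndarray:
    """Exact damped least squares via the sparse normal equations."""
    AtA = (A.T @ A).tocsc()
    AtA = AtA + (damp ** 2) * sp.identity(A.shape[1], format="csc")
    return spsolve(AtA, A.T @ b)


def _pair_shift_bins(p: PairOverlap, dk: float):
    bi = np.round(np.asarray(p.k_i) / dk).astype(int)   # (bx, by)
    bj = np.round(np.asarray(p.k_j) / dk).astype(int)
    return bi, bj


def solve_pupil_phase(eqs: OverlapEquationSet, pupil: Pupil,
                      regularization: float = 1e-4,
                      smoothing: float = 1e-2,
                      n_zernike_fill: int = 21,
                      camera_grid=None) -> AberrationEstimate:
    """Weighted least-squares solve for the pupil phase and patch constants.

    Assembles the wrapped-first-difference equations

        phi(a+e) - phi(a) - phi(b+e) + phi(b) = wrap(Delta(u+e) - Delta(u)),
        a = u + k_i,  b = u + k_j,  e in {x-step, y-step},

    (the per-patch constants cancel in the differencing) and solves them with
    LSMR plus a Tikhonov damp (``regularization``) and a weak first-difference
    smoothness penalty between adjacent covered disk nodes (``smoothing``,
    relative to the median constraint weight).  A robust second pass zeroes
    the weight of constraints that disagree with the first solution by more
    than 1 radian (isolated branch/noise errors).  Piston/tip/tilt are then
    removed, uncovered nodes are Zernike-extrapolated, and the per-patch
    constants are estimated by weighted circular means of the original
    wrapped constraints given the solved phase.

    ``camera_grid`` names the grid the patches live on when it differs from
    ``pupil.grid`` (the frequency step must agree).
    """
    grid = camera_grid if camera_grid is not None else pupil.grid
    if abs(grid.dk - pupil.grid.dk) > 1e-9 * pupil.grid.dk:
        raise ValueError("patch grid and pupil grid must share one frequency step")
    support = grid.disk_mask(pupil.na)
    n = support.shape[0]
    node_id = np.full(support.shape, -1, dtype=int)
    node_id[support] = np.arange(int(support.sum()))
    n_nodes = int(support.sum())
    n_patch = eqs.n_patches

    # connectivity of the patch-overlap graph
    edges = [(p.i, p.j) for p in eqs.pairs if p.weight.max() > 0]
    comps = _connected_components(n_patch, edges)
    if len(comps) > 1:
        named = [sorted(eqs.labels[i] for i in c) for c in comps]
        raise ValueError(f"patch overlap graph is disconnected: components {named}")
    if not any(p.mask.any() for p in eqs.pairs):
        raise ValueError("insufficient data: all overlap weights are zero")

    dk = grid.dk
    cols_list, rhs_list, w_list = [], [], []
    for p in eqs.pairs:
        if not p.mask.any():
            continue
        bi, bj = _pair_shift_bins(p, dk)
        for dy, dx in ((0, 1), (1, 0)):
            here = p.mask & np.roll(p.mask, (-dy, -dx), axis=(0, 1))
            if dy:
                here[-1, :] = False
            if dx:
                here[:, -1] = False
            ry, rx = np.nonzero(here)
            if len(ry) == 0:
                continue
            rhs = wrap_angle(p.delta[ry + dy, rx + dx] - p.delta[ry, rx])
            w = np.minimum(p.weight[ry, rx], p.weight[ry + dy, rx + dx])
            ids = np.stack([
                node_id[(ry + dy + bi[1]) % n, (rx + dx + bi[0]) % n],
                node_id[(ry + bi[1]) % n, (rx + bi[0]) % n],
                node_id[(ry + dy + bj[1]) % n, (rx + dx + bj[0]) % n],
                node_id[(ry + bj[1]) % n, (rx + bj[0]) % n],
            ], axis=1)
            inb = ((ry + dy + bi[1] < n) & (rx + dx + bi[0] < n)
                   & (ry + dy + bj[1] < n) & (rx + dx + bj[0] < n)
                   & (ry + bi[1] >= 0) & (rx + bi[0] >= 0)
                   & (ry + bj[1] >= 0) & (rx + bj[0] >= 0))
            good = inb & np.all(ids >= 0, axis=1) & (w > 0)
            cols_list.append(ids[good])
            rhs_list.append(rhs[good])
            w_list.append(w[good])
    cols4 = np.concatenate(cols_list) if cols_list else np.empty((0, 4), int)
    d_all = np.concatenate(rhs_list) if rhs_list else np.empty(0)
    w_all = np.concatenate(w_list) if w_list else np.empty(0)
    n_eq = len(d_all)
    if n_eq == 0:
        # degenerate spectra (e.g. a uniform sample: delta patches) carry no
        # pupil-phase information beyond DC; report a flat pupil and recover
        # only the per-patch constants.
        warnings.warn("no usable phase-difference constraints; assuming a "
                      "flat pupil", stacklevel=2)
        phase = np.zeros(support.shape)
        consts, residual_rms = _estimate_constants(eqs, phase, node_id,
                                                   dk, n)
        constants = {eqs.labels[i]: float(consts[i]) for i in range(n_patch)}
        return AberrationEstimate(
            phase, constants, residual_rms, np.zeros(n_zernike_fill),
            np.zeros(support.shape, dtype=bool),
            {"n_equations": 0, "n_nodes": n_nodes, "degenerate": True})
    w_all = w_all / np.median(w_all)  # damp is relative to unit weight scale

    covered_nodes = np.zeros(n_nodes, dtype=bool)
    covered_nodes[cols4.ravel()] = True
    cov_map = np.zeros(support.shape, dtype=bool)
    cov_map[support] = covered_nodes

    # smoothness rows between adjacent covered disk nodes
    lam = smoothing
    sm_a, sm_b = [], []
    for dy, dx in ((0, 1), (1, 0)):
        here = cov_map & np.roll(cov_map, (-dy, -dx), axis=(0, 1))
        if dy:
            here[-1, :] = False
        if dx:
            here[:, -1] = False
        hy, hx = np.nonzero(here)
        sm_a.append(node_id[hy, hx])
        sm_b.append(node_id[hy + dy, hx + dx])
    sm_a = np.concatenate(sm_a)
    sm_b = np.concatenate(sm_b)
    n_sm = len(sm_a)

    signs = np.array([1.0, -1.0, -1.0, 1.0])

    def assemble(w):
        eq = np.repeat(np.arange(n_eq), 4)
        vals = (w[:, None] * signs[None, :]).ravel()
        sm_eq = n_eq + np.arange(n_sm)
        A = sp.coo_matrix(
            (np.concatenate([vals, np.full(n_sm, lam), np.full(n_sm, -lam)]),
             (np.concatenate([eq, sm_eq, sm_eq]),
              np.concatenate([cols4.ravel(), sm_a, sm_b]))),
            shape=(n_eq + n_sm, n_nodes)).tocsr()
        return A

    def solve(w):
        A = assemble(w)
        b = np.concatenate([w * d_all, np.zeros(n_sm)])
        x = _lsq_solve(A, b, regularization)
        return x, (A @ x - b)[:n_eq]

    x0, resid = solve(w_all)
    node_err = np.divide(resid, w_all, out=np.zeros_like(resid),
                         where=w_all > 0)
    bad = np.abs(node_err) > 1.0
    n_trim = int(bad.sum())
    if n_trim:
        w_all = np.where(bad, 0.0, w_all)
        x0, resid = solve(w_all)
    phase = np.zeros(support.shape)
    phase[support] = x0

    # bootstrap constants, then Gauss-Newton refinement on the *absolute*
    # wrapped constraints: the difference system determines smooth (low-
    # order) modes weakly, the absolute system pins them once wraps are
    # resolved by proximity to the bootstrap solution.
    consts, _ = _estimate_constants(eqs, phase, node_id, dk, n)
    refiner = _AbsoluteRefiner(eqs, phase, consts, support, node_id, dk, n,
                               regularization, lam, sm_a, sm_b)
    refine_diag = {}
    for _ in range(8):
        phase, consts, refine_diag = refiner.step(phase, consts)
        if refine_diag.get("update_rms", 0.0) < 1e-4:
            break
    # repair branch-locked node clusters, then let the data re-settle
    phase = _despike_2pi(phase, support)
    for _ in range(3):
        phase, consts, refine_diag = refiner.step(phase, consts)
        if refine_diag.get("update_rms", 0.0) < 1e-4:
            break
    phase = _despike_2pi(phase, support)
    phi_nodes = phase[support]

    # Zernike fit on covered nodes; extrapolate the rest
    rho = np.clip(grid.wavelength * grid.kr / pupil.na, 0.0, 1.0)
    theta = np.arctan2(grid.kyy, grid.kxx)
    basis = ZernikeBasis(support, rho, theta, n_zernike_fill)
    zc = basis.fit(phi_nodes[covered_nodes], covered_nodes)
    phi_nodes = np.where(covered_nodes, phi_nodes, basis.matrix @ zc)

    # gauge: remove piston/tip/tilt (plane fit over the disk); the removed
    # plane is absorbed into the constants (phi + a + b.p, c - a - b.k_i is
    # the unobservable family)
    px = grid.kxx[support]
    py = grid.kyy[support]
    P = np.column_stack([np.ones(n_nodes), px, py])
    coef, *_ = np.linalg.lstsq(P, phi_nodes, rcond=None)
    phi_nodes = phi_nodes - P @ coef
    ks_of = {}
    for p in eqs.pairs:
        ks_of[p.i] = p.k_i
        ks_of[p.j] = p.k_j
    for i in range(n_patch):
        if i in ks_of:
            consts[i] += coef[0] + coef[1] * ks_of[i][0] + coef[2] * ks_of[i][1]

    phase = np.zeros(support.shape)
    phase[support] = phi_nodes
    residual_rms = _wrapped_residual_rms(eqs, phase, consts, dk, n)

    covered = np.zeros(support.shape, dtype=bool)
    covered[support] = covered_nodes
    z_report = basis.decompose(phase)
    constants = {eqs.labels[i]: float(consts[i]) for i in range(n_patch)}
    diag = {"n_equations": n_eq, "n_nodes": n_nodes,
            "n_trimmed": n_trim, "refine": refine_diag,
            "coverage_fraction": float(covered_nodes.mean())}
    return AberrationEstimate(phase, constants, residual_rms, z_report,
                              covered, diag)


def _estimate_constants(eqs: OverlapEquationSet, phase: np.ndarray,
                        node_id: np.ndarray, dk: float, n: int):
    """Per-patch constants from c_i - c_j offsets, given the solved phase.

    Offsets are weighted circular means of ``Delta - (phi(a) - phi(b))`` per
    pair; the constants follow from a spanning-tree walk plus one linear
    refinement with branch-corrected offsets.  Their common level (the global
    phase) is left at the tree root's zero.
    """
    n_patch = eqs.n_patches
    offs, wts, pairs_idx = [], [], []
    for p in eqs.pairs:
        if not p.mask.any():
            continue
        bi, bj = _pair_shift_bins(p, dk)
        ry, rx = np.nonzero(p.mask)
        ay, ax = (ry + bi[1]) % n, (rx + bi[0]) % n
        by_, bx_ = (ry + bj[1]) % n, (rx + bj[0]) % n
        model = phase[ay, ax] - phase[by_, bx_]
        w = p.weight[ry, rx]
        z = np.sum(w * np.exp(1j * (p.delta[ry, rx] - model)))
        if np.abs(z) == 0:
            continue
        offs.append(np.angle(z))
        wts.append(np.abs(z))
        pairs_idx.append((p.i, p.j))
    consts = np.zeros(n_patch)
    seen = {pairs_idx[0][0]} if pairs_idx else set(range(n_patch))
    # spanning-tree walk
    changed = True
    while changed:
        changed = False
        for (i, j), off in zip(pairs_idx, offs):
            if i in seen and j not in seen:
                consts[j] = consts[i] - off
                seen.add(j)
                changed = True
            elif j in seen and i not in seen:
                consts[i] = consts[j] + off
                seen.add(i)
                changed = True
    # one LS refinement with branch-corrected offsets
    if pairs_idx:
        rows, cols, vals, rhs = [], [], [], []
        for r, ((i, j), off, w) in enumerate(zip(pairs_idx, offs, wts)):
            off_c = off + 2 * np.pi * np.round(
                (consts[i] - consts[j] - off) / (2 * np.pi))
            rows += [r, r]
            cols += [i, j]
            vals += [w, -w]
            rhs.append(w * off_c)
        A = sp.coo_matrix((vals, (rows, cols)),
                          shape=(len(pairs_idx), n_patch)).tocsr()
        sol = lsmr(A, np.array(rhs), damp=1e-8)
        consts = sol[0]

    return consts, _wrapped_residual_rms(eqs, phase, consts, dk, n)


def _wrapped_residual_rms(eqs: OverlapEquationSet, phase: np.ndarray,
                          consts: np.ndarray, dk: float, n: int) -> float:
    """Weighted RMS of the wrapped misfit of the absolute constraints."""
    num = den = 0.0
    for p in eqs.pairs:
        if not p.mask.any():
            continue
        bi, bj = _pair_shift_bins(p, dk)
        ry, rx = np.nonzero(p.mask)
        ay, ax = (ry + bi[1]) % n, (rx + bi[0]) % n
        by_, bx_ = (ry + bj[1]) % n, (rx + bj[0]) % n
        model = phase[ay, ax] - phase[by_, bx_] + consts[p.i] - consts[p.j]
        err = wrap_angle(p.delta[ry, rx] - model)
        w = p.weight[ry, rx]
        num += float(np.sum((w * err) ** 2))
        den += float(np.sum(w ** 2))
    return float(np.sqrt(num / den)) if den else 0.0


class _AbsoluteRefiner:
    """Gauss-Newton iterations on the absolute wrapped constraints.

    Each step solves for updates (delta_phi, delta_c) of
    ``phi(a) - phi(b) + c_i - c_j = Delta`` with the residual re-wrapped
    around the current model (branch-safe when the model is within ~pi).
    The system matrix is fixed at construction (weights frozen, outliers
    with wrapped misfit > 1 rad against the bootstrap zeroed), so the
    sparse node-block normal matrix is factorized once and the per-patch
    constant columns — dense in the normal equations — are eliminated by a
    Schur complement; every subsequent step is two cheap triangular solves.
    """

    def __init__(self, eqs: OverlapEquationSet, phase: np.ndarray,
                 consts: np.ndarray, support: np.ndarray,
                 node_id: np.ndarray, dk: float, n: int,
                 regularization: float, lam: float,
                 sm_a: np.ndarray, sm_b: np.ndarray) -> None:
        from scipy.sparse.linalg import splu

        self.support = support
        self.n = n
        n_nodes = int(support.sum())
        n_patch = len(consts)
        self.n_nodes, self.n_patch = n_nodes, n_patch
        a_ids, b_ids, ii, jj, ww = [], [], [], [], []
        self._rows = []   # (pair, ry, rx, a_id, b_id) for rhs recomputation
        for p in eqs.pairs:
            if not p.mask.any():
                continue
            bi, bj = _pair_shift_bins(p, dk)
            ry, rx = np.nonzero(p.mask)
            ay, ax = ry + bi[1], rx + bi[0]
            by_, bx_ = ry + bj[1], rx + bj[0]
            inb = ((ay >= 0) & (ay < n) & (ax >= 0) & (ax < n)
                   & (by_ >= 0) & (by_ < n) & (bx_ >= 0) & (bx_ < n))
            a_id = np.where(inb, node_id[ay % n, ax % n], -1)
            b_id = np.where(inb, node_id[by_ % n, bx_ % n], -1)
            good = (a_id >= 0) & (b_id >= 0)
            ry, rx = ry[good], rx[good]
            a_id, b_id = a_id[good], b_id[good]
            model = phase.reshape(-1)[(ry + bi[1]) * n + (rx + bi[0])] \
                - phase.reshape(-1)[(ry + bj[1]) * n + (rx + bj[0])] \
                + consts[p.i] - consts[p.j]
            r0 = wrap_angle(p.delta[ry, rx] - model)
            w = np.where(np.abs(r0) > 1.0, 0.0, p.weight[ry, rx])
            self._rows.append((p, ry, rx, a_id, b_id))
            a_ids.append(a_id)
            b_ids.append(b_id)
            ii.append(np.full(len(ry), p.i))
            jj.append(np.full(len(ry), p.j))
            ww.append(w)
        a_ids = np.concatenate(a_ids)
        b_ids = np.concatenate(b_ids)
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        ww = np.concatenate(ww)
        pos = ww > 0
        self.ok = pos.any()
        if not self.ok:
            return
        ww = ww / np.median(ww[pos])
        self.w = ww
        self.n_trim = int((~pos).sum())
        n_eq = len(ww)
        self.n_eq = n_eq
        eq = np.arange(n_eq)
        n_sm = len(sm_a)
        sm_eq = n_eq + np.arange(n_sm)
        Aphi = sp.coo_matrix(
            (np.concatenate([ww, -ww, np.full(n_sm, lam), np.full(n_sm, -lam)]),
             (np.concatenate([eq, eq, sm_eq, sm_eq]),
              np.concatenate([a_ids, b_ids, sm_a, sm_b]))),
            shape=(n_eq + n_sm, n_nodes)).tocsr()
        Ac = sp.coo_matrix(
            (np.concatenate([ww, -ww]),
             (np.concatenate([eq, eq]), np.concatenate([ii, jj]))),
            shape=(n_eq + n_sm, n_patch)).tocsr()
        damp2 = regularization ** 2
        P = (Aphi.T @ Aphi).tocsc() + damp2 * sp.identity(n_nodes, format="csc")
        self._Aphi, self._Ac = Aphi, Ac
        self._lu = splu(P)
        C = np.asarray((Aphi.T @ Ac).todense())
        D = np.asarray((Ac.T @ Ac).todense()) + damp2 * np.eye(n_patch)
        PinvC = np.column_stack([self._lu.solve(C[:, j])
                                 for j in range(n_patch)])
        self._C, self._PinvC = C, PinvC
        self._S = D - C.T @ PinvC

    def step(self, phase: np.ndarray, consts: np.ndarray):
        if not self.ok:
            return phase, consts, {"abs_equations": 0, "update_rms": 0.0}
        n = self.n
        rr = np.empty(self.n_eq)
        pos = 0
        flat = phase.reshape(-1)
        for p, ry, rx, a_id, b_id in self._rows:
            m = len(ry)
            model = self._phi_of(flat, a_id) - self._phi_of(flat, b_id) \
                + consts[p.i] - consts[p.j]
            rr[pos:pos + m] = wrap_angle(p.delta[ry, rx] - model)
            pos += m
        b = np.concatenate([self.w * rr, np.zeros(self._Aphi.shape[0] - self.n_eq)])
        g1 = self._Aphi.T @ b
        g2 = self._Ac.T @ b
        y1 = self._lu.solve(g1)
        dc = np.linalg.solve(self._S, g2 - self._C.T @ y1)
        dphi = y1 - self._PinvC @ dc
        new_phase = phase.copy()
        new_phase[self.support] = phase[self.support] + dphi
        diag = {"abs_equations": self.n_eq, "abs_trimmed": self.n_trim,
                "update_rms": float(np.sqrt(np.mean(dphi ** 2)))}
        return new_phase, consts + dc, diag

    def _phi_of(self, flat_phase: np.ndarray, node_ids: np.ndarray):
        # phase values at disk node ids
        if not hasattr(self, "_node_pos"):
            sy, sx = np.nonzero(self.support)
            self._node_pos = sy * self.n + sx
        return flat_phase[self._node_pos[node_ids]]


def zernike_decompose(phase: np.ndarray, pupil: Pupil, n_modes: int,
                      camera_grid=None) -> tuple[np.ndarray, float]:
    """Project a pupil phase map onto the discrete-orthonormal Zernike basis.

    Returns ``(coeffs, residual)`` where ``coeffs[j-1]`` is the Noll-``j``
    coefficient in radians and ``residual`` the relative L2 remainder on the
    disk after keeping ``n_modes`` modes.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    grid = camera_grid if camera_grid is not None else pupil.grid
    support = grid.disk_mask(pupil.na)
    rho = np.clip(grid.wavelength * grid.kr / pupil.na, 0.0, 1.0)
    theta = np.arctan2(grid.kyy, grid.kxx)
    basis = ZernikeBasis(support, rho, theta, n_modes)
    coeffs = basis.decompose(phase)
    return coeffs, basis.residual(phase, coeffs)
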