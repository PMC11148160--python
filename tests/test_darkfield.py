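"""Darkfield spectrum extension: correlations, region logic, linear solve."""

import warnings

import numpy as np
import pytest

from apic import (FrequencyGrid, Pupil, PriorSpectrum,
                  make_smooth_phantom, simulate_measurement)
from apic._fft import ft
from apic.darkfield import (KnownUnknownSplit,
                            exclusive_cross_region, order_darkfield,
                            residual_after_known_autocorr, solve_unknown,
                            split_known_unknown, update_prior, xcorr,
                            _cross_operator)
from apic.simulate import IlluminationGeometry

from conftest import NA, WL


def make_setup(N=24, R=5, M=48, seed=3, band=15):
    """Camera grid N with pupil radius R bins; simulation/prior grid M."""
    fine = FrequencyGrid.for_pupil_radius(M, NA, WL, R)
    cam = FrequencyGrid(N, fine.pixel_size * M / N, WL)
    samp = make_smooth_phantom(M, fine.pixel_size, band_limit_bins=band // 2,
                               seed=seed)
    pupil = Pupil.ideal(fine, NA)
    S_cam = ft(samp.field) * (N ** 2 / M ** 2)  # camera-unit spectrum
    return fine, cam, samp, pupil, S_cam


def truth_prior(fine, S_cam, na_prior):
    m = fine.disk_mask(na_prior)
    return PriorSpectrum(np.where(m, S_cam, 0), m.copy(), m.astype(int), fine)


def test_xcorr_matches_brute_force():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
    B = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
    C = xcorr(A, B)
    for qy in range(-3, 4):
        for qx in range(-3, 4):
            s = sum(np.conj(A[y, x]) * B[y + qy, x + qx]
                    for y in range(4) for x in range(4)
                    if 0 <= y + qy < 4 and 0 <= x + qx < 4)
            assert abs(C[3 + qy, 3 + qx] - s) < 1e-10


def test_cross_operator_adjoint():
    fine, cam, samp, pupil, S_cam = make_setup()
    prior = truth_prior(fine, S_cam, 2 * NA)
    k_i = np.array([10 * fine.dk, 0.0])
    split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
    region = exclusive_cross_region(split)
    op, _ = _cross_operator(split, region, split.U_support)
    rng = np.random.default_rng(1)
    v = rng.normal(size=op.shape[1]) + 1j * rng.normal(size=op.shape[1])
    r = rng.normal(size=op.shape[0]) + 1j * rng.normal(size=op.shape[0])
    lhs = np.vdot(r, op.matvec(v))
    rhs = np.vdot(op.rmatvec(r), v)
    assert abs(lhs - rhs) < 1e-8 * (abs(lhs) + 1)


class TestOrderDarkfield:
    def test_single_led(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        geom = IlluminationGeometry(np.array([[2 * NA, 0.0]])).classify(
            NA, 2 * fine.dk * WL)
        assert list(order_darkfield(geom, prior, NA)) == [0]

    def test_inner_ring_first(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        sines = []
        for r in (2.0, 1.5):  # outer listed first on purpose
            for a in np.linspace(0, 2 * np.pi, 4, endpoint=False):
                sines.append([r * NA * np.cos(a), r * NA * np.sin(a)])
        geom = IlluminationGeometry(np.array(sines)).classify(
            NA, 2 * fine.dk * WL)
        order = order_darkfield(geom, prior, NA)
        assert set(order[:4]) == {4, 5, 6, 7}  # the inner ring

    def test_tie_broken_by_azimuth(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        sines = np.array([[0.0, 1.5 * NA], [1.5 * NA, 0.0]])
        geom = IlluminationGeometry(sines).classify(NA, 2 * fine.dk * WL)
        a = order_darkfield(geom, prior, NA)
        b = order_darkfield(geom, prior, NA)
        assert list(a) == list(b) == [1, 0]  # azimuth 0 before pi/2


class TestSplitKnownUnknown:
    def test_partition_covers_disk(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        split = split_known_unknown(prior, np.array([10 * fine.dk, 0.0]),
                                    pupil, None, camera_grid=cam)
        disk = split.disk_support
        assert not (split.K_support & split.U_support).any()
        assert (split.K_support | split.U_support).sum() == disk.sum()
        assert 0 < split.known_fraction < 1

    def test_fully_known_is_redundant(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 3 * NA)
        split = split_known_unknown(prior, np.array([10 * fine.dk, 0.0]),
                                    pupil, None, camera_grid=cam)
        assert split.redundant

    def test_no_anchor_rejected(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        m = fine.disk_mask(0.2 * NA)
        prior = PriorSpectrum(np.where(m, S_cam, 0), m.copy(),
                              m.astype(int), fine)
        with pytest.raises(ValueError, match="anchor"):
            split_known_unknown(prior, np.array([10 * fine.dk, 0.0]),
                                pupil, None, camera_grid=cam)


class TestResidual:
    def test_fully_known_complete_subtraction(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 3 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        R, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        FTI = np.abs(ft(I)).max() * cam.shape ** 2
        assert np.abs(R).max() < 1e-10 * FTI

    def test_hermitian_symmetry(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        R, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        assert np.allclose(R, np.conj(R[::-1, ::-1]),
                           atol=1e-9 * np.abs(R).max())

    def test_matches_brute_force_correlations(self):
        """R equals the explicitly-enumerated sum of the three remaining
        correlation products (O(N^4) oracle on a 16^2 box)."""
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        R, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        D = split.box
        r0, c0 = split.origin
        U = np.zeros((D, D), complex)
        uy, ux = np.nonzero(split.U_support)
        U[uy, ux] = S_cam[r0 + uy, c0 + ux]
        K = split.K

        def brute(A, B):
            out = np.zeros((2 * D - 1, 2 * D - 1), complex)
            for qy in range(-D + 1, D):
                for qx in range(-D + 1, D):
                    s = 0
                    for y in range(D):
                        for x in range(D):
                            y2, x2 = y + qy, x + qx
                            if 0 <= y2 < D and 0 <= x2 < D:
                                s += np.conj(A[y, x]) * B[y2, x2]
                    out[D - 1 + qy, D - 1 + qx] = s
            return out

        pred = brute(K, U) + brute(U, K) + brute(U, U)
        assert np.allclose(R, pred, atol=1e-8 * np.abs(pred).max())

    def test_gain_calibration_recovers_true_gain(self):
        fine, cam, samp, pupil, S_cam = make_setup(N=32, R=6, M=64)
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = 1.7 * simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            R, g = residual_after_known_autocorr(I, split, cam, gain=None)
        assert g == pytest.approx(1.7, rel=1e-6)


class TestExclusiveRegion:
    def test_empty_unknown_empty_region(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 3 * NA)
        split = split_known_unknown(prior, np.array([10 * fine.dk, 0.0]),
                                    pupil, None, camera_grid=cam)
        region = exclusive_cross_region(split)
        assert region.n_lags == 0

    def test_one_dimensional_interval_lags(self):
        """K on {0..3}, U on {4..7} (one row): K*U spans lags 1..7, U*U
        spans -3..3, U*K spans -7..-1, K*K spans -3..3; the exclusive lags
        are exactly 4..7."""
        D = 8
        K_sup = np.zeros((D, D), bool)
        U_sup = np.zeros((D, D), bool)
        K_sup[0, 0:4] = True
        U_sup[0, 4:8] = True
        split = KnownUnknownSplit(
            np.array([0.0, 0.0]), (0, 0), D,
            np.where(K_sup, 1.0 + 0j, 0), K_sup, U_sup,
            np.ones((D, D), complex), 0.5)
        region = exclusive_cross_region(split, sensitivity_floor=0.0)
        lags = {(int(q[0]), int(q[1])) for q in region.lags}
        assert lags == {(0, 4), (0, 5), (0, 6), (0, 7)}

    def test_region_grows_with_known_support(self):
        """More known spectrum => at least as many lags where the cross
        term K*U is separable from the unknown-only terms U*U and U*K
        (checked over nested priors).  The returned region additionally
        masks lags inside supp(K*K) — where the subtraction, not the
        geometry, removes the known contribution — and that subset is not
        monotone."""
        from apic.darkfield import _corr_supports

        fine, cam, samp, pupil, S_cam = make_setup()
        k_i = np.array([10 * fine.dk, 0.0])
        sizes = []
        for na_prior in (1.6 * NA, 2 * NA, 2.4 * NA):
            prior = truth_prior(fine, S_cam, na_prior)
            split = split_known_unknown(prior, k_i, pupil, None,
                                        camera_grid=cam)
            sup = _corr_supports(split)
            sizes.append(int((sup["KU"] & ~sup["UU"] & ~sup["UK"]).sum()))
        assert sizes[0] <= sizes[1] <= sizes[2]


class TestSolveUnknown:
    def test_exact_recovery_with_exact_prior(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        R, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        region = exclusive_cross_region(split)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_unknown(split, region, R, regularization=1e-8)
        dy, dx = np.nonzero(sol.determined)
        r0, c0 = split.origin
        truth = S_cam[r0 + dy, c0 + dx]
        err = np.linalg.norm(sol.S_hat[dy, dx] - truth) / np.linalg.norm(truth)
        assert err < 1e-6

    def test_staged_matches_dense_brute_force(self):
        """The staged solve agrees with an independently-built dense least
        squares over the exclusive region (same Tikhonov damp) to 1e-6."""
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        R, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        region = exclusive_cross_region(split)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            staged = solve_unknown(split, region, R, regularization=1e-4)
            # force the iterative path on the same system
            iterative = solve_unknown(split, region, R, regularization=1e-4,
                                      dense_limit=0)
        # independent dense construction by explicit loops
        D = split.box
        uy, ux = np.nonzero(split.U_support)
        lags = region.lags
        A = np.zeros((len(lags), len(uy)), complex)
        for r, (qy, qx) in enumerate(lags):
            for cidx, (y, x) in enumerate(zip(uy, ux)):
                yy, xx = y - qy, x - qx
                if 0 <= yy < D and 0 <= xx < D and split.K_support[yy, xx]:
                    A[r, cidx] = np.conj(split.K[yy, xx])
        b = R[region.mask]
        damp = 1e-4 * float(region.sensitivity[region.mask].max())
        Aaug = np.vstack([A, damp * np.eye(len(uy))])
        x, *_ = np.linalg.lstsq(Aaug, np.concatenate([b, np.zeros(len(uy))]),
                                rcond=None)
        oracle = x * np.conj(split.phase[uy, ux])
        keep = staged.determined[uy, ux]
        scale = np.linalg.norm(oracle[keep])
        assert np.linalg.norm(staged.S_hat[uy, ux][keep] - oracle[keep]) \
            / scale < 1e-6
        assert np.linalg.norm(iterative.S_hat[uy, ux][keep] - oracle[keep]) \
            / scale < 1e-6

    def test_zero_measurement_gives_zero_unknown(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        region = exclusive_cross_region(split)
        R = np.zeros((2 * split.box - 1, 2 * split.box - 1), complex)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_unknown(split, region, R, regularization=1e-6)
        assert np.linalg.norm(sol.S_hat) < 1e-10


class TestUpdatePrior:
    def test_empty_solution_is_noop(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        from apic.darkfield import DarkfieldSolve
        D = split.box
        sol = DarkfieldSolve(np.zeros((D, D), complex),
                             np.zeros((D, D), bool), True)
        before = prior.known_mask.sum()
        update_prior(prior, split, sol)
        assert prior.known_mask.sum() == before

    def test_full_ring_reaches_three_na(self):
        """One full darkfield ring at illumination sine 2NA extends the
        known support to ~3 NA / wavelength."""
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        R_bins = fine.pupil_radius_bins(NA)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(2):
                for a in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                    p = np.round(2 * R_bins * np.array([np.cos(a), np.sin(a)]))
                    k_i = p * fine.dk
                    I = simulate_measurement(samp, k_i, pupil,
                                             out_shape=cam.shape)
                    try:
                        split = split_known_unknown(prior, k_i, pupil, None,
                                                    camera_grid=cam)
                    except ValueError:
                        continue
                    if split.redundant:
                        continue
                    Rm, g = residual_after_known_autocorr(I, split, cam,
                                                          gain=1.0)
                    region = exclusive_cross_region(split)
                    sol = solve_unknown(split, region, Rm)
                    if sol.ok:
                        update_prior(prior, split, sol)
        assert prior.support_radius_bins == pytest.approx(3 * R_bins, abs=1)

    def test_known_area_strictly_grows(self):
        fine, cam, samp, pupil, S_cam = make_setup()
        prior = truth_prior(fine, S_cam, 2 * NA)
        k_i = np.array([10 * fine.dk, 0.0])
        I = simulate_measurement(samp, k_i, pupil, out_shape=cam.shape)
        split = split_known_unknown(prior, k_i, pupil, None, camera_grid=cam)
        Rm, g = residual_after_known_autocorr(I, split, cam, gain=1.0)
        region = exclusive_cross_region(split)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_unknown(split, region, Rm)
        before = int(prior.known_mask.sum())
        update_prior(prior, split, sol)
        assert prior.known_mask.sum() > before
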