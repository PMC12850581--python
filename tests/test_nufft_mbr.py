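"""NUFFT operators, derivative operators, TGV denoising and the
model-based encoding operator: exactness, adjointness and null spaces."""

import numpy as np
import pytest

from cestll import mbr, phantom
from cestll import signal_model as sm
from cestll.nufft import (BatchedFrameNufft, KbNufft, direct_ndft,
                          radial_density_weights)


def _rand_img(n, seed=0, cplx=True):
    rng = np.random.default_rng(seed)
    img = rng.standard_normal((n, n))
    if cplx:
        img = img + 1j * rng.standard_normal((n, n))
    return img


def _ortho_fft(img):
    from scipy.fft import fft2, fftshift, ifftshift
    return fftshift(fft2(ifftshift(img), norm="ortho"))


def _grid_traj(n):
    k = np.arange(n) - n // 2
    kx, ky = np.meshgrid(k, k, indexing="ij")
    return np.stack([kx.ravel(), ky.ravel()], axis=1).astype(float)


class TestKbNufft:
    def test_on_grid_matches_ortho_fft(self):
        n = 16
        img = _rand_img(n)
        op = KbNufft(n, _grid_traj(n))
        ref = _ortho_fft(img).ravel()
        assert np.max(np.abs(op.forward(img) - ref)) < 1e-12 * np.abs(ref).max()

    def test_off_grid_matches_direct_ndft(self):
        n = 24
        rng = np.random.default_rng(3)
        traj = rng.uniform(-n / 2, n / 2 - 1e-9, size=(200, 2))
        img = _rand_img(n, seed=4)
        op = KbNufft(n, traj)
        ref = direct_ndft(img, traj)
        rel = np.abs(op.forward(img) - ref) / np.abs(ref).max()
        assert rel.max() < 1e-6

    def test_adjoint_identity(self):
        n = 12
        rng = np.random.default_rng(5)
        traj = rng.uniform(-n / 2, n / 2 - 1e-9, size=(90, 2))
        op = KbNufft(n, traj)
        x = _rand_img(n, seed=6)
        y = rng.standard_normal(90) + 1j * rng.standard_normal(90)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_batched_forward(self):
        n = 10
        rng = np.random.default_rng(7)
        traj = rng.uniform(-n / 2, n / 2 - 1e-9, size=(40, 2))
        op = KbNufft(n, traj)
        imgs = np.stack([_rand_img(n, seed=s) for s in range(3)])
        batch = op.forward(imgs)
        for i in range(3):
            assert np.allclose(batch[i], op.forward(imgs[i]), atol=1e-13)

    def test_out_of_box_trajectory_rejected(self):
        with pytest.raises(ValueError):
            KbNufft(8, np.array([[5.0, 0.0]]))

    def test_bad_traj_shape_rejected(self):
        with pytest.raises(ValueError):
            KbNufft(8, np.zeros((4, 3)))


class TestBatchedFrameNufft:
    def test_matches_per_frame_kbnufft(self):
        n = 16
        traj = phantom.golden_angle_trajectory(5, 3, n)
        op = BatchedFrameNufft(n, traj, os=2.0, width=8, dtype=np.complex128)
        imgs = np.stack([_rand_img(n, seed=s) for s in range(5)])
        out = op.forward(imgs)
        for f in range(5):
            ref = KbNufft(n, traj[f]).forward(imgs[f])
            assert np.max(np.abs(out[f] - ref)) < 1e-10 * np.abs(ref).max()

    def test_adjoint_identity(self):
        n = 12
        traj = phantom.golden_angle_trajectory(4, 2, n)
        op = BatchedFrameNufft(n, traj, os=2.0, width=8, dtype=np.complex128)
        rng = np.random.default_rng(11)
        x = rng.standard_normal((4, n, n)) + 1j * rng.standard_normal((4, n, n))
        y = (rng.standard_normal((4, traj.shape[1]))
             + 1j * rng.standard_normal((4, traj.shape[1])))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_leading_batch_axis(self):
        n = 10
        traj = phantom.golden_angle_trajectory(3, 2, n)
        op = BatchedFrameNufft(n, traj, os=2.0, width=8, dtype=np.complex128)
        rng = np.random.default_rng(12)
        x = rng.standard_normal((2, 3, n, n)) + 0j
        out = op.forward(x)
        assert out.shape == (2, 3, traj.shape[1])
        assert np.allclose(out[1], op.forward(x[1]), atol=1e-12)


class TestDensityWeights:
    def test_ramp_properties(self):
        traj = phantom.golden_angle_trajectory(1, 1, 32)[0]
        w = radial_density_weights(traj)
        assert w.max() == pytest.approx(1.0)
        assert np.all(w > 0)
        r = np.hypot(traj[:, 0], traj[:, 1])
        order = np.argsort(r)
        assert np.all(np.diff(w[order]) >= -1e-12)


class TestDerivativeOperators:
    def test_grad_div_adjoint(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 9, 8))
        p = rng.standard_normal((2, 3, 9, 8))
        lhs = np.sum(mbr.grad(x) * p)
        rhs = np.sum(x * mbr.neg_div(p))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_sym_grad_adjoint(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((2, 3, 7, 6))
        q = rng.standard_normal((3, 3, 7, 6))
        lhs = np.sum(mbr.sym_grad(v) * q)
        rhs = np.sum(v * mbr.sym_grad_adjoint(q))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_grad_of_constant_is_zero(self):
        assert np.all(mbr.grad(np.full((5, 5), 3.0)) == 0)

    def test_joint_ball_project(self):
        rng = np.random.default_rng(2)
        p = rng.standard_normal((2, 3, 6, 6)) * 10
        proj = mbr._joint_ball_project(p, 1.0)
        norms = np.sqrt((proj ** 2).sum(axis=(0, 1)))
        assert np.all(norms <= 1.0 + 1e-12)
        small = mbr._joint_ball_project(p * 1e-6, 1.0)
        assert np.allclose(small, p * 1e-6)


class TestTgvDenoise:
    def test_affine_null_space(self):
        """TGV vanishes on affine images, so the denoiser is the identity
        away from the boundary rows (the discrete Neumann differences leave
        a small boundary layer)."""
        n = 16
        yy, xx = np.mgrid[0:n, 0:n]
        f = 0.3 + 0.05 * yy - 0.02 * xx
        out = mbr.tgv_denoise(f, gamma=0.02, iterations=600)
        inner = (slice(3, -3), slice(3, -3))
        assert np.max(np.abs(out[inner] - f[inner])) < 1e-3 * np.abs(f).max()

    def test_constant_null_space(self):
        f = np.full((12, 12), 0.7)
        out = mbr.tgv_denoise(f, gamma=0.4, iterations=300)
        assert np.max(np.abs(out - f)) < 1e-8

    def test_reduces_noise_on_piecewise_constant(self):
        n = 24
        rng = np.random.default_rng(9)
        truth = np.zeros((n, n))
        truth[6:18, 6:18] = 1.0
        noisy = truth + 0.2 * rng.standard_normal((n, n))
        out = mbr.tgv_denoise(noisy, gamma=0.3, iterations=200)
        assert np.mean(np.abs(out - truth)) < 0.5 * np.mean(np.abs(noisy - truth))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            mbr.tgv_denoise(np.zeros((4, 4)), gamma=0.0)


def _tiny_problem(seed=0, noise=0.0):
    """Small radial acquisition of a 2-region phantom for operator tests."""
    cfg_offsets = np.array([-4.0, -1.0, 1.0, 4.2, 6.0])
    times = sm.flash_time_grid(4.2e-3, 240, 4)
    scheme = sm.AcquisitionScheme(
        sat=sm.SaturationSpec(b1_ut=1.0, tprep=1.5),
        readout=sm.ReadoutSpec(tr=4.2e-3, flip=np.deg2rad(6), time_grid=times),
        offsets_ppm=cfg_offsets)
    n = 16
    layout = phantom.build_layout(n, t1_ms=(800.0,), fraction=(0.005,),
                                  ring_radius_frac=0.0, tube_radius_frac=0.15)
    water = {0: sm.WaterPool(r1=1.0, r2=1 / 0.110),
             1: sm.WaterPool(r1=1.25, r2=1 / 0.110)}
    pools = {0: [], 1: [sm.ExchangePool(0.005, 200.0, 1 / 0.110, 4.2)]}
    sigs = {}
    for lab in (0, 1):
        p = [(sm.rex_amplitude(q.fs, q.ks, q.r2s, scheme.sat.omega1),
              sm.rad_to_ppm(sm.rex_width(q.ks, q.r2s, scheme.sat.omega1)),
              q.delta_ppm) for q in pools[lab]]
        params = sm.CombinedModelParams(1.0, water[lab].r1, 1.308,
                                        water[lab].r2, 0.0, p)
        sigs[lab] = sm.combined_signal(params, scheme.sat, scheme.readout,
                                       cfg_offsets).signal
    series = phantom.render_signal(layout, sigs)
    coils = phantom.make_coil_maps(n, n_coils=3, seed=seed)
    ksp = phantom.synthesize_radial(series, coils, cfg_offsets, times,
                                    spokes_per_frame=3, seed=seed,
                                    noise_level=noise)
    return ksp, scheme, layout


class TestEncodingOperator:
    def test_apply_adjoint_identity(self):
        ksp, scheme, _ = _tiny_problem()
        enc = mbr.EncodingOperator(ksp, scheme)
        rng = np.random.default_rng(3)
        f = ksp.traj.shape[0]
        x = (rng.standard_normal((f, 16, 16))
             + 1j * rng.standard_normal((f, 16, 16))).astype(np.complex64)
        y = (rng.standard_normal(ksp.data.shape)
             + 1j * rng.standard_normal(ksp.data.shape)).astype(np.complex64)
        lhs = np.vdot(y, enc.apply_images(x))
        rhs = np.vdot(enc.adjoint_images(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-4   # float32 operator

    def test_model_frames_matches_signal_model(self):
        ksp, scheme, _ = _tiny_problem()
        enc = mbr.EncodingOperator(ksp, scheme)
        u = np.zeros((7, 16, 16))
        u[0], u[1], u[2], u[3] = 1.0, 1.1, 1.308, 9.0
        u[5], u[6] = 0.5, 0.9
        frames = enc.model_frames(u)
        ref = sm.combined_signal_arrays(
            1.0, 1.1, 1.308, 9.0, 0.0, [(0.5, 0.9, 4.2)], scheme.offsets_ppm,
            scheme.readout.time_grid, scheme.sat.omega1, scheme.sat.tprep)
        assert np.allclose(frames[:, 0, 0], ref.ravel(), rtol=1e-6)

    def test_jacobian_matches_central_difference(self):
        ksp, scheme, _ = _tiny_problem()
        enc = mbr.EncodingOperator(ksp, scheme)
        u = np.zeros((7, 16, 16))
        u[0], u[1], u[2], u[3], u[5], u[6] = 1.0, 1.1, 1.3, 9.0, 0.5, 0.9
        jac = enc.model_jacobian(u, rel_step=1e-5)
        base = enc.model_frames(u)
        for j in (1, 5):
            up = u.copy()
            h = 1e-5
            up[j] += h
            fd = (enc.model_frames(up) - base) / h
            scale = np.abs(jac[..., j]).max()
            assert np.max(np.abs(jac[..., j] - fd)) < 1e-3 * scale

    def test_forward_of_truth_matches_noise_free_data(self):
        ksp, scheme, layout = _tiny_problem(noise=0.0)
        enc = mbr.EncodingOperator(ksp, scheme)
        u = np.zeros((7, 16, 16))
        u[0] = layout.support().astype(float)
        u[1] = np.where(layout.labels == 1, 1.25, 1.0) * layout.support()
        u[1] = np.maximum(u[1], 0.05)
        u[2], u[3] = 1.308, 1 / 0.110
        om1 = scheme.sat.omega1
        a = sm.rex_amplitude(0.005, 200.0, 1 / 0.110, om1)
        g = sm.rad_to_ppm(sm.rex_width(200.0, 1 / 0.110, om1))
        u[5] = a * (layout.labels == 1)
        u[6] = g
        pred = enc.forward(u)
        rel = np.linalg.norm(pred - ksp.data) / np.linalg.norm(ksp.data)
        assert rel < 1e-3   # float32 NUFFT + piecewise-constant model


class TestGaussNewton:
    def test_smoke_returns_finite_maps(self):
        ksp, scheme, layout = _tiny_problem(noise=0.01)
        u0 = np.zeros((7, 16, 16))
        u0[0] = layout.support().astype(float)
        u0[1], u0[2], u0[3], u0[5], u0[6] = 1.0, 1.308, 9.0, 0.1, 1.0
        cfg = mbr.TgvConfig(gn_steps=3, pd_iterations=25)
        pm, log = mbr.gauss_newton_reconstruct(ksp, scheme, cfg, init=u0)
        assert set(mbr.PARAM_NAMES) <= set(pm.maps)
        for v in pm.maps.values():
            assert np.all(np.isfinite(v))
        assert len(log.fidelity) == 4   # one per GN step + final check
        assert log.fidelity[-1] < log.fidelity[0]

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            mbr.TgvConfig(reduction=1.5)
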