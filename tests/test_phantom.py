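"""Tube phantom geometry, coil maps and k-space synthesis."""

import numpy as np
import pytest

from cestll import phantom


class TestLayout:
    def test_all_regions_present(self):
        lay = phantom.build_layout(128)
        for lab in range(12):
            assert np.sum(lay.labels == lab) > 0
        assert np.sum(lay.labels == phantom.OUTSIDE) > 0

    def test_deterministic(self):
        a = phantom.build_layout(64)
        b = phantom.build_layout(64)
        assert np.array_equal(a.labels, b.labels)

    def test_tubes_disjoint_and_inside_disk(self):
        lay = phantom.build_layout(96)
        # every tube pixel was also a disk pixel (labels only overwrite bg)
        assert np.all(lay.labels[lay.labels > 0] <= 11)
        counts = [np.sum(lay.labels == lab) for lab in range(1, 12)]
        assert max(counts) - min(counts) <= 0.25 * max(counts)

    def test_maps_piecewise_constant(self):
        lay = phantom.build_layout(64)
        t1 = lay.t1_map()
        fr = lay.fraction_map()
        assert t1[lay.labels == 0].max() == lay.t1_ms[0]
        for lab in range(1, 12):
            assert np.all(t1[lay.labels == lab] == lay.t1_ms[lab])
            assert np.all(fr[lay.labels == lab] == lay.fraction[lab])
        assert np.all(t1[lay.labels == phantom.OUTSIDE] == 0)

    def test_erosion_shrinks_rois(self):
        lay = phantom.build_layout(64)
        m0 = lay.roi_masks(0)
        m1 = lay.roi_masks(1)
        for lab in range(12):
            assert m1[lab].sum() < m0[lab].sum()
            assert np.all(m0[lab][m1[lab]])

    def test_overlapping_tubes_rejected(self):
        with pytest.raises(ValueError):
            phantom.build_layout(64, tube_radius_frac=0.2)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            phantom.build_layout(64, t1_ms=(500.0,), fraction=(0.0, 0.1))


class TestRenderSignal:
    def test_roi_exactness(self):
        lay = phantom.build_layout(48)
        sigs = {lab: np.array([float(lab), -float(lab)]) for lab in range(12)}
        img = phantom.render_signal(lay, sigs)
        assert img.shape == (2, 48, 48)
        for lab in range(12):
            assert np.all(img[0][lay.labels == lab] == lab)
            assert np.all(img[1][lay.labels == lab] == -lab)
        assert np.all(img[:, lay.labels == phantom.OUTSIDE] == 0)

    def test_missing_label_rejected(self):
        lay = phantom.build_layout(48)
        with pytest.raises(KeyError):
            phantom.render_signal(lay, {0: np.array([1.0])})

    def test_inconsistent_shapes_rejected(self):
        lay = phantom.build_layout(48)
        sigs = {lab: np.zeros(2) for lab in range(12)}
        sigs[3] = np.zeros(5)
        with pytest.raises(ValueError):
            phantom.render_signal(lay, sigs)


class TestCoilMaps:
    def test_shapes_and_coverage(self):
        cm = phantom.make_coil_maps(32, n_coils=6, seed=1)
        assert cm.maps.shape == (6, 32, 32)
        assert cm.n_coils == 6
        assert np.all(cm.rss() > 0)

    def test_seed_determinism(self):
        a = phantom.make_coil_maps(32, 4, seed=5).maps
        b = phantom.make_coil_maps(32, 4, seed=5).maps
        c = phantom.make_coil_maps(32, 4, seed=6).maps
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_combine_inverts_weighting(self):
        cm = phantom.make_coil_maps(16, 4, seed=0)
        rng = np.random.default_rng(2)
        img = rng.standard_normal((16, 16))
        coil_imgs = img[None] * cm.maps
        assert np.allclose(cm.combine(coil_imgs), img, atol=1e-10)


class TestCartesian:
    def test_noise_free_round_trip(self):
        lay = phantom.build_layout(32)
        img = lay.support().astype(float)[None]
        cm = phantom.make_coil_maps(32, 3, seed=0)
        k, sigma = phantom.synthesize_cartesian(img, cm, noise_level=0.0)
        assert sigma == 0.0
        rec = phantom.reconstruct_cartesian(k, cm)
        assert np.allclose(rec, img, atol=1e-10)

    def test_noise_statistics(self):
        img = np.ones((4, 32, 32))
        cm = phantom.make_coil_maps(32, 2, seed=0)
        k0, _ = phantom.synthesize_cartesian(img, cm, noise_level=0.0)
        k1, sigma = phantom.synthesize_cartesian(img, cm, noise_level=0.05,
                                                 seed=3)
        assert sigma == pytest.approx(0.05 * np.abs(img).max())
        noise = (k1 - k0).ravel()
        assert np.std(noise.real) == pytest.approx(sigma, rel=0.05)
        assert np.std(noise.imag) == pytest.approx(sigma, rel=0.05)

    def test_seed_determinism(self):
        img = np.ones((1, 16, 16))
        cm = phantom.make_coil_maps(16, 2, seed=0)
        a, _ = phantom.synthesize_cartesian(img, cm, 0.05, seed=7)
        b, _ = phantom.synthesize_cartesian(img, cm, 0.05, seed=7)
        assert np.array_equal(a, b)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            phantom.synthesize_cartesian(np.ones((1, 8, 8)),
                                         phantom.make_coil_maps(8, 2),
                                         noise_level=-0.1)

    def test_streaming_recon_matches_batch(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal((5, 16, 16))
        cm = phantom.make_coil_maps(16, 3, seed=1)
        k, _ = phantom.synthesize_cartesian(series, cm, 0.05, seed=9)
        ref = phantom.reconstruct_cartesian(k, cm)
        out = phantom.noisy_cartesian_recon(series, cm, 0.05, seed=9,
                                            chunk=64)
        # identical noise stream when one chunk covers all frames
        assert np.allclose(out, ref, atol=1e-4)

    def test_unknown_interpretation_rejected(self):
        with pytest.raises(ValueError):
            phantom.noisy_cartesian_recon(np.ones((1, 8, 8)),
                                          phantom.make_coil_maps(8, 2),
                                          noise_interpretation="kspace-amplitude")


class TestGoldenAngle:
    def test_shape_and_box(self):
        traj = phantom.golden_angle_trajectory(10, 3, 64)
        assert traj.shape == (10, 3 * 128, 2)
        assert np.all(np.abs(traj) <= 32.0)

    def test_angle_increment(self):
        traj = phantom.golden_angle_trajectory(1, 4, 64)[0].reshape(4, 128, 2)
        ang = np.arctan2(traj[:, -1, 1], traj[:, -1, 0])
        inc = np.rad2deg(np.diff(np.unwrap(ang)))
        assert np.allclose(np.mod(inc, 360.0), phantom.GOLDEN_ANGLE_DEG,
                           atol=1e-9)

    def test_angles_continue_across_frames(self):
        t1 = phantom.golden_angle_trajectory(2, 3, 32)
        flat = phantom.golden_angle_trajectory(1, 6, 32)[0]
        assert np.allclose(t1.reshape(-1, 2), flat)

    def test_every_spoke_crosses_center(self):
        traj = phantom.golden_angle_trajectory(3, 3, 32)
        r = np.hypot(traj[..., 0], traj[..., 1]).reshape(3, 3, 64)
        assert np.all(r.min(axis=-1) == 0.0)

    def test_nominal_undersampling(self):
        assert phantom.nominal_undersampling(80, 128) == \
            pytest.approx(np.pi / 2 * 128 / 80)
        assert phantom.nominal_undersampling(3, 64) > 30


class TestRadialSynthesis:
    def test_zero_object_zero_samples(self):
        cm = phantom.make_coil_maps(16, 2, seed=0)
        series = np.zeros((2, 3, 16, 16))
        ksp = phantom.synthesize_radial(series, cm, np.arange(2.0),
                                        np.arange(3.0), noise_level=0.0)
        assert np.all(ksp.data == 0)
        assert ksp.sigma == 0.0

    def test_metadata_layout(self):
        cm = phantom.make_coil_maps(16, 2, seed=0)
        series = np.ones((2, 3, 16, 16))
        offs = np.array([-1.0, 4.2])
        times = np.array([0.1, 0.5, 1.0])
        ksp = phantom.synthesize_radial(series, cm, offs, times,
                                        noise_level=0.0)
        assert ksp.data.shape == (2, 6, 3 * 32)
        assert np.allclose(ksp.offsets_ppm, np.repeat(offs, 3))
        assert np.allclose(ksp.times, np.tile(times, 2))
        assert ksp.coils is cm

    def test_dense_sampling_recovers_image(self):
        """With many spokes the density-compensated adjoint correlates
        strongly with the object."""
        from cestll.nufft import BatchedFrameNufft, radial_density_weights
        lay = phantom.build_layout(32)
        img = lay.support().astype(float)
        cm = phantom.CoilMaps(maps=np.ones((1, 32, 32), dtype=complex))
        series = img[None, None]
        ksp = phantom.synthesize_radial(series, cm, np.zeros(1), np.zeros(1),
                                        spokes_per_frame=64, noise_level=0.0)
        w = radial_density_weights(ksp.traj[0])
        op = BatchedFrameNufft(32, ksp.traj, os=2.0, width=8,
                               dtype=np.complex128)
        rec = np.real(op.adjoint(ksp.data * w[None, None])[0, 0])
        corr = np.corrcoef(rec.ravel(), img.ravel())[0, 1]
        assert corr > 0.99


class TestCoilCompression:
    def test_full_rank_preserves_span(self):
        cm = phantom.make_coil_maps(16, 5, seed=2)
        vc, basis = phantom.compress_coils(cm, 5)
        assert vc.maps.shape == (5, 16, 16)
        # unitary compression preserves the RSS image
        assert np.allclose(vc.rss(), cm.rss(), atol=1e-10)

    def test_basis_consistency(self):
        cm = phantom.make_coil_maps(16, 6, seed=3)
        vc, basis = phantom.compress_coils(cm, 3)
        ref = (basis @ cm.maps.reshape(6, -1)).reshape(3, 16, 16)
        assert np.allclose(vc.maps, ref)
        assert np.allclose(basis @ basis.conj().T, np.eye(3), atol=1e-12)

    def test_smooth_maps_compress_well(self):
        cm = phantom.make_coil_maps(32, 20, seed=0)
        vc, _ = phantom.compress_coils(cm, 8)
        assert np.allclose(vc.rss(), cm.rss(), rtol=1e-3)

    def test_invalid_count_rejected(self):
        cm = phantom.make_coil_maps(8, 3, seed=0)
        with pytest.raises(ValueError):
            phantom.compress_coils(cm, 0)
        with pytest.raises(ValueError):
            phantom.compress_coils(cm, 4)
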