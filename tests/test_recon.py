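"""Gridding reconstruction, partition FFT, adaptive coil combination."""

import numpy as np
import pytest

from spiralcine import recon, trajectory as tj
from spiralcine.phantom import PhantomConfig, make_coil_sensitivities
from spiralcine.recon import (ImageVolumeSeries, ReconError, adaptive_combine,
                              grid_nufft, nrmse, partition_fft,
                              reconstruct_filled, reconstruct_series,
                              zero_fill)


@pytest.fixture(scope="module")
def small_traj():
    return tj.make_trajectory(256.0, 32, 12)


class TestGridNufft:
    def test_zero_kspace_gives_zero_images(self, small_traj):
        dcf = tj.density_compensation(small_traj)
        ksp = np.zeros((1, 2, 12, small_traj.n_readout, 2), np.complex64)
        img = grid_nufft(ksp, small_traj, dcf)
        assert np.abs(img).max() == 0.0

    def test_point_source_psf_concentrated(self, small_traj):
        # flat unit k-space = point source at the centre voxel
        dcf = tj.density_compensation(small_traj)
        ksp = np.ones((1, 1, 12, small_traj.n_readout, 1), np.complex64)
        img = np.abs(grid_nufft(ksp, small_traj, dcf))[0, 0, 0]
        n = small_traj.matrix
        peak = img[n // 2, n // 2]
        assert img.max() == peak
        yy, xx = np.mgrid[:n, :n]
        far = np.hypot(yy - n // 2, xx - n // 2) > 3
        assert peak >= 10 * img[far].max()

    def test_shape_mismatch_raises(self, small_traj):
        dcf = tj.density_compensation(small_traj)
        bad = np.zeros((1, 2, 12, 7, 2), np.complex64)
        with pytest.raises(ReconError, match="trajectory"):
            grid_nufft(bad, small_traj, dcf)

    def test_chain_linear_in_kspace(self, small_traj):
        rng = np.random.default_rng(0)
        dcf = tj.density_compensation(small_traj)
        shape = (1, 4, 12, small_traj.n_readout, 2)
        a = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        b = rng.normal(size=shape) + 1j * rng.normal(size=shape)

        def chain(x):
            return partition_fft(grid_nufft(x, small_traj, dcf), 4)

        lhs = chain(2.0 * a - 1.0j * b)
        rhs = 2.0 * chain(a) - 1.0j * chain(b)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-10)


class TestPartitionFft:
    def test_sixteen_encoded_keep_twelve(self):
        hybrid = np.zeros((1, 16, 1, 4, 4), np.complex64)
        out = partition_fft(hybrid, 12)
        assert out.shape[1] == 12

    def test_central_kz_delta_gives_identical_slices(self):
        hybrid = np.zeros((1, 8, 1, 4, 4), np.complex64)
        hybrid[:, 4] = 1.0 + 0j  # only the central kz plane
        out = partition_fft(hybrid, 6)
        for z in range(1, 6):
            np.testing.assert_allclose(out[:, z], out[:, 0], rtol=1e-12)

    def test_two_slab_object_round_trip(self):
        # forward z-FFT of a two-slab profile, then inverse: slabs recovered
        nz = 10
        profile = np.zeros(nz)
        profile[2] = 1.0
        profile[7] = 2.0
        vol = profile[None, :, None, None, None] * np.ones((1, 1, 1, 4, 4))
        kz = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(vol, axes=1),
                                        axis=1, norm="ortho"), axes=1)
        out = np.abs(partition_fft(kz, nz))
        rec = out[0, :, 0, 0, 0]
        assert int(np.argmax(rec)) == 7
        assert rec[2] == pytest.approx(1.0, abs=1e-9)

    def test_nominal_exceeding_encoded_raises(self):
        with pytest.raises(ReconError):
            partition_fft(np.zeros((1, 8, 1, 4, 4), complex), 10)


class TestAdaptiveCombine:
    def test_single_channel_identity(self):
        rng = np.random.default_rng(1)
        vols = rng.normal(size=(1, 3, 16, 16)) \
            + 1j * rng.normal(size=(1, 3, 16, 16))
        out = adaptive_combine(vols, normalize="none")
        np.testing.assert_allclose(out, np.abs(vols[0]), atol=1e-10)

    def test_identical_sensitivities_proportional_output(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1, 2, 16, 16)) \
            + 1j * rng.normal(size=(1, 2, 16, 16))
        vols = np.repeat(base, 4, axis=0)
        out = adaptive_combine(vols, normalize="none")
        ratio = out / np.abs(base[0])
        assert np.nanstd(ratio) / np.nanmean(ratio) < 1e-6

    def test_normalization_flattens_background_shading(self):
        # uniform object seen through Gaussian-lobe coils: normalized
        # combination varies less over the object than root-sum-of-squares
        cfg = PhantomConfig(matrix=48, partitions_encoded=4,
                            partitions_nominal=4)
        sens = make_coil_sensitivities(8, cfg, seed=3)[:, :1]
        obj = np.ones((1, 48, 48))
        coil = sens * obj[None]
        rss = np.sqrt((np.abs(coil) ** 2).sum(axis=0))
        out = adaptive_combine(coil, normalize="lowpass")
        inner = (slice(0, 1), slice(10, 38), slice(10, 38))
        cov_norm = out[inner].std() / out[inner].mean()
        cov_rss = rss[inner].std() / rss[inner].mean()
        assert cov_norm < cov_rss

    def test_all_zero_block_gives_zero_output(self):
        vols = np.zeros((4, 1, 16, 16), complex)
        out = adaptive_combine(vols, normalize="none")
        assert np.abs(out).max() == 0.0


class TestEndToEnd:
    def test_r6_nrmse_within_bound(self, desk_recon_grappa, desk_recon_full,
                                   desk_support):
        assert nrmse(desk_recon_grappa, desk_recon_full,
                     desk_support) <= 0.15

    def test_zero_filling_strictly_worse(self, desk_data, desk_pattern,
                                         desk_traj, desk_dcf, desk_cfg,
                                         desk_recon_grappa, desk_recon_full,
                                         desk_support):
        zf = zero_fill(desk_data["dynamic"].data, desk_pattern,
                       desk_traj.n_readout) * desk_pattern.r
        img_z = reconstruct_filled(zf, desk_traj,
                                   desk_cfg.partitions_nominal,
                                   dcf=desk_dcf, normalize="none")
        assert nrmse(img_z, desk_recon_full, desk_support) > \
            nrmse(desk_recon_grappa, desk_recon_full, desk_support)

    def test_r1_bypasses_grappa_bitwise(self, desk_full, desk_traj,
                                        desk_cfg):
        pat1 = tj.undersampling_pattern(24, 1)
        series = reconstruct_series(
            desk_full[:2], None, desk_traj, pat1,
            desk_cfg.partitions_nominal, normalize="none")
        direct = reconstruct_filled(desk_full[:2], desk_traj,
                                    desk_cfg.partitions_nominal,
                                    normalize="none")
        np.testing.assert_array_equal(series.volumes, direct)

    def test_energy_outside_support_small(self, desk_recon_grappa,
                                          desk_support):
        total = (desk_recon_grappa ** 2).sum()
        outside = (desk_recon_grappa[~desk_support] ** 2).sum()
        assert outside / total < 0.05

    def test_deterministic(self, desk_data, desk_traj, desk_pattern,
                           desk_cfg):
        kwargs = dict(traj=desk_traj, pattern=desk_pattern,
                      partitions_nominal=desk_cfg.partitions_nominal,
                      normalize="none")
        a = reconstruct_series(desk_data["dynamic"].data[:1],
                               desk_data["calibration"].data[:2], **kwargs)
        b = reconstruct_series(desk_data["dynamic"].data[:1],
                               desk_data["calibration"].data[:2], **kwargs)
        np.testing.assert_array_equal(a.volumes, b.volumes)

    def test_missing_calibration_names_stage(self, desk_data, desk_traj,
                                             desk_pattern, desk_cfg):
        with pytest.raises(ReconError, match="calibrat"):
            reconstruct_series(desk_data["dynamic"].data, None, desk_traj,
                               desk_pattern, desk_cfg.partitions_nominal)

    def test_series_metadata(self, desk_full, desk_traj, desk_cfg):
        pat1 = tj.undersampling_pattern(24, 1)
        series = reconstruct_series(desk_full[:1], None, desk_traj, pat1,
                                    desk_cfg.partitions_nominal,
                                    normalize="none")
        assert isinstance(series, ImageVolumeSeries)
        assert series.volumes.shape[1] == desk_cfg.partitions_nominal
        assert (series.volumes >= 0).all()
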