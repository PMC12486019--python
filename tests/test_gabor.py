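"""Core estimator tests: filter-bank oracle equivalence, closed-form
recovery, invariances, and the full pipeline."""

import numpy as np
import pytest

import octoprops as op
from conftest import MU_REF, RADII, exponential_ratio


def brute_force_bank(ratio: op.RatioVolume, bank: op.GaborBank) -> np.ndarray:
    """Independent oracle: per-voxel windowed DFT with explicit kernels."""
    sig_vox = [(r / 2.0) / s for r, s in zip(bank.radii, ratio.spacing)]
    radii_vox = [max(int(np.ceil(4.0 * s)), 1) for s in sig_vox]
    kernels = []
    for s, rad in zip(sig_vox, radii_vox):
        x = np.arange(-rad, rad + 1)
        k = np.exp(-(x**2) / (2 * s**2))
        kernels.append(k / k.sum())
    k3 = kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    # edge-including reflection, the boundary rule the filter uses
    padded = np.pad(ratio.data, [(r, r) for r in radii_vox], mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, [2 * r + 1 for r in radii_vox]
    )
    dz_mm = ratio.spacing[2] * 1e-3
    dzs = np.arange(-radii_vox[2], radii_vox[2] + 1) * dz_mm
    out = np.empty((bank.freqs.size,) + ratio.shape, dtype=complex)
    for i, f in enumerate(bank.freqs):
        phase = np.exp(-2j * np.pi * f * dzs)[None, None, :]
        kk = k3 * phase
        out[i] = np.einsum("xyzijk,ijk->xyz", windows, kk.real) + 1j * np.einsum(
            "xyzijk,ijk->xyz", windows, kk.imag
        )
    return out


class TestBankConstruction:
    def test_paper_radii_give_half_sigmas(self):
        bank = op.build_gabor_bank((20.0, 20.0, 6.1), spacing=(1, 1, 0.61))
        assert bank.sigma == (10.0, 10.0, 3.05)

    def test_dc_gain_is_exactly_one(self, small_bank):
        assert abs(small_bank.dc_gain() - 1.0) < 1e-12
        assert small_bank.norm_const > 0

    def test_frequency_spacing_arithmetic(self):
        bank = op.build_gabor_bank((20, 20, 6.1), spacing=(2, 2, 1),
                                   n_freqs=5, freq_span=40.0)
        assert bank.dfreq == pytest.approx(20.0)
        np.testing.assert_allclose(bank.freqs, [-40, -20, 0, 20, 40])

    def test_default_span_keeps_spectrum_well_conditioned(self, small_bank):
        sigma_z_mm = small_bank.sigma_mm[2]
        assert small_bank.freqs.max() == pytest.approx(1 / (2 * np.pi * sigma_z_mm))

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(radii=(1.0, 20, 6.1), spacing=(2, 2, 1)), "unresolvable"),
            (dict(radii=(20, 20, 6.1), spacing=(2, 2, 1), n_freqs=4), "odd"),
            (dict(radii=(20, 20, 6.1), spacing=(2, 2, 1), freq_span=500.0), "2 pi sigma_z"),
        ],
    )
    def test_invalid_banks_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            op.build_gabor_bank(**kwargs)


class TestNormalization:
    def _noiseless_pair(self, mu_s, mu_r, confocal=None):
        kw = dict(shape=(6, 6, 120), spacing=(2, 2, 1.5),
                  speckle=op.SpeckleModel(kind="none"), confocal=confocal)
        sample = op.simulate_volume(op.make_homogeneous_phantom(mu_s, 1.0, **kw))
        ref = op.simulate_reference(mu_r, shape=(6, 6, 120), spacing=(2, 2, 1.5),
                                    confocal=confocal, speckle=op.SpeckleModel(kind="none"))
        return sample, ref

    def test_identical_volumes_give_unit_ratio(self):
        sample, _ = self._noiseless_pair(0.7, 0.7)
        ratio = op.normalize_to_reference(sample, sample, MU_REF, reference_mode="voxelwise")
        np.testing.assert_allclose(ratio.data, 1.0, rtol=1e-14)

    def test_log_ratio_slope_is_minus_two_delta_mu(self):
        sample, ref = self._noiseless_pair(1.5, 1.0)  # mu_s = mu_r + 0.5
        ratio = op.normalize_to_reference(sample, ref, 1.0)
        z = ratio.depth_axis_mm()
        slope = np.polyfit(z, np.log(ratio.data[3, 3]), 1)[0]
        np.testing.assert_allclose(slope, -1.0, atol=1e-9)

    def test_confocal_profile_cancels_exactly(self):
        confocal = op.ConfocalModel("gaussian_focus", focus_depth=90, rayleigh_range=50)
        s0, r0 = self._noiseless_pair(1.2, 1.0)
        s1, r1 = self._noiseless_pair(1.2, 1.0, confocal=confocal)
        plain = op.normalize_to_reference(s0, r0, 1.0, reference_mode="voxelwise")
        focused = op.normalize_to_reference(s1, r1, 1.0, reference_mode="voxelwise")
        np.testing.assert_allclose(focused.data, plain.data, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = op.OCTVolume(np.ones((4, 4, 8)), (1, 1, 1))
        b = op.OCTVolume(np.ones((4, 4, 9)), (1, 1, 1))
        with pytest.raises(ValueError, match="grid mismatch"):
            op.normalize_to_reference(a, b, 1.0)

    def test_reference_below_floor_lists_depths(self):
        sample = op.OCTVolume(np.ones((4, 4, 8)), (1, 1, 1))
        ref_data = np.ones((4, 4, 8))
        ref_data[:, :, 5:] = 1e-9
        ref = op.OCTVolume(ref_data, (1, 1, 1))
        with pytest.raises(ValueError, match="depth indices"):
            op.normalize_to_reference(sample, ref, 1.0, floor=1e-6)

    def test_floor_mask_marks_dark_voxels(self):
        data = np.ones((8, 8, 16))
        data[2, 3, :] = 0.0
        sample = op.OCTVolume(data, (1, 1, 1))
        ref = op.OCTVolume(np.ones((8, 8, 16)), (1, 1, 1))
        ratio = op.normalize_to_reference(sample, ref, 1.0, floor=1e-6)
        assert ratio.floor_mask[2, 3].all()
        assert not ratio.floor_mask[0, 0].any()


class TestGaborFiltering:
    def test_constant_ratio_gives_gaussian_spectral_magnitude(self, small_bank):
        c = 0.37
        ratio = exponential_ratio(0.0, level=c, shape=(40, 40, 80), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        np.testing.assert_allclose(G[small_bank.freqs == 0][0], c, rtol=1e-12)
        sigma_z_mm = small_bank.sigma_mm[2]
        for i, f in enumerate(small_bank.freqs):
            expected = c * np.exp(-2 * np.pi**2 * sigma_z_mm**2 * f**2)
            np.testing.assert_allclose(np.abs(G[i][20, 20, 40]), expected, rtol=5e-3)

    def test_matches_brute_force_windowed_dft(self):
        rng = np.random.default_rng(1)
        spacing = (4.0, 4.0, 1.5)
        bank = op.build_gabor_bank(RADII, spacing=spacing, n_freqs=5)
        data = rng.uniform(0.2, 2.0, (24, 22, 40))
        ratio = op.RatioVolume(data=data, spacing=spacing, mu_ref=1.0,
                               floor_mask=np.zeros(data.shape, bool))
        G = op.apply_gabor_bank(ratio, bank)
        G_oracle = brute_force_bank(ratio, bank)
        err = np.abs(G - G_oracle) / np.abs(G_oracle)
        assert err.max() < 1e-6

    def test_exponential_ratio_phase_is_linear_in_frequency(self, small_bank):
        a = 1.0  # mm^-1 decay of the ratio
        ratio = exponential_ratio(a, shape=(24, 24, 160), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        sigma_z_mm = small_bank.sigma_mm[2]
        phases = np.angle(G[:, 12, 12, 80])
        expected = 2 * np.pi * sigma_z_mm**2 * a * small_bank.freqs
        np.testing.assert_allclose(phases, expected, rtol=1e-2, atol=1e-9)

    def test_impulse_returns_kernel_centre_coefficient(self, small_bank):
        shape = (32, 32, 64)
        data = np.full(shape, 1e-12)
        data[16, 16, 32] = 1.0
        ratio = op.RatioVolume(data=data, spacing=(2, 2, 1), mu_ref=1.0,
                               floor_mask=np.zeros(shape, bool))
        G = op.apply_gabor_bank(ratio, small_bank)
        kx, ky, kz = small_bank.kernels()
        centre = kx[len(kx) // 2] * ky[len(ky) // 2] * kz[len(kz) // 2]
        np.testing.assert_allclose(
            np.abs(G[small_bank.freqs == 0][0][16, 16, 32]), centre, rtol=1e-6
        )


class TestEstimators:
    def test_constant_ratio_maps_to_reference(self, small_bank):
        ratio = exponential_ratio(0.0, shape=(24, 24, 64), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        mu_hat = op.estimate_ac(G, small_bank, mu_ref=MU_REF)
        np.testing.assert_allclose(mu_hat, 1.0, atol=1e-9)
        bsc = op.estimate_bsc(G, small_bank, ac_map=mu_hat, mu_ref=MU_REF)
        np.testing.assert_allclose(bsc, 1.0, rtol=1e-6)

    @pytest.mark.parametrize("mu_s", [0.5, 0.25])
    def test_noiseless_closed_form_recovery(self, small_bank, mu_s):
        # Delta_mu recovered to 0.1% on a noiseless exponential ratio
        ratio = exponential_ratio(2 * (mu_s - MU_REF), level=0.7,
                                  shape=(32, 32, 160), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        mu_hat = op.estimate_ac(G, small_bank, mu_ref=MU_REF)
        mx, my, mz = small_bank.margin_vox()
        interior = mu_hat[mx:-mx, my:-my, 2 * mz : -2 * mz]
        np.testing.assert_allclose(interior, mu_s / MU_REF, rtol=1e-3)
        bsc = op.estimate_bsc(G, small_bank, ac_map=mu_hat, mu_ref=MU_REF)
        np.testing.assert_allclose(
            bsc[mx:-mx, my:-my, 2 * mz : -2 * mz], 0.7, rtol=1e-3
        )

    def test_two_point_slope_agrees_with_weighted(self, small_bank):
        ratio = exponential_ratio(-0.8, shape=(24, 24, 120), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        w = op.estimate_ac(G, small_bank, mu_ref=MU_REF)
        t = op.estimate_ac(G, small_bank, mu_ref=MU_REF, slope_mode="two_point")
        mx, my, mz = small_bank.margin_vox()
        np.testing.assert_allclose(
            t[mx:-mx, my:-my, mz:-mz], w[mx:-mx, my:-my, mz:-mz], rtol=1e-4
        )

    def test_difference_mode_returns_delta_mu(self, small_bank):
        ratio = exponential_ratio(-1.0, shape=(24, 24, 120), spacing=(2, 2, 1))
        G = op.apply_gabor_bank(ratio, small_bank)
        dmu = op.estimate_ac(G, small_bank, mu_ref=MU_REF, normalization="difference")
        mx, my, mz = small_bank.margin_vox()
        np.testing.assert_allclose(dmu[mx:-mx, my:-my, 2 * mz : -2 * mz], -0.5, rtol=1e-3)

    def test_two_region_backscatter_contrast(self, small_bank):
        # beta levels 1 and 2.5 at mu_s = mu_r: region means recover the 2.5x
        shape = (48, 24, 64)
        data = np.ones(shape)
        data[28:, :, :] = 2.5
        ratio = op.RatioVolume(data=data, spacing=(2, 2, 1), mu_ref=MU_REF,
                               floor_mask=np.zeros(shape, bool))
        G = op.apply_gabor_bank(ratio, small_bank)
        mu_hat = op.estimate_ac(G, small_bank, mu_ref=MU_REF)
        bsc = op.estimate_bsc(G, small_bank, ac_map=mu_hat, mu_ref=MU_REF)
        lo = bsc[5:12, 8:16, 20:44].mean()
        hi = bsc[36:43, 8:16, 20:44].mean()
        assert hi / lo == pytest.approx(2.5, rel=0.01)


class TestPipeline:
    def test_sample_equal_reference_gives_unit_maps(self, small_bank):
        phantom = op.make_homogeneous_phantom(1.0, 1.0, (32, 32, 80), (2, 2, 1), seed=5)
        vol = op.simulate_volume(phantom)
        amap = op.estimate_acbsc(vol, vol, small_bank, mu_ref=MU_REF,
                                 reference_mode="voxelwise")
        assert amap.mask.any()
        np.testing.assert_allclose(amap.ac[amap.mask], 1.0, atol=1e-9)
        np.testing.assert_allclose(amap.bsc[amap.mask], 1.0, rtol=1e-9)

    def test_intensity_scale_invariance(self, small_bank):
        phantom = op.make_homogeneous_phantom(0.7, 0.4, (32, 32, 96), (2, 2, 1), seed=8)
        sample = op.simulate_volume(phantom)
        ref = op.simulate_reference(MU_REF, shape=(32, 32, 96), spacing=(2, 2, 1), seed=9)
        k = 3.7
        scaled = op.OCTVolume(k * sample.data, sample.spacing)
        m1 = op.estimate_acbsc(sample, ref, small_bank, mu_ref=MU_REF)
        m2 = op.estimate_acbsc(scaled, ref, small_bank, mu_ref=MU_REF)
        sel = m1.mask
        np.testing.assert_allclose(m2.ac[sel], m1.ac[sel], atol=1e-9)
        np.testing.assert_allclose(m2.bsc[sel], k * m1.bsc[sel], rtol=1e-12)

    def test_mean_ac_strictly_increasing_in_true_mu(self, small_bank):
        means = []
        for mu_s in (0.25, 0.5, 0.75, 1.0, 1.5):
            phantom = op.make_homogeneous_phantom(
                mu_s, 1.0, (40, 40, 96), (2, 2, 1),
                speckle=op.SpeckleModel(kind="none"),
            )
            sample = op.simulate_volume(phantom)
            ref = op.simulate_reference(MU_REF, shape=(40, 40, 96), spacing=(2, 2, 1),
                                        speckle=op.SpeckleModel(kind="none"))
            amap = op.estimate_acbsc(sample, ref, small_bank, mu_ref=MU_REF)
            means.append(np.nanmean(amap.ac[amap.mask]))
        assert np.all(np.diff(means) > 0)

    def test_floor_masked_voxels_are_invalid_not_contaminating(self, small_bank):
        phantom = op.make_homogeneous_phantom(
            1.0, 1.0, (32, 32, 80), (2, 2, 1), speckle=op.SpeckleModel(kind="none")
        )
        sample = op.simulate_volume(phantom)
        dark = sample.data.copy()
        dark[16, 16, :] = 0.0
        dark_vol = op.OCTVolume(dark, sample.spacing)
        ref = op.simulate_reference(MU_REF, shape=(32, 32, 80), spacing=(2, 2, 1),
                                    speckle=op.SpeckleModel(kind="none"))
        amap = op.estimate_acbsc(dark_vol, ref, small_bank, mu_ref=MU_REF, floor=1e-9)
        assert not amap.mask[16, 16].any()
        # neighbours stay finite and close to the reference value
        assert np.isfinite(amap.ac[amap.mask]).all()
        np.testing.assert_allclose(np.nanmean(amap.ac[amap.mask]), 1.0, atol=0.02)

    def test_voxel_precision_improves_with_lateral_window(self):
        # the per-voxel spread of mu_hat falls as the lateral radii grow
        spacing = (2.0, 2.0, 1.0)
        shape = (64, 64, 128)
        stds = []
        for dxy in (10.0, 20.0, 40.0):
            bank = op.build_gabor_bank((dxy, dxy, 6.1), spacing=spacing)
            per_seed = []
            for seed in range(3):
                phantom = op.make_homogeneous_phantom(0.5, 1.0, shape, spacing, seed=seed)
                sample = op.simulate_volume(phantom)
                ref = op.simulate_reference(MU_REF, shape=shape, spacing=spacing,
                                            seed=100 + seed)
                amap = op.estimate_acbsc(sample, ref, bank, mu_ref=MU_REF)
                per_seed.append(np.std(amap.ac[amap.mask]))
            stds.append(np.mean(per_seed))
        assert stds[0] > stds[1] > stds[2]
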