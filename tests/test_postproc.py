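"""Bias-field correction, averaging, downsampling, PSF and metrics."""

import numpy as np
import pytest

import retromoco as rm
from retromoco.postproc import (bias_correct, coregister_average, downsample,
                                effective_resolution, fwhm_broadening, nrmse,
                                psf_profile, smoothn, voxel_economics)


# -- bias field -------------------------------------------------------------

@pytest.fixture(scope="module")
def biased_volume():
    n = 48
    ph = rm.make_phantom(n, seed=0, texture=0.0)
    x = (np.arange(n) - n / 2) / (n / 2)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    field = 1.0 + 0.4 * X + 0.3 * Y - 0.2 * Z + 0.3 * X * Y
    return ph, ph.pd * field


def _tissue_cov(vol, labels):
    return np.mean([vol[labels == l].std() / vol[labels == l].mean()
                    for l in (2, 3, 4)])


def test_flat_volume_stays_flat():
    flat = np.full((24, 24, 24), 2.0)
    out = bias_correct(flat, 1.0)
    assert np.abs(out / 2.0 - 1).max() < 1e-6


def test_smooth_field_reduces_tissue_cov_5x(biased_volume):
    ph, vol = biased_volume
    corr = bias_correct(vol, 0.3)
    assert _tissue_cov(vol, ph.labels) / _tissue_cov(corr, ph.labels) >= 5.0


def test_bias_correction_nearly_idempotent(biased_volume):
    ph, vol = biased_volume
    c1 = bias_correct(vol, 0.3)
    c2 = bias_correct(c1, 0.3)
    assert nrmse(c2, c1) < 0.01


def test_mean_intensity_preserved(biased_volume):
    ph, vol = biased_volume
    corr = bias_correct(vol, 0.3)
    m = vol > 0.3
    assert corr[m].mean() == pytest.approx(vol[m].mean(), rel=1e-9)


def test_threshold_above_maximum_rejected():
    with pytest.raises(ValueError):
        bias_correct(np.ones((8, 8, 8)), 2.0)


def test_smoothn_interpolates_missing_data():
    rng = np.random.default_rng(30)
    x = np.linspace(0, 2 * np.pi, 40)
    truth = np.sin(x)[:, None, None] * np.ones((1, 8, 8))
    w = np.ones_like(truth)
    w[15:20] = 0.0  # hole
    z, s = smoothn(truth, w=w, s=10.0)
    assert np.abs(z[15:20] - truth[15:20]).max() < 0.2


# -- co-register and average -----------------------------------------------

def test_identical_volumes_average_to_input(phantom64):
    v = phantom64.pd
    mean, poses = coregister_average([v, v])
    assert nrmse(mean, v) < 1e-6
    assert np.all(np.abs(poses[1].as_array()) < 1e-2)


def test_known_shift_recovered_and_mean_sharper(phantom64):
    from retromoco.geometry import Pose, resample_volume
    v = phantom64.pd
    shifted = resample_volume(v, Pose(tx=1.0))
    mean, poses = coregister_average([v, shifted])
    assert abs(poses[1].tx - 1.0) < 0.2
    naive = 0.5 * (v + shifted)
    # registered mean keeps more high-frequency energy than the naive mean
    def hf_energy(a):
        K = np.fft.fftn(a)
        K[:10, :10, :10] = 0
        return np.sum(np.abs(K) ** 2)
    assert hf_energy(mean) > hf_energy(naive)


def test_averaging_reduces_noise_as_sqrt_n(phantom64):
    rng = np.random.default_rng(31)
    v = phantom64.pd
    sigma = 0.01  # modest noise so registration jitter stays sub-voxel
    vols = [v + sigma * rng.standard_normal(v.shape) for _ in range(4)]
    mean, _ = coregister_average(vols)
    # measure noise in the empty background corner
    bg = (slice(0, 6), slice(0, 6), slice(0, 6))
    assert mean[bg].std() == pytest.approx(sigma / 2.0, rel=0.10)


def test_average_needs_two_volumes(phantom64):
    with pytest.raises(ValueError):
        coregister_average([phantom64.pd])


# -- downsampling -----------------------------------------------------------

def test_downsample_identity_when_target_equals_source():
    rng = np.random.default_rng(32)
    v = rng.standard_normal((16, 16, 16))
    assert np.array_equal(downsample(v, 1.0, 1.0), v)


def test_downsample_rejects_upsampling():
    with pytest.raises(ValueError):
        downsample(np.zeros((8, 8, 8)), 0.5, 1.0)


def test_downsample_500um_shape(phantom64):
    out = downsample(phantom64.pd, 2.0, 1.0)
    assert out.shape == (32, 32, 32)


# -- PSF / effective resolution --------------------------------------------

def test_full_sampling_psf_fwhm_is_dirichlet():
    p = psf_profile(512, 1.0)
    assert p.fwhm_voxels == pytest.approx(1.2067, abs=2e-3)


def test_three_quarter_zero_fill_broadening_matches_15pct():
    r = fwhm_broadening(0.75)
    assert r == pytest.approx(2.0 / np.sqrt(3.0), abs=1e-6)
    assert abs(r - 1.15) <= 0.02


def test_halfmax_broadening_monotone_in_fraction():
    ratios = [fwhm_broadening(f, measure="halfmax")
              for f in (0.6, 0.75, 0.9, 1.0)]
    assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
    assert ratios[-1] == pytest.approx(1.0, abs=1e-9)


def test_psf_widths_never_below_full_sampling():
    full = psf_profile(512, 1.0)
    for f in (0.6, 0.75, 0.9):
        p = psf_profile(512, f)
        assert p.fwhm_voxels >= full.fwhm_voxels - 1e-9
        assert p.fwhm_equiv_voxels >= full.fwhm_equiv_voxels - 1e-9


def test_psf_fwhm_converged_in_pad_factor():
    a = psf_profile(512, 0.75, pad_factor=64).fwhm_voxels
    b = psf_profile(512, 0.75, pad_factor=128).fwhm_voxels
    assert abs(a - b) / a < 1e-3


def test_psf_requires_reasonable_n():
    with pytest.raises(ValueError):
        psf_profile(16, 0.75)


def test_effective_resolution_values():
    assert effective_resolution(350, 0.75) == 400
    assert effective_resolution(380, 0.75) == 440
    assert effective_resolution(350, 1.0) == 350


# -- economics --------------------------------------------------------------

def test_voxel_economics_paper_case():
    e = voxel_economics(500, 350)
    assert e["volume_ratio"] == pytest.approx(2.92, abs=0.01)
    assert e["volume_ratio_printed"] == 3
    assert e["time_ratio"] == pytest.approx(8.5, abs=0.01)
    assert e["time_ratio_printed"] == 9


def test_voxel_economics_trivial_cases():
    e = voxel_economics(700, 350)
    assert e["volume_ratio"] == pytest.approx(8.0)
    assert e["time_ratio"] == pytest.approx(64.0)
    eq = voxel_economics(350, 350)
    assert eq["volume_ratio"] == 1.0 and eq["time_ratio"] == 1.0
    with pytest.raises(ValueError):
        voxel_economics(-1, 350)


# -- NRMSE ------------------------------------------------------------------

def test_nrmse_basic_properties():
    rng = np.random.default_rng(33)
    b = rng.standard_normal((8, 8, 8))
    assert nrmse(b, b) == 0.0
    assert nrmse(np.zeros_like(b), b) == pytest.approx(1.0)
    assert nrmse(3 * b, 3 * b + 0.3) == pytest.approx(nrmse(b, b + 0.1))
    mask = b > 0
    assert nrmse(b, b, mask=mask) == 0.0
    with pytest.raises(ValueError):
        nrmse(b, np.zeros_like(b))
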