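"""Retrospective k-space motion correction."""

import numpy as np
import pytest

import retromoco as rm
from retromoco.acquisition import AcquisitionPlan
from retromoco.encode import corrupt, line_coords
from retromoco.geometry import MotionTrace, Pose
from retromoco.moco import (correct, correct_with_estimated_trace,
                            rss_combine, uncorrected_recon)
from retromoco.nufft import cart_fft, cart_ifft
from retromoco.postproc import nrmse


@pytest.fixture(scope="module")
def small_sim():
    n = 32
    ph = rm.make_phantom(n, seed=0)
    coils = rm.make_coils(n, 4, seed=1)
    channels = coils.maps * rm.contrast_image(ph, "GRE-T2*", te_ms=15.6)[None]
    plan = AcquisitionPlan(matrix=(n, n, n), protocol="custom",
                           pf=(0.75, 0.75), tr_ms=27.0, n_shots=8).build()
    mask = plan.pe_mask_2d()
    reference = rss_combine(np.stack([cart_ifft(cart_fft(c) * mask[None])
                                      for c in channels]))
    return channels, plan, reference


def test_zero_motion_correction_matches_zero_filled_recon(small_sim):
    channels, plan, reference = small_sim
    shots = corrupt(channels, MotionTrace.identity(8), plan)
    out = rss_combine(correct(shots, MotionTrace.identity(8), (32, 32, 32)))
    assert nrmse(out, reference) < 1e-5


def test_translation_only_correction_exact_in_kspace(small_sim):
    channels, plan, _ = small_sim
    trace = MotionTrace([Pose(1.25, -0.8, 2.0)] * 8)
    shots = corrupt(channels, trace, plan)
    clean = corrupt(channels, MotionTrace.identity(8), plan)
    # undoing the phase ramp reproduces the motion-free samples exactly
    n = 32
    for s, c in zip(shots, clean):
        cart = line_coords(s.lines, (n, n, n))
        phase = np.exp(-2j * np.pi * cart @ (np.array([1.25, -0.8, 2.0]) / n))
        fixed = s.data.reshape(s.n_channels, -1) * np.conj(phase)[None]
        ref = c.data.reshape(c.n_channels, -1)
        assert np.abs(fixed - ref).max() / np.abs(ref).max() < 1e-9


def test_correction_with_true_trace_beats_uncorrected(moco_sim):
    """Seeded 64^3 / 8-coil / 16-shot experiment, |t|<=3 mm, |r|<=3 deg."""
    assert moco_sim["nrmse_corrected"] <= moco_sim["nrmse_uncorrected"] / 3.0


def test_correction_error_nondecreasing_in_rotation_angle(small_sim):
    channels, plan, reference = small_sim
    errs = []
    for ang in (0.0, 0.5, 2.0):
        trace = MotionTrace([Pose(rz=ang)] * 8)
        shots = corrupt(channels, trace, plan)
        out = rss_combine(correct(shots, trace, (32, 32, 32)))
        errs.append(nrmse(out, reference))
    assert errs[0] <= errs[1] + 1e-9 <= errs[2] + 1e-9
    assert errs[0] < 1e-5


def test_graceful_degradation_under_small_pose_errors(moco_sim):
    rng = np.random.default_rng(99)
    pert = moco_sim["trace"].as_array().copy()
    pert[1:, :3] += rng.uniform(-0.1, 0.1, size=pert[1:, :3].shape)
    pert[1:, 3:] += rng.uniform(-0.1, 0.1, size=pert[1:, 3:].shape)
    out = rss_combine(correct(moco_sim["shots"], MotionTrace.from_array(pert),
                              (64, 64, 64)))
    e = nrmse(out, moco_sim["reference"])
    gain = moco_sim["nrmse_uncorrected"] - moco_sim["nrmse_corrected"]
    assert abs(e - moco_sim["nrmse_corrected"]) < 0.5 * gain


def test_correct_is_linear_in_samples(small_sim):
    channels, plan, _ = small_sim
    rng = np.random.default_rng(3)
    trace = MotionTrace.from_array(
        np.concatenate([np.zeros((1, 6)), rng.uniform(-2, 2, (7, 6))]))
    shots = corrupt(channels, trace, plan)
    import copy
    doubled = copy.deepcopy(shots)
    for s in doubled:
        s.data = 2.0 * s.data
    a = correct(shots, trace, (32, 32, 32))
    b = correct(doubled, trace, (32, 32, 32))
    assert np.abs(b - 2 * a).max() <= 1e-9 * np.abs(a).max()


# -- channel combination ----------------------------------------------------

def test_rss_single_channel_is_magnitude():
    rng = np.random.default_rng(5)
    c = rng.standard_normal((1, 4, 4, 4)) + 1j * rng.standard_normal((1, 4, 4, 4))
    assert np.allclose(rss_combine(c), np.abs(c[0]))


def test_rss_two_identical_channels_scale_sqrt2():
    rng = np.random.default_rng(6)
    c = rng.standard_normal((4, 4, 4)) + 1j * rng.standard_normal((4, 4, 4))
    out = rss_combine(np.stack([c, c]))
    assert np.allclose(out, np.sqrt(2) * np.abs(c))


def test_rss_invariant_to_channel_order():
    rng = np.random.default_rng(7)
    c = rng.standard_normal((5, 4, 4, 4)) + 1j * rng.standard_normal((5, 4, 4, 4))
    a, b = rss_combine(c), rss_combine(c[::-1])
    # identical up to summation round-off
    assert np.allclose(a, b, rtol=1e-14, atol=0)


def test_rss_shape_mismatch_raises():
    with pytest.raises(Exception):
        rss_combine([np.zeros((4, 4, 4)), np.zeros((3, 3, 3))])


# -- end-to-end with estimated trace ---------------------------------------

def test_estimated_trace_correction_improves_image(moco_sim, nav_series16):
    vol, report = correct_with_estimated_trace(
        moco_sim["shots"], nav_series16, (64, 64, 64),
        truth=moco_sim["reference"], true_trace=moco_sim["trace"])
    assert report.nrmse_corrected < report.nrmse_uncorrected
    assert np.median(report.pose_error_mm) < 0.3
    assert np.median(report.pose_error_deg) < 0.3
    assert len(report.poses) == 16 and len(report.flags) == 16


def test_motion_free_correction_is_a_no_op(small_sim):
    from retromoco.navigator import simulate_fatnavs
    channels, plan, reference = small_sim
    ph = rm.make_phantom(32, seed=0)
    coils = rm.make_coils(32, 4, seed=1)
    shots = corrupt(channels, MotionTrace.identity(8), plan)
    navs = simulate_fatnavs(ph, coils, MotionTrace.identity(8))
    vol, report = correct_with_estimated_trace(shots, navs, (32, 32, 32),
                                               truth=reference)
    assert abs(report.nrmse_corrected - report.nrmse_uncorrected) < 0.01


def test_missing_pose_policies(small_sim):
    channels, plan, _ = small_sim
    trace = MotionTrace.identity(8)
    shots = corrupt(channels, trace, plan)
    bad = trace.as_array()
    bad[4] = np.nan
    nearest = correct(shots, MotionTrace.from_array(bad), (32, 32, 32),
                      missing="nearest")
    dropped = correct(shots, MotionTrace.from_array(bad), (32, 32, 32),
                      missing="drop")
    # nearest keeps all data; drop loses one shot's lines
    assert np.linalg.norm(dropped) < np.linalg.norm(nearest)
    with pytest.raises(ValueError):
        correct(shots, MotionTrace.identity(4), (32, 32, 32))
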