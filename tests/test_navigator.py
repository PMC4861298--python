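"""Fat navigators, GRAPPA reconstruction and motion estimation."""

import numpy as np
import pytest

import retromoco as rm
from retromoco.acquisition import AcquisitionPlan
from retromoco.geometry import MotionTrace, Pose, compose, invert
from retromoco.navigator import (NavSeries, estimate_motion,
                                 grappa_calibrate, grappa_reconstruct,
                                 simulate_fatnavs, _extract_acs)
from retromoco.nufft import cart_fft, cart_ifft
from retromoco.postproc import nrmse


# -- simulation -------------------------------------------------------------

def test_identity_trace_gives_identical_navigators(phantom64, coils8):
    navs = simulate_fatnavs(phantom64, coils8, MotionTrace.identity(3))
    assert np.array_equal(navs[0], navs[1])
    assert np.array_equal(navs[0], navs[2])


def test_navigators_are_fat_only(phantom64, coils8):
    navs = simulate_fatnavs(phantom64, coils8, MotionTrace.identity(2))
    # a brain-interior ball carries water signal but no navigator signal
    n = navs[0].shape[0]
    c = n // 2
    brain_region = navs[0][c - 4:c + 4, c - 4:c + 4, c - 4:c + 4]
    shell_peak = navs[0].max()
    assert np.median(np.abs(brain_region)) < 0.05 * shell_peak


def test_phantom_without_fat_rejected(coils8):
    from retromoco.phantom import Compartment
    ph = rm.make_phantom(32, spec=[Compartment("w", (0.6, 0.6, 0.6))])
    coils = rm.make_coils(32, 2, seed=0)
    with pytest.raises(ValueError):
        simulate_fatnavs(ph, coils, MotionTrace.identity(2))


def test_known_translation_moves_center_of_mass(phantom64, coils8):
    from scipy import ndimage
    shift = Pose(tx=3.0)
    navs = simulate_fatnavs(phantom64, coils8,
                            MotionTrace([Pose(), shift]))
    com0 = ndimage.center_of_mass(navs[0])
    com1 = ndimage.center_of_mass(navs[1])
    moved_mm = (com1[0] - com0[0]) * navs.voxel_mm
    assert abs(moved_mm - 3.0) < 0.5 * navs.voxel_mm
    assert abs(com1[1] - com0[1]) < 0.5 and abs(com1[2] - com0[2]) < 0.5


# -- GRAPPA -----------------------------------------------------------------

@pytest.fixture(scope="module")
def grappa_case():
    n = 48
    ph = rm.make_phantom(n, seed=0)
    coils = rm.make_coils(n, 8, seed=1)
    chans = np.stack([cart_fft(ph.pd * c) for c in coils.maps])
    return ph, chans


def _grappa_nrmse(chans, R, calib):
    plan = AcquisitionPlan(matrix=(48, 48, 48), pf=(1.0, 1.0),
                           grappa=R, calib=calib)
    under = chans * plan.pe_mask_2d()[None, None, :, :]
    w = grappa_calibrate(_extract_acs(chans, plan), plan.grappa)
    full = grappa_reconstruct(under, w, plan)
    rss = lambda k: np.sqrt(np.sum(
        np.abs(np.stack([cart_ifft(x) for x in k])) ** 2, axis=0))
    return nrmse(rss(full), rss(chans)), full, under, plan


def test_fully_sampled_input_passes_through(grappa_case):
    _, chans = grappa_case
    plan = AcquisitionPlan(matrix=(48, 48, 48), pf=(1.0, 1.0),
                           grappa=(1, 1))
    w = grappa_calibrate(chans[:, :, 12:36, 12:36], (1, 1))
    out = grappa_reconstruct(chans, w, plan)
    assert np.array_equal(out, chans)


def test_acquired_lines_preserved_bit_exact(grappa_case):
    _, chans = grappa_case
    err, full, under, plan = _grappa_nrmse(chans, (2, 1), (24, 0))
    mask = plan.pe_mask_2d()
    assert np.abs(full[:, :, mask] - chans[:, :, mask]).max() == 0.0


def test_r2_eight_coils_under_2pct(grappa_case):
    _, chans = grappa_case
    err, *_ = _grappa_nrmse(chans, (2, 1), (24, 0))
    assert err < 0.02


def test_error_decreases_with_calibration_size(grappa_case):
    _, chans = grappa_case
    e24, *_ = _grappa_nrmse(chans, (2, 1), (24, 0))
    e48, *_ = _grappa_nrmse(chans, (2, 1), (48, 0))
    assert e48 <= e24


def test_single_coil_worse_than_coil_array(grappa_case):
    ph, chans8 = grappa_case
    chans1 = np.stack([cart_fft(ph.pd.astype(complex))])
    e1, *_ = _grappa_nrmse(chans1, (2, 1), (24, 0))
    e8, *_ = _grappa_nrmse(chans8, (2, 1), (24, 0))
    assert e1 > e8


def test_weight_geometry_mismatch_rejected(grappa_case):
    _, chans = grappa_case
    plan = AcquisitionPlan(matrix=(48, 48, 48), grappa=(4, 1))
    w = grappa_calibrate(_extract_acs(chans, plan), (2, 1))
    with pytest.raises(ValueError):
        grappa_reconstruct(chans, w, plan)


def test_calibration_smaller_than_kernel_rejected(grappa_case):
    _, chans = grappa_case
    with pytest.raises(ValueError):
        grappa_calibrate(chans[:, :, :2, :2], (2, 2))


def test_kspace_navigator_path_runs(phantom64, coils8):
    nav_plan = AcquisitionPlan(matrix=(32, 32, 32), pf=(0.75, 0.75),
                               grappa=(2, 2), calib=(12, 12))
    navs = simulate_fatnavs(phantom64, coils8,
                            MotionTrace.identity(2), nav_shape=(32, 32, 32),
                            nav_plan=nav_plan, kspace_path=True)
    # image-path navigator agrees within GRAPPA + zero-fill artifact level
    ref = simulate_fatnavs(phantom64, coils8, MotionTrace.identity(2),
                           nav_shape=(32, 32, 32))
    assert nrmse(navs[0], ref[0]) < 0.25
    assert np.array_equal(navs[0], navs[1])


# -- motion estimation ------------------------------------------------------

def test_identical_volumes_register_to_identity(phantom64, coils8):
    navs = simulate_fatnavs(phantom64, coils8, MotionTrace.identity(3))
    trace = estimate_motion(navs)
    for p in trace:
        assert np.all(np.abs(p.as_array()) < 1e-3)


def test_single_axis_motion_recovered(phantom64, coils8):
    true = [Pose(), Pose(tx=2.0), Pose(ry=2.0)]
    navs = simulate_fatnavs(phantom64, coils8, MotionTrace(true))
    est = estimate_motion(navs)
    assert abs(est[1].tx - 2.0) < 0.2
    assert np.all(np.abs(est[1].as_array()[[1, 2]]) < 0.2)
    assert abs(est[2].ry - 2.0) < 0.2
    assert np.all(np.abs(est[2].as_array()[[0, 1, 2]]) < 0.2)
    # residual cross-talk into the unmoved rotation axes stays small
    assert np.all(np.abs(est[1].as_array()[3:]) < 0.35)
    assert np.all(np.abs(est[2].as_array()[[3, 5]]) < 0.35)


def test_pose_recovery_median_error(pose_recovery):
    """20 random poses within 3 mm / 3 deg: median abs error < 0.2."""
    true, est = pose_recovery
    err = est[1:] - true[1:]
    assert np.median(np.abs(err[:, :3])) < 0.2
    assert np.median(np.abs(err[:, 3:])) < 0.2


def test_rereferencing_consistency(phantom64, coils8):
    rng = np.random.default_rng(21)
    poses = [Pose(*rng.uniform(-2, 2, 6)) for _ in range(4)]
    navs = simulate_fatnavs(phantom64, coils8, MotionTrace(poses))
    est0 = estimate_motion(navs, reference=0)
    est2 = estimate_motion(navs, reference=2)
    # est0 poses should equal compose(est0[2], est2 poses) within tolerance
    for i in range(4):
        lhs = est0[i].as_array()
        rhs = compose(est0[2], est2[i]).as_array()
        assert np.all(np.abs(lhs - rhs)[:3] < 0.2)
        assert np.all(np.abs(lhs - rhs)[3:] < 0.25)


def test_needs_at_least_two_volumes():
    with pytest.raises(ValueError):
        estimate_motion(NavSeries(np.zeros((1, 16, 16, 16))))
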