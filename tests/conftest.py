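"""Shared fixtures: one seeded motion-corruption experiment reused across
the moco / navigator / acceptance tests (session scope keeps the NUFFT and
registration work to a single run each)."""

import numpy as np
import pytest

import retromoco as rm
from retromoco.acquisition import AcquisitionPlan
from retromoco.encode import corrupt
from retromoco.geometry import MotionTrace, Pose
from retromoco.moco import correct, rss_combine, uncorrected_recon
from retromoco.navigator import simulate_fatnavs
from retromoco.nufft import cart_fft, cart_ifft
from retromoco.postproc import nrmse

SIM_SEED = 5  # fixed study seed for the 64^3 / 8-coil / 16-shot experiment


@pytest.fixture(scope="session")
def phantom64():
    return rm.make_phantom(64, seed=0)


@pytest.fixture(scope="session")
def coils8(phantom64):
    return rm.make_coils(64, 8, seed=1)


@pytest.fixture(scope="session")
def moco_sim(phantom64, coils8):
    """Seeded 64^3, 8-coil, 16-shot corruption with |t|<=3 mm, |r|<=3 deg.

    Returns everything the correction tests need: the shots, true trace,
    motion-free zero-filled reference, uncorrected and true-trace-corrected
    reconstructions.
    """
    ph, coils = phantom64, coils8
    img = rm.contrast_image(ph, "GRE-T2*", te_ms=15.6)
    channels = coils.maps * img[None]
    plan = AcquisitionPlan(matrix=(64, 64, 64), protocol="custom",
                           pf=(0.75, 0.75), tr_ms=27.0, n_shots=16).build()
    rng = np.random.default_rng(SIM_SEED)
    trace = MotionTrace([Pose()] + [Pose(*rng.uniform(-3, 3, 6))
                                    for _ in range(15)])
    shots = corrupt(channels, trace, plan)
    mask = plan.pe_mask_2d()
    reference = rss_combine(np.stack([cart_ifft(cart_fft(ch) * mask[None])
                                      for ch in channels]))
    uncorrected = rss_combine(uncorrected_recon(shots, (64, 64, 64)))
    corrected = rss_combine(correct(shots, trace, (64, 64, 64)))
    return {
        "phantom": ph, "coils": coils, "channels": channels, "plan": plan,
        "trace": trace, "shots": shots, "reference": reference,
        "uncorrected": uncorrected, "corrected": corrected,
        "nrmse_uncorrected": nrmse(uncorrected, reference),
        "nrmse_corrected": nrmse(corrected, reference),
    }


@pytest.fixture(scope="session")
def nav_series16(moco_sim):
    """Navigator series matching the 16-shot experiment's trace."""
    return simulate_fatnavs(moco_sim["phantom"], moco_sim["coils"],
                            moco_sim["trace"])


@pytest.fixture(scope="session")
def pose_recovery(phantom64, coils8):
    """20 random poses (|t|<=3 mm, |r|<=3 deg) tracked through the full
    navigator pipeline; returns (true array, estimated array)."""
    from retromoco.navigator import estimate_motion
    rng = np.random.default_rng(7)
    poses = [Pose()] + [Pose(*rng.uniform(-3, 3, 6)) for _ in range(19)]
    trace = MotionTrace(poses)
    navs = simulate_fatnavs(phantom64, coils8, trace)
    est = estimate_motion(navs)
    return trace.as_array(), est.as_array()
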