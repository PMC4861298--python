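"""Sampling masks, shot assignment and scan-time arithmetic."""

import numpy as np
import pytest

from retromoco.acquisition import (AcquisitionPlan, acquired_fraction,
                                   assign_shots, grappa_pattern,
                                   navigator_cadence_s, partial_fourier_mask,
                                   plan_from_config, plan_to_config,
                                   printed_minutes, protocol_plan, scan_time)


# -- partial Fourier --------------------------------------------------------

def test_full_fraction_keeps_all_lines():
    assert partial_fourier_mask(64, 1.0).all()


def test_three_quarters_of_128_keeps_96_lines_incl_center():
    m = partial_fourier_mask(128, 0.75)
    assert m.sum() == 96
    assert m[64]  # center line of the centred index grid


def test_small_case_complement_is_most_negative():
    m = partial_fourier_mask(8, 0.75)
    assert m.sum() == 6
    assert list(np.nonzero(~m)[0]) == [0, 1]  # k = -4, -3


@pytest.mark.parametrize("bad", [0.5, 0.3, 1.2])
def test_fraction_out_of_range_rejected(bad):
    with pytest.raises(ValueError):
        partial_fourier_mask(64, bad)


# -- GRAPPA pattern ---------------------------------------------------------

def test_grappa_r1_keeps_everything():
    assert grappa_pattern(64, 1).all()


def test_grappa_count_matches_enumeration():
    n, R, calib = 128, 4, 24
    m = grappa_pattern(n, R, calib)
    center = n // 2
    lo, hi = center - calib // 2, center - calib // 2 + calib
    expect = set(range(lo, hi))
    expect |= {i for i in range(n) if (i - center) % R == 0}
    assert m.sum() == len(expect)
    assert set(np.nonzero(m)[0]) == expect


@pytest.mark.parametrize("n,R,calib", [(64, 2, 0), (64, 3, 12), (128, 4, 24)])
def test_center_line_always_acquired(n, R, calib):
    assert grappa_pattern(n, R, calib)[n // 2]


def test_calibration_larger_than_grid_rejected():
    with pytest.raises(ValueError):
        grappa_pattern(16, 2, 32)


# -- shot assignment --------------------------------------------------------

def test_gre_plan_has_333_shots_of_240_lines():
    plan = protocol_plan("gre").build()
    assert len(plan.shots) == 333
    assert all(len(s) == 240 for s in plan.shots)


def test_mp2rage_plan_has_312_shots():
    plan = protocol_plan("mp2rage").build()
    assert len(plan.shots) == 312


def test_turbo_equal_to_total_lines_gives_single_shot():
    plan = AcquisitionPlan(matrix=(32, 8, 8), protocol="tse",
                           tr_ms=1000.0, turbo=64)
    shots = assign_shots(plan)
    assert len(shots) == 1 and len(shots[0]) == 64


def test_turbo_larger_than_acquired_rejected():
    plan = AcquisitionPlan(matrix=(32, 8, 8), protocol="tse",
                           tr_ms=1000.0, turbo=65)
    with pytest.raises(ValueError):
        assign_shots(plan)


@pytest.mark.parametrize("name", ["gre", "mp2rage", "tse"])
def test_shots_cover_masked_lines_exactly_once(name):
    overrides = {}
    if name != "tse":  # full-size plans are cheap, but keep tse modest
        overrides = {}
    plan = protocol_plan(name, **overrides).build()
    seen = [tuple(line) for shot in plan.shots for line in shot]
    assert len(seen) == len(set(seen))
    mask = plan.pe_mask_2d()
    assert set(seen) == set(zip(*np.nonzero(mask)))


# -- timing -----------------------------------------------------------------

def test_gre_host_time_is_36_minutes():
    plan = protocol_plan("gre").build()
    t = scan_time(plan)
    assert t["host_s"] == pytest.approx(2157.84, abs=0.01)
    assert printed_minutes(t["host_s"]) == 36


def test_gre_total_time_is_42_minutes_with_7p6s_cadence():
    plan = protocol_plan("gre").build()
    t = scan_time(plan)
    assert printed_minutes(t["total_s"]) == 42
    assert navigator_cadence_s(plan) == pytest.approx(7.6, abs=0.05)


def test_mp2rage_total_time_is_31_minutes():
    plan = protocol_plan("mp2rage").build()
    t = scan_time(plan)
    assert t["host_s"] == pytest.approx(312 * 6.0, abs=1e-9)
    assert printed_minutes(t["total_s"]) == 31


def test_partial_fourier_saves_7_16_of_scan_time():
    kw = dict(matrix=(512, 444, 320), protocol="gre", tr_ms=27.0, outer_pe=1)
    full = scan_time(AcquisitionPlan(pf=(1.0, 1.0), **kw).build())
    part = scan_time(AcquisitionPlan(pf=(0.75, 0.75), **kw).build())
    assert part["host_s"] / full["host_s"] == pytest.approx(9 / 16, rel=1e-9)


def test_scan_time_additive_over_shot_partitions():
    plan = protocol_plan("gre").build()
    t = scan_time(plan)
    assert t["total_s"] == pytest.approx(
        t["host_s"] + t["navigators_s"] + t["calibration_s"])
    # removing the navigator duration reproduces the host-only time
    bare = protocol_plan("gre", nav_ms=0.0, calib_s=0.0).build()
    assert scan_time(bare)["total_s"] == pytest.approx(t["host_s"])


def test_missing_timing_constant_rejected():
    plan = AcquisitionPlan(matrix=(32, 16, 16), protocol="mp2rage")
    with pytest.raises(ValueError):
        scan_time(plan)


# -- coverage fraction ------------------------------------------------------

def test_acquired_fraction_values():
    kw = dict(matrix=(64, 64, 64))
    assert acquired_fraction(AcquisitionPlan(pf=(0.75, 0.75), **kw)) == 0.5625
    assert acquired_fraction(AcquisitionPlan(pf=(1.0, 1.0), **kw)) == 1.0
    assert acquired_fraction(AcquisitionPlan(pf=(0.75, 1.0), **kw)) == 0.75


# -- config I/O -------------------------------------------------------------

def test_plan_config_roundtrip():
    plan = protocol_plan("mp2rage")
    cfg = plan_to_config(plan)
    back = plan_from_config(cfg)
    assert plan_to_config(back) == cfg


def test_unknown_config_key_rejected():
    with pytest.raises(ValueError):
        plan_from_config({"matrix": [32, 32, 32], "bogus": 1})
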