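"""Sampling patterns, shot ordering, navigator cadence and scan-time accounting.

Three multi-shot 3D Cartesian protocols are modelled, mirroring a published
ultra-high-resolution 7T study setup:

* ``gre``     — T2*-weighted 3D-GRE, 512x444x320, TE/TR 15.6/27 ms, 3/4
  partial Fourier in both phase-encode dims; a navigator follows every
  completed partition-encoding loop and adds to the scan time.
* ``mp2rage`` — 552x442x416, 6000 ms between inversions, 3/4 partial
  Fourier both PE dims, 2x GRAPPA in the first PE dim; one shot (and one
  navigator, in dead time) per inversion cycle.
* ``tse``     — 512x320x448, turbo factor 166, 3/4 partial Fourier both PE
  dims; navigators in the dead time between trains.
* ``fatnav``  — the navigator itself: 2 mm, 88x128x128, 4x4 GRAPPA, 3/4
  partial Fourier both PE dims, 1152 ms per volume plus a 2.3 s
  calibration prescan.

Axes follow array order: dim 0 is the readout, dims 1 and 2 are phase
encodes.  A "shot" is the set of (ky, kz) lines acquired contiguously
between navigators, assumed to share one head pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AcquisitionPlan",
    "partial_fourier_mask",
    "grappa_pattern",
    "assign_shots",
    "scan_time",
    "acquired_fraction",
    "navigator_cadence_s",
    "protocol_plan",
    "plan_from_config",
    "printed_minutes",
]


def partial_fourier_mask(n: int, fraction: float) -> np.ndarray:
    """Asymmetric partial-Fourier mask over centred line indices.

    Keeps ``round(fraction * n)`` contiguous lines including the k-space
    centre (index ``n // 2`` of the centred array) and all positive
    frequencies; the omitted lines are the extreme negative frequencies.
    """
    if not 0.5 < fraction <= 1.0:
        raise ValueError("partial-Fourier fraction must be in (0.5, 1]")
    m = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[n - m:] = True
    return mask


def grappa_pattern(n: int, R: int, calib: int = 0) -> np.ndarray:
    """Regular undersampling: every R-th line plus a central calibration block.

    The stride is anchored at the centre line so the k-space centre is always
    acquired.
    """
    if R < 1:
        raise ValueError("GRAPPA factor must be >= 1")
    if calib > n:
        raise ValueError("calibration block larger than the line grid")
    idx = np.arange(n)
    center = n // 2
    mask = (idx - center) % R == 0
    if calib > 0:
        lo = center - calib // 2
        hi = lo + calib
        mask[max(lo, 0):min(hi, n)] = True
    return mask


@dataclass
class AcquisitionPlan:
    """Matrix, sampling masks, shot grouping and timing for one protocol."""

    matrix: tuple  # (nx, ny, nz); dim 0 = readout
    protocol: str = "custom"  # gre | mp2rage | tse | custom
    pe_dims: tuple = (1, 2)
    pf: tuple = (1.0, 1.0)  # partial-Fourier fraction per PE dim
    grappa: tuple = (1, 1)  # undersampling factor per PE dim
    calib: tuple = (0, 0)  # calibration lines per PE dim
    tr_ms: float = 0.0
    esp_ms: float = 0.0
    turbo: int = 0  # TSE echoes per train
    inv_period_ms: float = 0.0  # MP2RAGE cycle period
    nav_ms: float = 0.0
    calib_s: float = 0.0  # navigator GRAPPA calibration prescan
    nav_in_deadtime: bool = False  # navigator costs no extra scan time
    outer_pe: int = 2  # dim index of the outer (slow) PE loop
    n_shots: int = 0  # custom protocol: contiguous chunks
    voxel_mm: float = 1.0
    shots: list = field(default=None, repr=False)

    # -- masks ---------------------------------------------------------
    def pe_mask_1d(self, dim: int) -> np.ndarray:
        """Combined PF + GRAPPA mask along PE dim 1 or 2 (GRAPPA stride
        applied within the PF-acquired region)."""
        i = self.pe_dims.index(dim)
        n = self.matrix[dim]
        mask = partial_fourier_mask(n, self.pf[i])
        if self.grappa[i] > 1:
            mask &= grappa_pattern(n, self.grappa[i], self.calib[i])
        return mask

    def pe_mask_2d(self) -> np.ndarray:
        """(ny, nz) boolean mask of acquired phase-encode points."""
        my = self.pe_mask_1d(self.pe_dims[0])
        mz = self.pe_mask_1d(self.pe_dims[1])
        return np.outer(my, mz)

    @property
    def n_acquired_lines(self) -> int:
        return int(self.pe_mask_2d().sum())

    def build(self) -> "AcquisitionPlan":
        self.shots = assign_shots(self)
        return self


def _ordered_lines(plan: AcquisitionPlan) -> list:
    """All acquired (ky, kz) pairs, outer PE dim ascending, inner within."""
    my = plan.pe_mask_1d(plan.pe_dims[0])
    mz = plan.pe_mask_1d(plan.pe_dims[1])
    ys, zs = np.nonzero(my)[0], np.nonzero(mz)[0]
    if plan.outer_pe == plan.pe_dims[1]:
        return [(y, z) for z in zs for y in ys]
    return [(y, z) for y in ys for z in zs]


def assign_shots(plan: AcquisitionPlan) -> list:
    """Group acquired lines into shots by the protocol's loop structure.

    * ``mp2rage`` — one shot per outer-PE step (one inversion cycle) holding
      that step's inner-PE lines.
    * ``gre``     — one shot per completed inner partition loop (same
      grouping, different loop naming).
    * ``tse``     — consecutive trains of ``turbo`` lines from the linear
      ordering; the final train may be shorter.
    * ``custom``  — ``n_shots`` near-equal contiguous chunks.

    Returns a list of lists of (ky, kz) index pairs; every acquired line
    appears in exactly one shot.
    """
    lines = _ordered_lines(plan)
    if plan.protocol in ("mp2rage", "gre"):
        inner = plan.pe_dims[1] if plan.outer_pe == plan.pe_dims[0] \
            else plan.pe_dims[0]
        per_shot = int(plan.pe_mask_1d(inner).sum())
        return [lines[i:i + per_shot] for i in range(0, len(lines), per_shot)]
    if plan.protocol == "tse":
        if plan.turbo < 1:
            raise ValueError("TSE plan requires a positive turbo factor")
        if plan.turbo > len(lines):
            raise ValueError("train length exceeds the number of acquired lines")
        return [lines[i:i + plan.turbo]
                for i in range(0, len(lines), plan.turbo)]
    # custom: contiguous near-equal chunks
    k = plan.n_shots if plan.n_shots > 0 else 1
    bounds = np.linspace(0, len(lines), k + 1).round().astype(int)
    return [lines[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def scan_time(plan: AcquisitionPlan) -> dict:
    """Total scan time in seconds with a {host, navigators, calibration} split.

    Host time: GRE — acquired lines x TR; MP2RAGE — shots x inversion
    period; TSE — shots x TR (one train per TR).  Navigator time is
    ``shots x nav_ms`` when the navigator extends the scan (GRE), zero when
    it fits in sequence dead time (MP2RAGE, TSE), plus the calibration
    prescan.
    """
    shots = plan.shots if plan.shots is not None else assign_shots(plan)
    n_shots = len(shots)
    n_lines = sum(len(s) for s in shots)
    if plan.protocol == "mp2rage":
        if plan.inv_period_ms <= 0:
            raise ValueError("MP2RAGE plan requires inv_period_ms")
        host = n_shots * plan.inv_period_ms / 1000.0
    elif plan.protocol == "tse":
        if plan.tr_ms <= 0:
            raise ValueError("TSE plan requires tr_ms")
        host = n_shots * plan.tr_ms / 1000.0
    else:  # gre / custom: line-by-line readout
        if plan.tr_ms <= 0:
            raise ValueError("plan requires tr_ms")
        host = n_lines * plan.tr_ms / 1000.0
    nav = 0.0 if plan.nav_in_deadtime else n_shots * plan.nav_ms / 1000.0
    cal = plan.calib_s if plan.nav_ms > 0 else 0.0
    return {
        "host_s": host,
        "navigators_s": nav,
        "calibration_s": cal,
        "total_s": host + nav + cal,
        "n_shots": n_shots,
        "n_lines": n_lines,
    }


def navigator_cadence_s(plan: AcquisitionPlan) -> float:
    """Shot-to-shot period in seconds (one navigator per shot)."""
    t = scan_time(plan)
    extra = 0.0 if plan.nav_in_deadtime else plan.nav_ms / 1000.0
    if plan.protocol == "mp2rage":
        return plan.inv_period_ms / 1000.0
    if plan.protocol == "tse":
        return plan.tr_ms / 1000.0
    return t["host_s"] / t["n_shots"] + extra


def acquired_fraction(plan: AcquisitionPlan) -> float:
    """Fraction of the full Cartesian ny x nz phase-encode grid acquired."""
    ny = plan.matrix[plan.pe_dims[0]]
    nz = plan.matrix[plan.pe_dims[1]]
    return plan.n_acquired_lines / float(ny * nz)


def printed_minutes(seconds: float) -> int:
    """Scan time in whole minutes, rounded half-up (as quoted in protocols)."""
    return int(np.floor(seconds / 60.0 + 0.5))


_PROTOCOLS = {
    "gre": dict(matrix=(512, 444, 320), protocol="gre", pf=(0.75, 0.75),
                tr_ms=27.0, nav_ms=1152.0, calib_s=2.3, outer_pe=1,
                nav_in_deadtime=False, voxel_mm=0.35),
    "mp2rage": dict(matrix=(552, 442, 416), protocol="mp2rage",
                    pf=(0.75, 0.75), grappa=(2, 1), calib=(0, 0),
                    esp_ms=7.8, inv_period_ms=6000.0, nav_ms=1152.0,
                    calib_s=2.3, outer_pe=2, nav_in_deadtime=True,
                    voxel_mm=0.35),
    "tse": dict(matrix=(512, 320, 448), protocol="tse", pf=(0.75, 0.75),
                tr_ms=2700.0, esp_ms=997.0 / 166.0, turbo=166,
                nav_ms=1152.0, calib_s=2.3, outer_pe=2,
                nav_in_deadtime=True, voxel_mm=0.38),
    # the navigator acquisition itself; nav_ms is its own duration, a stored
    # constant (not derivable from the matrix/undersampling alone)
    "fatnav": dict(matrix=(88, 128, 128), protocol="custom",
                   pf=(0.75, 0.75), grappa=(4, 4), calib=(24, 24),
                   tr_ms=3.0, nav_ms=1152.0, calib_s=2.3, voxel_mm=2.0),
}


def protocol_plan(name: str, **overrides) -> AcquisitionPlan:
    """Preset plan for ``gre``, ``mp2rage``, ``tse`` or ``fatnav``."""
    if name not in _PROTOCOLS:
        raise KeyError(f"unknown protocol {name!r}; have {sorted(_PROTOCOLS)}")
    kw = dict(_PROTOCOLS[name])
    kw.update(overrides)
    return AcquisitionPlan(**kw)


_CONFIG_KEYS = {"matrix", "pe_dims", "pf", "grappa", "calib", "tr_ms",
                "esp_ms", "turbo", "inv_period_ms", "nav_ms", "calib_s",
                "protocol", "outer_pe", "n_shots", "nav_in_deadtime",
                "voxel_mm"}


def plan_from_config(cfg: dict) -> AcquisitionPlan:
    """Build a plan from a flat config mapping (JSON/YAML-style keys)."""
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown plan keys: {sorted(unknown)}")
    kw = dict(cfg)
    for key in ("matrix", "pe_dims", "pf", "grappa", "calib"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return AcquisitionPlan(**kw)


def plan_to_config(plan: AcquisitionPlan) -> dict:
    d = asdict(plan)
    d.pop("shots", None)
    for key in ("matrix", "pe_dims", "pf", "grappa", "calib"):
        d[key] = list(d[key])
    return d
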