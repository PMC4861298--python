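"""MP2RAGE signal model, UNI combination and lookup-table T1 mapping.

The sequence acquires two gradient-echo readout trains at inversion times
TI1 and TI2 after each adiabatic inversion, with flip angles alpha1 and
alpha2.  The longitudinal magnetization obeys a piecewise-affine recursion
over one cycle of period TR_mp2rage:

    inversion:    Mz -> -eta * Mz
    relaxation dt: Mz -> E * Mz + (1 - E) * M0,   E = exp(-dt / T1)
    RF pulse:     Mz -> cos(alpha) * Mz

iterated to its periodic steady state (the cycle map is affine, so the
fixed point is available in closed form).  The two train signals
S_i = sin(alpha_i) * Mz at the central echo combine into the uniform,
bias-free image

    UNI = Re(S1* S2) / (|S1|^2 + |S2|^2)  in [-0.5, 0.5],

which is monotone in T1 over a wide branch and therefore invertible by a
lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MP2RAGEParams", "mp2rage_signals", "uni_combine",
           "build_lookup", "t1_map", "uni_image"]


@dataclass(frozen=True)
class MP2RAGEParams:
    """Timing and flip angles of one MP2RAGE cycle.

    Defaults mirror a 7T 350-um protocol: TI 800/2700 ms, flips 5/7 deg,
    echo spacing 7.8 ms, 166 echoes per train (442 lines x 3/4 partial
    Fourier / GRAPPA 2), 6000 ms between inversions.  The inversion
    efficiency of the adiabatic pulse is a free parameter (default 0.96).
    """

    ti1_ms: float = 800.0
    ti2_ms: float = 2700.0
    alpha1_deg: float = 5.0
    alpha2_deg: float = 7.0
    esp_ms: float = 7.8
    n_echoes: int = 166
    tr_cycle_ms: float = 6000.0
    inv_eff: float = 0.96

    def __post_init__(self):
        if not 0 < self.inv_eff <= 1:
            raise ValueError("inversion efficiency must be in (0, 1]")
        if not self.ti1_ms < self.ti2_ms < self.tr_cycle_ms:
            raise ValueError("require TI1 < TI2 < cycle period")
        half = self.n_echoes * self.esp_ms / 2.0
        if self.ti1_ms - half <= 0 or self.ti2_ms + half >= self.tr_cycle_ms:
            raise ValueError("readout trains do not fit inside the cycle")


def _cycle_affine(t1_ms: float, p: MP2RAGEParams):
    """Affine map Mz -> a*Mz + b over one cycle, plus per-train signal maps.

    TI is referenced to the train centre (the k-space centre of a linearly
    ordered train), so each train spans TI -/+ n*esp/2.
    """

    def relax(dt):
        e = np.exp(-dt / t1_ms)
        return e, (1.0 - e)

    def chain(seq):
        a, b = 1.0, 0.0
        for (ai, bi) in seq:
            a, b = ai * a, ai * b + bi
        return a, b

    ca1 = np.cos(np.deg2rad(p.alpha1_deg))
    ca2 = np.cos(np.deg2rad(p.alpha2_deg))
    eh, bh = relax(p.esp_ms / 2.0)  # half an echo-spacing
    # one echo cell: pulse centred in its esp window
    cell1 = [(eh, bh), (ca1, 0.0), (eh, bh)]
    cell2 = [(eh, bh), (ca2, 0.0), (eh, bh)]
    train1 = chain(cell1 * p.n_echoes)
    train2 = chain(cell2 * p.n_echoes)
    t_start1 = p.ti1_ms - p.n_echoes * p.esp_ms / 2.0
    gap12 = (p.ti2_ms - p.n_echoes * p.esp_ms / 2.0) \
        - (p.ti1_ms + p.n_echoes * p.esp_ms / 2.0)
    t_end = p.tr_cycle_ms - (p.ti2_ms + p.n_echoes * p.esp_ms / 2.0)
    inv = (-p.inv_eff, 0.0)
    segs = [inv, relax(t_start1), train1, relax(gap12), train2, relax(t_end)]
    a, b = chain(segs)

    # signal taps: Mz just before the central pulse of each train
    c = p.n_echoes // 2
    to_tap1 = chain([inv, relax(t_start1)] + cell1 * c + [(eh, bh)])
    to_tap2 = chain([inv, relax(t_start1), train1, relax(gap12)]
                    + cell2 * c + [(eh, bh)])
    return (a, b), to_tap1, to_tap2


def mp2rage_signals(t1_ms, p: MP2RAGEParams = MP2RAGEParams()):
    """Signed steady-state signal pair (S1, S2) for tissue(s) of given T1.

    Vectorized over ``t1_ms``.  The steady state is the closed-form fixed
    point of the affine cycle map, Mz* = b / (1 - a); S_i = sin(alpha_i)
    times the longitudinal magnetization at the central echo of train i.
    S1 is signed — tissue still recovering at TI1 gives a negative value.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    s1 = np.empty_like(t1)
    s2 = np.empty_like(t1)
    sa1 = np.sin(np.deg2rad(p.alpha1_deg))
    sa2 = np.sin(np.deg2rad(p.alpha2_deg))
    for i, t in enumerate(t1.ravel()):
        (a, b), tap1, tap2 = _cycle_affine(t, p)
        mz = b / (1.0 - a)  # |a| < 1 always: relaxation is contractive
        s1.ravel()[i] = sa1 * (tap1[0] * mz + tap1[1])
        s2.ravel()[i] = sa2 * (tap2[0] * mz + tap2[1])
    if np.isscalar(t1_ms):
        return float(s1[0]), float(s2[0])
    return s1, s2


def mp2rage_steady_state_check(t1_ms: float, p: MP2RAGEParams,
                               n_iter: int = 10_000, tol: float = 1e-9):
    """Fixed-point iteration of the cycle map (oracle for the closed form)."""
    (a, b), _, _ = _cycle_affine(t1_ms, p)
    mz = 1.0
    for _ in range(n_iter):
        new = a * mz + b
        if abs(new - mz) < tol:
            return new
        mz = new
    raise RuntimeError("steady-state iteration did not converge")


def uni_combine(s1, s2):
    """UNI = Re(S1* S2) / (|S1|^2 + |S2|^2), bounded in [-0.5, 0.5].

    Defined as 0 where both signals vanish.  Invariant to any global
    complex scaling of (S1, S2) — the bias-field-free property.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    num = np.real(np.conj(s1) * s2)
    den = np.abs(s1) ** 2 + np.abs(s2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        uni = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if uni.ndim == 0:
        return float(uni)
    return uni


@dataclass
class T1Lookup:
    """Strictly monotone UNI(T1) branch, ready for inversion."""

    t1_ms: np.ndarray
    uni: np.ndarray
    truncated: bool  # True if the requested grid was cut to stay monotone

    def to_tsv(self, path):
        rows = "\n".join(f"{t:.6g}\t{u:.9g}"
                         for t, u in zip(self.t1_ms, self.uni))
        from pathlib import Path
        Path(path).write_text("t1_ms\tuni\n" + rows + "\n")


def build_lookup(p: MP2RAGEParams = MP2RAGEParams(),
                 t1_grid=None) -> T1Lookup:
    """Tabulate UNI(T1) and keep the largest strictly monotone branch.

    Default grid: 100-5000 ms in 1 ms steps.  With the default protocol the
    curve is strictly decreasing over the whole grid; if not, the longest
    strictly monotone run is returned and flagged ``truncated``.
    """
    if t1_grid is None:
        t1_grid = np.arange(100.0, 5000.0 + 1e-9, 1.0)
    t1_grid = np.asarray(t1_grid, dtype=float)
    if np.any(np.diff(t1_grid) <= 0):
        raise ValueError("T1 grid must be strictly increasing")
    s1, s2 = mp2rage_signals(t1_grid, p)
    uni = uni_combine(s1, s2)
    d = np.diff(uni)
    sign = -1.0 if np.median(d) < 0 else 1.0
    ok = sign * d > 0
    if np.all(ok):
        return T1Lookup(t1_grid, uni, truncated=False)
    # longest run of strictly monotone steps
    best_len, best_start, run, start = 0, 0, 0, 0
    for i, good in enumerate(ok):
        if good:
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run, start = 0, i + 1
    sl = slice(best_start, best_start + best_len + 1)
    import warnings
    warnings.warn("UNI(T1) not monotone over the requested grid; "
                  f"returning T1 in [{t1_grid[sl][0]:.0f}, "
                  f"{t1_grid[sl][-1]:.0f}] ms")
    return T1Lookup(t1_grid[sl], uni[sl], truncated=True)


def t1_map(uni_volume: np.ndarray, table: T1Lookup):
    """Invert a UNI volume to T1 (ms) by linear interpolation in the table.

    Out-of-range UNI values are clamped to the branch ends; the clamp count
    is returned alongside the map.
    """
    if table.t1_ms.size == 0:
        raise ValueError("empty lookup table")
    uni_volume = np.asarray(uni_volume, dtype=float)
    u = table.uni
    t = table.t1_ms
    if u[0] > u[-1]:  # np.interp needs ascending x
        u, t = u[::-1], t[::-1]
    clipped = int(np.sum((uni_volume < u[0]) | (uni_volume > u[-1])))
    vals = np.interp(np.clip(uni_volume, u[0], u[-1]), u, t)
    return vals, clipped


def uni_image(t1_volume: np.ndarray,
              p: MP2RAGEParams = MP2RAGEParams()) -> np.ndarray:
    """Synthesize a UNI volume from a T1 map (voxels with T1<=0 map to 0)."""
    t1_volume = np.asarray(t1_volume, dtype=float)
    out = np.zeros_like(t1_volume)
    mask = t1_volume > 0
    vals = np.unique(t1_volume[mask])
    if vals.size and vals.size <= 4096:  # piecewise-constant fast path
        s1, s2 = mp2rage_signals(vals, p)
        lut = dict(zip(vals, uni_combine(s1, s2)))
        for v in vals:
            out[t1_volume == v] = lut[v]
    elif vals.size:
        s1, s2 = mp2rage_signals(t1_volume[mask], p)
        out[mask] = uni_combine(s1, s2)
    return out
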