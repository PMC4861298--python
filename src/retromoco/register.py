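"""Multi-resolution rigid registration by damped Gauss-Newton on the MSE.

Same-modality volumes only (navigator-to-navigator, average-to-average), so
the metric is the mean squared intensity difference with trilinear
resampling.  Three pyramid levels (x4, x2, x1 decimation after Gaussian
smoothing); the coarsest level is initialized by an FFT phase-correlation
translation estimate, which makes the basin of attraction comfortably wider
than the few-mm / few-degree motion this package targets.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import Pose, invert, resample_volume

__all__ = ["register_rigid", "RegistrationFailure"]


class RegistrationFailure(RuntimeError):
    """Raised when the metric is degenerate (e.g. no overlapping support)."""


def _decimate(vol: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return vol
    sm = ndimage.gaussian_filter(vol, sigma=0.5 * f, mode="nearest")
    return sm[::f, ::f, ::f]


def _phase_corr_shift(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Integer-voxel translation of ``mov`` relative to ``ref`` (voxels)."""
    F1 = np.fft.fftn(ref)
    F2 = np.fft.fftn(mov)
    denom = np.abs(F1) * np.abs(F2)
    denom[denom == 0] = 1.0
    xc = np.fft.ifftn(F1 * np.conj(F2) / denom).real
    peak = np.array(np.unravel_index(np.argmax(xc), xc.shape), dtype=float)
    shape = np.array(ref.shape, dtype=float)
    peak[peak > shape / 2] -= shape[peak > shape / 2]
    return peak


def _residual(x: np.ndarray, ref: np.ndarray, mov: np.ndarray,
              voxel_mm: float) -> np.ndarray:
    q = Pose.from_array(x)
    return (resample_volume(mov, q, voxel_mm) - ref).ravel()


def _gauss_newton(ref, mov, voxel_mm, x0, max_iter=100, tol=1e-3):
    """Levenberg-damped Gauss-Newton over the 6 rigid parameters (mm, deg)."""
    # fixed central-difference steps: a quarter voxel / a quarter degree
    h = np.array([0.25 * voxel_mm] * 3 + [0.25] * 3)
    x = np.asarray(x0, dtype=float).copy()
    r = _residual(x, ref, mov, voxel_mm)
    cost = float(r @ r)
    lam = 1e-3
    for _ in range(max_iter):
        J = np.empty((r.size, 6))
        for i in range(6):
            xp, xm = x.copy(), x.copy()
            xp[i] += h[i]
            xm[i] -= h[i]
            J[:, i] = (_residual(xp, ref, mov, voxel_mm)
                       - _residual(xm, ref, mov, voxel_mm)) / (2 * h[i])
        g = J.T @ r
        H = J.T @ J
        if not np.all(np.isfinite(H)) or np.trace(H) <= 0:
            raise RegistrationFailure("degenerate registration metric")
        step_taken = False
        for _ in range(8):
            try:
                d = np.linalg.solve(H + lam * np.diag(np.diag(H))
                                    + 1e-12 * np.eye(6), -g)
            except np.linalg.LinAlgError:
                raise RegistrationFailure("singular normal equations")
            rn = _residual(x + d, ref, mov, voxel_mm)
            cn = float(rn @ rn)
            if cn < cost:
                x, r, cost = x + d, rn, cn
                lam = max(lam / 3.0, 1e-10)
                step_taken = True
                break
            lam *= 10.0
        if not step_taken:
            break
        if np.max(np.abs(d)) < tol:
            break
    return x


def register_rigid(ref: np.ndarray, mov: np.ndarray, voxel_mm: float = 1.0,
                   levels: int = 3, init: Pose | None = None,
                   max_iter: int = 100, tol: float = 1e-3) -> Pose:
    """Pose of ``mov`` relative to ``ref`` (mm / degrees).

    Internally finds q minimizing ``||resample(mov, q) - ref||^2`` and
    returns ``invert(q)``: if ``mov`` shows the object displaced by p from
    its position in ``ref``, the returned pose is p.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("volumes must share a grid")
    if not (np.any(ref) and np.any(mov)):
        raise RegistrationFailure("empty volume")
    factors = [f for f in (2 ** (levels - 1 - i) for i in range(levels))
               if min(ref.shape) // f >= 8]
    x = np.zeros(6) if init is None else invert(init).as_array()
    first = True
    for f in factors:
        rf, mf = _decimate(ref, f), _decimate(mov, f)
        if first and init is None:
            shift = _phase_corr_shift(rf, mf)
            x[:3] = shift * f * voxel_mm
        first = False
        x = _gauss_newton(rf, mf, voxel_mm * f, x,
                          max_iter=max_iter, tol=tol)
    return invert(Pose.from_array(x))
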