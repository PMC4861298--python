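"""Fat-navigator simulation, GRAPPA reconstruction and motion estimation.

The navigator is a rapid low-resolution 3D volume acquired with
fat-selective excitation between readout trains; only the scalp-fat shell
(which moves rigidly with the brain) contributes signal.  Excitation
physics is not simulated: fat selectivity is modelled by imaging the
``fat_fraction * PD`` map alone.  Pose tracking then reduces to rigid
registration of each navigator volume to the first of the series.

The optional k-space path reproduces the navigator's own acquisition:
partial-Fourier zero-filling plus regular GRAPPA undersampling, with the
missing lines synthesized from a calibration block via least-squares
fitted kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionPlan
from .geometry import MotionTrace, Pose, resample_volume
from .nufft import cart_fft, cart_ifft, fourier_resample
from .phantom import CoilSet, Phantom
from .register import RegistrationFailure, register_rigid

__all__ = ["NavSeries", "GrappaWeights", "simulate_fatnavs",
           "grappa_calibrate", "grappa_reconstruct", "estimate_motion"]


@dataclass
class NavSeries:
    """Low-resolution magnitude navigator volumes, one per shot."""

    volumes: np.ndarray  # (n_shots, mx, my, mz), float
    voxel_mm: float = 1.0
    plan: AcquisitionPlan | None = None

    def __len__(self) -> int:
        return self.volumes.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.volumes[i]


def simulate_fatnavs(ph: Phantom, coils: CoilSet, trace: MotionTrace,
                     nav_shape=None, nav_plan: AcquisitionPlan | None = None,
                     kspace_path: bool = False, noise_std: float = 0.0,
                     seed: int | None = None) -> NavSeries:
    """Simulate one fat-only navigator volume per pose in ``trace``.

    Per shot the fat map is rigidly resampled under that shot's pose and
    band-limited down to the navigator grid (``nav_shape``, default half
    the phantom grid).  With ``kspace_path=True`` the navigator's own
    undersampling is applied per channel (partial Fourier zero-filled,
    GRAPPA lines synthesized from the calibration block) before
    root-sum-of-squares combination.
    """
    fat = ph.fat_pd
    if not np.any(fat > 0):
        raise ValueError("phantom has no fat shell; navigators need one")
    if nav_shape is None:
        # default: 3/4 of the phantom grid, so the head spans enough
        # navigator voxels for degree-accurate rotation tracking (the real
        # 2 mm navigator has the head ~85 voxels across)
        nav_shape = tuple(max(int(round(s * 3 / 8)) * 2, 16)
                          for s in ph.shape)
    nav_shape = tuple(int(s) for s in nav_shape)
    scale = ph.shape[0] / nav_shape[0]
    rng = np.random.default_rng(seed)
    vols = np.empty((len(trace),) + nav_shape)
    weights = None
    for i, pose in enumerate(trace):
        moved = resample_volume(fat, pose, ph.voxel_size_mm)
        if not kspace_path:
            nav = np.abs(fourier_resample(moved * coils.rss(), nav_shape))
        else:
            if nav_plan is None:
                raise ValueError("kspace_path requires a nav_plan")
            chans = np.stack([
                cart_fft(fourier_resample(moved * c, nav_shape))
                for c in coils.maps])
            mask = nav_plan.pe_mask_2d()[None, None, :, :]
            under = chans * mask
            if weights is None:
                acs = _extract_acs(chans, nav_plan)
                weights = grappa_calibrate(acs, nav_plan.grappa)
            full = grappa_reconstruct(under, weights, nav_plan)
            imgs = np.stack([cart_ifft(k) for k in full])
            nav = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
        if noise_std > 0:
            nav = np.abs(nav + noise_std * rng.standard_normal(nav.shape))
        vols[i] = nav
    return NavSeries(vols, voxel_mm=ph.voxel_size_mm * scale, plan=nav_plan)


# ---------------------------------------------------------------------------
# GRAPPA
# ---------------------------------------------------------------------------

@dataclass
class GrappaWeights:
    """Least-squares GRAPPA kernels, one per missing-line offset.

    ``weights[(dy, dz)]`` maps the flattened source vector (channels x
    readout span x 2 source positions per undersampled PE dim) to all
    target channels at PE offset (dy, dz) from the acquired lattice.
    """

    R: tuple
    kx_span: int
    source_offsets: dict  # (dy, dz) -> list of (dx, sy, sz)
    weights: dict  # (dy, dz) -> (n_sources_total, n_channels)


def _offsets_for_target(dy: int, dz: int, R, kx_span: int):
    """Source offsets relative to the target: 2 bracketing acquired lattice
    lines per undersampled PE dim, 3 taps along each fully-sampled dim
    (readout included) — e.g. a 2x3x3 pattern for R x 1 undersampling."""
    sy = [-1, 0, 1] if R[0] == 1 else [-dy, R[0] - dy]
    sz = [-1, 0, 1] if R[1] == 1 else [-dz, R[1] - dz]
    dxs = range(-(kx_span // 2), kx_span // 2 + 1)
    return [(dx, a, b) for a in sy for b in sz for dx in dxs]


def grappa_calibrate(acs: np.ndarray, R, kx_span: int = 3,
                     lam: float = 1e-4) -> GrappaWeights:
    """Fit GRAPPA kernels on a fully-sampled calibration block.

    Parameters
    ----------
    acs : ndarray
        (n_channels, cx, cy, cz) fully-sampled central k-space.
    R : int or (R1, R2)
        Undersampling factor per PE dim.
    kx_span : int
        Readout positions per source (odd).
    lam : float
        Tikhonov factor, scaled by the mean source energy.
    """
    R = (int(R), 1) if np.isscalar(R) else tuple(int(r) for r in R)
    acs = np.asarray(acs, dtype=np.complex128)
    nc, cx, cy, cz = acs.shape
    src_off, wts = {}, {}
    for dy in range(R[0]):
        for dz in range(R[1]):
            if dy == 0 and dz == 0:
                continue
            offs = _offsets_for_target(dy, dz, R, kx_span)
            xs = [dx for dx, _, _ in offs]
            ys = [sy for _, sy, _ in offs]
            zs = [sz for _, _, sz in offs]
            x0, x1 = -min(xs), cx - max(xs)
            y0, y1 = -min(ys), cy - max(ys)
            z0, z1 = -min(zs), cz - max(zs)
            if x1 <= x0 or y1 <= y0 or z1 <= z0:
                raise ValueError("calibration block smaller than kernel span")
            tgt = acs[:, x0:x1, y0:y1, z0:z1]
            npos = tgt[0].size
            A = np.empty((npos, nc * len(offs)), dtype=np.complex128)
            col = 0
            for (dx, sy, sz), ox, oy, oz in zip(offs, xs, ys, zs):
                blk = acs[:, x0 + ox:x1 + ox, y0 + oy:y1 + oy,
                          z0 + oz:z1 + oz]
                A[:, col:col + nc] = blk.reshape(nc, npos).T
                col += nc
            B = tgt.reshape(nc, npos).T
            AhA = A.conj().T @ A
            reg = lam * np.trace(AhA).real / AhA.shape[0]
            W = np.linalg.solve(AhA + reg * np.eye(AhA.shape[0]),
                                A.conj().T @ B)
            if np.linalg.norm(A @ W - B) > 0.05 * np.linalg.norm(B) and \
                    npos < W.shape[0]:
                raise ValueError("underdetermined GRAPPA fit")
            src_off[(dy, dz)] = offs
            wts[(dy, dz)] = W
    return GrappaWeights(R=R, kx_span=kx_span, source_offsets=src_off,
                         weights=wts)


def _shift_periodic(a: np.ndarray, off) -> np.ndarray:
    """a shifted so out[t] = a[t + off], circularly.

    The k-space of a gridded object is periodic (sensitivity weighting is a
    circular convolution), so periodic indexing is the exact boundary
    treatment here and edge lines need no special-cased kernels.
    """
    return np.roll(a, shift=[-o for o in off], axis=(1, 2, 3))


def grappa_reconstruct(under: np.ndarray, w: GrappaWeights,
                       plan: AcquisitionPlan) -> np.ndarray:
    """Fill missing k-space lines from the fitted kernels.

    ``under`` is (n_channels, nx, ny, nz) with zeros on missing lines;
    acquired lines (per the plan's masks) are preserved bit-exactly.
    """
    under = np.asarray(under, dtype=np.complex128)
    nc, nx, ny, nz = under.shape
    if w.R != tuple(plan.grappa):
        raise ValueError(f"weights fitted for R={w.R}, plan has "
                         f"R={tuple(plan.grappa)}")
    mask2d = plan.pe_mask_2d()
    # only synthesize within the partial-Fourier-covered region; the rest
    # stays zero-filled, as in the navigator reconstruction being modelled
    from .acquisition import partial_fourier_mask
    pfm = [partial_fourier_mask(n_, f_) for n_, f_ in
           zip((ny, nz), plan.pf)]
    anchor = (ny // 2 % w.R[0], nz // 2 % w.R[1])
    out = under.copy()
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    for (dy, dz), offs in w.source_offsets.items():
        W = w.weights[(dy, dz)]
        pred = np.zeros_like(under)
        col = 0
        for dx, sy, sz in offs:
            src = _shift_periodic(under, (dx, sy, sz))
            for c in range(nc):
                pred += W[col + c][:, None, None, None] * src[c][None]
            col += nc
        sel = ((yy % w.R[0] == (anchor[0] + dy) % w.R[0])
               & (zz % w.R[1] == (anchor[1] + dz) % w.R[1])
               & ~mask2d & pfm[0][:, None] & pfm[1][None, :])
        out[:, :, sel] = pred[:, :, sel]
    return out


def _extract_acs(full_kspace: np.ndarray, plan: AcquisitionPlan) -> np.ndarray:
    """Central fully-sampled calibration block implied by the plan."""
    nc, nx, ny, nz = full_kspace.shape
    cy = plan.calib[0] if plan.grappa[0] > 1 else min(ny, 24)
    cz = plan.calib[1] if plan.grappa[1] > 1 else min(nz, 24)
    cy, cz = max(cy, 8), max(cz, 8)
    y0, z0 = ny // 2 - cy // 2, nz // 2 - cz // 2
    return full_kspace[:, :, y0:y0 + cy, z0:z0 + cz]


# ---------------------------------------------------------------------------
# Motion estimation
# ---------------------------------------------------------------------------

def estimate_motion(navs: NavSeries, reference: int = 0,
                    upsample: int = 2) -> MotionTrace:
    """6-DOF pose of every navigator relative to the reference volume.

    Multi-resolution rigid registration (MSE metric, trilinear resampling);
    the reference pose is exactly identity.  Volumes are sinc-upsampled
    (Fourier zero-padding, factor ``upsample``) before registration: the
    navigators are band-limited, so on the finer grid trilinear resampling
    is nearly exact and the aliasing bias it would otherwise introduce in
    the rotation estimates disappears.  A volume whose registration fails
    gets the previous shot's pose and is flagged in ``trace.flags``.
    """
    if len(navs) < 2:
        raise ValueError("need at least two navigator volumes")

    def prep(v):
        v = np.asarray(v, dtype=float)
        if upsample > 1:
            v = fourier_resample(v, tuple(s * upsample for s in v.shape))
        return v

    voxel = navs.voxel_mm / max(upsample, 1)
    ref = prep(navs[reference])
    poses, flags = [], []
    for i in range(len(navs)):
        if i == reference:
            poses.append(Pose())
            flags.append(False)
            continue
        try:
            poses.append(register_rigid(ref, prep(navs[i]), voxel_mm=voxel))
            flags.append(False)
        except RegistrationFailure:
            poses.append(poses[-1] if poses else Pose())
            flags.append(True)
    trace = MotionTrace(poses)
    trace.flags = flags
    return trace
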