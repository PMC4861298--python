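"""Forward model: motion-corrupted multi-channel k-space of a static object.

Motion is piecewise-constant per shot — one rigid pose per navigator
interval.  For a shot whose pose moves the object by (R, t), the measured
sample at Cartesian coordinate k is

    m(k) = exp(-2*pi*i * k . t_fov) * F(R^T k)

where F is the spectrum of the static, coil-weighted object and t_fov is
the translation as a fraction of the field of view (the Fourier rotation
and shift theorems).  Coil sensitivities are fixed to the scanner frame;
weighting the object by each coil map *before* applying the motion is a
small-motion approximation shared with the correction step.

Rotated coordinates falling past the grid Nyquist are wrapped periodically,
the self-consistent convention for a gridded object (see ``nufft``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionPlan, assign_shots
from .geometry import MotionTrace, Pose, rotation_matrix
from . import nufft

__all__ = ["ShotData", "line_coords", "corrupt", "cartesian_reference"]


@dataclass
class ShotData:
    """Multi-channel complex k-space samples for one shot.

    ``data`` has shape (n_channels, n_lines, nx); ``lines`` is the list of
    (ky, kz) array indices on the Cartesian PE grid.
    """

    index: int
    data: np.ndarray
    lines: np.ndarray
    pose_index: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data[0].size


def line_coords(lines, grid_shape) -> np.ndarray:
    """Cartesian k-space coordinates (cycles/FoV) for a set of PE lines.

    Returns (n_lines * nx, 3): the readout coordinate varies fastest, and
    every coordinate is the centred integer frequency ``index - n // 2``.
    """
    nx, ny, nz = grid_shape
    lines = np.asarray(lines, dtype=np.int64)
    kx = np.arange(nx) - nx // 2
    ky = lines[:, 0] - ny // 2
    kz = lines[:, 1] - nz // 2
    out = np.empty((lines.shape[0], nx, 3), dtype=np.float64)
    out[:, :, 0] = kx[None, :]
    out[:, :, 1] = ky[:, None]
    out[:, :, 2] = kz[:, None]
    return out.reshape(-1, 3)


def _pose_coords_phase(pose: Pose, cart: np.ndarray, grid_shape,
                       voxel_mm: float):
    """Rotated sample coordinates and translation phase for one shot."""
    R = rotation_matrix(pose.rx, pose.ry, pose.rz)
    coords = cart @ R  # row-vectors: equivalent to (R^T k)^T
    coords = nufft.wrap_to_box(coords, grid_shape)
    fov = np.array(grid_shape, dtype=float) * voxel_mm
    phase = np.exp(-2j * np.pi * (cart @ (pose.translation / fov)))
    return coords, phase


def corrupt(channels: np.ndarray, trace: MotionTrace, plan: AcquisitionPlan,
            voxel_mm: float | None = None, noise_std: float = 0.0,
            seed: int | None = None) -> list:
    """Simulate per-shot, per-channel k-space of a moving object.

    Parameters
    ----------
    channels : ndarray
        Coil-weighted object, shape (n_channels, nx, ny, nz), complex.
    trace : MotionTrace
        One pose per shot (piecewise-constant motion).
    plan : AcquisitionPlan
        Supplies the shot list; its matrix must equal the channel grid.
    noise_std : float
        Std of i.i.d. complex Gaussian noise added per sample (seeded).

    Returns
    -------
    list of ShotData
    """
    channels = np.asarray(channels, dtype=np.complex128)
    if channels.ndim != 4:
        raise ValueError("channels must be (n_channels, nx, ny, nz)")
    grid = channels.shape[1:]
    if tuple(plan.matrix) != tuple(grid):
        raise ValueError(f"plan matrix {plan.matrix} != channel grid {grid}")
    shots = plan.shots if plan.shots is not None else assign_shots(plan)
    if len(trace) != len(shots):
        raise ValueError(
            f"trace has {len(trace)} poses for {len(shots)} shots")
    if voxel_mm is None:
        voxel_mm = plan.voxel_mm
    plans = [nufft.fine_spectrum(ch) for ch in channels]
    rng = np.random.default_rng(seed)
    out = []
    nx = grid[0]
    for i, lines in enumerate(shots):
        cart = line_coords(lines, grid)
        coords, phase = _pose_coords_phase(trace[i], cart, grid, voxel_mm)
        data = np.empty((channels.shape[0], len(lines), nx),
                        dtype=np.complex128)
        for c, p in enumerate(plans):
            samp = nufft.interpolate_spectrum(p, coords) * phase
            if noise_std > 0:
                samp = samp + noise_std * (rng.standard_normal(samp.shape)
                                           + 1j * rng.standard_normal(samp.shape))
            data[c] = samp.reshape(len(lines), nx)
        out.append(ShotData(index=i, data=data,
                            lines=np.asarray(lines, dtype=np.int64),
                            pose_index=i))
    return out


def cartesian_reference(channels: np.ndarray,
                        plan: AcquisitionPlan) -> np.ndarray:
    """Motion-free zero-filled k-space on the full grid (per channel).

    Acquired lines carry the centred FFT of each channel; unacquired
    partial-Fourier lines stay zero — the reference the corrected data are
    compared against.
    """
    channels = np.asarray(channels, dtype=np.complex128)
    grid = channels.shape[1:]
    mask2d = plan.pe_mask_2d()
    out = np.zeros_like(channels)
    for c, ch in enumerate(channels):
        K = nufft.cart_fft(ch)
        out[c] = K * mask2d[None, :, :]
    return out
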