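"""Rigid-body transforms and their action on points, volumes and motion traces.

A head pose is parameterized by six degrees of freedom: translations
``(tx, ty, tz)`` in millimetres and rotations ``(rx, ry, rz)`` in degrees.
Rotations are intrinsic, applied in the order x, then y, then z,
right-handed, about a caller-supplied centre (usually the volume centre).
Millimetres and degrees at the interface; radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Pose",
    "MotionTrace",
    "pose_to_matrix",
    "matrix_to_pose",
    "compose",
    "invert",
    "rotation_matrix",
    "resample_volume",
]


@dataclass(frozen=True)
class Pose:
    """One 6-DOF rigid transform of the head relative to the scanner frame."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        """Translation vector in mm."""
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def rotation_deg(self) -> np.ndarray:
        """Rotation angles (rx, ry, rz) in degrees."""
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    def as_array(self) -> np.ndarray:
        """Six parameters as ``[tx, ty, tz, rx, ry, rz]`` (mm, deg)."""
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz],
                        dtype=float)

    @classmethod
    def from_array(cls, a) -> "Pose":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"pose array must have 6 entries, got {a.shape}")
        return cls(*a)

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.as_array()) <= tol))


IDENTITY = Pose()


def rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """3x3 right-handed rotation: intrinsic x, then y, then z (R = Rz @ Ry @ Rx)."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def pose_to_matrix(p: Pose, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """4x4 homogeneous rigid matrix (mm) rotating about ``center``.

    Maps a point x (mm) to ``R @ (x - c) + c + t``.
    """
    R = rotation_matrix(p.rx, p.ry, p.rz)
    c = np.asarray(center, dtype=float)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = p.translation + c - R @ c
    return M


def matrix_to_pose(M: np.ndarray, center=(0.0, 0.0, 0.0)) -> Pose:
    """Inverse of :func:`pose_to_matrix` (angles returned in (-180, 180])."""
    R = np.asarray(M, dtype=float)[:3, :3]
    # R = Rz @ Ry @ Rx  =>  standard extraction; gimbal lock at |ry| = 90 deg
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if np.abs(np.cos(ry)) > 1e-9:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # degenerate: fold everything into rz
        rx = 0.0
        rz = np.arctan2(-R[0, 1], R[1, 1])
    c = np.asarray(center, dtype=float)
    t = np.asarray(M, dtype=float)[:3, 3] - c + R @ c
    return Pose(t[0], t[1], t[2], *np.rad2deg([rx, ry, rz]))


def compose(a: Pose, b: Pose) -> Pose:
    """Pose whose matrix is ``matrix(a) @ matrix(b)`` (b applied first)."""
    return matrix_to_pose(pose_to_matrix(a) @ pose_to_matrix(b))


def invert(p: Pose) -> Pose:
    """Pose whose matrix is the inverse of ``matrix(p)``."""
    return matrix_to_pose(np.linalg.inv(pose_to_matrix(p)))


def resample_volume(vol: np.ndarray, p: Pose, voxel_size_mm: float = 1.0,
                    interpolation: str = "trilinear") -> np.ndarray:
    """Resample ``vol`` under pose ``p`` (trilinear, out-of-field voxels = 0).

    The output at voxel x holds the input at ``M^-1 x`` where M is the pose
    matrix about the volume centre, i.e. the returned volume shows the object
    *moved* by ``p``.

    Parameters
    ----------
    vol : ndarray
        3D volume on an isotropic grid.
    p : Pose
        Rigid transform to apply (mm / degrees).
    voxel_size_mm : float
        Isotropic voxel edge length; translations are divided by it.
    """
    if interpolation != "trilinear":
        raise ValueError("only trilinear interpolation is supported")
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if p.is_identity():
        return vol.copy()
    center_vox = (np.array(vol.shape, dtype=float) - 1.0) / 2.0
    M = pose_to_matrix(p, center=(0.0, 0.0, 0.0))
    R = M[:3, :3]
    t_vox = M[:3, 3] / float(voxel_size_mm)
    # output x -> input R^T (x - c - t) + c
    Rinv = R.T
    offset = center_vox - Rinv @ (center_vox + t_vox)
    if np.iscomplexobj(vol):
        re = ndimage.affine_transform(vol.real, Rinv, offset=offset, order=1,
                                      mode="constant", cval=0.0)
        im = ndimage.affine_transform(vol.imag, Rinv, offset=offset, order=1,
                                      mode="constant", cval=0.0)
        return re + 1j * im
    return ndimage.affine_transform(vol, Rinv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


class MotionTrace:
    """Ordered head poses indexed by shot: one pose per navigator interval.

    Serialized as TSV with columns
    ``shot_index  tx_mm  ty_mm  tz_mm  rx_deg  ry_deg  rz_deg``.
    """

    _COLUMNS = ("shot_index", "tx_mm", "ty_mm", "tz_mm",
                "rx_deg", "ry_deg", "rz_deg")

    def __init__(self, poses):
        self.poses: list[Pose] = list(poses)

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i) -> Pose:
        return self.poses[i]

    def __iter__(self):
        return iter(self.poses)

    def __eq__(self, other) -> bool:
        return (isinstance(other, MotionTrace)
                and len(self) == len(other)
                and all(np.allclose(a.as_array(), b.as_array(), atol=0.0)
                        for a, b in zip(self.poses, other.poses)))

    def as_array(self) -> np.ndarray:
        """(n_shots, 6) array of [tx, ty, tz, rx, ry, rz]."""
        return np.array([p.as_array() for p in self.poses], dtype=float)

    @classmethod
    def from_array(cls, a) -> "MotionTrace":
        return cls(Pose.from_array(row) for row in np.atleast_2d(a))

    @classmethod
    def identity(cls, n_shots: int) -> "MotionTrace":
        return cls([IDENTITY] * n_shots)

    def rereference(self, ref: int) -> "MotionTrace":
        """Express every pose relative to pose ``ref`` (which becomes identity)."""
        inv_ref = invert(self.poses[ref])
        return MotionTrace([compose(inv_ref, p) for p in self.poses])

    def to_tsv(self, path) -> None:
        lines = ["\t".join(self._COLUMNS)]
        for i, p in enumerate(self.poses):
            vals = "\t".join(f"{v:.9g}" for v in p.as_array())
            lines.append(f"{i}\t{vals}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MotionTrace":
        text = Path(path).read_text().strip().splitlines()
        header = text[0].split("\t")
        if tuple(header) != cls._COLUMNS:
            raise ValueError(f"unexpected trace header {header!r}")
        rows = sorted((line.split("\t") for line in text[1:]),
                      key=lambda r: int(r[0]))
        return cls(Pose(*(float(v) for v in r[1:7])) for r in rows)
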