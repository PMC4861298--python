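"""NIfTI / TSV / HDF5 I/O and the run configuration container.

Conventions: the NIfTI affine is diagonal with the voxel size, origin at
the volume centre (scanner frame); voxel indexing is 0-based internally.
Shot k-space goes into an HDF5 container with one group per shot
(``/shots/<i>/data``, ``/shots/<i>/lines``) plus the plan as a JSON string
and the motion trace as an embedded TSV string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import AcquisitionPlan, plan_from_config, plan_to_config
from .encode import ShotData
from .geometry import MotionTrace

__all__ = ["save_volume", "load_volume", "save_shots", "load_shots",
           "RunConfig"]


def _affine(shape, voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_mm * (np.array(shape, dtype=float) - 1) / 2.0
    return aff


def save_volume(path, vol: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Write a 3D/4D volume as NIfTI (complex data saved as complex64)."""
    vol = np.asarray(vol)
    if np.iscomplexobj(vol):
        vol = vol.astype(np.complex64)
    else:
        vol = vol.astype(np.float64)
    shape3 = vol.shape[:3] if vol.ndim >= 3 else vol.shape
    img = nib.Nifti1Image(vol, _affine(shape3, voxel_mm))
    img.header.set_zooms((voxel_mm,) * 3 + (1.0,) * (vol.ndim - 3))
    nib.save(img, str(path))


def load_volume(path):
    """Read a NIfTI volume; returns ``(data, voxel_mm)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def save_shots(path, shots: list, plan: AcquisitionPlan,
               trace: MotionTrace | None = None) -> None:
    """Store ShotData + plan (+ trace) in one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("plan", data=json.dumps(plan_to_config(plan)))
        if trace is not None:
            lines = ["shot_index\ttx_mm\tty_mm\ttz_mm\trx_deg\try_deg\trz_deg"]
            for i, p in enumerate(trace):
                lines.append(f"{i}\t" + "\t".join(f"{v:.9g}"
                                                  for v in p.as_array()))
            f.create_dataset("trace", data="\n".join(lines))
        g = f.create_group("shots")
        for s in shots:
            gi = g.create_group(str(s.index))
            gi.create_dataset("data", data=s.data)
            gi.create_dataset("lines", data=s.lines)
            gi.attrs["pose_index"] = s.pose_index


def load_shots(path):
    """Read back ``(shots, plan, trace_or_None)`` from an HDF5 container."""
    with h5py.File(path, "r") as f:
        plan = plan_from_config(json.loads(f["plan"][()].decode()
                                           if isinstance(f["plan"][()], bytes)
                                           else f["plan"][()]))
        trace = None
        if "trace" in f:
            raw = f["trace"][()]
            text = raw.decode() if isinstance(raw, bytes) else raw
            rows = text.strip().splitlines()[1:]
            from .geometry import Pose
            trace = MotionTrace(
                Pose(*(float(v) for v in r.split("\t")[1:7])) for r in rows)
        shots = []
        for key in sorted(f["shots"], key=int):
            gi = f["shots"][key]
            shots.append(ShotData(index=int(key),
                                  data=gi["data"][()],
                                  lines=gi["lines"][()],
                                  pose_index=int(gi.attrs["pose_index"])))
    return shots, plan, trace


@dataclass
class RunConfig:
    """Seeded description of one synthetic acquisition + correction run."""

    protocol: str = "custom"
    n: int = 64
    n_coils: int = 8
    n_shots: int = 16
    pf: tuple = (0.75, 0.75)
    voxel_mm: float = 1.0
    contrast: str = "GRE-T2*"
    te_ms: float = 15.6
    tr_ms: float = 27.0
    amp_mm: float = 3.0
    amp_deg: float = 3.0
    jerk_at: float = 0.6  # fraction of the scan where a sudden jump occurs
    noise_std: float = 0.0
    nav_shape: tuple | None = None
    seed: int = 0
    out_dir: str | None = None

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["pf"] = list(self.pf)
        if self.nav_shape is not None:
            d["nav_shape"] = list(self.nav_shape)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pf" in d:
            d["pf"] = tuple(d["pf"])
        if d.get("nav_shape") is not None:
            d["nav_shape"] = tuple(d["nav_shape"])
        return cls(**d)
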