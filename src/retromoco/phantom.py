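"""Seeded brain-like digital phantoms, scalp-fat shells and coil sensitivities.

The phantom is a set of co-registered 3D parameter maps (proton density,
T1, T2, T2*, fat fraction) built from nested ellipsoidal compartments:
white matter, grey matter and CSF inside a "head" ellipsoid, surrounded by
a skull gap and a thin scalp-fat shell.  The fat shell moves rigidly with
the brain and is the only fat-bearing compartment, so it serves as the
object seen by a fat-selective navigator while the water compartments
provide the host-sequence contrast.

Default 7T-like tissue values (fixture choices, freely editable):
WM T1 1200 ms, GM T1 2000 ms, CSF T1 4000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "Phantom",
    "CoilSet",
    "default_compartments",
    "make_phantom",
    "make_coils",
    "contrast_image",
]


@dataclass(frozen=True)
class Compartment:
    """One ellipsoidal tissue compartment.

    ``semiaxes`` are fractions of the half-grid; later compartments overwrite
    earlier ones inside their ellipsoid (nesting by listing outside-in).
    """

    name: str
    semiaxes: tuple  # (ax, ay, az) as fraction of n/2
    center: tuple = (0.0, 0.0, 0.0)  # offset in fractions of n/2
    pd: float = 1.0
    t1_ms: float = 1000.0
    t2_ms: float = 80.0
    t2s_ms: float = 50.0
    fat_fraction: float = 0.0


def default_compartments() -> list[Compartment]:
    """Nested head: fat shell / skull gap / CSF / GM / WM, outside-in.

    The fat shell occupies the band between the outermost two ellipsoids;
    the gap between shell and CSF mimics the signal-free skull.
    """
    return [
        # outer scalp fat: short T1, bright; only fat-bearing compartment.
        # Distinct semiaxes (head-like, longer front-back) make all three
        # rotation axes observable to the navigator registration.
        Compartment("fat_shell", (0.82, 0.95, 0.72), center=(0.0, 0.0, 0.08),
                    pd=0.9, t1_ms=400.0, t2_ms=60.0, t2s_ms=30.0,
                    fat_fraction=1.0),
        Compartment("skull_gap", (0.74, 0.87, 0.64), center=(0.0, 0.0, 0.08),
                    pd=0.0, t1_ms=1000.0, t2_ms=1.0, t2s_ms=1.0),
        Compartment("csf", (0.68, 0.80, 0.58), center=(0.0, 0.0, 0.08),
                    pd=1.0, t1_ms=4000.0, t2_ms=500.0, t2s_ms=100.0),
        Compartment("gm", (0.58, 0.70, 0.50), center=(0.0, 0.0, 0.08),
                    pd=0.85, t1_ms=2000.0, t2_ms=55.0, t2s_ms=33.0),
        Compartment("wm", (0.42, 0.55, 0.36), center=(0.0, -0.05, 0.08),
                    pd=0.7, t1_ms=1200.0, t2_ms=45.0, t2s_ms=27.0),
    ]


@dataclass
class Phantom:
    """Co-registered 3D parameter maps on an isotropic grid."""

    pd: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    t2s_ms: np.ndarray
    fat_fraction: np.ndarray
    voxel_size_mm: float = 1.0
    labels: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.pd.shape[0]

    @property
    def shape(self):
        return self.pd.shape

    @property
    def water_pd(self) -> np.ndarray:
        """Proton density of the non-fat (water) fraction."""
        return self.pd * (1.0 - self.fat_fraction)

    @property
    def fat_pd(self) -> np.ndarray:
        """Proton density of the fat fraction — the navigator's object."""
        return self.pd * self.fat_fraction

    def maps(self) -> dict:
        return {"pd": self.pd, "t1_ms": self.t1_ms, "t2_ms": self.t2_ms,
                "t2s_ms": self.t2s_ms, "fat_fraction": self.fat_fraction}


def _ellipsoid_mask(n: int, semiaxes, center) -> np.ndarray:
    half = n / 2.0
    coords = np.arange(n) - (n - 1) / 2.0
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    ax, ay, az = (np.asarray(semiaxes, dtype=float) * half)
    cx, cy, cz = (np.asarray(center, dtype=float) * half)
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0


def make_phantom(n: int, seed: int = 0, spec: list[Compartment] | None = None,
                 voxel_size_mm: float = 1.0, texture: float = 0.05) -> Phantom:
    """Build an ellipsoid-compartment phantom; pure function of (args, seed).

    Parameters
    ----------
    n : int
        Isotropic grid size (n**3 voxels), n >= 16.
    seed : int
        Seed for the smooth within-compartment PD variation.
    spec : list of Compartment, optional
        Compartments listed outside-in; each overwrites the previous inside
        its ellipsoid.  Defaults to :func:`default_compartments`.
    texture : float
        Relative amplitude of the smooth within-compartment PD modulation
        (0 disables it).
    """
    if n < 16:
        raise ValueError("grid size must be >= 16")
    if spec is None:
        spec = default_compartments()

    shape = (n, n, n)
    pd = np.zeros(shape)
    t1 = np.full(shape, 1000.0)
    t2 = np.full(shape, 80.0)
    t2s = np.full(shape, 50.0)
    fat = np.zeros(shape)
    labels = np.full(shape, -1, dtype=np.int16)

    for idx, comp in enumerate(spec):
        if comp.pd < 0:
            raise ValueError(f"compartment {comp.name!r} has negative PD")
        m = _ellipsoid_mask(n, comp.semiaxes, comp.center)
        pd[m] = comp.pd
        t1[m] = comp.t1_ms
        t2[m] = comp.t2_ms
        t2s[m] = comp.t2s_ms
        fat[m] = comp.fat_fraction
        labels[m] = idx

    if texture > 0:
        rng = np.random.default_rng(seed)
        k = np.fft.fftfreq(n)
        kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
        lowpass = np.exp(-((kx**2 + ky**2 + kz**2) / (2 * 0.04**2)))
        noise = rng.standard_normal(shape)
        smooth = np.fft.ifftn(np.fft.fftn(noise) * lowpass).real
        smooth /= max(np.abs(smooth).max(), 1e-12)
        pd = pd * (1.0 + texture * smooth)
        np.clip(pd, 0.0, None, out=pd)

    # relaxation times must stay positive wherever there is signal
    signal = pd > 0
    for m_ in (t1, t2, t2s):
        m_[signal] = np.maximum(m_[signal], 1e-3)
    return Phantom(pd, t1, t2, t2s, fat, voxel_size_mm=voxel_size_mm,
                   labels=labels)


@dataclass
class CoilSet:
    """Complex receive-sensitivity maps, one per channel, on the phantom grid."""

    maps: np.ndarray  # (n_coils, n, n, n) complex

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def make_coils(n: int, n_coils: int = 8, seed: int = 0,
               radius: float = 1.1, width: float = 0.7) -> CoilSet:
    """Smooth complex coil profiles: Gaussian lobes on a ring, RSS-normalized.

    ``n_coils = 1`` returns constant unit sensitivity.  Coil centres sit on a
    ring of ``radius`` (in half-grid units) in the x-y plane, alternately
    displaced in z, with a smooth linear phase per coil.  The maps are
    globally scaled so that the root-sum-of-squares is ~1 in the object
    region (central half of the grid).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilSet(np.ones((1, n, n, n), dtype=complex))
    rng = np.random.default_rng(seed)
    half = n / 2.0
    coords = (np.arange(n) - (n - 1) / 2.0) / half
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    maps = np.empty((n_coils, n, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        cz = 0.35 if c % 2 else -0.35
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        mag = np.exp(-r2 / (2 * width**2))
        # gentle random linear phase, fixed by the seed
        g = rng.uniform(-1.0, 1.0, size=3)
        phase = np.pi * (g[0] * x + g[1] * y + g[2] * z) / 4 + ang
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    lo = n // 4
    scale = np.mean(rss[lo:n - lo, lo:n - lo, lo:n - lo])
    maps /= scale
    return CoilSet(maps)


def contrast_image(ph: Phantom, model: str, te_ms: float | None = None) -> np.ndarray:
    """Static voxelwise signal weighting for one host-sequence contrast.

    ``model`` is one of ``"GRE-T2*"`` (w = PD exp(-TE/T2*)), ``"TSE-T2"``
    (w = PD exp(-TE/T2)) or ``"PD"``.  Returns a complex volume with zero
    phase.  The MP2RAGE contrast has its own module.
    """
    if model == "PD":
        return ph.pd.astype(complex)
    if te_ms is None:
        raise ValueError(f"model {model!r} requires te_ms")
    if model == "GRE-T2*":
        relax = ph.t2s_ms
    elif model == "TSE-T2":
        relax = ph.t2_ms
    else:
        raise ValueError(f"unknown contrast model {model!r}")
    with np.errstate(divide="ignore"):
        w = np.where(ph.pd > 0, ph.pd * np.exp(-te_ms / relax), 0.0)
    return w.astype(complex)
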