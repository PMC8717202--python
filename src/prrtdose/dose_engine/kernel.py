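"""The DoseKernel type: radial table handling and voxelization.

A kernel is stored as a cumulative absorbed fraction C(r) (fraction of the
per-decay electron energy absorbed within radius r of an isotropic point
source in water) plus the total electron energy per decay. Voxelization
volume-integrates the radial energy density over each (possibly anisotropic)
voxel rather than point-sampling it: the far field uses 2³ subsamples per
voxel, the near field (where the 1/r² density varies steeply) is computed on
a 9× finer subgrid whose central element receives the energy within the
equivalent-radius sphere. The voxelized kernel is renormalized to the exact
table total, so discretization never violates energy conservation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

PACKAGED_KERNEL = "lu177_dpk_water_synthetic.csv"


class CorruptKernelError(ValueError):
    """Raised when a kernel table violates its invariants."""


@dataclass
class DoseKernel:
    """Radial dose-point kernel: cumulative absorbed fraction vs radius."""

    radius_um: np.ndarray
    cumulative_fraction: np.ndarray
    total_energy_mev: float
    provenance: str = "unknown"

    def __post_init__(self):
        r = np.asarray(self.radius_um, dtype=float)
        c = np.asarray(self.cumulative_fraction, dtype=float)
        if r.ndim != 1 or r.shape != c.shape or len(r) < 2:
            raise CorruptKernelError("kernel table must be two equal-length 1-D columns")
        if np.any(np.diff(r) <= 0):
            raise CorruptKernelError("kernel radii must be strictly increasing")
        if np.any(np.diff(c) < 0):
            raise CorruptKernelError("cumulative absorbed fraction must be nondecreasing")
        if not np.isclose(c[-1], 1.0, atol=1e-6):
            raise CorruptKernelError("cumulative absorbed fraction must reach 1 at truncation")
        if self.total_energy_mev <= 0:
            raise CorruptKernelError("total energy per decay must be positive")
        self.radius_um = r
        self.cumulative_fraction = np.clip(c, 0.0, 1.0)

    @property
    def truncation_radius_um(self) -> float:
        """Radius beyond which the kernel deposits nothing."""
        idx = np.searchsorted(self.cumulative_fraction, 1.0 - 1e-9)
        return float(self.radius_um[min(idx, len(self.radius_um) - 1)])

    def cumulative_energy_mev(self, r_um) -> np.ndarray:
        """Energy (MeV) absorbed within radius r of a point source."""
        r_full = np.concatenate([[0.0], self.radius_um])
        c_full = np.concatenate([[0.0], self.cumulative_fraction])
        return np.interp(r_um, r_full, c_full) * self.total_energy_mev

    def voxelize(self, spacing_um, anisotropy_tol: float = 5.0) -> np.ndarray:
        """3-D voxel kernel: energy (MeV) deposited per voxel per decay.

        The returned array is odd-sized and centered on the source voxel.
        """
        px, py, pz = (float(s) for s in spacing_um)
        if max(px, py, pz) / min(px, py, pz) > anisotropy_tol:
            raise ValueError(
                f"voxel anisotropy {max(px,py,pz)/min(px,py,pz):.1f} exceeds "
                f"kernel resampling tolerance {anisotropy_tol}"
            )
        r_full = np.concatenate([[0.0], self.radius_um])
        c_full = np.concatenate([[0.0], self.cumulative_fraction]) * self.total_energy_mev
        density = np.gradient(c_full, r_full)  # dC/dr, MeV/um

        rmax = self.truncation_radius_um
        nx, ny, nz = (int(np.ceil(rmax / p)) for p in (px, py, pz))
        ax = np.arange(-nx, nx + 1) * px
        ay = np.arange(-ny, ny + 1) * py
        az = np.arange(-nz, nz + 1) * pz
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")

        K = np.zeros_like(X)
        offs = (np.arange(2) - 0.5) / 2.0
        for sx in offs * px:
            for sy in offs * py:
                for sz in offs * pz:
                    r = np.sqrt((X + sx) ** 2 + (Y + sy) ** 2 + (Z + sz) ** 2)
                    K += np.interp(r, r_full, density) / (
                        4.0 * np.pi * np.maximum(r, 1e-9) ** 2
                    )
        K *= px * py * pz / 8.0

        # near field on a 9x finer subgrid (handles the 1/r^2 divergence)
        nn, f = 2, 9
        idx = np.arange((2 * nn + 1) * f) - ((2 * nn + 1) * f - 1) / 2.0
        Xf, Yf, Zf = np.meshgrid(idx * px / f, idx * py / f, idx * pz / f, indexing="ij")
        rf = np.sqrt(Xf**2 + Yf**2 + Zf**2)
        Kf = np.interp(rf, r_full, density) / (4.0 * np.pi * np.maximum(rf, 1e-9) ** 2)
        Kf *= px * py * pz / f**3
        r_eq = (3.0 * px * py * pz / f**3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        center = np.unravel_index(np.argmin(rf), rf.shape)
        Kf[center] = np.interp(r_eq, r_full, c_full)
        near = Kf.reshape(2 * nn + 1, f, 2 * nn + 1, f, 2 * nn + 1, f).sum(axis=(1, 3, 5))
        K[nx - nn : nx + nn + 1, ny - nn : ny + nn + 1, nz - nn : nz + nn + 1] = near

        return K * (self.total_energy_mev / K.sum())


def build_kernel(path: str | Path | None = None) -> DoseKernel:
    """Load a radial kernel table (CSV: radius_um, cumulative_fraction).

    With no path, loads the packaged synthetic ¹⁷⁷Lu water kernel. Header
    comment lines may carry ``total_energy_mev=`` and ``provenance=`` tags.
    """
    if path is None:
        ref = resources.files("prrtdose.dose_engine") / "data" / PACKAGED_KERNEL
        text = ref.read_text()
    else:
        text = Path(path).read_text()

    total_energy = None
    provenance = "unknown"
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("total_energy_mev="):
                total_energy = float(body.split("=", 1)[1])
            elif body.startswith("provenance="):
                provenance = body.split("=", 1)[1]
            continue
        rows.append(line)
    reader = csv.reader(rows)
    header = next(reader)
    if [h.strip() for h in header] != ["radius_um", "cumulative_fraction"]:
        raise CorruptKernelError(f"unexpected kernel table columns: {header}")
    data = np.array([[float(a), float(b)] for a, b in reader])
    if total_energy is None:
        raise CorruptKernelError("kernel table lacks a total_energy_mev header tag")
    return DoseKernel(data[:, 0], data[:, 1], total_energy, provenance)
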