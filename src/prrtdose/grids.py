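"""Raster containers for 3-D voxel models, activity maps and dose maps.

Arrays are indexed ``(ix, iy, iz)`` with physical position
``origin + index * spacing`` (0-based indices; spacing in μm). NRRD I/O goes
through SimpleITK, which stores arrays ``(z, y, x)``; the transpose is handled
here so user code never sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

LABEL_BACKGROUND = 0
LABEL_HEALTHY = 1
LABEL_TUMOR = 2


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive lengths in um, got {spacing}")
    return spacing


@dataclass
class VoxelGrid:
    """Cell-type label grid with an optional receptor-expression field.

    labels: uint8 array with values in {background, healthy, tumor}.
    expression: nonnegative intensity, zero outside tissue (same shape).
    spacing: voxel pitch in μm.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    expression: np.ndarray | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = _check_spacing(self.spacing)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.expression is not None:
            self.expression = np.asarray(self.expression, dtype=float)
            if self.expression.shape != self.labels.shape:
                raise ValueError("expression shape must match labels")
            if np.any(self.expression < 0):
                raise ValueError("expression intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == LABEL_TUMOR

    def tumor_fraction(self) -> float:
        """Tumor voxels as a fraction of tissue voxels."""
        n_tissue = int(self.tissue_mask.sum())
        if n_tissue == 0:
            return 0.0
        return float(self.tumor_mask.sum()) / n_tissue


@dataclass
class ActivityMap:
    """Per-voxel activity (Bq, or decay weights when normalized)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = _check_spacing(self.spacing)
        if self.values.ndim != 3:
            raise ValueError("activity map must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("activities must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def decay_weights(self) -> np.ndarray:
        """Per-voxel probability that a given decay occurs in that voxel."""
        tot = self.total
        if tot <= 0:
            raise ValueError("activity map has zero total activity")
        return self.values / tot


@dataclass
class DoseMap:
    """3-D absorbed dose (``unit`` is 'Gy/decay' or 'Gy' or 'mGy/h')."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: str = "Gy/decay"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_mass_kg(self) -> float:
        # water density: 1 um^3 of water = 1e-15 kg
        return float(np.prod(self.spacing)) * 1e-15

    def scaled(self, factor: float, unit: str) -> "DoseMap":
        return replace(self, values=self.values * factor, unit=unit)


def write_nrrd(path: str | Path, values: np.ndarray, spacing_um, origin_um=(0, 0, 0)) -> None:
    """Write a 3-D raster as NRRD with spacing metadata in mm."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(values, (2, 1, 0))))
    img.SetSpacing([s / 1000.0 for s in spacing_um])
    img.SetOrigin([o / 1000.0 for o in origin_um])
    sitk.WriteImage(img, str(path), useCompression=False)


def read_nrrd(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NRRD; returns (values indexed (x,y,z), spacing in μm)."""
    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = tuple(s * 1000.0 for s in img.GetSpacing())
    return values, spacing
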