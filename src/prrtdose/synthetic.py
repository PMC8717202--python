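"""Synthetic study inputs with controlled ground truth.

The real study worked from excised-tissue immunofluorescence: SSTR2 tile
scans defining voxelized tissue/activity models, biodistribution series,
in vitro γH2AX foci decay, caliper tumor-volume curves, and high-resolution
costained sections. This module emulates each of those inputs from known
parameters so every downstream fit can be checked against its truth.

Receptor-like expression is modelled as an exponentiated gaussian random
field with a squared-exponential kernel: spatially smooth, strictly
positive, with a controllable correlation length and high/low-intensity
contrast. Tissue occupies an ellipsoid in the grid; tumor voxels are the
top quantile of a second, independent correlated field, thresholded by rank
so the tumor fraction is met to within one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .grids import LABEL_HEALTHY, LABEL_TUMOR, ActivityMap, VoxelGrid
from .kinetics import KineticParams, dose_rate
from .survival import RadiobiologyParams


@dataclass
class TissuePhantomSpec:
    """Geometry and texture of a synthetic tissue phantom.

    Default size is a 2x-coarsened version of the study stack (128x128x64 at
    11.4x11.4x20 μm) so full pipeline runs stay fast; the full-resolution
    507x507x289 grid at 5.7x5.7x10 μm is supported but not default.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_size_um: tuple[float, float, float] = (11.4, 11.4, 20.0)
    tumor_fraction: float = 0.97
    expression_correlation_length_um: float = 50.0
    expression_contrast: float = 4.0
    tissue_fill: float = 1.0  # fraction of each semi-axis the tissue ellipsoid spans
    seed: int = 0

    def __post_init__(self):
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid dimensions must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor fraction must lie in [0, 1]")
        if self.expression_correlation_length_um <= 0:
            raise ValueError("correlation length must be positive")
        if self.expression_contrast <= 0:
            raise ValueError("expression contrast must be positive")
        if not 0.0 < self.tissue_fill <= 1.0:
            raise ValueError("tissue_fill must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Simulation truth seeding every generator (anchored to the study's
    printed estimates where they exist, realistic values elsewhere)."""

    kinetics: KineticParams
    radiobiology: RadiobiologyParams
    dsb_yield_per_mgy: float = 0.0223
    foci_t0_per_cell: float = 8.0
    v0_mm3: float = 300.0
    k0_per_d: float = 0.12
    k1_per_d: float = 0.25
    k2_per_d: float = field(default=None)  # type: ignore[assignment]
    t0_d: float = 3.0
    t1_d: float = 20.0

    def __post_init__(self):
        if self.k2_per_d is None:
            # choose regrowth rate so ln2/(k0-k1+k2) equals the doubling time
            # implied by the radiobiology repopulation rate
            td_d = np.log(2.0) / (self.radiobiology.gamma * 24.0)
            self.k2_per_d = np.log(2.0) / td_d - self.k0_per_d + self.k1_per_d
        if self.dsb_yield_per_mgy < 0:
            raise ValueError("DSB yield must be nonnegative")
        if min(self.k0_per_d, self.k1_per_d, self.k2_per_d) < 0:
            raise ValueError("growth/shrinkage rates must be nonnegative")
        if not self.t0_d < self.t1_d:
            raise ValueError("shrinkage onset must precede regrowth onset")

    @property
    def td_days(self) -> float:
        return float(np.log(2.0) / (self.k0_per_d - self.k1_per_d + self.k2_per_d))

    @property
    def t_mu_h(self) -> float:
        return float(np.log(2.0) / self.radiobiology.mu)


def default_ground_truth(alpha: float = 0.14, alpha_beta_ratio: float = 100.0,
                         alpha_sd: float | None = None) -> GroundTruth:
    """Study-condition truth: T_μ=60 h, T_D=14.5 d, pooled DSB yield
    0.0223 per cell per mGy; kinetics are realistic stand-ins (the study's
    fitted biodistribution parameters are not published)."""
    kin = KineticParams(r0=40.0, p=2.0, lambda_e=np.log(2.0) / 55.0)
    rad = RadiobiologyParams.from_half_times(
        alpha=alpha, alpha_beta_ratio=alpha_beta_ratio, t_mu_h=60.0, t_d_days=14.5,
        alpha_sd=alpha_sd,
    )
    return GroundTruth(kinetics=kin, radiobiology=rad)


# ------------------------------------------------------------------ fields

def correlated_field(
    shape: tuple[int, ...],
    spacing_um: tuple[float, ...],
    correlation_length_um: float,
    seed: int,
) -> np.ndarray:
    """Standardized gaussian random field with squared-exponential correlation.

    White noise smoothed with a gaussian of σ = ℓ/√2 per axis has correlation
    ρ(r) = exp(−r²/2ℓ²), i.e. ρ(ℓ) = e^(−1/2); ℓ is the correlation length.
    Periodic boundary handling keeps the field stationary.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma_vox = [correlation_length_um / np.sqrt(2.0) / s for s in spacing_um]
    smooth = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0:
        raise ValueError("degenerate field (correlation length too large for grid)")
    return smooth / sd


def _ellipsoid_mask(shape, fill: float) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= fill**2


def generate_tissue(spec: TissuePhantomSpec) -> VoxelGrid:
    """Voxelized tissue model: labels {background, healthy, tumor} and a
    positive, spatially correlated receptor-expression intensity.

    Tumor voxels are the top ``tumor_fraction`` quantile (by rank, exact to
    one voxel) of an independent correlated field within the tissue
    ellipsoid. Expression is exp(s·g) with g a standardized correlated field
    and s = ln(contrast)/2, so the ±1σ intensity modes differ by the
    requested contrast ratio; expression is zero outside tissue.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    tissue = _ellipsoid_mask(spec.grid_shape, spec.tissue_fill)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue ellipsoid contains no voxels")

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[tissue] = LABEL_HEALTHY
    n_tumor = int(round(spec.tumor_fraction * n_tissue))
    if n_tumor > 0:
        label_field = correlated_field(
            spec.grid_shape, spec.voxel_size_um,
            spec.expression_correlation_length_um, int(seeds[0]),
        )
        vals = label_field[tissue]
        cutoff = np.partition(vals, n_tissue - n_tumor)[n_tissue - n_tumor]
        tumor = tissue & (label_field >= cutoff)
        # rank threshold can tie; trim any excess deterministically
        excess = int(tumor.sum()) - n_tumor
        if excess > 0:
            idx = np.flatnonzero(tumor.ravel() & (label_field.ravel() == cutoff))[:excess]
            tumor.ravel()[idx] = False
        labels[tumor] = LABEL_TUMOR

    s = np.log(spec.expression_contrast) / 2.0
    g = correlated_field(
        spec.grid_shape, spec.voxel_size_um,
        spec.expression_correlation_length_um, int(seeds[1]),
    )
    expression = np.where(tissue, np.exp(s * g), 0.0)
    return VoxelGrid(labels=labels, spacing=spec.voxel_size_um, expression=expression)


def generate_activity_map(
    grid: VoxelGrid, total_activity_bq: float, specificity: float = 1.0
) -> ActivityMap:
    """Activity ∝ receptor expression in tumor voxels; the non-specific
    remainder (1 − specificity) is uniform over all tissue voxels. The map
    sums exactly to the requested total."""
    if total_activity_bq < 0:
        raise ValueError("total activity must be nonnegative")
    if not 0.0 <= specificity <= 1.0:
        raise ValueError("specificity must lie in [0, 1]")
    if grid.expression is None:
        raise ValueError("grid has no expression field")
    tumor = grid.tumor_mask
    tissue = grid.tissue_mask
    values = np.zeros(grid.shape, dtype=float)
    bound = grid.expression * tumor
    if specificity > 0:
        if bound.sum() <= 0:
            raise ValueError("specific binding requested but no expressing tumor voxels")
        values += specificity * total_activity_bq * bound / bound.sum()
    if specificity < 1:
        n_tissue = int(tissue.sum())
        if n_tissue == 0:
            raise ValueError("no tissue voxels for the non-specific component")
        values += (1.0 - specificity) * total_activity_bq * tissue / n_tissue
    return ActivityMap(values, grid.spacing)


# ------------------------------------------------------------- time series

def generate_biodistribution(
    truth: GroundTruth, times_h, noise_cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Bound-activity time series following the biexponential dose-rate
    shape, with multiplicative lognormal noise of the stated CV."""
    times = np.asarray(times_h, dtype=float)
    if times.size == 0:
        raise ValueError("no sampling times given")
    values = dose_rate(truth.kinetics, times).astype(float)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        values = values * rng.lognormal(-sigma**2 / 2.0, sigma, size=times.shape)
    return pd.DataFrame({"t_h": times, "value_mgy_per_h": values})


def generate_foci_series(
    truth: GroundTruth, times_h, n_cells: int = 500, seed: int = 0, exact: bool = False
) -> pd.DataFrame:
    """γH2AX foci per cell decaying mono-exponentially with half-life T_μ.

    Per time point the reported value is the mean of ``n_cells`` Poisson
    draws around the true mean; ``exact=True`` returns the noiseless curve.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    times = np.asarray(times_h, dtype=float)
    if times.size == 0:
        raise ValueError("no sampling times given")
    mean = truth.foci_t0_per_cell * np.exp(-truth.radiobiology.mu * times)
    if exact:
        observed = mean
    else:
        rng = np.random.default_rng(seed)
        observed = np.array(
            [rng.poisson(m, size=n_cells).mean() for m in mean], dtype=float
        )
    return pd.DataFrame({"t_h": times, "foci_per_cell": observed, "n_cells": n_cells})


def generate_volume_curve(
    truth: GroundTruth, times_d, noise_cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Tumor volume following the piecewise-exponential growth model
    (growth at k0, shrinkage from T0, regrowth from T1), lognormal noise."""
    from .survival import growth_curve

    times = np.asarray(times_d, dtype=float)
    if times.size == 0:
        raise ValueError("no sampling times given")
    v = growth_curve(times, truth.v0_mm3, truth.k0_per_d, truth.k1_per_d,
                     truth.k2_per_d, truth.t0_d, truth.t1_d)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        v = v * rng.lognormal(-sigma**2 / 2.0, sigma, size=times.shape)
    return pd.DataFrame({"t_d": times, "volume_mm3": v})


# ----------------------------------------------------- costained sections

@dataclass
class CostainedSection:
    """High-resolution 2-D section: expression image + per-cell DSB counts."""

    image: np.ndarray            # uint16 expression raster
    cells: pd.DataFrame          # columns: x_px, y_px, dsb_count
    mean_dose_mgy: float         # true mean dose over sampled cells
    pixel_size_um: float


def generate_costained_section(
    spec: TissuePhantomSpec,
    truth: GroundTruth,
    dose_map_mgy: np.ndarray,
    n_cells: int = 2000,
    pixel_size_um: float = 0.325,
    seed: int = 0,
) -> CostainedSection:
    """Costained 2-D section: a correlated expression raster (16-bit range)
    plus Poisson DSB counts, mean = dsb_yield × local absorbed dose (mGy),
    for cells at uniformly random pixel positions."""
    dose = np.asarray(dose_map_mgy, dtype=float)
    if dose.ndim != 2:
        raise ValueError("dose map for a section must be 2-D")
    if dose.shape != tuple(spec.grid_shape[:2]):
        raise ValueError(
            f"dose map shape {dose.shape} does not match the section plane "
            f"{tuple(spec.grid_shape[:2])}"
        )
    rng = np.random.default_rng(seed)
    g = correlated_field(
        dose.shape, (pixel_size_um, pixel_size_um),
        spec.expression_correlation_length_um, int(rng.integers(2**31 - 1)),
    )
    expr = np.exp(np.log(spec.expression_contrast) / 2.0 * g)
    image = np.round(expr / expr.max() * 60000.0).astype(np.uint16)

    xs = rng.integers(0, dose.shape[0], size=n_cells)
    ys = rng.integers(0, dose.shape[1], size=n_cells)
    local_dose = dose[xs, ys]
    counts = rng.poisson(truth.dsb_yield_per_mgy * local_dose)
    cells = pd.DataFrame({"x_px": xs, "y_px": ys, "dsb_count": counts})
    return CostainedSection(
        image=image,
        cells=cells,
        mean_dose_mgy=float(local_dose.mean()),
        pixel_size_um=pixel_size_um,
    )


def write_section_tiff(path, section: CostainedSection) -> None:
    """Write the section's expression raster as a 16-bit TIFF with
    pixel-size metadata (pixels per cm, as TIFF resolution expects)."""
    px_per_cm = 1e4 / section.pixel_size_um
    tifffile.imwrite(
        str(path), section.image, resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_section_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))
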