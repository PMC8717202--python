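"""Dose–DSB correlation and χ² template matching on expression rasters.

The dose–DSB analysis regresses mean γH2AX foci per cell against the mean
absorbed dose to cancer cells, per tumor (slope distribution, tested for
normality) and pooled over all sections (OLS with a t-based 95% CI).

Template matching localizes regions of a large tissue section resembling a
small high-expression/high-DSB template: a sliding window is compared to
the template by the χ² distance between intensity histograms of min-max
normalized patches — scale-robust for immunofluorescence stainings, where
absolute intensities are not comparable across scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from skimage.filters import threshold_otsu


@dataclass
class SectionRecord:
    """One costained section: mean dose to cancer cells and mean DSB count."""

    section_id: str
    tumor_id: str
    mean_dose_mgy: float
    dsb_per_cell: float
    n_cells: int = 0

    def __post_init__(self):
        if self.mean_dose_mgy < 0 or self.dsb_per_cell < 0:
            raise ValueError("dose and DSB per cell must be nonnegative")


@dataclass
class DoseDSBFit:
    """Per-tumor and pooled dose-response of DSB induction."""

    per_tumor_slopes: dict[str, float]
    mean_slope: float
    slope_normality_p: float
    pooled_slope: float
    pooled_slope_ci95: tuple[float, float]
    pooled_intercept: float
    pooled_r_squared: float


def fit_dose_dsb(records: list[SectionRecord]) -> DoseDSBFit:
    """Per-tumor simple regressions plus pooled OLS of DSB/cell on dose.

    The pooled CI half-width uses the t distribution on the OLS slope
    standard error. Shapiro–Wilk tests the per-tumor slopes for normality
    (needs at least 3 tumors with >= 2 sections each; NaN otherwise).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 sections for the pooled regression")
    x = np.array([r.mean_dose_mgy for r in records])
    y = np.array([r.dsb_per_cell for r in records])
    if np.ptp(x) == 0:
        raise ValueError("all sections share one mean dose; no slope is identifiable")

    slopes: dict[str, float] = {}
    for tumor in sorted({r.tumor_id for r in records}):
        sel = [r for r in records if r.tumor_id == tumor]
        if len(sel) >= 2:
            xs = np.array([r.mean_dose_mgy for r in sel])
            ys = np.array([r.dsb_per_cell for r in sel])
            if np.ptp(xs) > 0:
                slopes[tumor] = float(np.polyfit(xs, ys, 1)[0])
    slope_vals = np.array(list(slopes.values()))
    if len(slope_vals) >= 3 and np.ptp(slope_vals) > 0:
        normality_p = float(stats.shapiro(slope_vals)[1])
    else:
        normality_p = float("nan")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return DoseDSBFit(
        per_tumor_slopes=slopes,
        mean_slope=float(slope_vals.mean()) if len(slope_vals) else float("nan"),
        slope_normality_p=normality_p,
        pooled_slope=float(model.params[1]),
        pooled_slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        pooled_intercept=float(model.params[0]),
        pooled_r_squared=float(model.rsquared),
    )


# ----------------------------------------------------------- thresholding

def threshold_expression(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Otsu two-class split into (low, high) expression masks.

    The masks partition the image; a constant image has no threshold and
    raises.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expression image must be single-channel 2-D")
    if np.ptp(img) == 0:
        raise ValueError("constant image: threshold is degenerate")
    thr = threshold_otsu(img)
    high = img > thr
    return ~high, high


# -------------------------------------------------------- template match

@dataclass
class TemplateMatchMap:
    """Sliding-window χ² dissimilarity between a section and a template.

    chi2: raster over window positions (smaller = more similar);
    positions: top-left corner (row, col) of each window;
    best: coordinates of the global minimum.
    """

    chi2: np.ndarray
    row_starts: np.ndarray
    col_starts: np.ndarray
    window_shape: tuple[int, int]
    stride: int
    best: tuple[int, int]


def _patch_histogram(patch: np.ndarray, n_bins: int) -> np.ndarray:
    p = patch.astype(float)
    rng_ = np.ptp(p)
    if rng_ > 0:
        p = (p - p.min()) / rng_
    else:
        p = np.zeros_like(p)
    h, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return h / h.sum()


def chi2_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Symmetric χ² distance between two normalized histograms."""
    denom = h1 + h2
    ok = denom > 0
    return float(np.sum((h1[ok] - h2[ok]) ** 2 / denom[ok]))


def template_match(
    test_image: np.ndarray,
    template: np.ndarray,
    stride: int | None = None,
    n_bins: int = 32,
    pixelwise: bool = False,
) -> TemplateMatchMap:
    """χ² similarity map of a template slid over a larger test image.

    Default metric: χ² distance between 32-bin intensity histograms of
    min-max normalized patches. ``pixelwise=True`` switches to the χ²
    distance computed pixel-by-pixel on the normalized patches instead.
    Default stride is a quarter of the template size.
    """
    img = np.asarray(test_image)
    tpl = np.asarray(template)
    if img.ndim != 2 or tpl.ndim != 2:
        raise ValueError("images must be 2-D")
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise ValueError("template must not be larger than the test image")
    if stride is None:
        stride = max(min(tpl.shape) // 4, 1)
    if stride < 1:
        raise ValueError("stride must be >= 1")

    th, tw = tpl.shape
    rows = np.arange(0, img.shape[0] - th + 1, stride)
    cols = np.arange(0, img.shape[1] - tw + 1, stride)

    def normalize(p):
        p = p.astype(float)
        r = np.ptp(p)
        return (p - p.min()) / r if r > 0 else np.zeros_like(p)

    if pixelwise:
        tnorm = normalize(tpl)
    else:
        thist = _patch_histogram(tpl, n_bins)

    chi2 = np.empty((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            win = img[r : r + th, c : c + tw]
            if pixelwise:
                wnorm = normalize(win)
                denom = wnorm + tnorm
                ok = denom > 0
                chi2[i, j] = float(np.sum((wnorm[ok] - tnorm[ok]) ** 2 / denom[ok]))
            else:
                chi2[i, j] = chi2_distance(_patch_histogram(win, n_bins), thist)
    best = np.unravel_index(np.argmin(chi2), chi2.shape)
    return TemplateMatchMap(
        chi2=chi2,
        row_starts=rows,
        col_starts=cols,
        window_shape=(th, tw),
        stride=stride,
        best=(int(rows[best[0]]), int(cols[best[1]])),
    )


@dataclass
class OverlapReport:
    """Agreement of template similarity with the local absorbed dose."""

    rank_correlation: float
    rank_p_value: float
    top_decile_overlap: float


def flag_high_dsb_regions(match: TemplateMatchMap, dose_map_2d: np.ndarray) -> OverlapReport:
    """Do the most template-similar windows sit on the highest-dose areas?

    Computes the Spearman correlation between similarity (negated χ²) and
    the window-mean dose, and the fraction of top-decile-similar windows
    that are also top-decile in dose.
    """
    dose = np.asarray(dose_map_2d, dtype=float)
    th, tw = match.window_shape
    if dose.shape[0] < match.row_starts[-1] + th or dose.shape[1] < match.col_starts[-1] + tw:
        raise ValueError("dose map does not cover the matched windows")
    mean_dose = np.empty_like(match.chi2)
    for i, r in enumerate(match.row_starts):
        for j, c in enumerate(match.col_starts):
            mean_dose[i, j] = dose[r : r + th, c : c + tw].mean()
    sim = -match.chi2.ravel()
    d = mean_dose.ravel()
    rho, p = stats.spearmanr(sim, d)
    k = max(len(sim) // 10, 1)
    top_sim = np.argsort(sim)[-k:]
    top_dose = np.argsort(d)[-k:]
    overlap = len(np.intersect1d(top_sim, top_dose)) / k
    return OverlapReport(
        rank_correlation=float(rho), rank_p_value=float(p), top_decile_overlap=float(overlap)
    )
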