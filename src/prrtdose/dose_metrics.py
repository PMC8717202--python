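"""Dose-distribution descriptors: DVH, gEUD, S-value comparison, normality.

The generalized equivalent uniform dose is the power mean of order ``a`` of
voxel doses; a negative exponent penalizes cold spots and is the standard
choice for tumors. The cumulative DVH reports the volume fraction receiving
at least each dose level; the fraction of volume at or above the mean dose
summarizes how well the mean represents the distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_engine.engine import SValueResult


@dataclass
class DVH:
    """Normalized dose-volume histogram (frequency + cumulative forms)."""

    bin_edges: np.ndarray        # Gy
    frequency: np.ndarray        # sums to 1
    cumulative: np.ndarray       # volume fraction receiving >= left bin edge
    fraction_ge_mean: float      # computed from the raw sample, not the bins
    mean_dose: float
    median_dose: float


def dvh(dose_values: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 256) -> DVH:
    """DVH of a dose map over a region (equal-width bins).

    ``dose_values`` may be any array; ``mask`` selects the region (required
    to be nonempty when given).
    """
    d = np.asarray(dose_values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != d.shape:
            raise ValueError("mask shape must match dose map")
        if not mask.any():
            raise ValueError("region mask is empty")
        d = d[mask]
    d = d.ravel()
    if d.size == 0:
        raise ValueError("no voxels to histogram")
    freq, edges = np.histogram(d, bins=n_bins)
    freq = freq / freq.sum()
    cumulative = np.concatenate([[1.0], 1.0 - np.cumsum(freq)])
    cumulative = np.clip(cumulative, 0.0, 1.0)
    mean = float(d.mean())
    return DVH(
        bin_edges=edges,
        frequency=freq,
        cumulative=cumulative,
        fraction_ge_mean=float((d >= mean).mean()),
        mean_dose=mean,
        median_dose=float(np.median(d)),
    )


def geud(dose_values: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose: (mean of dᵃ)^(1/a).

    a=1 is the arithmetic mean; a→−∞ approaches the minimum dose. For a<0,
    zero-dose voxels make the power mean collapse; they are excluded with a
    warning reporting the count (0.0 is returned if every voxel is cold).
    """
    if a == 0:
        raise ValueError("gEUD exponent must be nonzero")
    d = np.asarray(dose_values, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty dose sample")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    if a < 0:
        n_zero = int((d == 0).sum())
        if n_zero:
            warnings.warn(
                f"gEUD(a={a}): excluding {n_zero} zero-dose voxels "
                "(power mean diverges); cold coverage is under-penalized",
                stacklevel=2,
            )
            d = d[d > 0]
            if d.size == 0:
                return 0.0
    return float(np.mean(d**a) ** (1.0 / a))


@dataclass
class SValueComparison:
    """Heterogeneous-vs-homogeneous S-value percent differences."""

    percent_differences: np.ndarray  # (S_het - S_hom)/S_hom, in %
    max_spread_percent: float        # max - min percent difference
    t_statistic: float
    p_value: float


def compare_s_values(het: list[SValueResult], hom: SValueResult) -> SValueComparison:
    """Percent excess of each heterogeneous S value over the homogeneous
    reference, plus a paired two-sided t test of the difference."""
    if len(het) < 2:
        raise ValueError("need at least 2 heterogeneous S values for the paired test")
    s_het = np.array([h.s_gy_per_decay for h in het])
    s_hom = hom.s_gy_per_decay
    if s_hom <= 0:
        raise ValueError("homogeneous S value must be positive")
    pct = (s_het - s_hom) / s_hom * 100.0
    tstat, pval = stats.ttest_rel(s_het, np.full_like(s_het, s_hom))
    return SValueComparison(
        percent_differences=pct,
        max_spread_percent=float(pct.max() - pct.min()),
        t_statistic=float(tstat),
        p_value=float(pval),
    )


@dataclass
class NormalityReport:
    """Shapiro–Wilk result plus a Q–Q straightness summary."""

    statistic: float
    p_value: float
    qq_r_squared: float
    degenerate: bool


def normality_report(sample: np.ndarray) -> NormalityReport:
    """Shapiro–Wilk test and Q–Q plot R² against normal quantiles.

    A constant sample is degenerate and flagged rather than tested.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        return NormalityReport(float("nan"), float("nan"), float("nan"), degenerate=True)
    stat, p = stats.shapiro(x)
    (_, _), (_, _, r) = stats.probplot(x, dist="norm")
    return NormalityReport(float(stat), float(p), float(r**2), degenerate=False)
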