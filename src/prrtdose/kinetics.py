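"""Biexponential dose-rate kinetics and effective-half-life fitting.

The per-voxel (or region-average) dose rate after injection follows

    dD/dt (t) = (R0 - P) exp(-λe t) + P exp(-λp t),    t in hours,

where R0 is the initial dose rate, P a slowly clearing "biologic plateau"
amplitude decaying only with the ¹⁷⁷Lu physical constant λp, and λe the
effective (biological + physical) clearance rate of the fast component. Its
time integral gives the cumulative dose; both have closed forms used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import LAMBDA_P_LU177


@dataclass
class KineticParams:
    """Parameters of the biexponential dose-rate time course.

    r0 may be a scalar (region average, mGy/h) or a voxel map; p, lambda_e
    and lambda_p are scalars. Invariant: lambda_e > lambda_p > 0 and
    r0 >= p >= 0.
    """

    r0: float | np.ndarray
    p: float
    lambda_e: float
    lambda_p: float = LAMBDA_P_LU177

    def __post_init__(self):
        if not (self.lambda_e > self.lambda_p > 0):
            raise ValueError(
                f"need lambda_e > lambda_p > 0, got {self.lambda_e}, {self.lambda_p}"
            )
        if self.p < 0 or np.any(np.asarray(self.r0) < self.p):
            raise ValueError("need r0 >= p >= 0")

    def normalized_rate_shape(self, t_h) -> np.ndarray:
        """dD/dt divided by R0 — the shared bound-fraction time shape that a
        per-voxel amplitude map multiplies. Requires scalar r0."""
        if not np.isscalar(self.r0):
            raise ValueError("normalized shape requires a scalar-amplitude template")
        return dose_rate(self, t_h) / self.r0

    def normalized_dose_shape(self, t_h) -> np.ndarray:
        """Cumulative dose divided by R0 (hours); scalar-r0 template only."""
        if not np.isscalar(self.r0):
            raise ValueError("normalized shape requires a scalar-amplitude template")
        return cumulative_dose(self, t_h) / self.r0


@dataclass
class TreatmentSchedule:
    """Interval boundaries in days; default is the 0-2, 2-5, 5-11, 11-14 d split."""

    boundaries_d: tuple[float, ...] = (0.0, 2.0, 5.0, 11.0, 14.0)

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries_d)
        if len(b) < 2 or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("schedule boundaries must be strictly increasing")
        self.boundaries_d = b

    @property
    def boundaries_h(self) -> np.ndarray:
        return np.asarray(self.boundaries_d) * 24.0

    @property
    def intervals_h(self) -> list[tuple[float, float]]:
        b = self.boundaries_h
        return list(zip(b[:-1], b[1:]))


def dose_rate(params: KineticParams, t_h) -> np.ndarray:
    """Dose rate (mGy/h) at time t (hours); vectorizes over t and voxel r0."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    r0 = np.asarray(params.r0)
    return (r0 - params.p) * np.exp(-params.lambda_e * t) + params.p * np.exp(
        -params.lambda_p * t
    )


def cumulative_dose(params: KineticParams, t_h) -> np.ndarray:
    """Cumulative dose (mGy) over [0, t]; t may be np.inf for the asymptote."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    r0 = np.asarray(params.r0)
    fast = (r0 - params.p) / params.lambda_e * -np.expm1(-params.lambda_e * t)
    slow = params.p / params.lambda_p * -np.expm1(-params.lambda_p * t)
    return fast + slow


@dataclass
class FitReport:
    """Model-selection report for a time-activity fit."""

    selected_model: str  # "biexponential" | "monoexponential"
    r_squared: float
    adequate: bool  # R^2 >= 0.7
    aicc: dict = field(default_factory=dict)
    effective_half_life_h: float = float("nan")


def _aicc(rss: float, n: int, k: int) -> float:
    if n <= k + 1:
        return np.inf
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_biexponential(
    t_h, values, lambda_p: float = LAMBDA_P_LU177, n_starts: int = 12
) -> tuple[KineticParams, FitReport]:
    """Least-squares fit of the biexponential dose-rate model.

    λp is fixed to the ¹⁷⁷Lu physical constant; λe and the amplitudes are
    free. A mono-exponential (P=0) alternative is fitted too and the model
    with lower AICc is reported. Multistart over log-spaced λe guards
    against local minima; ties break toward lower AICc then smaller λe.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points to fit kinetics")

    def biexp(tt, r0, p, lam_e):
        return (r0 - p) * np.exp(-lam_e * tt) + p * np.exp(-lambda_p * tt)

    def monoexp(tt, r0, lam_e):
        return r0 * np.exp(-lam_e * tt)

    span = max(t.max() - t.min(), 1.0)
    lam_starts = np.geomspace(0.3 / span, 30.0 / span, n_starts)
    lam_starts = lam_starts[lam_starts > lambda_p * 1.01]
    if len(lam_starts) == 0:
        lam_starts = np.array([lambda_p * 2.0])
    y0 = max(y[np.argmin(t)], 1e-12)

    best = {"bi": None, "mono": None}
    for lam0 in lam_starts:
        for key, f, p0, bounds in (
            ("bi", biexp, [y0, 0.1 * y0, lam0],
             ([0.0, 0.0, lambda_p * (1 + 1e-9)], [np.inf, np.inf, np.inf])),
            ("mono", monoexp, [y0, lam0],
             ([0.0, lambda_p * (1 + 1e-9)], [np.inf, np.inf])),
        ):
            try:
                popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((y - f(t, *popt)) ** 2))
            cand = (rss, popt[-1], popt)
            if best[key] is None or cand[:2] < best[key][:2]:
                best[key] = cand
    if best["bi"] is None and best["mono"] is None:
        raise RuntimeError("kinetic fit failed to converge from every start")

    reports = {}
    for key, k_free in (("bi", 3), ("mono", 2)):
        if best[key] is not None:
            reports[key] = _aicc(best[key][0], len(t), k_free)
        else:
            reports[key] = np.inf
    selected = "biexponential" if reports["bi"] < reports["mono"] else "monoexponential"

    if selected == "biexponential":
        r0, p, lam_e = best["bi"][2]
        p = min(p, r0)  # clamp boundary-rounding
        rss = best["bi"][0]
    else:
        r0, lam_e = best["mono"][2]
        p = 0.0
        rss = best["mono"][0]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    params = KineticParams(float(r0), float(p), float(lam_e), lambda_p)
    report = FitReport(
        selected_model=selected,
        r_squared=r2,
        adequate=r2 >= 0.7,
        aicc={"biexponential": reports["bi"], "monoexponential": reports["mono"]},
        effective_half_life_h=float(np.log(2.0) / lam_e),
    )
    return params, report


def interval_fractions(params: KineticParams, schedule: TreatmentSchedule) -> np.ndarray:
    """Fraction of the dose accumulated by the schedule end delivered in each
    interval. The last boundary may be infinite, in which case fractions are
    of the total (asymptotic) dose. Requires scalar r0."""
    bounds = np.asarray(schedule.boundaries_d, dtype=float) * 24.0
    cum = np.array([cumulative_dose(params, b) for b in bounds])
    total = cum[-1] - cum[0]
    if total <= 0:
        raise ValueError("schedule covers no dose")
    return np.diff(cum) / total
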