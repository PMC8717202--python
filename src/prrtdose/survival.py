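"""Linear-quadratic in vivo survival under protracted irradiation.

Survival of cells receiving cumulative dose D(t) at exponentially decaying
dose rate is modelled as

    E(t) = exp(γ t) · exp(−α D(t) − G(t) β D(t)²),

where γ = ln2/T_D is the repopulation rate, α and β = α/(α/β) the LQ
radiosensitivity coefficients, and G(t) ∈ (0, 1] the Lea–Catcheside
protraction factor discounting the quadratic (two-track) term for sublethal
damage repaired at rate μ = ln2/T_μ during delivery:

    G(t) = (2 / D(t)²) ∫₀ᵗ Ṙ(t′) ∫₀^{t′} Ṙ(t″) e^{−μ (t′−t″)} dt″ dt′.

For the biexponential dose-rate course Ṙ = (R0−P)e^{−λe t} + P e^{−λp t}
the double integral has a closed form, implemented below and verified
against adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.optimize import brentq, curve_fit, minimize_scalar

from .kinetics import KineticParams, cumulative_dose, dose_rate


class FitFailureError(RuntimeError):
    """A least-squares fit could not produce a usable result."""


@dataclass
class RadiobiologyParams:
    """LQ radiosensitivity with repair and repopulation rates.

    alpha: Gy⁻¹; alpha_beta_ratio: Gy; mu: repair rate h⁻¹; gamma:
    repopulation rate h⁻¹ (0 disables repopulation); alpha_sd: optional
    gaussian spread of alpha across the cell population (Gy⁻¹).
    """

    alpha: float
    alpha_beta_ratio: float
    mu: float
    gamma: float = 0.0
    alpha_sd: float | None = None

    def __post_init__(self):
        if self.alpha <= 0 or self.alpha_beta_ratio <= 0 or self.mu <= 0:
            raise ValueError("alpha, alpha/beta and mu must be positive")
        if self.gamma < 0 or (self.alpha_sd is not None and self.alpha_sd < 0):
            raise ValueError("gamma and alpha_sd must be nonnegative")

    @property
    def beta(self) -> float:
        return self.alpha / self.alpha_beta_ratio

    @classmethod
    def from_half_times(
        cls, alpha: float, alpha_beta_ratio: float, t_mu_h: float, t_d_days: float,
        alpha_sd: float | None = None,
    ) -> "RadiobiologyParams":
        """Build from the repair half-life (h) and doubling time (days)."""
        return cls(
            alpha=alpha,
            alpha_beta_ratio=alpha_beta_ratio,
            mu=np.log(2.0) / t_mu_h,
            gamma=np.log(2.0) / (t_d_days * 24.0),
            alpha_sd=alpha_sd,
        )


# ---------------------------------------------------------------- G factor

_DEGENERACY_TOL = 1e-6  # h^-1; below this the closed-form denominators blow up


def lea_catcheside_G_quadrature(kinetics: KineticParams, mu: float, t_h: float) -> float:
    """G(t) by adaptive quadrature of the generic double integral (slow)."""
    if not np.isscalar(kinetics.r0):
        raise ValueError("G is evaluated on a scalar-amplitude kinetics template")

    def rate(tt):
        return float(dose_rate(kinetics, tt))

    def outer(tp):
        inner, _ = integrate.quad(
            lambda ts: rate(ts) * np.exp(-mu * (tp - ts)), 0.0, tp, limit=200
        )
        return rate(tp) * inner

    num, _ = integrate.quad(outer, 0.0, t_h, limit=200)
    d = float(cumulative_dose(kinetics, t_h))
    return 2.0 * num / d**2


def lea_catcheside_G(kinetics: KineticParams, mu: float, t_h: float) -> float:
    """Closed-form Lea–Catcheside factor for biexponential kinetics.

    Near rate degeneracies (|λ−μ| below 1e-6 h⁻¹, removable singularities of
    the closed form) the quadrature evaluation is used instead.
    """
    if t_h <= 0:
        raise ValueError("G requires t > 0")
    if mu <= 0:
        raise ValueError("repair rate must be positive")
    if not np.isscalar(kinetics.r0):
        raise ValueError("G is evaluated on a scalar-amplitude kinetics template")

    a, b = kinetics.lambda_e, kinetics.lambda_p
    if min(abs(mu - a), abs(mu - b)) < _DEGENERACY_TOL:
        return lea_catcheside_G_quadrature(kinetics, mu, t_h)

    A = kinetics.r0 - kinetics.p
    B = kinetics.p

    def I(p_, q_):
        return -np.expm1(-(p_ + q_) * t_h) / (p_ + q_)

    total = (
        A * A / (mu - a) * (I(a, a) - I(a, mu))
        + A * B / (mu - b) * (I(a, b) - I(a, mu))
        + A * B / (mu - a) * (I(a, b) - I(b, mu))
        + B * B / (mu - b) * (I(b, b) - I(b, mu))
    )
    d = float(cumulative_dose(kinetics, t_h))
    return float(2.0 * total / d**2)


# ---------------------------------------------------------------- survival

def survival(params: RadiobiologyParams, dose_gy, g, t_h) -> np.ndarray:
    """LQ survival E = exp(γt)·exp(−αD − GβD²); vectorizes over dose maps."""
    D = np.asarray(dose_gy, dtype=float)
    G = np.asarray(g, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be nonnegative")
    if np.any((G <= 0) | (G > 1)):
        raise ValueError("G must lie in (0, 1]")
    return np.exp(params.gamma * t_h) * np.exp(-params.alpha * D - G * params.beta * D**2)


@dataclass
class SurvivalResult:
    """Per-voxel survival over one delivery interval.

    e: survival per tumor voxel; dose_gy and g the corresponding D(t) and
    G(t) components; duration_h the interval length since excision.
    """

    e: np.ndarray
    dose_gy: np.ndarray
    g: float
    duration_h: float
    approach: str = "heterogeneous"  # or "average"

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.e, [25, 50, 75])
        return {
            "mean": float(self.e.mean()),
            "sd": float(self.e.std(ddof=1)) if self.e.size > 1 else 0.0,
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "n": int(self.e.size),
        }


def survival_map(
    r0_map_mgy_h: np.ndarray,
    kinetics_template: KineticParams,
    params: RadiobiologyParams,
    duration_h: float,
    average_approach: bool = False,
    alpha_samples: np.ndarray | None = None,
) -> SurvivalResult:
    """Per-voxel LQ survival over one interval.

    Every voxel shares the template's normalized bound-fraction time shape;
    the voxel dose-rate amplitude R0i (mGy/h, flattened over tumor voxels)
    scales it, so D_i = R0i·τ(t) while G is common to all voxels. In
    average-approach mode the map is replaced by its mean (the S-value
    route), which is exactly the scalar pipeline on the mean amplitude.

    alpha_samples, if given, assigns one α draw per voxel (gaussian
    radiosensitivity heterogeneity); its length must match the map.
    """
    if duration_h <= 0:
        raise ValueError("interval duration must be positive")
    r0 = np.asarray(r0_map_mgy_h, dtype=float).ravel()
    if average_approach:
        r0 = np.full(1, r0.mean()) if alpha_samples is None else np.full(
            len(alpha_samples), r0.mean())
    tau_h = float(kinetics_template.normalized_dose_shape(duration_h))
    dose_gy = r0 * tau_h / 1000.0
    g = lea_catcheside_G(kinetics_template, params.mu, duration_h)
    if alpha_samples is not None:
        alpha_samples = np.asarray(alpha_samples, dtype=float)
        if alpha_samples.shape != r0.shape:
            raise ValueError("alpha_samples length must match the voxel map")
        beta = alpha_samples / params.alpha_beta_ratio
        e = np.exp(params.gamma * duration_h) * np.exp(
            -alpha_samples * dose_gy - g * beta * dose_gy**2
        )
    else:
        e = survival(params, dose_gy, g, duration_h)
    return SurvivalResult(
        e=e, dose_gy=dose_gy, g=g, duration_h=duration_h,
        approach="average" if average_approach else "heterogeneous",
    )


@dataclass
class ChainedSurvival:
    """Monte Carlo product of per-interval survivals (treatment course)."""

    samples: np.ndarray
    boundaries_d: tuple[float, ...]

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.samples, [25, 50, 75])
        return {
            "mean": float(self.samples.mean()),
            "sd": float(self.samples.std(ddof=1)),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "n": int(self.samples.size),
        }


def chain_intervals(
    results: list[SurvivalResult],
    boundaries_d: tuple[float, ...] | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    gaussian: bool = False,
) -> ChainedSurvival:
    """Chain per-interval survival distributions into a course-level one.

    Each interval's per-voxel survival values come from an independent
    tissue section (different animals per time point), so draws across
    intervals are independent: a sample is the product of one draw per
    interval. With ``gaussian=True`` each interval's empirical distribution
    is replaced by a normal approximation (clipped to positive).
    """
    if not results:
        raise ValueError("no interval results to chain")
    rng = np.random.default_rng(seed)
    samples = np.ones(n_samples)
    for res in results:
        if gaussian:
            mu_, sd_ = res.e.mean(), res.e.std(ddof=1) if res.e.size > 1 else 0.0
            draw = rng.normal(mu_, sd_, n_samples)
            draw = np.clip(draw, 1e-300, None)
        else:
            draw = rng.choice(res.e, size=n_samples, replace=True)
        samples *= draw
    if boundaries_d is None:
        boundaries_d = tuple(np.cumsum([0.0] + [r.duration_h / 24.0 for r in results]))
    return ChainedSurvival(samples=samples, boundaries_d=tuple(boundaries_d))


# ------------------------------------------------------- growth and repair

@dataclass
class GrowthFit:
    """Piecewise-exponential tumor volume fit.

    V(t) = V0·exp(k0 t)·exp(−k1·max(t−T0,0))·exp(k2·max(t−T1,0)); rates per
    day, onsets in days. T_D = ln2/(k0−k1+k2) is the regrowth doubling time
    (undefined and flagged when the net late rate is not positive).
    """

    v0: float
    k0: float
    k1: float
    k2: float
    t0_d: float
    t1_d: float
    td_days: float
    gamma_per_h: float
    r_squared: float
    td_defined: bool


def growth_curve(t_d, v0, k0, k1, k2, t0_d, t1_d) -> np.ndarray:
    """Piecewise-exponential tumor volume model (growth, shrinkage, regrowth)."""
    t = np.asarray(t_d, dtype=float)
    return v0 * np.exp(
        k0 * t - k1 * np.maximum(t - t0_d, 0.0) + k2 * np.maximum(t - t1_d, 0.0)
    )


def fit_growth(times_d, volumes_mm3, t0_d: float = 3.0) -> GrowthFit:
    """Least-squares fit of the growth model in log-volume space.

    The shrinkage onset T0 is imposed (3 d by default); the regrowth onset
    T1 is profiled: for each candidate T1 the remaining parameters are the
    exact linear least-squares solution in log space, and T1 itself is
    refined continuously around the best grid point.
    """
    t = np.asarray(times_d, dtype=float)
    v = np.asarray(volumes_mm3, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points spanning growth and shrinkage")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    logv = np.log(v)

    def solve(t1):
        X = np.column_stack(
            [np.ones_like(t), t, np.maximum(t - t0_d, 0.0), np.maximum(t - t1, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(X, logv, rcond=None)
        rss = float(np.sum((logv - X @ coef) ** 2))
        return coef, rss

    t1_grid = np.linspace(t0_d + 0.5, t.max() - 0.5, 60)
    rss_grid = [solve(t1)[1] for t1 in t1_grid]
    k_best = int(np.argmin(rss_grid))
    lo = t1_grid[max(k_best - 1, 0)]
    hi = t1_grid[min(k_best + 1, len(t1_grid) - 1)]
    opt = minimize_scalar(lambda t1: solve(t1)[1], bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    t1_hat = float(opt.x)
    coef, rss = solve(t1_hat)
    c0, c1, c2, c3 = coef
    k0, k1, k2 = float(c1), float(-c2), float(c3)
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    net = k0 - k1 + k2
    td_defined = net > 0
    td = float(np.log(2.0) / net) if td_defined else float("nan")
    gamma = float(np.log(2.0) / (td * 24.0)) if td_defined else float("nan")
    return GrowthFit(
        v0=float(np.exp(c0)), k0=k0, k1=k1, k2=k2, t0_d=t0_d, t1_d=t1_hat,
        td_days=td, gamma_per_h=gamma, r_squared=r2, td_defined=td_defined,
    )


@dataclass
class RepairFit:
    """Mono-exponential γH2AX foci decay fit: repair rate and half-life."""

    mu_per_h: float
    t_mu_h: float
    amplitude: float
    baseline: float
    model: str  # "decay" | "decay+baseline"
    r_squared: float
    flagged_flat: bool


def _aicc(rss: float, n: int, k: int) -> float:
    if n <= k + 1:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_repair(times_h, foci_per_cell) -> RepairFit:
    """Fit foci(t) = A·e^(−μt) (+ optional baseline, chosen by AICc).

    Raises FitFailureError for clearly non-decaying series; near-flat data
    fit with an essentially zero rate are returned flagged.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(foci_per_cell, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points for the repair fit")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if y[-1] > y[0] * 1.05 + 1e-12:
        raise FitFailureError("foci series is not decaying; no repair rate can be fitted")

    span = max(t.max() - t.min(), 1.0)
    y0 = max(y[0], 1e-12)
    # log-linear start where possible
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        mu0 = max(-slope, 1e-6)
    else:
        mu0 = 1.0 / span

    fits = {}
    try:
        popt, _ = curve_fit(
            lambda tt, A, m: A * np.exp(-m * tt), t, y, p0=[y0, mu0],
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
        )
        rss = float(np.sum((y - popt[0] * np.exp(-popt[1] * t)) ** 2))
        fits["decay"] = (popt, rss, _aicc(rss, len(t), 2))
    except RuntimeError:
        pass
    if len(t) >= 5:
        try:
            popt, _ = curve_fit(
                lambda tt, A, m, c: A * np.exp(-m * tt) + c, t, y, p0=[y0, mu0, 0.0],
                bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=20000,
            )
            rss = float(np.sum((y - (popt[0] * np.exp(-popt[1] * t) + popt[2])) ** 2))
            fits["decay+baseline"] = (popt, rss, _aicc(rss, len(t), 3))
        except RuntimeError:
            pass
    if not fits:
        raise FitFailureError("repair fit did not converge")
    model = min(fits, key=lambda k_: fits[k_][2])
    popt, rss, _ = fits[model]
    mu = float(popt[1])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    t_mu = float(np.log(2.0) / mu) if mu > 0 else float("inf")
    return RepairFit(
        mu_per_h=mu,
        t_mu_h=t_mu,
        amplitude=float(popt[0]),
        baseline=float(popt[2]) if model == "decay+baseline" else 0.0,
        model=model,
        r_squared=r2,
        flagged_flat=bool(t_mu > 10.0 * span),
    )


# ------------------------------------------------- dose-rate threshold, RBE

def minimal_effective_dose_rate(params: RadiobiologyParams) -> float:
    """Smallest constant dose rate (mGy/h) at which cell kill balances
    repopulation under continuous irradiation.

    At constant rate R with repair rate μ and long exposure, the protracted
    quadratic term tends to 2βR²/μ per unit time, so the steady-state kill
    rate is αR + (2β/μ)R²; the threshold is the positive root of
    αR + (2β/μ)R² = γ, found by bisection to 1e-6 mGy/h.
    """
    if params.gamma <= 0:
        raise ValueError("repopulation rate must be positive to define a threshold")
    alpha, beta, mu, gamma = params.alpha, params.beta, params.mu, params.gamma
    if beta == 0:
        return gamma / alpha * 1000.0

    def f(r_gy_h):
        return alpha * r_gy_h + (2.0 * beta / mu) * r_gy_h**2 - gamma

    hi = gamma / alpha  # kill already exceeds repopulation here (beta>0)
    if f(hi) <= 0:
        raise FitFailureError("no positive root for the minimal effective dose rate")
    return float(brentq(f, 0.0, hi, xtol=1e-9)) * 1000.0


def rbe(alpha_internal: float, alpha_reference: float) -> float:
    """Relative biological effectiveness as the ratio of fitted α values
    (quadratic terms neglected, as appropriate at low dose rate)."""
    if alpha_reference <= 0 or alpha_internal <= 0:
        raise ValueError("alpha values must be positive")
    return alpha_internal / alpha_reference


def sample_alpha(params: RadiobiologyParams, n: int, seed: int = 0) -> np.ndarray:
    """Gaussian α draws (truncated at 0) modelling radiosensitivity spread."""
    if params.alpha_sd is None or params.alpha_sd == 0:
        return np.full(n, params.alpha)
    a = (0.0 - params.alpha) / params.alpha_sd
    dist = stats.truncnorm(a, np.inf, loc=params.alpha, scale=params.alpha_sd)
    return dist.rvs(size=n, random_state=np.random.default_rng(seed))
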