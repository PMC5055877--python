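"""Unstructured batch-fermentation kinetics: logistic growth plus
Luedeking-Piret product formation and substrate consumption.

Model family (time in days):

* biomass follows the logistic law ``dX/dt = mu_max X (1 - X/Xm)`` with
  closed form ``X(t) = X0 e^{mu t} / (1 - (X0/Xm)(1 - e^{mu t}))``;
* the product proxy (inhibition-zone diameter, mm) follows Luedeking-Piret,
  ``dP/dt = alpha dX/dt + beta X`` -- alpha captures growth-associated and
  beta non-growth-associated formation;
* limiting substrate follows the modified Luedeking-Piret law
  ``-dS/dt = gamma dX/dt + eta X``.

Substituting the logistic solution gives closed forms for all three series
(the "logistic-incorporated" LP / modified-LP models), implemented here in an
overflow-safe parameterisation.  Estimation is sequential: the logistic
parameters are fitted by bounded nonlinear least squares, then (alpha, beta)
and (gamma, eta) by non-negative linear least squares conditional on the
growth fit, mirroring the equations' structure; a joint refinement is
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .response_surface import fit_metrics

__all__ = [
    "KineticsError",
    "ConvergenceError",
    "KineticParams",
    "TimeCourse",
    "logistic_biomass",
    "limlp_substrate",
    "lilp_product",
    "log_growth_term",
    "eta_from_stationary",
    "beta_from_stationary",
    "stationary_slope",
    "LogisticGrowthModel",
    "LuedekingPiretProduct",
    "LuedekingPiretSubstrate",
    "fit_logistic",
    "fit_lilp",
    "fit_limlp",
    "fit_kinetics",
    "KineticFit",
    "goodness",
    "read_timecourse",
    "write_timecourse",
    "TIMECOURSE_COLUMNS",
]

TIMECOURSE_COLUMNS = ("time_days", "biomass_g_per_L", "substrate_g_per_L", "product_mm")

# stationary phase of the producing strain: growth plateau from day 5 to 11
DEFAULT_STATIONARY_WINDOW = (5.0, 11.0)


class KineticsError(ValueError):
    """Invalid kinetic parameters or time-course data."""


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


@dataclass(frozen=True)
class KineticParams:
    """Parameter set of the logistic / Luedeking-Piret model family.

    Units: ``mu_max`` day^-1; ``x0``, ``xm``, ``s0`` g/L; ``gamma`` g
    substrate per g biomass; ``eta`` g substrate per (g biomass * day);
    ``alpha`` mm per g biomass; ``beta`` mm per (g biomass * day); ``p0`` mm.
    """

    mu_max: float
    x0: float
    xm: float
    gamma: float = 0.0
    eta: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    s0: float = 20.0
    p0: float = 0.0

    def __post_init__(self):
        if not (self.mu_max > 0):
            raise KineticsError(f"mu_max must be > 0, got {self.mu_max}")
        if not (0 < self.x0 < self.xm):
            raise KineticsError(f"need 0 < x0 < xm, got x0={self.x0}, xm={self.xm}")
        for name in ("gamma", "eta", "alpha", "beta", "s0", "p0"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class TimeCourse:
    """Sampled fermentation trajectory: times (days) plus biomass and,
    optionally, substrate and product-proxy series."""

    times: np.ndarray
    biomass: np.ndarray
    substrate: np.ndarray | None = None
    product: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.biomass, dtype=float)
        if t.ndim != 1 or x.shape != t.shape:
            raise KineticsError("times and biomass must be equal-length 1-D arrays")
        if t.size and t[0] < 0:
            raise KineticsError("times must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass", x)
        for name in ("substrate", "product"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != t.shape:
                    raise KineticsError(f"{name} length does not match times")
                object.__setattr__(self, name, v)

    @property
    def n_points(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        data = {"time_days": self.times, "biomass_g_per_L": self.biomass}
        if self.substrate is not None:
            data["substrate_g_per_L"] = self.substrate
        if self.product is not None:
            data["product_mm"] = self.product
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeCourse":
        for col in TIMECOURSE_COLUMNS[:2]:
            if col not in frame.columns:
                raise KineticsError(f"time-course table missing column {col!r}")
        return cls(
            times=frame["time_days"].to_numpy(float),
            biomass=frame["biomass_g_per_L"].to_numpy(float),
            substrate=frame["substrate_g_per_L"].to_numpy(float)
            if "substrate_g_per_L" in frame.columns else None,
            product=frame["product_mm"].to_numpy(float)
            if "product_mm" in frame.columns else None,
        )


def read_timecourse(path) -> TimeCourse:
    """Read a time-course from comma-separated text (see TIMECOURSE_COLUMNS)."""
    return TimeCourse.from_frame(pd.read_csv(path))


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# closed forms (overflow-safe)


def log_growth_term(t, p: KineticParams) -> np.ndarray:
    """ln[1 - (X0/Xm)(1 - e^{mu t})], the integral term of the closed forms.

    Equals mu*t + ln(X0/Xm) + ln1p((Xm/X0 - 1) e^{-mu t}); always >= 0 for
    t >= 0 and valid parameters, and safe against overflow at large mu*t.
    """
    t = np.asarray(t, dtype=float)
    mt = p.mu_max * t
    return mt + np.log(p.x0 / p.xm) + np.log1p((p.xm / p.x0 - 1.0) * np.exp(-mt))


def logistic_biomass(t, p: KineticParams):
    """Logistic biomass X(t) in g/L.

    X(0) = x0, monotone non-decreasing, supremum xm.  Evaluated in the
    sigmoid form xm / (1 + (xm/x0 - 1) e^{-mu t}) to avoid overflow.
    """
    t = np.asarray(t, dtype=float)
    out = p.xm / (1.0 + (p.xm / p.x0 - 1.0) * np.exp(-p.mu_max * t))
    return float(out) if out.ndim == 0 else out


def limlp_substrate(t, p: KineticParams, warn_negative: bool = True):
    """Substrate S(t) in g/L under the logistic-incorporated modified
    Luedeking-Piret model:

        S(t) = s0 - gamma (X(t) - x0) - (eta xm / mu_max) ln[1 - (x0/xm)(1 - e^{mu t})]

    The log term's argument is >= 1 for t >= 0, so both consumption terms are
    non-negative and S decreases from s0.  A predicted negative value is
    returned as-is with a substrate-exhaustion warning.
    """
    x = logistic_biomass(t, p)
    s = p.s0 - p.gamma * (np.asarray(x) - p.x0) - (p.eta * p.xm / p.mu_max) * log_growth_term(t, p)
    if warn_negative and np.any(np.asarray(s) < 0):
        warnings.warn("predicted substrate is negative (substrate exhaustion)", stacklevel=2)
    s = np.asarray(s)
    return float(s) if s.ndim == 0 else s


def lilp_product(t, p: KineticParams):
    """Product proxy P(t) in mm under the logistic-incorporated
    Luedeking-Piret model:

        P(t) = p0 + alpha (X(t) - x0) + (beta xm / mu_max) ln[1 - (x0/xm)(1 - e^{mu t})]

    Non-decreasing for alpha, beta >= 0; P(0) = p0.
    """
    x = logistic_biomass(t, p)
    out = p.p0 + p.alpha * (np.asarray(x) - p.x0) + (p.beta * p.xm / p.mu_max) * log_growth_term(t, p)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# stationary-phase estimators


def eta_from_stationary(dsdt_stationary: float, x_max: float) -> float:
    """Non-growth-associated substrate coefficient from the stationary-phase
    substrate slope: eta = -(dS/dt)_stationary / Xmax."""
    if not (x_max > 0):
        raise KineticsError(f"x_max must be > 0, got {x_max}")
    return -float(dsdt_stationary) / float(x_max)


def beta_from_stationary(dpdt_stationary: float, x_max: float) -> float:
    """Non-growth-associated product coefficient from the stationary-phase
    product slope: beta = (dP/dt)_stationary / Xmax."""
    if not (x_max > 0):
        raise KineticsError(f"x_max must be > 0, got {x_max}")
    return float(dpdt_stationary) / float(x_max)


def stationary_slope(tc: TimeCourse, series: str = "S",
                     window: tuple[float, float] = DEFAULT_STATIONARY_WINDOW) -> float:
    """OLS slope (per day) of a series restricted to a stationary-phase window.

    ``series`` is "S" (substrate) or "P" (product); the default window is the
    day 5-11 growth plateau.
    """
    key = {"S": "substrate", "P": "product", "X": "biomass"}.get(series.upper())
    if key is None:
        raise KineticsError(f"unknown series {series!r}; expected 'S' or 'P'")
    values = getattr(tc, key)
    if values is None:
        raise KineticsError(f"time-course has no {key} series")
    lo, hi = window
    mask = (tc.times >= lo) & (tc.times <= hi)
    if int(mask.sum()) < 2:
        raise KineticsError(f"window {window} contains {int(mask.sum())} points; need >= 2")
    t, v = tc.times[mask], values[mask]
    if np.ptp(t) == 0:
        raise KineticsError("window points share a single time value")
    return float(stats.linregress(t, v).slope)


# ---------------------------------------------------------------------------
# estimation


def _r2(observed, predicted) -> float:
    obs = np.asarray(observed, float)
    res = obs - np.asarray(predicted, float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - float(res @ res) / ss_tot if ss_tot > 0 else np.nan


def _times_of(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2:
        if arr.shape[1] != 1:
            raise KineticsError("time input must be 1-D or a single column")
        arr = arr[:, 0]
    return arr


class LogisticGrowthModel(RegressorMixin, BaseEstimator):
    """Logistic growth law fitted by bounded nonlinear least squares.

    The optimisation runs in log-space over (mu_max, x0, dx) with
    xm = x0 + dx, which enforces positivity and x0 < xm without explicit
    constraints.  A deterministic multi-start (``n_starts`` seeded
    perturbations of the data-driven initial guess) guards against local
    minima.

    Parameters
    ----------
    n_starts : int, default 5
        Number of starts (first is the data-driven guess).
    seed : int, default 0
        Seed of the start-perturbation generator.
    xtol : float, default 1e-10
        Parameter tolerance passed to the optimizer.

    Attributes
    ----------
    mu_max_, x0_, xm_ : fitted parameters (day^-1, g/L, g/L).
    r_squared_ : R2 of the biomass fit.
    n_iter_ : evaluations used by the best start.
    """

    def __init__(self, n_starts: int = 5, seed: int = 0, xtol: float = 1e-10):
        self.n_starts = n_starts
        self.seed = seed
        self.xtol = xtol

    def fit(self, X, y):
        t = _times_of(X)
        x_obs = np.asarray(y, dtype=float).ravel()
        if t.shape != x_obs.shape:
            raise KineticsError("time and biomass lengths differ")
        if t.size < 4:
            raise KineticsError(f"need >= 4 biomass points, got {t.size}")
        if np.any(x_obs <= 0):
            raise KineticsError("biomass observations must be positive")
        if np.ptp(x_obs) < 1e-12 * max(1.0, abs(x_obs[0])):
            raise ConvergenceError(
                "biomass series is constant: logistic parameters are unidentifiable"
            )

        # data-driven initial guess: x0 = first obs, xm = max obs,
        # mu = slope of ln X over the first half of the series
        x0_g = x_obs[0]
        xm_g = float(np.max(x_obs))
        half = max(2, t.size // 2)
        mu_g = float(stats.linregress(t[:half], np.log(x_obs[:half])).slope)
        if not np.isfinite(mu_g) or mu_g <= 0:
            mu_g = 1.0 / max(np.ptp(t), 1.0)
        dx_g = max(xm_g - x0_g, 1e-3 * xm_g)
        theta0 = np.log([mu_g, x0_g, dx_g])

        def residuals(theta):
            mu, x0, dx = np.exp(theta)
            p = KineticParams(mu_max=mu, x0=x0, xm=x0 + dx)
            return logistic_biomass(t, p) - x_obs

        rng = np.random.default_rng(self.seed)
        best = None
        failures = []
        for k in range(self.n_starts):
            start = theta0 if k == 0 else theta0 + rng.normal(scale=0.5, size=3)
            try:
                res = scipy.optimize.least_squares(
                    residuals, start, xtol=self.xtol, ftol=1e-14, gtol=1e-12, max_nfev=2000
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if not np.all(np.isfinite(res.x)):
                failures.append("non-finite solution")
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise ConvergenceError(
                f"logistic fit failed on all {self.n_starts} starts: {failures}"
            )
        mu, x0, dx = np.exp(best.x)
        self.mu_max_ = float(mu)
        self.x0_ = float(x0)
        self.xm_ = float(x0 + dx)
        self.params_ = KineticParams(mu_max=self.mu_max_, x0=self.x0_, xm=self.xm_)
        self.r_squared_ = _r2(x_obs, logistic_biomass(t, self.params_))
        self.n_iter_ = int(best.nfev)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return logistic_biomass(_times_of(X), self.params_)


class _ConditionalLP(RegressorMixin, BaseEstimator):
    """Shared machinery of the conditional Luedeking-Piret fits.

    Both conditional problems are *linear* in their two coefficients once the
    growth parameters are fixed, so the non-negative least-squares optimum is
    computed exactly (scipy.optimize.nnls) rather than by iterative search.
    """

    _series = ""  # "product" | "substrate"

    def __init__(self, growth: KineticParams | None = None, intercept: float | None = None):
        self.growth = growth
        self.intercept = intercept

    def _growth_params(self) -> KineticParams:
        g = self.growth
        if g is None:
            raise KineticsError("growth parameters are required (fit the logistic model first)")
        if isinstance(g, LogisticGrowthModel):
            g = g.params_
        if not isinstance(g, KineticParams):
            raise KineticsError("growth must be a KineticParams or fitted LogisticGrowthModel")
        return g

    def _design(self, t, g: KineticParams) -> np.ndarray:
        growth_col = logistic_biomass(t, g) - g.x0
        accum_col = (g.xm / g.mu_max) * log_growth_term(t, g)
        return np.column_stack([growth_col, accum_col])

    def fit(self, X, y):
        g = self._growth_params()
        t = _times_of(X)
        obs = np.asarray(y, dtype=float).ravel()
        if t.shape != obs.shape:
            raise KineticsError("time and series lengths differ")
        if t.size < 2:
            raise KineticsError("need >= 2 observations")
        c0 = float(obs[0]) if self.intercept is None else float(self.intercept)
        A = self._design(t, g)
        target = obs - c0 if self._series == "product" else c0 - obs
        coef, _ = scipy.optimize.nnls(A, target)
        self.coef_ = coef
        self.intercept_ = c0
        self.growth_params_ = g
        self.r_squared_ = _r2(obs, self._predict_from(t))
        self.n_features_in_ = 1
        return self

    def _predict_from(self, t):
        contrib = self._design(t, self.growth_params_) @ self.coef_
        return self.intercept_ + contrib if self._series == "product" else self.intercept_ - contrib

    def predict(self, X):
        return self._predict_from(_times_of(X))


class LuedekingPiretProduct(_ConditionalLP):
    """Product-formation fit: P(t) = p0 + alpha (X - x0) + (beta xm/mu) ln[.].

    ``alpha`` (growth-associated, mm per g biomass) and ``beta``
    (non-growth-associated, mm per g biomass per day) are constrained
    non-negative; ``p0`` is fixed at the first product observation unless
    ``intercept`` is given.
    """

    _series = "product"

    @property
    def alpha_(self) -> float:
        return float(self.coef_[0])

    @property
    def beta_(self) -> float:
        return float(self.coef_[1])


class LuedekingPiretSubstrate(_ConditionalLP):
    """Substrate-consumption fit: S(t) = s0 - gamma (X - x0) - (eta xm/mu) ln[.].

    ``gamma`` (growth-associated, g substrate per g biomass) and ``eta``
    (non-growth-associated, per day) are constrained non-negative; ``s0`` is
    fixed at the first substrate observation unless ``intercept`` is given.
    """

    _series = "substrate"

    @property
    def gamma_(self) -> float:
        return float(self.coef_[0])

    @property
    def eta_(self) -> float:
        return float(self.coef_[1])


# ---------------------------------------------------------------------------
# functional wrappers and the combined pipeline


def fit_logistic(tc: TimeCourse, n_starts: int = 5, seed: int = 0):
    """Fit the logistic growth law to a time-course.

    Returns ``(mu_max, x0, xm, r_squared)``.
    """
    est = LogisticGrowthModel(n_starts=n_starts, seed=seed).fit(tc.times, tc.biomass)
    return est.mu_max_, est.x0_, est.xm_, est.r_squared_


def fit_lilp(tc: TimeCourse, growth: KineticParams, p0: float | None = None):
    """Fit (alpha, beta) of the product model conditional on growth params.

    Returns ``(alpha, beta, r_squared)``; ``p0`` defaults to the first
    product observation.
    """
    if tc.product is None:
        raise KineticsError("time-course has no product series")
    est = LuedekingPiretProduct(growth=growth, intercept=p0).fit(tc.times, tc.product)
    return est.alpha_, est.beta_, est.r_squared_


def fit_limlp(tc: TimeCourse, growth: KineticParams, s0: float | None = None):
    """Fit (gamma, eta) of the substrate model conditional on growth params.

    Returns ``(gamma, eta, r_squared)``; ``s0`` defaults to the first
    substrate observation.
    """
    if tc.substrate is None:
        raise KineticsError("time-course has no substrate series")
    est = LuedekingPiretSubstrate(growth=growth, intercept=s0).fit(tc.times, tc.substrate)
    return est.gamma_, est.eta_, est.r_squared_


@dataclass(frozen=True)
class KineticFit:
    """Combined estimation result over all available series."""

    params: KineticParams
    r_squared_biomass: float
    r_squared_substrate: float = np.nan
    r_squared_product: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        rows = [
            ("mu_max", "1/day", p.mu_max), ("X0", "g/L", p.x0), ("Xm", "g/L", p.xm),
            ("gamma", "g.S/g.X", p.gamma), ("eta", "g.S/(g.X.day)", p.eta),
            ("alpha", "mm/g.X", p.alpha), ("beta", "mm/(g.X.day)", p.beta),
            ("S0", "g/L", p.s0), ("P0", "mm", p.p0),
            ("R2_biomass", "-", self.r_squared_biomass),
            ("R2_substrate", "-", self.r_squared_substrate),
            ("R2_product", "-", self.r_squared_product),
        ]
        return pd.DataFrame(rows, columns=["parameter", "units", "value"])


def fit_kinetics(tc: TimeCourse, joint: bool = False, n_starts: int = 5, seed: int = 0) -> KineticFit:
    """Fit every model the time-course supports.

    Sequential by default (logistic first, then conditional LP fits); with
    ``joint=True`` all parameters are refined simultaneously by least squares
    on the stacked, per-series-scaled residuals, initialised at the
    sequential solution.
    """
    mu, x0, xm, r2x = fit_logistic(tc, n_starts=n_starts, seed=seed)
    growth = KineticParams(mu_max=mu, x0=x0, xm=xm)
    gamma = eta = alpha = beta = 0.0
    # intercepts fixed at the first observation; a slightly negative noisy
    # first reading is clipped to the physical floor of zero
    s0 = max(float(tc.substrate[0]), 0.0) if tc.substrate is not None else 20.0
    p0 = max(float(tc.product[0]), 0.0) if tc.product is not None else 0.0
    r2s = r2p = np.nan
    if tc.substrate is not None:
        gamma, eta, r2s = fit_limlp(tc, growth, s0=s0)
    if tc.product is not None:
        alpha, beta, r2p = fit_lilp(tc, growth, p0=p0)
    params = KineticParams(mu_max=mu, x0=x0, xm=xm, gamma=gamma, eta=eta,
                           alpha=alpha, beta=beta, s0=s0, p0=p0)
    if joint:
        params = _joint_refine(tc, params)
        r2x = _r2(tc.biomass, logistic_biomass(tc.times, params))
        if tc.substrate is not None:
            r2s = _r2(tc.substrate, limlp_substrate(tc.times, params, warn_negative=False))
        if tc.product is not None:
            r2p = _r2(tc.product, lilp_product(tc.times, params))
    return KineticFit(params=params, r_squared_biomass=r2x,
                      r_squared_substrate=r2s, r_squared_product=r2p)


def _joint_refine(tc: TimeCourse, start: KineticParams) -> KineticParams:
    """Simultaneous least squares over all series, scaled by each series'
    dispersion so mm- and g/L-sized residuals weigh comparably."""
    scales = {"X": max(np.ptp(tc.biomass), 1e-6)}
    if tc.substrate is not None:
        scales["S"] = max(np.ptp(tc.substrate), 1e-6)
    if tc.product is not None:
        scales["P"] = max(np.ptp(tc.product), 1e-6)

    def unpack(theta):
        mu, x0, dx, gamma, eta, alpha, beta = np.exp(theta[:3]).tolist() + list(theta[3:])
        return KineticParams(
            mu_max=mu, x0=x0, xm=x0 + dx,
            gamma=max(gamma, 0.0), eta=max(eta, 0.0),
            alpha=max(alpha, 0.0), beta=max(beta, 0.0),
            s0=start.s0, p0=start.p0,
        )

    def residuals(theta):
        p = unpack(theta)
        parts = [(logistic_biomass(tc.times, p) - tc.biomass) / scales["X"]]
        if tc.substrate is not None:
            parts.append((limlp_substrate(tc.times, p, warn_negative=False) - tc.substrate) / scales["S"])
        if tc.product is not None:
            parts.append((lilp_product(tc.times, p) - tc.product) / scales["P"])
        return np.concatenate(parts)

    theta0 = np.concatenate([
        np.log([start.mu_max, start.x0, start.xm - start.x0]),
        [start.gamma, start.eta, start.alpha, start.beta],
    ])
    lb = [-np.inf] * 3 + [0.0] * 4
    res = scipy.optimize.least_squares(
        residuals, theta0, bounds=(lb, [np.inf] * 7), xtol=1e-12, ftol=1e-14, max_nfev=5000
    )
    return unpack(res.x)


def goodness(observed, predicted):
    """(R2, RMSE, AAD%) of a predicted vs observed series (same formulas as
    the response-surface fit metrics)."""
    fs = fit_metrics(observed, predicted, p_terms=0, leverage=None)
    return fs.r_squared, fs.rmse, fs.aad_percent
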