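"""Second-order response-surface regression on coded factors.

Fits the full quadratic polynomial

    Y = b0 + sum_i bi Xi + sum_{i<j} bij Xi Xj + sum_i bii Xi^2

by ordinary least squares on the coded design matrix, and produces the
companion diagnostics a response-surface study reports: sequential model
comparison (mean -> linear -> two-factor-interaction -> quadratic -> cubic),
per-term ANOVA with the lack-of-fit / pure-error split from replicated runs,
R-squared family (plain, adjusted, predicted via PRESS), CV%, RMSE and AAD%,
plus constrained optimization over the coded cube and 2-D surface grids for
plotting.

The central estimator is :class:`ResponseSurfaceRegressor`; the module-level
functions (:func:`fit_quadratic`, :func:`sequential_model_ss`, ...) are thin
wrappers over it for script use.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .doe import DesignTable

__all__ = [
    "QuadraticModel",
    "FitSummary",
    "AnovaReport",
    "LackOfFit",
    "SequentialComparison",
    "OptimumResult",
    "ResponseSurfaceRegressor",
    "RankDeficientError",
    "build_design_matrix",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "sequential_model_ss",
    "lack_of_fit",
    "fit_metrics",
    "optimum_on_cube",
    "surface_grid",
    "MODEL_TIERS",
]

MODEL_TIERS = ("mean", "linear", "2FI", "quadratic", "cubic")

_DEFAULT_LABELS = "ABCDEFGHJKLMNPQRSTUVWXYZ"


class RankDeficientError(ValueError):
    """Model matrix is rank deficient; message names the dependent columns."""


def _labels(n: int, names=None) -> list[str]:
    if names is not None:
        return [str(x) for x in names]
    if n <= len(_DEFAULT_LABELS):
        return list(_DEFAULT_LABELS[:n])
    return [f"X{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# model terms and matrices


def _term_set(n: int, tier: str, labels: list[str]):
    """(name, exponent-vector) pairs for a model tier, in canonical order.

    Canonical quadratic order: intercept, linear in factor order, pairwise
    interactions lexicographic (i<j), pure quadratics in factor order.  The
    cubic tier appends pure cubics and linear-by-quadratic cross terms; on a
    three-level design many of these are aliased and are pruned later.
    """
    if tier not in MODEL_TIERS:
        raise ValueError(f"unknown model tier {tier!r}; expected one of {MODEL_TIERS}")
    terms: list[tuple[str, np.ndarray]] = []

    def add(name, expo):
        terms.append((name, np.asarray(expo, dtype=int)))

    add("Intercept", np.zeros(n))
    if tier == "mean":
        return terms
    eye = np.eye(n, dtype=int)
    for i in range(n):
        add(labels[i], eye[i])
    if tier == "linear":
        return terms
    for i, j in itertools.combinations(range(n), 2):
        add(f"{labels[i]}{labels[j]}", eye[i] + eye[j])
    if tier == "2FI":
        return terms
    for i in range(n):
        add(f"{labels[i]}^2", 2 * eye[i])
    if tier == "quadratic":
        return terms
    for i in range(n):
        add(f"{labels[i]}^3", 3 * eye[i])
    for i in range(n):
        for j in range(n):
            if i != j:
                add(f"{labels[i]}{labels[j]}^2", eye[i] + 2 * eye[j])
    return terms


def _eval_terms(coded: np.ndarray, terms) -> np.ndarray:
    cols = [np.prod(coded ** expo, axis=1) for _, expo in terms]
    return np.column_stack(cols)


def _independent_columns(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask of columns kept by a greedy left-to-right rank scan."""
    keep = np.zeros(M.shape[1], dtype=bool)
    basis: list[np.ndarray] = []
    # incremental Gram-Schmidt against the already-kept columns
    for j in range(M.shape[1]):
        v = M[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for b in basis:
            v -= (b @ M[:, j]) * b
        if np.linalg.norm(v) > tol * max(norm0, 1.0):
            basis.append(v / np.linalg.norm(v))
            keep[j] = True
    return keep


def model_matrix(coded, tier: str = "quadratic", names=None, on_alias: str = "ignore"):
    """Model matrix for a tier plus the term names, in canonical column order.

    ``on_alias`` controls what happens when columns are linearly dependent:
    ``"ignore"`` (default, for evaluating points) leaves them in place;
    ``"raise"`` raises :class:`RankDeficientError` naming the dependent
    columns; ``"drop"`` silently removes them (used for the cubic tier, whose
    pure-cubic columns are aliased with the linear ones on any three-level
    design).
    """
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    labels = _labels(coded.shape[1], names)
    terms = _term_set(coded.shape[1], tier, labels)
    M = _eval_terms(coded, terms)
    if on_alias != "ignore":
        keep = _independent_columns(M)
        if not keep.all():
            dropped = [terms[j][0] for j in np.flatnonzero(~keep)]
            if on_alias == "raise":
                raise RankDeficientError(
                    f"model matrix is rank deficient; dependent columns: {dropped}"
                )
            M = M[:, keep]
            terms = [t for t, k in zip(terms, keep) if k]
    return M, [name for name, _ in terms]


def build_design_matrix(design, names=None):
    """Full quadratic model matrix of a design (columns: 1, linear, 2FI, quadratic)."""
    coded = design.coded if isinstance(design, DesignTable) else design
    if names is None and isinstance(design, DesignTable):
        names = None  # keep letter labels; factor names used in reports instead
    return model_matrix(coded, tier="quadratic", names=names, on_alias="raise")


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class QuadraticModel:
    """Coefficients of the second-order polynomial on coded factors.

    ``interaction`` is ordered lexicographically over factor pairs (i<j),
    matching the canonical model-matrix column order.
    """

    intercept: float
    linear: np.ndarray
    interaction: np.ndarray
    quadratic: np.ndarray
    factor_names: tuple[str, ...] = ()

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float)
        n = lin.size
        inter = np.asarray(self.interaction, dtype=float)
        quad = np.asarray(self.quadratic, dtype=float)
        if inter.size != n * (n - 1) // 2:
            raise ValueError(f"expected {n * (n - 1) // 2} interaction terms, got {inter.size}")
        if quad.size != n:
            raise ValueError(f"expected {n} quadratic terms, got {quad.size}")
        names = tuple(self.factor_names) if self.factor_names else tuple(_labels(n))
        if len(names) != n:
            raise ValueError("factor_names length does not match linear coefficients")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "interaction", inter)
        object.__setattr__(self, "quadratic", quad)
        object.__setattr__(self, "factor_names", names)

    @property
    def n_factors(self) -> int:
        return self.linear.size

    @property
    def n_terms(self) -> int:
        n = self.n_factors
        return 1 + 2 * n + n * (n - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(itertools.combinations(range(self.n_factors), 2))

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients in canonical model-matrix order."""
        return np.concatenate([[self.intercept], self.linear, self.interaction, self.quadratic])

    @classmethod
    def from_vector(cls, beta, n_factors: int, factor_names=()) -> "QuadraticModel":
        beta = np.asarray(beta, dtype=float)
        n = n_factors
        npair = n * (n - 1) // 2
        if beta.size != 1 + 2 * n + npair:
            raise ValueError(f"expected {1 + 2 * n + npair} coefficients, got {beta.size}")
        return cls(
            intercept=float(beta[0]),
            linear=beta[1 : 1 + n],
            interaction=beta[1 + n : 1 + n + npair],
            quadratic=beta[1 + n + npair :],
            factor_names=tuple(factor_names),
        )

    def predict(self, points) -> np.ndarray | float:
        """Evaluate the polynomial term by term at coded point(s)."""
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[1] != self.n_factors:
            raise ValueError(
                f"points have {pts.shape[1]} coordinates; model has {self.n_factors} factors"
            )
        y = np.full(pts.shape[0], self.intercept, dtype=float)
        y += pts @ self.linear
        for k, (i, j) in enumerate(self.pairs):
            y += self.interaction[k] * pts[:, i] * pts[:, j]
        y += (pts**2) @ self.quadratic
        return float(y[0]) if scalar else y

    def hessian(self) -> np.ndarray:
        """Hessian of the polynomial (constant for a quadratic)."""
        n = self.n_factors
        H = np.diag(2.0 * self.quadratic)
        for k, (i, j) in enumerate(self.pairs):
            H[i, j] = H[j, i] = self.interaction[k]
        return H

    def gradient(self, point) -> np.ndarray:
        x = np.asarray(point, dtype=float)
        return self.linear + self.hessian() @ x

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.factor_names)
        names = (
            ["Intercept"]
            + labels
            + [f"{labels[i]}:{labels[j]}" for i, j in self.pairs]
            + [f"{l}^2" for l in labels]
        )
        return pd.DataFrame({"term": names, "coefficient": self.coefficient_vector()})


@dataclass(frozen=True)
class FitSummary:
    """Goodness-of-fit statistics of one response-surface fit."""

    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    std_dev: float          # sqrt(MS_residual)
    cv_percent: float       # 100 * std_dev / mean(observed)
    rmse: float             # sqrt(SS_residual / n)
    aad_percent: float      # mean(|obs - pred| / obs) * 100
    press: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "R2": self.r_squared,
                "adj_R2": self.adj_r_squared,
                "pred_R2": self.pred_r_squared,
                "std_dev": self.std_dev,
                "CV_percent": self.cv_percent,
                "RMSE": self.rmse,
                "AAD_percent": self.aad_percent,
                "PRESS": self.press,
            }
        )


@dataclass(frozen=True)
class LackOfFit:
    """Lack-of-fit / pure-error split of the residual sum of squares."""

    available: bool
    ss_lof: float = np.nan
    df_lof: int = 0
    ss_pe: float = np.nan
    df_pe: int = 0
    f_value: float = np.nan
    p_value: float = np.nan
    note: str = ""


@dataclass(frozen=True)
class AnovaReport:
    """Response-surface-software-style ANOVA: model row, per-term rows, residual split.

    Per-term sums of squares are partial (type III): SS_j = t_j^2 * MS_res.
    The lack-of-fit and pure-error rows appear when the design contains
    replicated coded points; otherwise they are reported as not computable.
    """

    table: pd.DataFrame
    lack_of_fit: LackOfFit

    def row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    @property
    def ss_model(self) -> float:
        return float(self.row("Model")["sum_sq"])

    @property
    def ss_residual(self) -> float:
        return float(self.row("Residual")["sum_sq"])

    @property
    def ss_total(self) -> float:
        return float(self.row("Cor Total")["sum_sq"])


@dataclass(frozen=True)
class SequentialComparison:
    """Incremental sum-of-squares comparison of nested model tiers."""

    table: pd.DataFrame

    def row(self, tier: str) -> pd.Series:
        return self.table.set_index("tier").loc[tier]


@dataclass(frozen=True)
class OptimumResult:
    point: np.ndarray
    value: float
    classification: str  # interior stationary max | boundary max | saddle-adjusted


# ---------------------------------------------------------------------------
# metrics


def fit_metrics(observed, predicted, p_terms: int, leverage=None) -> FitSummary:
    """Goodness-of-fit family from observed/predicted pairs.

    ``p_terms`` is the number of model terms including the intercept;
    ``leverage`` (hat-matrix diagonal) enables PRESS and predicted R2 via the
    standard shortcut PRESS = sum((e_i / (1 - h_i))^2).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    resid = obs - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if n > p_terms:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_terms)
        ms_res = ss_res / (n - p_terms)
    else:
        adj = np.nan
        ms_res = np.nan
    press = np.nan
    pred_r2 = np.nan
    if leverage is not None:
        h = np.asarray(leverage, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            press = float(np.sum((resid / (1.0 - h)) ** 2))
        pred_r2 = 1.0 - press / ss_tot if ss_tot > 0 else np.nan
    std_dev = float(np.sqrt(ms_res)) if np.isfinite(ms_res) else np.nan
    mean_obs = float(obs.mean())
    cv = 100.0 * std_dev / mean_obs if mean_obs != 0 and np.isfinite(std_dev) else np.nan
    rmse = float(np.sqrt(ss_res / n))
    if np.any(obs == 0):
        warnings.warn("observed values contain zeros; AAD% undefined", stacklevel=2)
        aad = np.nan
    else:
        aad = float(100.0 / n * np.sum(np.abs(resid / obs)))
    return FitSummary(
        r_squared=r2,
        adj_r_squared=adj,
        pred_r_squared=pred_r2,
        std_dev=std_dev,
        cv_percent=cv,
        rmse=rmse,
        aad_percent=aad,
        press=press,
    )


# ---------------------------------------------------------------------------
# core fitting


def _coded_of(design) -> np.ndarray:
    return design.coded if isinstance(design, DesignTable) else np.atleast_2d(np.asarray(design, float))


def _names_of(design, n: int) -> tuple[str, ...]:
    if isinstance(design, DesignTable):
        return design.names
    return tuple(_labels(n))


def _ols(M: np.ndarray, y: np.ndarray):
    """OLS through statsmodels; returns (beta, fitted, hat_diag, bse, df_resid)."""
    import statsmodels.api as sm

    res = sm.OLS(y, M).fit()
    hat = res.get_influence().hat_matrix_diag
    return res.params, res.fittedvalues, hat, res.bse, int(res.df_resid)


def _replicate_groups(coded: np.ndarray):
    """Indices grouped by exact coded-coordinate equality."""
    _, inverse = np.unique(coded, axis=0, return_inverse=True)
    groups = {}
    for idx, g in enumerate(inverse):
        groups.setdefault(int(g), []).append(idx)
    return list(groups.values())


def _lack_of_fit_split(coded, y, fitted, df_resid) -> LackOfFit:
    resid = np.asarray(y, float) - np.asarray(fitted, float)
    ss_res = float(resid @ resid)
    groups = [g for g in _replicate_groups(coded) if len(g) > 1]
    if not groups:
        return LackOfFit(available=False, note="no replicated coded points; pure error undefined")
    y = np.asarray(y, float)
    ss_pe = 0.0
    df_pe = 0
    for g in groups:
        vals = y[g]
        ss_pe += float(np.sum((vals - vals.mean()) ** 2))
        df_pe += len(g) - 1
    ss_lof = max(ss_res - ss_pe, 0.0)
    df_lof = df_resid - df_pe
    if df_lof <= 0:
        return LackOfFit(
            available=False, ss_pe=ss_pe, df_pe=df_pe,
            note="model saturates the distinct design points; no lack-of-fit df",
        )
    if ss_pe == 0.0:
        return LackOfFit(
            available=True, ss_lof=ss_lof, df_lof=df_lof, ss_pe=0.0, df_pe=df_pe,
            f_value=np.nan, p_value=np.nan,
            note="identical replicate responses: pure error is zero, F undefined",
        )
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    p = float(stats.f.sf(f, df_lof, df_pe))
    return LackOfFit(True, ss_lof, df_lof, ss_pe, df_pe, float(f), p)


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS response-surface model on coded factors, sklearn style.

    Parameters
    ----------
    tier : {"mean", "linear", "2FI", "quadratic", "cubic"}, default "quadratic"
        Polynomial tier to fit.  The cubic tier drops aliased columns (on a
        three-level design pure cubics are collinear with the linear terms).
    factor_names : sequence of str, optional
        Labels used in coefficient and ANOVA tables; defaults to A, B, C, ...

    Attributes
    ----------
    model_ : QuadraticModel
        Fitted coefficients (quadratic tier only).
    coef_vector_, term_names_ : coefficients and labels in canonical order.
    summary_ : FitSummary
    anova_ : AnovaReport
    n_features_in_ : int
    """

    def __init__(self, tier: str = "quadratic", factor_names=None):
        self.tier = tier
        self.factor_names = factor_names

    # -- sklearn plumbing ---------------------------------------------------
    def _validate_X(self, X, fitting: bool):
        if isinstance(X, DesignTable):
            coded = X.coded
            names = X.names
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(-1, 1)
            coded = arr
            names = None
        if not np.all(np.isfinite(coded)):
            raise ValueError("coded design matrix contains non-finite values")
        if fitting:
            self.n_features_in_ = coded.shape[1]
            if self.factor_names is not None:
                self._names = tuple(str(s) for s in self.factor_names)
                if len(self._names) != coded.shape[1]:
                    raise ValueError("factor_names length does not match X")
            elif names is not None:
                self._names = tuple(names)
            else:
                self._names = tuple(_labels(coded.shape[1]))
        elif coded.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {coded.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return coded

    def fit(self, X, y):
        coded = self._validate_X(X, fitting=True)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != coded.shape[0]:
            raise ValueError(f"response length {y.size} does not match {coded.shape[0]} runs")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains missing or non-finite values")
        n, k = coded.shape
        labels = list(self._names)

        if np.ptp(y) == 0.0:
            # degenerate: constant response -> intercept-only fit
            warnings.warn("response has zero variance; returning intercept-only model")
            self._fit_intercept_only(coded, y, labels)
            return self

        n_terms_full = len(_term_set(k, self.tier, labels))
        if n <= n_terms_full and self.tier != "cubic":
            raise ValueError(
                f"{n} runs cannot estimate {n_terms_full} model terms plus error"
            )
        on_alias = "drop" if self.tier == "cubic" else "raise"
        M, terms = model_matrix(coded, tier=self.tier, names=labels, on_alias=on_alias)
        beta, fitted, hat, bse, df_resid = _ols(M, y)
        self.term_names_ = terms
        self.coef_vector_ = np.asarray(beta, dtype=float)
        self.fitted_values_ = np.asarray(fitted, dtype=float)
        self.leverage_ = np.asarray(hat, dtype=float)
        self.df_resid_ = df_resid
        if self.tier == "quadratic":
            self.model_ = QuadraticModel.from_vector(self.coef_vector_, k, labels)
        self.summary_ = fit_metrics(y, fitted, p_terms=len(terms), leverage=hat)
        self.anova_ = self._build_anova(coded, y, fitted, beta, bse, terms, df_resid)
        self._y = y
        self._coded = coded
        return self

    def _fit_intercept_only(self, coded, y, labels):
        k = coded.shape[1]
        npair = k * (k - 1) // 2
        self.term_names_ = ["Intercept"]
        self.coef_vector_ = np.array([float(y.mean())])
        self.fitted_values_ = np.full(y.size, y.mean())
        self.leverage_ = np.full(y.size, 1.0 / y.size)
        self.df_resid_ = y.size - 1
        if self.tier == "quadratic":
            self.model_ = QuadraticModel(
                intercept=float(y.mean()),
                linear=np.zeros(k),
                interaction=np.zeros(npair),
                quadratic=np.zeros(k),
                factor_names=tuple(labels),
            )
        self.summary_ = FitSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        table = pd.DataFrame(
            {"source": ["Model", "Residual", "Cor Total"], "sum_sq": [0.0, 0.0, 0.0],
             "df": [0, y.size - 1, y.size - 1], "mean_sq": [np.nan] * 3,
             "F": [np.nan] * 3, "p": [np.nan] * 3}
        )
        self.anova_ = AnovaReport(table=table, lack_of_fit=LackOfFit(False, note="constant response"))
        self._y = y
        self._coded = coded

    def _build_anova(self, coded, y, fitted, beta, bse, terms, df_resid) -> AnovaReport:
        n = y.size
        resid = y - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_model = ss_tot - ss_res
        df_model = len(terms) - 1
        ms_res = ss_res / df_resid if df_resid > 0 else np.nan
        rows = []
        f_model = (ss_model / df_model) / ms_res if df_model > 0 and ms_res > 0 else np.nan
        p_model = float(stats.f.sf(f_model, df_model, df_resid)) if np.isfinite(f_model) else np.nan
        rows.append(("Model", ss_model, df_model, ss_model / df_model if df_model else np.nan,
                     f_model, p_model))
        for j, name in enumerate(terms):
            if name == "Intercept":
                continue
            t = beta[j] / bse[j] if bse[j] > 0 else np.nan
            ss_j = t**2 * ms_res if np.isfinite(t) else np.nan
            f_j = ss_j / ms_res if ms_res > 0 else np.nan
            p_j = float(stats.f.sf(f_j, 1, df_resid)) if np.isfinite(f_j) else np.nan
            rows.append((name, ss_j, 1, ss_j, f_j, p_j))
        lof = _lack_of_fit_split(coded, y, fitted, df_resid)
        rows.append(("Residual", ss_res, df_resid, ms_res, np.nan, np.nan))
        if lof.available:
            rows.append(("Lack of Fit", lof.ss_lof, lof.df_lof,
                         lof.ss_lof / lof.df_lof if lof.df_lof else np.nan,
                         lof.f_value, lof.p_value))
            rows.append(("Pure Error", lof.ss_pe, lof.df_pe,
                         lof.ss_pe / lof.df_pe if lof.df_pe else np.nan, np.nan, np.nan))
        rows.append(("Cor Total", ss_tot, n - 1, np.nan, np.nan, np.nan))
        table = pd.DataFrame(rows, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"])
        return AnovaReport(table=table, lack_of_fit=lof)

    def predict(self, X):
        coded = self._validate_X(X, fitting=False)
        # rebuild columns from the stored term names so prediction matches the
        # fitted (possibly alias-pruned) term set exactly
        terms_all = _term_set(coded.shape[1], self.tier, list(self._names))
        name_to_expo = {name: expo for name, expo in terms_all}
        cols = [np.prod(coded ** name_to_expo[t], axis=1) for t in self.term_names_]
        return np.column_stack(cols) @ self.coef_vector_

    # -- extras -------------------------------------------------------------
    def optimum(self, seed: int = 0) -> OptimumResult:
        """Maximize the fitted quadratic over the coded cube [-1, 1]^n."""
        if self.tier != "quadratic":
            raise ValueError("optimum search requires the quadratic tier")
        return optimum_on_cube(self.model_, seed=seed)

    def surface(self, factor_pair, fixed_point=None, grid_size: int = 41):
        if self.tier != "quadratic":
            raise ValueError("surface grids require the quadratic tier")
        return surface_grid(self.model_, factor_pair, fixed_point, grid_size)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_quadratic(design, response, factor_names=None):
    """Fit the full quadratic surface; returns (QuadraticModel, FitSummary, AnovaReport)."""
    est = ResponseSurfaceRegressor(tier="quadratic", factor_names=factor_names)
    est.fit(design, response)
    return est.model_, est.summary_, est.anova_


def predict(model: QuadraticModel, coded_point):
    """Evaluate a quadratic model at coded point(s)."""
    return model.predict(coded_point)


def sequential_model_ss(design, response, factor_names=None) -> SequentialComparison:
    """Incremental sum-of-squares over nested tiers mean -> ... -> cubic.

    The incremental F for each tier is (delta SS / delta df) / MS_residual of
    the larger (that tier's) model.  A tier that adds no estimable columns on
    the given design is marked aliased.
    """
    coded = _coded_of(design)
    y = np.asarray(response, dtype=float).ravel()
    names = list(factor_names) if factor_names else list(_names_of(design, coded.shape[1]))
    n = y.size
    rows = []
    prev_ss_res = float(np.sum((y - y.mean()) ** 2))
    prev_p = 1
    for tier in MODEL_TIERS:
        M, terms = model_matrix(coded, tier=tier, names=names, on_alias="drop")
        p = len(terms)
        aliased_tier = tier != "mean" and p == prev_p
        if tier == "mean":
            rows.append((tier, float(n * y.mean() ** 2), 1, float(n * y.mean() ** 2),
                         np.nan, np.nan, False))
            continue
        if p >= n:
            rows.append((tier, np.nan, p - prev_p, np.nan, np.nan, np.nan, True))
            continue
        beta, fitted, _, _, df_resid = _ols(M, y)
        ss_res = float(np.sum((y - fitted) ** 2))
        d_ss = prev_ss_res - ss_res
        d_df = p - prev_p
        ms_res = ss_res / df_resid if df_resid > 0 else np.nan
        if aliased_tier or d_df == 0:
            rows.append((tier, 0.0, 0, np.nan, np.nan, np.nan, True))
            continue
        f = (d_ss / d_df) / ms_res if ms_res > 0 else np.nan
        pval = float(stats.f.sf(f, d_df, df_resid)) if np.isfinite(f) else np.nan
        rows.append((tier, d_ss, d_df, d_ss / d_df, f, pval, False))
        prev_ss_res = ss_res
        prev_p = p
    table = pd.DataFrame(
        rows, columns=["tier", "sum_sq", "df", "mean_sq", "F", "p", "aliased"]
    )
    return SequentialComparison(table=table)


def lack_of_fit(design, response, model: QuadraticModel) -> LackOfFit:
    """Lack-of-fit split of the residual SS of ``model`` on ``design``."""
    coded = _coded_of(design)
    y = np.asarray(response, dtype=float).ravel()
    fitted = model.predict(coded)
    df_resid = y.size - model.n_terms
    return _lack_of_fit_split(coded, y, fitted, df_resid)


def optimum_on_cube(model: QuadraticModel, seed: int = 0, n_starts: int = 32) -> OptimumResult:
    """Maximize the quadratic over the coded cube [-1, 1]^n.

    If the stationary point of the polynomial is an interior maximum it is
    returned directly; otherwise the cube is searched by multi-start L-BFGS-B
    from a deterministic seeded start set.  Ties (within 1e-9 of the best
    value) break to the lexicographically smallest point.
    """
    n = model.n_factors
    H = model.hessian()
    b = model.linear
    classification = None
    eigvals = np.linalg.eigvalsh(H)
    if np.all(eigvals < -1e-12):
        x_star = np.linalg.solve(H, -b)
        if np.all(np.abs(x_star) <= 1.0 + 1e-12):
            x_star = np.clip(x_star, -1.0, 1.0)
            return OptimumResult(
                point=x_star,
                value=float(model.predict(x_star)),
                classification="interior stationary max",
            )
        classification = "boundary max"
    rng = np.random.default_rng(seed)
    starts = [np.zeros(n)]
    starts += list(rng.uniform(-1.0, 1.0, size=(n_starts - 1, n)))
    neg = lambda x: -model.predict(x)
    neg_grad = lambda x: -model.gradient(x)
    candidates = []
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg, x0, jac=neg_grad, method="L-BFGS-B", bounds=[(-1.0, 1.0)] * n
        )
        candidates.append((float(-res.fun), np.clip(res.x, -1, 1)))
    best_val = max(v for v, _ in candidates)
    ties = [x for v, x in candidates if v >= best_val - 1e-9]
    point = min(ties, key=lambda x: tuple(np.round(x, 9)))
    if classification is None:
        on_boundary = np.any(np.abs(point) >= 1.0 - 1e-6)
        classification = "boundary max" if on_boundary else "saddle-adjusted"
    return OptimumResult(point=point, value=float(model.predict(point)), classification=classification)


def surface_grid(model: QuadraticModel, factor_pair, fixed_point=None, grid_size: int = 41):
    """Predicted-response grid over one factor pair's [-1, 1]^2 square.

    Returns ``(axis1, axis2, Z)`` with ``Z[i, j] = Y(axis1[i], axis2[j])``,
    all non-varied factors held at ``fixed_point`` (default: the center).
    """
    n = model.n_factors
    names = list(model.factor_names)

    def _index(f):
        if isinstance(f, str):
            if f not in names:
                raise ValueError(f"unknown factor {f!r}; have {names}")
            return names.index(f)
        return int(f)

    i, j = (_index(f) for f in factor_pair)
    if i == j:
        raise ValueError("factor pair must name two distinct factors")
    fixed = np.zeros(n) if fixed_point is None else np.asarray(fixed_point, dtype=float)
    if fixed.size != n:
        raise ValueError(f"fixed_point must supply all {n} coded coordinates")
    axis = np.linspace(-1.0, 1.0, grid_size)
    A1, A2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.tile(fixed, (A1.size, 1))
    pts[:, i] = A1.ravel()
    pts[:, j] = A2.ravel()
    Z = model.predict(pts).reshape(grid_size, grid_size)
    return axis.copy(), axis.copy(), Z


def surface_grid_frame(model: QuadraticModel, factor_pair, fixed_point=None, grid_size: int = 41) -> pd.DataFrame:
    """Long-format (factor1, factor2, value) export of :func:`surface_grid`."""
    a1, a2, Z = surface_grid(model, factor_pair, fixed_point, grid_size)
    G1, G2 = np.meshgrid(a1, a2, indexing="ij")
    names = list(model.factor_names)
    idx = [names.index(f) if isinstance(f, str) else int(f) for f in factor_pair]
    return pd.DataFrame(
        {names[idx[0]]: G1.ravel(), names[idx[1]]: G2.ravel(), "value": Z.ravel()}
    )
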