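"""Developmental trajectory fitting for windowed network metrics.

Each metric series (one value per age window, indexed by the window's median
age) is fitted with two models:

* a straight line (ordinary least squares), and
* a penalized smoothing spline: a weighted sum of 6 cubic B-splines with knots
  at quantiles of the ages, second-derivative penalty, and smoothing parameter
  chosen by restricted maximum likelihood (REML). The fit's effective degrees
  of freedom (edf, the trace of the smoother matrix) are capped at
  ``edf_max`` = 3.5 by inflating the penalty — a nonlinear trajectory over a
  ~10-year span is allowed to be at most about as wiggly as a quadratic.

The better model is chosen by AIC (small-sample-corrected AIC and BIC are
recorded as consistency checks) and
summarized on a dense age grid by its change parameters: Δmax, the absolute
difference between the curve's maximum and minimum; age_min, the age at the
curve minimum; a decreasing/increasing direction (does the maximum precede the
minimum in age?); and a linear/nonlinear shape class. Evidence of nonzero
change comes from an F-type test of the chosen model against a constant, with
BH adjustment across regions for nodal analyses. Confidence intervals for
age_min are percentile intervals over bootstrap-replicate trajectory refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import brentq, minimize_scalar

from .network import fdr_adjust

__all__ = [
    "LinearFit",
    "SplineFit",
    "TrajectoryFit",
    "TrajectoryParams",
    "fit_trajectory",
    "trajectory_params",
    "bootstrap_age_min_ci",
    "nodal_significance",
    "linear_rate",
]

DEFAULT_EDF_MAX = 3.5
DENSE_GRID_STEP = 0.01  # years
_N_BASIS = 6  # cubic B-splines; 2 interior knots at age terciles


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rss: float
    aic: float
    aicc: float
    bic: float
    pvalue: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass
class SplineFit:
    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    edf: float
    rss: float
    aic: float
    aicc: float
    bic: float
    pvalue: float

    def predict(self, x):
        return BSpline(self.knots, self.coefficients, 3)(np.asarray(x, float))


@dataclass
class TrajectoryFit:
    x: np.ndarray
    y: np.ndarray
    linear: LinearFit
    spline: SplineFit | None
    chosen: str                       # "linear" or "spline"
    grid: np.ndarray                  # dense age grid
    curve: np.ndarray                 # chosen-model fitted curve on grid
    curve_linear: np.ndarray = field(repr=False, default=None)
    curve_spline: np.ndarray | None = field(repr=False, default=None)

    @property
    def chosen_fit(self):
        return self.spline if self.chosen == "spline" else self.linear


@dataclass
class TrajectoryParams:
    delta_max: float                  # |max - min| of the fitted curve
    age_min: float                    # age at the curve minimum
    age_max: float                    # age at the curve maximum
    direction: str                    # "decreasing" or "increasing"
    shape: str                        # "linear" or "nonlinear"
    boundary_min: bool                # minimum attained at an endpoint
    pvalue: float                     # chosen model vs constant


# --------------------------------------------------------------------------
# spline machinery


def _knot_vector(x: np.ndarray) -> np.ndarray:
    """Clamped cubic knot vector with interior knots at age terciles."""
    lo, hi = x[0], x[-1]
    interior = np.quantile(x, [1 / 3, 2 / 3])
    eps = 1e-9 * (hi - lo)
    interior = np.clip(interior, lo + eps, hi - eps)
    if interior[1] - interior[0] < eps:
        interior = np.array([lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3])
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3).toarray()


def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
    """Exact integral of products of basis second derivatives.

    Second derivatives of cubic B-splines are piecewise linear, so their
    pairwise products are piecewise quadratic and 2-point Gauss-Legendre
    quadrature per inter-knot interval integrates them exactly.
    """
    breaks = np.unique(knots)
    gl_nodes = np.array([-1, 1]) / np.sqrt(3)
    S = np.zeros((_N_BASIS, _N_BASIS))
    eye = np.eye(_N_BASIS)
    d2 = [BSpline(knots, eye[j], 3).derivative(2) for j in range(_N_BASIS)]
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = (b - a) / 2
        pts = (a + b) / 2 + half * gl_nodes
        vals = np.array([f(pts) for f in d2])          # (n_basis, 2)
        S += half * vals @ vals.T
    return (S + S.T) / 2


def _fit_at_lambda(BtB, Bty, S, lam):
    A = BtB + lam * S
    beta = np.linalg.solve(A, Bty)
    edf = float(np.trace(np.linalg.solve(A, BtB)))
    return beta, edf, A


def _fit_spline(x: np.ndarray, y: np.ndarray, edf_max: float) -> SplineFit:
    n = len(x)
    knots = _knot_vector(x)
    B = _design_matrix(x, knots)
    S = _penalty_matrix(knots)
    BtB = B.T @ B
    Bty = B.T @ y

    eigs = np.linalg.eigvalsh(S)
    pos = eigs[eigs > 1e-10 * eigs[-1]]
    ld_S_plus = float(np.sum(np.log(pos)))
    rank_S = len(pos)            # n_basis - 2 (linear null space)
    m_null = _N_BASIS - rank_S

    def reml(log_lam):
        lam = np.exp(log_lam)
        beta, _, A = _fit_at_lambda(BtB, Bty, S, lam)
        resid = y - B @ beta
        pen = float(resid @ resid + lam * beta @ S @ beta)
        sign, ld_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (
            0.5 * (n - m_null) * np.log(max(pen, 1e-300))
            + 0.5 * ld_A
            - 0.5 * (rank_S * log_lam + ld_S_plus)
        )

    # The REML profile in log-lambda is routinely multimodal on near-linear
    # series (a spurious undersmoothing minimum besides the boundary optimum),
    # so locate the global minimum on a grid before local refinement.
    grid = np.linspace(-15.0, 25.0, 81)
    values = [reml(ll) for ll in grid]
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    log_lam = float(res.x) if res.fun <= values[best] else float(grid[best])
    beta, edf, _ = _fit_at_lambda(BtB, Bty, S, np.exp(log_lam))
    if edf > edf_max:
        # inflate the penalty (never drop basis functions) until edf == edf_max
        hi = log_lam
        while _fit_at_lambda(BtB, Bty, S, np.exp(hi))[1] > edf_max:
            hi += 2.0
            if hi > 60:
                break
        log_lam = brentq(
            lambda ll: _fit_at_lambda(BtB, Bty, S, np.exp(ll))[1] - edf_max,
            log_lam, hi,
        )
        beta, edf, _ = _fit_at_lambda(BtB, Bty, S, np.exp(log_lam))

    resid = y - B @ beta
    rss = float(resid @ resid)
    aic, aicc, bic = _information_criteria(n, rss, edf + 1.0)
    pvalue = _f_test_vs_constant(y, rss, edf, n)
    return SplineFit(knots=knots, coefficients=beta, lam=float(np.exp(log_lam)),
                     edf=edf, rss=rss, aic=aic, aicc=aicc, bic=bic,
                     pvalue=pvalue)


def _information_criteria(n, rss, k):
    """Gaussian AIC, small-sample-corrected AIC and BIC.

    k counts model df plus 1 for the error variance. With as few as ~9
    windows per series, plain AIC is anticonservative toward the spline, so
    model selection uses the standard small-sample correction
    AICc = AIC + 2k(k+1)/(n-k-1).
    """
    rss = max(rss, 1e-300)
    ll_term = n * np.log(rss / n)
    aic = ll_term + 2.0 * k
    aicc = aic + (2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf)
    return aic, aicc, ll_term + np.log(n) * k


def _f_test_vs_constant(y, rss, model_df, n):
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1 = model_df - 1.0
    df2 = n - model_df
    if df1 <= 1e-8 or df2 <= 0 or rss0 <= rss + 1e-300:
        return 1.0
    f = ((rss0 - rss) / df1) / max(rss / df2, 1e-300)
    return float(stats.f.sf(f, df1, df2))


def _fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    aic, aicc, bic = _information_criteria(n, rss, 3.0)  # slope, intercept, scale
    pvalue = _f_test_vs_constant(y, rss, 2.0, n)
    return LinearFit(slope=float(slope), intercept=float(intercept), rss=rss,
                     aic=aic, aicc=aicc, bic=bic, pvalue=pvalue)


# --------------------------------------------------------------------------
# public operations


def fit_trajectory(x, y, edf_max: float = DEFAULT_EDF_MAX,
                   grid_step: float = DENSE_GRID_STEP) -> TrajectoryFit:
    """Fit linear and constrained-spline models; select by corrected AIC.

    Requires at least 5 points with strictly increasing x. With fewer points
    than the 6-function spline basis can support, only the linear model is
    fitted (with a warning). Ties go to the linear model (parsimony).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit a trajectory")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    linear = _fit_linear(x, y)
    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    curve_lin = linear.predict(grid)

    spline = None
    curve_spl = None
    if len(x) >= _N_BASIS:
        spline = _fit_spline(x, y, edf_max)
        curve_spl = spline.predict(grid)
        chosen = "spline" if spline.aic < linear.aic else "linear"
    else:
        warnings.warn("too few points for the spline basis; linear fit only",
                      stacklevel=2)
        chosen = "linear"

    curve = curve_spl if chosen == "spline" else curve_lin
    return TrajectoryFit(x=x, y=y, linear=linear, spline=spline, chosen=chosen,
                         grid=grid, curve=curve, curve_linear=curve_lin,
                         curve_spline=curve_spl)


def trajectory_params(fit: TrajectoryFit) -> TrajectoryParams:
    """Δmax, age at minimum, direction and shape from the dense fitted curve."""
    curve, grid = fit.curve, fit.grid
    i_min = int(np.argmin(curve))
    i_max = int(np.argmax(curve))
    age_min = float(grid[i_min])
    age_max = float(grid[i_max])
    return TrajectoryParams(
        delta_max=float(curve[i_max] - curve[i_min]),
        age_min=age_min,
        age_max=age_max,
        direction="decreasing" if age_max < age_min else "increasing",
        shape="nonlinear" if fit.chosen == "spline" else "linear",
        boundary_min=i_min in (0, len(grid) - 1),
        pvalue=fit.chosen_fit.pvalue,
    )


def refit_curve_argmin(x, y, model: str, edf_max: float = DEFAULT_EDF_MAX,
                       grid_step: float = DENSE_GRID_STEP) -> float:
    """Age at minimum of a single-model refit (used for bootstrap replicates)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    if model == "linear":
        curve = _fit_linear(x, y).predict(grid)
    else:
        curve = _fit_spline(x, y, edf_max).predict(grid)
    return float(grid[int(np.argmin(curve))])


def bootstrap_age_min_ci(x, replicate_series, model: str = "spline",
                         level: float = 0.95, edf_max: float = DEFAULT_EDF_MAX,
                         grid_step: float = DENSE_GRID_STEP):
    """Percentile CI for the trajectory-minimum age over bootstrap replicates.

    ``replicate_series`` is (n_replicates, n_windows): each row is one
    bootstrap replicate of the windowed metric series. The chosen model is
    refitted to each replicate and the CI is the percentile interval of the
    resulting argmin distribution. Returns ``(lo, hi, argmins)``.
    """
    replicate_series = np.asarray(replicate_series, dtype=float)
    if replicate_series.ndim != 2:
        raise ValueError("replicate_series must be (n_replicates, n_windows)")
    if replicate_series.shape[0] < 100:
        warnings.warn("fewer than 100 bootstrap replicates: CI may be unstable",
                      stacklevel=2)
    argmins = np.array([
        refit_curve_argmin(x, row, model, edf_max, grid_step)
        for row in replicate_series
    ])
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(argmins, [tail, 100.0 - tail])
    return float(lo), float(hi), argmins


def nodal_significance(pvalues, alpha: float = 0.05):
    """BH-adjust per-region trajectory p-values; returns (p_fdr, significant)."""
    p = np.asarray(pvalues, dtype=float)
    p_fdr = fdr_adjust(p)
    return p_fdr, p_fdr < alpha


def linear_rate(y, x) -> float:
    """OLS slope of y on x (rate of change per unit age)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    return float(np.polyfit(x, y, 1)[0])
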