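"""Trend estimation over acquisition order.

A *trend* is the per-feature sequence of correction factors C_{p,b,i}
estimated from the intensities of a chosen subset of observations (the QC
injections alone, or all observations for *background* correction) as a
function of acquisition rank, and evaluated at every observation of the
fit unit (one batch, or the whole run).  Corrected intensities are the raw
intensities divided by the trend (times a rescaling constant).

Ranks are consecutive integers 1..m within each fit unit -- acquisition
count, not raw run index -- so that gaps left by removed observations do
not distort the smoothers.

Available trend methods
-----------------------
constant        mean or median of the fit values (flat trend)
linear          ordinary least-squares line over rank
moving_median   median of a moving rank window of half-width w
polynomial      degree-n least-squares polynomial (Chebyshev-conditioned)
spline          penalized cubic smoothing spline, lambda fixed or by GCV
loess           local linear regression with tricube weights, span alpha

All methods are linear in the fit values except the moving median; all are
equivariant under shifting and positive scaling of the fit values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Any, Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, EstimationError, ParameterError

TrendMethod = Literal["constant", "linear", "moving_median", "polynomial", "spline", "loess"]

#: Grid of smoothing-spline penalties searched by generalized
#: cross-validation when ``lam="auto"``.  Because ranks are consecutive
#: integers, the penalty scale is y-scale-free and a fixed log-spaced grid
#: covers everything from near-interpolation to a near-linear fit.
GCV_LAMBDA_GRID: np.ndarray = np.logspace(-4, 8, 61)


# ---------------------------------------------------------------------------
# Strategy description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendSpec:
    """Full description of a correction strategy.

    Parameters
    ----------
    method : str
        One of ``constant``, ``linear``, ``moving_median``, ``polynomial``,
        ``spline``, ``loess``.
    averaging : {"mean", "median"}
        Averaging measure for the constant method.
    w : int, optional
        Moving-median half-width; the window spans ranks [i-w, i+w].
    n : int, optional
        Polynomial degree.
    lam : float or "auto", optional
        Smoothing-spline penalty; ``"auto"`` selects it by GCV.
    alpha : float, optional
        LOESS neighbourhood fraction in (0, 1].
    scope : {"qc_only", "background"}
        Observations the trend is fitted to: the QC injections alone, or
        all observations (background correction).
    application : {"batchwise", "global"}
        Fit unit: each batch independently, or the whole run as one unit.
    rescale : {"first_batch", "all_batches", "none"}
        Rescaling factor R_p restoring corrected values to an
        interpretable intensity scale (see :mod:`msdrift.correction`).
    """

    method: TrendMethod
    averaging: Literal["mean", "median"] = "mean"
    w: int | None = None
    n: int | None = None
    lam: float | str | None = None
    alpha: float | None = None
    scope: Literal["qc_only", "background"] = "background"
    application: Literal["batchwise", "global"] = "batchwise"
    rescale: Literal["first_batch", "all_batches", "none"] = "all_batches"

    _PARAM_OF_METHOD = {
        "constant": None,
        "linear": None,
        "moving_median": "w",
        "polynomial": "n",
        "spline": "lam",
        "loess": "alpha",
    }

    def __post_init__(self) -> None:
        if self.method not in self._PARAM_OF_METHOD:
            raise ConfigurationError(f"unknown trend method {self.method!r}")
        if self.averaging not in ("mean", "median"):
            raise ConfigurationError(f"unknown averaging {self.averaging!r}")
        if self.scope not in ("qc_only", "background"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.application not in ("batchwise", "global"):
            raise ConfigurationError(f"unknown application {self.application!r}")
        if self.rescale not in ("first_batch", "all_batches", "none"):
            raise ConfigurationError(f"unknown rescale mode {self.rescale!r}")
        needed = self._PARAM_OF_METHOD[self.method]
        for name in ("w", "n", "lam", "alpha"):
            value = getattr(self, name)
            if name == needed:
                if value is None:
                    if name == "lam":
                        object.__setattr__(self, "lam", "auto")
                    else:
                        raise ConfigurationError(
                            f"method {self.method!r} requires parameter {name!r}"
                        )
            elif value is not None:
                raise ConfigurationError(
                    f"parameter {name!r} does not belong to method {self.method!r}"
                )
        if self.method == "moving_median" and (
            int(self.w) != self.w or self.w < 0
        ):
            raise ParameterError(f"window half-width w must be a non-negative integer, got {self.w}")
        if self.method == "polynomial" and (int(self.n) != self.n or self.n < 1):
            raise ParameterError(f"polynomial degree n must be a positive integer, got {self.n}")
        if self.method == "spline" and self.lam != "auto" and not float(self.lam) > 0:
            raise ParameterError(f"smoothing penalty lambda must be positive, got {self.lam}")
        if self.method == "loess" and not 0 < float(self.alpha) <= 1:
            raise ParameterError(f"loess alpha must be in (0, 1], got {self.alpha}")

    @property
    def parameter_name(self) -> str | None:
        return self._PARAM_OF_METHOD[self.method]

    @property
    def parameter_value(self) -> Any:
        name = self.parameter_name
        return None if name is None else getattr(self, name)

    def with_parameter(self, value: Any) -> "TrendSpec":
        name = self.parameter_name
        if name is None:
            raise ConfigurationError(f"method {self.method!r} has no tunable parameter")
        return replace(self, **{name: value})

    def label(self) -> str:
        bits = [self.application, self.scope, self.method]
        if self.method == "constant":
            bits.append(self.averaging)
        if self.parameter_name is not None:
            bits.append(f"{self.parameter_name}={self.parameter_value}")
        return " ".join(bits)

    def to_mapping(self) -> dict:
        out = {"method": self.method, "scope": self.scope,
               "application": self.application, "rescale": self.rescale}
        if self.method == "constant":
            out["averaging"] = self.averaging
        if self.parameter_name is not None:
            out[self.parameter_name] = self.parameter_value
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "TrendSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown TrendSpec key(s): {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass
class TrendFit:
    """Realized trend for one feature within one fit unit."""

    factors: np.ndarray  # trend evaluated at every rank of the unit
    fit_ranks: np.ndarray
    fit_values: np.ndarray
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _prepare(fit_ranks, values, eval_ranks):
    fit_ranks = np.asarray(fit_ranks, dtype=float)
    values = np.asarray(values, dtype=float)
    if fit_ranks.shape != values.shape:
        raise EstimationError(
            f"fit_ranks {fit_ranks.shape} and values {values.shape} differ in length"
        )
    eval_ranks = fit_ranks if eval_ranks is None else np.asarray(eval_ranks, dtype=float)
    return fit_ranks, values, eval_ranks


# ---------------------------------------------------------------------------
# Trend methods
# ---------------------------------------------------------------------------


def constant_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    averaging: str = "mean",
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Flat trend: every factor equals the mean or median of the fit values."""
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if values.size == 0:
        raise EstimationError("constant trend needs at least one fit value")
    if averaging == "mean":
        level = float(np.mean(values))
    elif averaging == "median":
        level = float(np.median(values))
    else:
        raise ConfigurationError(f"unknown averaging {averaging!r}")
    return TrendFit(
        np.full(eval_ranks.shape, level),
        fit_ranks,
        values,
        {"method": "constant", "averaging": averaging, "level": level},
    )


def linear_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Ordinary least-squares line over acquisition rank."""
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if len(np.unique(fit_ranks)) < 2:
        raise EstimationError("linear trend needs at least 2 distinct fit ranks")
    slope, intercept = np.polyfit(fit_ranks, values, 1)
    return TrendFit(
        slope * eval_ranks + intercept,
        fit_ranks,
        values,
        {"method": "linear", "slope": float(slope), "intercept": float(intercept)},
    )


def moving_median_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    w: int,
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Median of a moving rank window of half-width ``w``.

    The factor at fit rank i is the median of the fit values whose ranks
    lie in [i-w, i+w]; windows truncate at the ends of the unit.  At ranks
    without a fit value the trend is linearly interpolated between the
    neighbouring fit-rank factors (constant beyond the first/last).  With
    w=0 the trend reproduces the fit values at the fit ranks exactly.
    """
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if int(w) != w or w < 0:
        raise ParameterError(f"window half-width w must be a non-negative integer, got {w}")
    if values.size == 0:
        raise EstimationError("moving median needs at least one fit value")
    w = int(w)
    order = np.argsort(fit_ranks, kind="stable")
    r, v = fit_ranks[order], values[order]
    lo = np.searchsorted(r, r - w, side="left")
    hi = np.searchsorted(r, r + w, side="right")
    at_fit = np.array([np.median(v[a:b]) for a, b in zip(lo, hi)])
    factors = np.interp(eval_ranks, r, at_fit)
    return TrendFit(factors, fit_ranks, values, {"method": "moving_median", "w": w})


def polynomial_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    n: int,
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Degree-``n`` least-squares polynomial over rank.

    Ranks are rescaled to [-1, 1] internally for conditioning; degree 1 is
    identical to :func:`linear_trend`.
    """
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if int(n) != n or n < 1:
        raise ParameterError(f"polynomial degree n must be a positive integer, got {n}")
    if len(np.unique(fit_ranks)) <= n:
        raise EstimationError(
            f"degree-{n} polynomial needs more than {n} distinct fit ranks, "
            f"got {len(np.unique(fit_ranks))}"
        )
    poly = np.polynomial.Polynomial.fit(fit_ranks, values, deg=int(n))
    return TrendFit(
        poly(eval_ranks),
        fit_ranks,
        values,
        {"method": "polynomial", "n": int(n), "coefficients": poly.convert().coef.tolist()},
    )


# -- smoothing spline ------------------------------------------------------


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline roughness matrix K with f'' energy f^T K f.

    Green & Silverman's construction: K = D^T W^-1 D where D is the
    (m-2) x m second-difference matrix over knot spacings h and W the
    tridiagonal Gram matrix of the second-derivative basis.  For any
    natural cubic spline f with values f(x_i), int f''(t)^2 dt = f^T K f.
    """
    h = np.diff(x)
    m = len(x)
    D = np.zeros((m - 2, m))
    W = np.zeros((m - 2, m - 2))
    for i in range(m - 2):
        D[i, i] = 1 / h[i]
        D[i, i + 1] = -1 / h[i] - 1 / h[i + 1]
        D[i, i + 2] = 1 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3
        if i + 1 < m - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6
    return D.T @ np.linalg.solve(W, D)


@lru_cache(maxsize=128)
def _spline_eigensystem(fit_ranks: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the roughness matrix K (cached per rank set)."""
    K = _penalty_matrix(np.asarray(fit_ranks))
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)
    eigvals[:2] = 0.0  # null space (straight lines) has dimension exactly 2
    return U, eigvals


@lru_cache(maxsize=512)
def _spline_operators(
    fit_ranks: tuple[float, ...], eval_ranks: tuple[float, ...], lam: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Linear operators of the cubic smoothing spline at penalty ``lam``.

    The minimizer of sum (y_i - f(x_i))^2 + lam * int f''(t)^2 dt over all
    twice-differentiable f is a natural cubic spline with knots at the fit
    ranks and fitted values S y, S = (I + lam*K)^-1 (K the roughness
    matrix), so the whole fit is linear in y.  S is formed through the
    eigendecomposition of K -- exact for any lam, including the lam -> inf
    limit where S becomes the projection onto straight lines.  E maps y to
    evaluations at arbitrary ranks: the natural cubic interpolant of the
    fitted values inside the knot span, extended linearly beyond it.
    Operators are cached because all features of a fit unit share the same
    ranks, and the GCV score needs only S y and trace(S).
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(fit_ranks)
    U, eigvals = _spline_eigensystem(fit_ranks)
    shrink = 1.0 / (1.0 + lam * eigvals)
    S = (U * shrink) @ U.T
    ev = np.asarray(eval_ranks)
    cs = CubicSpline(x, S, bc_type="natural", axis=0)
    E = cs(np.clip(ev, x[0], x[-1]))
    below, above = ev < x[0], ev > x[-1]
    if below.any():
        E[below] = S[0] + np.outer(ev[below] - x[0], cs(x[0], 1))
    if above.any():
        E[above] = S[-1] + np.outer(ev[above] - x[-1], cs(x[-1], 1))
    return E, S, float(np.trace(S))


def _gcv_score(values: np.ndarray, S: np.ndarray, trace: float) -> float:
    m = len(values)
    resid = values - S @ values
    denom = m - trace
    return m * float(resid @ resid) / (denom * denom)


def spline_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    lam: float | str = "auto",
    eval_ranks: Sequence[float] | None = None,
    lambda_grid: Sequence[float] | None = None,
) -> TrendFit:
    """Penalized cubic smoothing spline.

    Minimizes ``sum (y - f)^2 + lam * int f''^2`` over natural cubic
    splines.  ``lam="auto"`` selects the penalty minimizing the generalized
    cross-validation score ``m * ||(I-S)y||^2 / (m - tr S)^2`` over
    :data:`GCV_LAMBDA_GRID` (or ``lambda_grid``).  As ``lam`` grows the fit
    converges to the least-squares line; as ``lam`` approaches 0 it
    interpolates the fit values.
    """
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if len(np.unique(fit_ranks)) < 4:
        raise EstimationError("smoothing spline needs at least 4 distinct fit ranks")
    order = np.argsort(fit_ranks, kind="stable")
    r, v = fit_ranks[order], values[order]
    rt, et = tuple(r), tuple(eval_ranks)
    if lam == "auto":
        grid = GCV_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
        scores = []
        for cand in grid:
            _, S, trace = _spline_operators(rt, et, float(cand))
            scores.append(_gcv_score(v, S, trace))
        best = int(np.argmin(scores))
        chosen = float(grid[best])
        diagnostics = {
            "method": "spline",
            "lam": chosen,
            "lam_auto": True,
            "gcv_scores": dict(zip(map(float, grid), map(float, scores))),
        }
    else:
        chosen = float(lam)
        if not chosen > 0:
            raise ParameterError(f"smoothing penalty lambda must be positive, got {lam}")
        diagnostics = {"method": "spline", "lam": chosen, "lam_auto": False}
    E, _, _ = _spline_operators(rt, et, chosen)
    return TrendFit(E @ v, fit_ranks, values, diagnostics)


# -- LOESS -----------------------------------------------------------------


@lru_cache(maxsize=512)
def _loess_matrix(
    fit_ranks: tuple[float, ...], eval_ranks: tuple[float, ...], alpha: float
) -> np.ndarray:
    """Hat matrix of local linear regression with tricube weights.

    At each evaluation rank the q = ceil(alpha * m) nearest fit points are
    weighted by (1 - (d/d_q)^3)^3, d_q the distance of the q-th nearest,
    and a weighted straight line is fitted; the matrix row maps fit values
    to the local fit.  Depends only on the ranks, so it is shared by every
    feature of a unit.
    """
    x = np.asarray(fit_ranks)
    m = len(x)
    q = math.ceil(alpha * m)
    if q < 2:
        raise ParameterError(
            f"loess neighbourhood ceil(alpha*m) = {q} < 2 (alpha={alpha}, m={m})"
        )
    q = min(q, m)
    L = np.empty((len(eval_ranks), m))
    for k, x0 in enumerate(eval_ranks):
        d = np.abs(x - x0)
        d_q = np.partition(d, q - 1)[q - 1]
        if d_q == 0:
            d_q = 1.0
        u = np.clip(d / d_q, 0.0, 1.0)
        wts = (1 - u**3) ** 3
        X = np.column_stack([np.ones(m), x - x0])
        XtW = X.T * wts
        A = XtW @ X
        try:
            beta_row = np.linalg.solve(A, XtW)[0]
        except np.linalg.LinAlgError:
            # degenerate neighbourhood (e.g. a single positive weight):
            # fall back to the locally weighted mean
            beta_row = wts / wts.sum()
        L[k] = beta_row
    return L


def loess_trend(
    fit_ranks: Sequence[float],
    values: Sequence[float],
    alpha: float,
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Locally weighted linear regression (LOESS) over rank.

    ``alpha`` in (0, 1] is the neighbourhood fraction; each local fit uses
    the ``ceil(alpha * m)`` nearest fit points with tricube weights and a
    degree-1 local polynomial (no robustness iterations).
    """
    fit_ranks, values, eval_ranks = _prepare(fit_ranks, values, eval_ranks)
    if not 0 < alpha <= 1:
        raise ParameterError(f"loess alpha must be in (0, 1], got {alpha}")
    order = np.argsort(fit_ranks, kind="stable")
    r, v = fit_ranks[order], values[order]
    L = _loess_matrix(tuple(r), tuple(eval_ranks), float(alpha))
    return TrendFit(L @ v, fit_ranks, values, {"method": "loess", "alpha": float(alpha)})


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def fit_trend(
    spec: TrendSpec,
    fit_ranks: Sequence[float],
    values: Sequence[float],
    eval_ranks: Sequence[float] | None = None,
) -> TrendFit:
    """Fit the trend described by ``spec`` (method + parameter only)."""
    if spec.method == "constant":
        return constant_trend(fit_ranks, values, spec.averaging, eval_ranks)
    if spec.method == "linear":
        return linear_trend(fit_ranks, values, eval_ranks)
    if spec.method == "moving_median":
        return moving_median_trend(fit_ranks, values, spec.w, eval_ranks)
    if spec.method == "polynomial":
        return polynomial_trend(fit_ranks, values, spec.n, eval_ranks)
    if spec.method == "spline":
        return spline_trend(fit_ranks, values, spec.lam, eval_ranks)
    if spec.method == "loess":
        return loess_trend(fit_ranks, values, spec.alpha, eval_ranks)
    raise ConfigurationError(f"unknown trend method {spec.method!r}")


MIN_FIT_POINTS = {
    "constant": 1,
    "linear": 2,
    "moving_median": 1,
    "polynomial": None,  # n + 1
    "spline": 4,
    "loess": 2,
}


def min_fit_points(spec: TrendSpec) -> int:
    if spec.method == "polynomial":
        return int(spec.n) + 1
    if spec.method == "loess":
        return max(2, math.ceil(2 / spec.alpha))
    return MIN_FIT_POINTS[spec.method]
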