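"""Assembling and applying correction factors.

The corrected intensity is

    X'_{p,b,i} = X_{p,b,i} * R_p / C_{p,b,i}

where C_{p,b,i} is the per-feature trend evaluated at observation i of
batch b (see :mod:`msdrift.trends`) and R_p is a per-feature rescaling
constant restoring corrected values to an interpretable intensity scale.
Division by a trend that dips towards zero is the known failure mode of
QC-only regression corrections; the *faithful* guard mode reproduces it
(while flagging the affected cells), the *clamp* mode substitutes a safe
factor instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EstimationError
from .peak_table import ROLE_CONDITIONING, ROLE_QC, PeakMatrix
from .trends import (
    TrendSpec,
    _loess_matrix,
    _spline_operators,
    fit_trend,
    min_fit_points,
    GCV_LAMBDA_GRID,
)

logger = logging.getLogger(__name__)

FLAG_OK = 0
FLAG_NONPOSITIVE = 1
FLAG_GUARDED = 2

#: |C| below this multiple of the unit's median positive factor is treated
#: as a near-zero division hazard.
TINY_FACTOR_RATIO = 1e-6


@dataclass
class CorrectionFactors:
    """Realized per-observation, per-feature trend and rescale factors."""

    factors: np.ndarray  # (n_observations, n_features) trend values C
    rescale: np.ndarray  # (n_features,) rescaling factors R
    spec: TrendSpec
    flags: np.ndarray  # (n_observations, n_features) cell markers
    diagnostics: dict = field(default_factory=dict)


def _unit_indices(matrix: PeakMatrix, spec: TrendSpec) -> list[tuple[str, np.ndarray]]:
    """Observation index blocks for each fit unit, in acquisition order."""
    if spec.application == "global":
        return [("all", np.arange(matrix.n_observations))]
    return [
        (f"batch {b}", np.flatnonzero(matrix.batch_mask(b))) for b in matrix.batches
    ]


def _fit_subset_mask(matrix: PeakMatrix, idx: np.ndarray, scope: str) -> np.ndarray:
    roles = matrix.observations["role"].to_numpy()[idx]
    if scope == "qc_only":
        return roles == ROLE_QC
    return roles != ROLE_CONDITIONING


def build_correction_factors(matrix: PeakMatrix, spec: TrendSpec) -> CorrectionFactors:
    """Fit the trend of ``spec`` for every feature and fit unit.

    Within each unit (batch, or the whole run for global application) the
    observations get consecutive ranks 1..m; the trend is fitted to the
    scope subset (QC injections only, or everything but conditioning runs)
    and evaluated at every rank.  Features whose fit subset is entirely
    zero in a unit are left uncorrected there (factors 1, logged).  Cells
    where the fitted trend is non-positive or non-finite are flagged
    ``nonpositive_factor``.
    """
    n_obs, n_feat = matrix.shape
    factors = np.empty((n_obs, n_feat))
    flags = np.zeros((n_obs, n_feat), dtype=np.uint8)
    diagnostics: dict = {"units": {}, "uncorrected": []}

    for unit_name, idx in _unit_indices(matrix, spec):
        m = len(idx)
        eval_ranks = np.arange(1, m + 1, dtype=float)
        fit_mask = _fit_subset_mask(matrix, idx, spec.scope)
        fit_ranks = eval_ranks[fit_mask]
        if len(fit_ranks) < min_fit_points(spec):
            raise EstimationError(
                f"{unit_name}: {len(fit_ranks)} fit observations in scope "
                f"{spec.scope!r} but method {spec.method!r} needs at least "
                f"{min_fit_points(spec)}"
            )
        Y = matrix.intensities[idx][fit_mask]  # (m_fit, n_features)
        all_zero = ~Y.any(axis=0)
        if all_zero.any():
            ids = matrix.feature_ids[all_zero]
            logger.warning(
                "%s: %d feature(s) with all-zero fit values left uncorrected",
                unit_name,
                len(ids),
            )
            diagnostics["uncorrected"].append(
                {"unit": unit_name, "features": [str(f) for f in ids]}
            )
        live = np.flatnonzero(~all_zero)
        block = np.ones((m, n_feat))
        if len(live):
            block[:, live], unit_diag = _fit_unit(
                spec, fit_ranks, eval_ranks, Y[:, live]
            )
            diagnostics["units"][unit_name] = unit_diag
        factors[idx] = block

    bad = ~np.isfinite(factors) | (factors <= 0)
    flags[bad] = FLAG_NONPOSITIVE
    rescale = rescale_factor(matrix, spec)
    return CorrectionFactors(factors, rescale, spec, flags, diagnostics)


def _fit_unit(
    spec: TrendSpec, fit_ranks: np.ndarray, eval_ranks: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Vectorized trend fit for one unit; Y is (m_fit, k) fit values.

    Linear-in-y methods (constant, linear, polynomial, spline, loess) go
    through a shared operator matrix so every feature of the unit reuses
    the same rank geometry; the moving median takes windowed medians
    directly.  Returns (m_eval, k) factors.
    """
    diag: dict = {}
    if spec.method == "constant":
        level = Y.mean(axis=0) if spec.averaging == "mean" else np.median(Y, axis=0)
        return np.broadcast_to(level, (len(eval_ranks), Y.shape[1])).copy(), diag
    if spec.method == "linear":
        slope, intercept = np.polyfit(fit_ranks, Y, 1)
        return np.outer(eval_ranks, slope) + intercept, diag
    if spec.method == "polynomial":
        # ranks conditioned to [-1, 1] as in trends.polynomial_trend
        lo, hi = fit_ranks.min(), fit_ranks.max()
        scale = lambda r: (2 * r - (lo + hi)) / (hi - lo)  # noqa: E731
        V_fit = np.vander(scale(fit_ranks), int(spec.n) + 1, increasing=True)
        V_eval = np.vander(scale(eval_ranks), int(spec.n) + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V_fit, Y, rcond=None)
        return V_eval @ coef, diag
    if spec.method == "loess":
        L = _loess_matrix(tuple(fit_ranks), tuple(eval_ranks), float(spec.alpha))
        return L @ Y, diag
    if spec.method == "spline":
        rt, et = tuple(fit_ranks), tuple(eval_ranks)
        if spec.lam == "auto":
            m = len(fit_ranks)
            scores = np.empty((len(GCV_LAMBDA_GRID), Y.shape[1]))
            for g, lam in enumerate(GCV_LAMBDA_GRID):
                _, S, trace = _spline_operators(rt, et, float(lam))
                resid = Y - S @ Y
                scores[g] = m * (resid**2).sum(axis=0) / (m - trace) ** 2
            best = np.argmin(scores, axis=0)
            out = np.empty((len(eval_ranks), Y.shape[1]))
            for g in np.unique(best):
                E, _, _ = _spline_operators(rt, et, float(GCV_LAMBDA_GRID[g]))
                cols = best == g
                out[:, cols] = E @ Y[:, cols]
            diag["lam_chosen"] = {
                "grid": GCV_LAMBDA_GRID.tolist(),
                "counts": np.bincount(best, minlength=len(GCV_LAMBDA_GRID)).tolist(),
            }
            return out, diag
        E, _, _ = _spline_operators(rt, et, float(spec.lam))
        return E @ Y, diag
    if spec.method == "moving_median":
        # per-feature path is already vectorized across columns
        order = np.argsort(fit_ranks, kind="stable")
        r, V = fit_ranks[order], Y[order]
        lo = np.searchsorted(r, r - spec.w, side="left")
        hi = np.searchsorted(r, r + spec.w, side="right")
        at_fit = np.stack([np.median(V[a:b], axis=0) for a, b in zip(lo, hi)])
        if np.array_equal(r, eval_ranks):
            return at_fit, diag
        out = np.empty((len(eval_ranks), Y.shape[1]))
        for j in range(Y.shape[1]):
            out[:, j] = np.interp(eval_ranks, r, at_fit[:, j])
        return out, diag
    # fall back to the scalar dispatcher for anything exotic
    out = np.empty((len(eval_ranks), Y.shape[1]))
    for j in range(Y.shape[1]):
        out[:, j] = fit_trend(spec, fit_ranks, Y[:, j], eval_ranks).factors
    return out, diag


def rescale_factor(
    matrix: PeakMatrix, spec: TrendSpec, rescale_mode: str | None = None
) -> np.ndarray:
    """Per-feature rescaling factor R_p.

    ``first_batch``: the average (per ``spec.averaging``) over the scope
    subset of the first batch; ``all_batches``: the average over the scope
    subset of the whole run; ``none``: 1, leaving corrected data on a
    fold-of-trend scale.
    """
    mode = spec.rescale if rescale_mode is None else rescale_mode
    if mode == "none":
        return np.ones(matrix.n_features)
    roles = matrix.observations["role"].to_numpy()
    scope_mask = (
        roles == ROLE_QC if spec.scope == "qc_only" else roles != ROLE_CONDITIONING
    )
    if mode == "first_batch":
        scope_mask = scope_mask & matrix.batch_mask(matrix.batches[0])
        if not scope_mask.any():
            raise ConfigurationError(
                "first_batch rescale: no scope observations in the first batch"
            )
    elif mode != "all_batches":
        raise ConfigurationError(f"unknown rescale mode {mode!r}")
    values = matrix.intensities[scope_mask]
    if spec.averaging == "median":
        return np.median(values, axis=0)
    return values.mean(axis=0)


def apply_correction(
    matrix: PeakMatrix, cf: CorrectionFactors, guard: str = "faithful"
) -> PeakMatrix:
    """Apply X' = X * R / C cell-wise.

    Zeros stay zero (0 encodes non-detection).  ``faithful`` divides by the
    fitted trend as-is -- reproducing the blow-ups caused by near-zero
    factors -- but flags cells where |C| falls below
    ``TINY_FACTOR_RATIO`` x the unit's median positive factor; cells with
    C <= 0 cannot yield a meaningful non-negative intensity and are set to
    0 (flagged ``nonpositive_factor``).  ``clamp`` instead substitutes the
    unit's median positive factor at all hazardous cells and flags them
    ``guarded``.  The two modes differ only at flagged cells.  Guard flags
    are recorded in ``cf.flags`` in place.
    """
    if matrix.shape != cf.factors.shape:
        raise ConfigurationError(
            f"matrix shape {matrix.shape} does not match factors {cf.factors.shape}"
        )
    if guard not in ("faithful", "clamp"):
        raise ConfigurationError(f"unknown guard mode {guard!r}")

    X = matrix.intensities
    C = cf.factors.copy()
    flags = cf.flags

    for _, idx in _unit_indices(matrix, cf.spec):
        block = cf.factors[idx]
        pos = np.where(block > 0, block, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(pos, axis=0)
        med = np.where(np.isfinite(med), med, 1.0)
        hazardous = (
            ~np.isfinite(block)
            | (block <= 0)
            | (np.abs(block) < TINY_FACTOR_RATIO * med)
        )
        if guard == "clamp":
            C[idx] = np.where(hazardous, np.broadcast_to(med, block.shape), block)
            sub = flags[idx]
            sub[hazardous] = FLAG_GUARDED
            flags[idx] = sub
        else:
            sub = flags[idx]
            sub[hazardous & (sub == FLAG_OK)] = FLAG_NONPOSITIVE
            flags[idx] = sub

    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = X * cf.rescale / C
    corrected[X == 0] = 0.0
    # non-positive or vanishing trend in faithful mode: no meaningful value
    corrected[~np.isfinite(corrected)] = 0.0
    corrected[corrected < 0] = 0.0

    n_flagged = int((flags != FLAG_OK).sum())
    if n_flagged:
        logger.info("apply_correction: %d flagged cells (guard=%s)", n_flagged, guard)
    return PeakMatrix(corrected, matrix.observations, matrix.features)


def correct(
    matrix: PeakMatrix, spec: TrendSpec, guard: str = "faithful"
) -> tuple[PeakMatrix, CorrectionFactors]:
    """Convenience composition: build factors, then apply them."""
    cf = build_correction_factors(matrix, spec)
    return apply_correction(matrix, cf, guard=guard), cf
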