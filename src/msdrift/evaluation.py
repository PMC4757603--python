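"""Performance metrics: replicate RSD and PCA-MANOVA.

Two complementary measures of how well a correction worked:

* the mean relative standard deviation (RSD) across biological replicate
  sets -- RSD = sigma / grand mean, where sigma is the sample standard
  deviation of a replicate set for one feature and the grand mean is the
  feature's mean over all experimental observations.  Lower is better; a
  correction that removes run-order drift should make replicates agree.
* PCA-MANOVA -- MANOVA applied to the first two principal-component
  scores of the autoscaled matrix, yielding an F statistic for the
  between-group to within-group variance ratio.  With an ideal correction
  the dominant grouping should be the experimental design, not the
  acquisition batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, ParameterError
from .peak_table import PeakMatrix

logger = logging.getLogger(__name__)

EXCLUDE_SET_TOO_SMALL = "set_too_small"
EXCLUDE_ZERO_IN_ORIGINAL = "zero_in_original"
EXCLUDE_ALL_ZERO_CORRECTED = "all_zero_corrected"
EXCLUDE_ZERO_GRAND_MEAN = "zero_grand_mean"


# ---------------------------------------------------------------------------
# Replicate RSD
# ---------------------------------------------------------------------------


@dataclass
class RsdReport:
    """Per (feature, replicate set) RSDs with exclusion flags."""

    entries: pd.DataFrame  # feature_id, replicate_set, sd, grand_mean, rsd, excluded
    mean_rsd: float  # unweighted mean over included entries (fraction)
    n_included: int
    n_excluded: int

    @property
    def mean_rsd_percent(self) -> float:
        return 100.0 * self.mean_rsd


def replicate_rsd(
    matrix: PeakMatrix,
    original: PeakMatrix | None = None,
    grand_mean: str = "experimental",
) -> RsdReport:
    """Mean RSD across biological replicate sets.

    For each feature and each replicate set of at least three members the
    RSD is the sample standard deviation (m-1 denominator) of the set's
    values divided by the grand mean.  ``grand_mean="experimental"`` (the
    default) uses the feature's mean over all experimental observations;
    ``"set"`` uses the set's own mean.

    Entries are excluded -- with exactly one reason each -- when the set
    has fewer than three members, when any of the set's values is zero in
    the *original* (pre-correction) data, when all of the set's values are
    zero in the evaluated matrix, or when the grand mean is zero.  Pass
    ``original`` when evaluating a corrected matrix so the zero-in-original
    rule sees pre-correction values; otherwise the matrix itself is used.
    """
    if grand_mean not in ("experimental", "set"):
        raise EvaluationError(f"unknown grand_mean mode {grand_mean!r}")
    obs = matrix.observations
    has_set = obs["replicate_set"].notna().to_numpy()
    if not has_set.any():
        raise EvaluationError("matrix carries no replicate_set labels")
    if original is None:
        original = matrix
    elif original.shape != matrix.shape:
        raise EvaluationError(
            f"original shape {original.shape} does not match matrix {matrix.shape}"
        )

    exp_mask = matrix.experimental_mask
    grand = matrix.intensities[exp_mask].mean(axis=0)  # per-feature

    feature_ids = matrix.feature_ids
    rows: list[dict] = []
    rsd_sum = 0.0
    n_inc = 0
    for rep_id, members in obs[has_set].groupby("replicate_set", observed=True):
        idx = members.index.to_numpy()
        k = len(idx)
        vals = matrix.intensities[idx]  # (k, n_features)
        if k < 3:
            for fid in feature_ids:
                rows.append(
                    {
                        "feature_id": fid,
                        "replicate_set": str(rep_id),
                        "sd": np.nan,
                        "grand_mean": np.nan,
                        "rsd": np.nan,
                        "excluded": EXCLUDE_SET_TOO_SMALL,
                    }
                )
            continue
        sd = vals.std(axis=0, ddof=1)
        gm = grand if grand_mean == "experimental" else vals.mean(axis=0)
        zero_orig = (original.intensities[idx] == 0).any(axis=0)
        all_zero = ~vals.any(axis=0)
        zero_gm = gm == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            rsd = sd / gm
        reason = np.full(len(feature_ids), "", dtype=object)
        reason[zero_gm] = EXCLUDE_ZERO_GRAND_MEAN
        reason[all_zero] = EXCLUDE_ALL_ZERO_CORRECTED
        reason[zero_orig] = EXCLUDE_ZERO_IN_ORIGINAL
        included = reason == ""
        rsd_sum += float(rsd[included].sum())
        n_inc += int(included.sum())
        rows.extend(
            {
                "feature_id": fid,
                "replicate_set": str(rep_id),
                "sd": float(s),
                "grand_mean": float(g),
                "rsd": float(r) if inc else np.nan,
                "excluded": rsn if rsn else None,
            }
            for fid, s, g, r, rsn, inc in zip(feature_ids, sd, gm, rsd, reason, included)
        )

    entries = pd.DataFrame(
        rows, columns=["feature_id", "replicate_set", "sd", "grand_mean", "rsd", "excluded"]
    )
    eligible_sets = (
        obs[has_set].groupby("replicate_set", observed=True).size() >= 3
    )
    if not eligible_sets.any():
        raise EvaluationError("no replicate set has at least three observations")
    if n_inc == 0:
        raise EvaluationError("every (feature, replicate set) entry was excluded")
    return RsdReport(
        entries=entries,
        mean_rsd=rsd_sum / n_inc,
        n_included=n_inc,
        n_excluded=int(len(entries) - n_inc),
    )


def qc_rsd(matrix: PeakMatrix) -> pd.Series:
    """Diagnostic: per-feature RSD (sd/mean, m-1 denominator) over the QCs."""
    qc = matrix.intensities[matrix.qc_mask]
    if qc.shape[0] < 2:
        raise EvaluationError("QC RSD needs at least two QC observations")
    mean = qc.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = qc.std(axis=0, ddof=1) / mean
    return pd.Series(out, index=matrix.feature_ids, name="qc_rsd")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(
    matrix: PeakMatrix | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and explained-variance fractions of the autoscaled matrix.

    Columns are mean-centred and scaled to unit variance (features with
    zero variance are dropped first, logged); the decomposition is by SVD.
    The sign of each component is fixed so that the largest-magnitude
    element of its loading vector is positive.
    """
    X = matrix.intensities if isinstance(matrix, PeakMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ParameterError("PCA needs at least 2 observations")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("pca_scores: dropped %d zero-variance features", int((~keep).sum()))
    if not keep.any():
        raise EvaluationError("all features have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rank = min(Z.shape[0] - 1, Z.shape[1])
    if n_components > rank:
        raise ParameterError(
            f"n_components={n_components} exceeds the matrix rank bound {rank}"
        )
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((S**2).sum())
    explained = S**2 / total
    scores = U * S
    for c in range(n_components):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
            Vt[c] = -Vt[c]
    return scores[:, :n_components], explained[:n_components]


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------


@dataclass
class PcaManovaReport:
    scores: np.ndarray
    explained_variance: np.ndarray
    f_stat: float
    p_value: float
    grouping: str
    df: tuple[float, float] = (np.nan, np.nan)
    wilks_lambda: float = np.nan
    group_sizes: dict = field(default_factory=dict)


def manova_f(scores: np.ndarray, labels) -> tuple[float, float]:
    """Wilks' lambda MANOVA on multivariate responses.

    Computes Wilks' Lambda = det(W) / det(W + B) from the within- and
    between-group SSCP matrices and converts it to an F statistic with
    Rao's approximation (exact for two groups or up to two response
    columns; for one response column this reduces to the classical one-way
    ANOVA F).  Returns (F, upper-tail p).
    """
    F, p, _, _, _ = _manova_full(scores, labels)
    return F, p


def _manova_full(scores: np.ndarray, labels):
    Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(labels)
    if len(labels) != len(Y):
        raise EvaluationError("labels length does not match score rows")
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    if g < 2:
        raise EvaluationError("MANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise EvaluationError(f"every group needs >= 2 observations; too small: {small}")
    n, p = Y.shape
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp, ng in zip(groups, counts):
        sub = Y[labels == grp]
        mu = sub.mean(axis=0)
        dev = sub - mu
        W += dev.T @ dev
        d = (mu - grand)[:, None]
        B += ng * (d @ d.T)
    det_w = np.linalg.det(W)
    det_t = np.linalg.det(W + B)
    if det_w <= 0 or det_t <= 0:
        raise EvaluationError(
            "singular within-group covariance; try fewer components or more data"
        )
    lam = det_w / det_t
    q = g - 1  # hypothesis df
    v = n - g  # error df
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        t = 1.0
    df1 = p * q
    df2 = t * (v - (p - q + 1) / 2) - (p * q - 2) / 2
    if df2 <= 0:
        raise EvaluationError("not enough observations for the F approximation")
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return float(F), pval, (float(df1), float(df2)), float(lam), dict(
        zip(map(str, groups), map(int, counts))
    )


def pca_manova(
    matrix: PeakMatrix,
    grouping: str = "group",
    groups_to_compare: list[str] | None = None,
    n_components: int = 2,
) -> PcaManovaReport:
    """PCA-MANOVA group-separation score.

    PCA is computed on the experimental observations (QCs carry no group
    and would only add dispersion), then MANOVA on the first
    ``n_components`` scores restricted to the named groups.
    ``grouping="group"`` tests experimental groups, ``grouping="batch"``
    tests acquisition batch (experimental observations only).
    """
    exp = matrix.select_observations(matrix.experimental_mask)
    if exp.n_observations < 3:
        raise EvaluationError("PCA-MANOVA needs at least 3 experimental observations")
    scores, explained = pca_scores(exp, n_components=n_components)
    if grouping == "group":
        labels = exp.observations["group"].to_numpy(dtype=object)
    elif grouping == "batch":
        labels = exp.observations["batch"].to_numpy()
    else:
        raise EvaluationError(f"unknown grouping {grouping!r}")
    valid = pd.notna(labels)
    if groups_to_compare is not None:
        wanted = set(map(str, groups_to_compare))
        valid &= np.array([str(l) in wanted for l in labels])
    if not valid.any():
        raise EvaluationError("no observations carry the requested labels")
    F, p, df, lam, sizes = _manova_full(scores[valid], labels[valid])
    name = grouping if groups_to_compare is None else "-".join(map(str, groups_to_compare))
    return PcaManovaReport(
        scores=scores,
        explained_variance=explained,
        f_stat=F,
        p_value=p,
        grouping=name,
        df=df,
        wilks_lambda=lam,
        group_sizes=sizes,
    )
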