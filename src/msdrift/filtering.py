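"""Variable-removal rules applied before trend estimation.

Features for which no accurate trend can be estimated are removed up front:
under the QC policy, features whose median over the QC injections is zero
(i.e. half or more of the QCs failed to record a value); under the overall
policy -- appropriate for background correction, where the trend is fitted
to all observations -- features whose median over *all* observations
(including QCs) is zero.  The "working set" additionally drops explicitly
named outlier observations before filtering.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .peak_table import ROLE_QC, PeakMatrix

logger = logging.getLogger(__name__)

FilterPolicy = Literal["qc_median_nonzero", "overall_median_nonzero"]


def filter_features(
    matrix: PeakMatrix, policy: FilterPolicy
) -> tuple[PeakMatrix, dict]:
    """Drop features whose median intensity is zero under ``policy``.

    ``qc_median_nonzero`` computes the median over QC observations only;
    ``overall_median_nonzero`` over all observations.  The median uses the
    midpoint convention for even counts, so a feature with exactly half its
    values zero has median a/2 > 0 and is retained (these borderline
    features are logged).

    Returns the filtered matrix (input unmodified) and a removal report
    ``{policy, dropped_features, n_dropped, n_retained, borderline_features}``.
    """
    if policy == "qc_median_nonzero":
        mask = matrix.qc_mask
        if not mask.any():
            raise ConfigurationError(
                "qc_median_nonzero policy requires at least one QC observation"
            )
        values = matrix.intensities[mask]
    elif policy == "overall_median_nonzero":
        values = matrix.intensities
    else:
        raise ConfigurationError(f"unknown filter policy {policy!r}")

    medians = np.median(values, axis=0)
    keep = medians > 0

    # even count with exactly half zeros: median = a/2 > 0, kept by convention
    n = values.shape[0]
    if n % 2 == 0:
        n_zero = (values == 0).sum(axis=0)
        borderline = np.flatnonzero(keep & (n_zero == n // 2))
    else:
        borderline = np.array([], dtype=int)
    if len(borderline):
        logger.info(
            "filter_features(%s): %d borderline features (exactly half zeros) retained",
            policy,
            len(borderline),
        )

    report = {
        "policy": policy,
        "dropped_features": [str(f) for f in matrix.feature_ids[~keep]],
        "dropped_observations": [],
        "n_dropped": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "borderline_features": [str(f) for f in matrix.feature_ids[borderline]],
    }
    return matrix.select_features(keep), report


def working_set(
    matrix: PeakMatrix,
    policy: FilterPolicy = "overall_median_nonzero",
    drop_observations: Iterable[str] = (),
) -> tuple[PeakMatrix, dict]:
    """Baseline matrix for evaluation: manual outlier removal + feature filter.

    ``drop_observations`` names sample_ids to remove (outliers identified by
    inspection) before :func:`filter_features` is applied with ``policy``.
    """
    drop = [str(s) for s in drop_observations]
    if drop:
        known = set(matrix.sample_ids)
        unknown = [s for s in drop if s not in known]
        if unknown:
            raise ConsistencyError(f"unknown sample_id(s) to drop: {unknown}")
        keep_mask = ~np.isin(matrix.sample_ids, drop)
        matrix = matrix.select_observations(keep_mask)
    filtered, report = filter_features(matrix, policy)
    report["dropped_observations"] = drop
    return filtered, report
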