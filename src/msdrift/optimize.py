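"""Grid search of smoother parameters against mean replicate RSD.

The tunable parameter of a trend method (moving-median window w,
polynomial degree n, LOESS neighbourhood alpha) is chosen to minimize the
mean RSD of biological replicates after correction.  The spline penalty
lambda is not searched here: it is selected inside the spline fit by
generalized cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .correction import correct
from .errors import ConfigurationError, MsDriftError, OptimizationError
from .evaluation import replicate_rsd
from .peak_table import PeakMatrix
from .trends import TrendSpec

#: Default parameter grids per trend method.
DEFAULT_GRIDS = {
    "moving_median": list(range(1, 16)),
    "polynomial": list(range(1, 9)),
    "loess": [round(0.05 * k, 2) for k in range(1, 21)],
}


@dataclass
class OptimizeResult:
    best_value: object
    best_spec: TrendSpec
    table: pd.DataFrame  # columns: value, mean_rsd_percent, error


def grid_optimize(
    matrix: PeakMatrix,
    spec_template: TrendSpec,
    grid: Sequence | None = None,
    guard: str = "faithful",
) -> OptimizeResult:
    """Evaluate every grid value of the template's tunable parameter.

    For each candidate value the full pipeline -- build factors, apply the
    correction, compute the mean replicate RSD against the uncorrected
    matrix -- is run, and the argmin is returned together with the full
    (value, mean RSD) table.  Candidates that fail estimation are recorded
    with their error and excluded from the argmin.  Ties (equal mean RSD
    to 1e-12) break towards the smoother model: smaller w or n, larger
    alpha.  The whole search is deterministic given the matrix and grid.
    """
    name = spec_template.parameter_name
    if name is None:
        raise ConfigurationError(
            f"method {spec_template.method!r} has no tunable parameter to optimize"
        )
    if grid is None:
        grid = DEFAULT_GRIDS.get(spec_template.method)
        if grid is None:
            raise ConfigurationError(
                f"no default grid for method {spec_template.method!r}; pass one"
            )
    grid = list(grid)
    if not grid:
        raise ConfigurationError("parameter grid is empty")

    rows = []
    for value in grid:
        try:
            spec = spec_template.with_parameter(value)
            corrected, _ = correct(matrix, spec, guard=guard)
            report = replicate_rsd(corrected, original=matrix)
            rows.append({"value": value, "mean_rsd_percent": report.mean_rsd_percent,
                         "error": None})
        except MsDriftError as exc:
            rows.append({"value": value, "mean_rsd_percent": np.nan,
                         "error": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows, columns=["value", "mean_rsd_percent", "error"])
    ok = table[table["error"].isna()]
    if ok.empty:
        raise OptimizationError(
            "every grid candidate failed: "
            + "; ".join(f"{r.value}: {r.error}" for r in table.itertuples())
        )
    best_rsd = ok["mean_rsd_percent"].min()
    tied = ok[ok["mean_rsd_percent"] <= best_rsd + 1e-12]
    # tie-break: prefer the smoother fit
    if name == "alpha":
        best_value = tied["value"].max()
    else:
        best_value = tied["value"].min()
    if name in ("w", "n"):
        best_value = int(best_value)
    return OptimizeResult(
        best_value=best_value,
        best_spec=spec_template.with_parameter(best_value),
        table=table,
    )
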