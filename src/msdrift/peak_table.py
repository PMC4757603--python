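"""Ordered peak-intensity matrices with observation and feature metadata.

The central container is :class:`PeakMatrix`: a non-negative intensity grid
(observations in acquisition order x detected features) together with
per-observation metadata (run index, batch, role, experimental group,
replicate set) and per-feature metadata (m/z, retention time).  Zero
intensity encodes "not detected".  Every downstream stage (filtering, trend
estimation, correction, evaluation) consumes and produces this object.

I/O uses a two-file delimited-text layout -- a purely numeric intensity
table plus a metadata table -- with a single-file mode (reserved metadata
column names mixed into one table) accepted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

ROLE_QC = "QC"
ROLE_EXPERIMENTAL = "experimental"
ROLE_CONDITIONING = "conditioning"
VALID_ROLES = (ROLE_QC, ROLE_EXPERIMENTAL, ROLE_CONDITIONING)

#: Observation-metadata columns.  ``sample_id`` .. ``role`` are required.
OBS_COLUMNS = (
    "sample_id",
    "run_index",
    "batch",
    "role",
    "group",
    "replicate_set",
    "timepoint",
)
REQUIRED_OBS_COLUMNS = OBS_COLUMNS[:4]

FEATURE_COLUMNS = ("feature_id", "mz", "rt")

# Advisory annotation ranges; violations warn but never reject.
MZ_BOUNDS = (80.0, 1000.0)
RT_BOUNDS = (1.0, 30.0)


def _normalise_observations(obs: pd.DataFrame) -> pd.DataFrame:
    obs = obs.copy()
    for col in ("group", "replicate_set", "timepoint"):
        if col not in obs.columns:
            obs[col] = pd.NA
    obs["sample_id"] = obs["sample_id"].astype(str)
    obs["run_index"] = obs["run_index"].astype(int)
    obs["batch"] = obs["batch"].astype(int)
    obs["role"] = obs["role"].astype(str)
    obs["group"] = obs["group"].astype("string")
    obs["replicate_set"] = obs["replicate_set"].astype("string")
    obs["timepoint"] = obs["timepoint"].astype("Int64")
    return obs[list(OBS_COLUMNS)]


def _normalise_features(feats: pd.DataFrame) -> pd.DataFrame:
    feats = feats.copy()
    for col in ("mz", "rt"):
        if col not in feats.columns:
            feats[col] = np.nan
    feats["feature_id"] = feats["feature_id"].astype(str)
    feats["mz"] = feats["mz"].astype(float)
    feats["rt"] = feats["rt"].astype(float)
    return feats[list(FEATURE_COLUMNS)]


@dataclass
class PeakMatrix:
    """An acquisition-ordered intensity matrix with linked metadata.

    Parameters
    ----------
    intensities : ndarray, shape (n_observations, n_features)
        Non-negative, finite intensities; 0 means not detected.
    observations : DataFrame
        One row per observation with columns ``sample_id``, ``run_index``,
        ``batch``, ``role`` and optionally ``group``, ``replicate_set``,
        ``timepoint``.  Rows are sorted by ``run_index`` on construction.
    features : DataFrame
        One row per feature with columns ``feature_id`` and optionally
        ``mz``, ``rt``.
    """

    intensities: np.ndarray
    observations: pd.DataFrame
    features: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise FormatError("intensities must be a 2-D grid")
        obs = _normalise_observations(pd.DataFrame(self.observations))
        if self.features is None:
            self.features = pd.DataFrame(
                {"feature_id": [f"F{j + 1}" for j in range(self.intensities.shape[1])]}
            )
        feats = _normalise_features(pd.DataFrame(self.features))
        if self.intensities.shape != (len(obs), len(feats)):
            raise FormatError(
                f"intensity grid {self.intensities.shape} does not match "
                f"{len(obs)} observations x {len(feats)} features"
            )
        self._validate_values()
        self._validate_observations(obs)
        self._validate_features(feats)
        order = np.argsort(obs["run_index"].to_numpy(), kind="stable")
        self.observations = obs.iloc[order].reset_index(drop=True)
        self.intensities = self.intensities[order]
        self.features = feats.reset_index(drop=True)

    # -- validation -------------------------------------------------------

    def _validate_values(self) -> None:
        if not np.all(np.isfinite(self.intensities)):
            i, j = np.argwhere(~np.isfinite(self.intensities))[0]
            raise FormatError(f"non-finite intensity at observation {i}, feature {j}")
        if np.any(self.intensities < 0):
            i, j = np.argwhere(self.intensities < 0)[0]
            raise FormatError(f"negative intensity at observation {i}, feature {j}")

    def _validate_observations(self, obs: pd.DataFrame) -> None:
        if obs["sample_id"].duplicated().any():
            dupes = obs.loc[obs["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConsistencyError(f"duplicate sample_id values: {dupes}")
        if obs["run_index"].duplicated().any():
            dupes = obs.loc[obs["run_index"].duplicated(), "run_index"].tolist()
            raise ConsistencyError(f"duplicate run_index values: {dupes}")
        bad_roles = sorted(set(obs["role"]) - set(VALID_ROLES))
        if bad_roles:
            raise FormatError(
                f"unknown role values {bad_roles}; expected one of {VALID_ROLES}"
            )
        qc_with_set = obs[(obs["role"] != ROLE_EXPERIMENTAL) & obs["replicate_set"].notna()]
        if len(qc_with_set):
            raise ConsistencyError(
                "replicate_set assigned to non-experimental observations: "
                f"{qc_with_set['sample_id'].tolist()}"
            )
        has_set = obs[obs["replicate_set"].notna()]
        for rep_id, members in has_set.groupby("replicate_set"):
            if members["group"].nunique(dropna=False) > 1:
                raise ConsistencyError(f"replicate_set {rep_id!r} spans multiple groups")
            if members["timepoint"].nunique(dropna=False) > 1:
                raise ConsistencyError(f"replicate_set {rep_id!r} spans multiple timepoints")

    def _validate_features(self, feats: pd.DataFrame) -> None:
        if feats["feature_id"].duplicated().any():
            dupes = feats.loc[feats["feature_id"].duplicated(), "feature_id"].tolist()
            raise ConsistencyError(f"duplicate feature_id values: {dupes}")
        mz = feats["mz"].dropna()
        out_mz = mz[(mz < MZ_BOUNDS[0]) | (mz > MZ_BOUNDS[1])]
        if len(out_mz):
            warnings.warn(
                f"{len(out_mz)} features outside advisory m/z range {MZ_BOUNDS}",
                stacklevel=3,
            )
        rt = feats["rt"].dropna()
        out_rt = rt[(rt < RT_BOUNDS[0]) | (rt > RT_BOUNDS[1])]
        if len(out_rt):
            warnings.warn(
                f"{len(out_rt)} features outside advisory RT range {RT_BOUNDS} min",
                stacklevel=3,
            )

    # -- convenience accessors -------------------------------------------

    @property
    def n_observations(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def sample_ids(self) -> np.ndarray:
        return self.observations["sample_id"].to_numpy()

    @property
    def feature_ids(self) -> np.ndarray:
        return self.features["feature_id"].to_numpy()

    @property
    def batches(self) -> list[int]:
        """Distinct batch labels in acquisition order."""
        seen: dict[int, None] = {}
        for b in self.observations["batch"]:
            seen.setdefault(int(b), None)
        return list(seen)

    def role_mask(self, role: str) -> np.ndarray:
        return (self.observations["role"] == role).to_numpy()

    @property
    def qc_mask(self) -> np.ndarray:
        return self.role_mask(ROLE_QC)

    @property
    def experimental_mask(self) -> np.ndarray:
        return self.role_mask(ROLE_EXPERIMENTAL)

    def batch_mask(self, batch: int) -> np.ndarray:
        return (self.observations["batch"] == batch).to_numpy()

    def select_observations(self, mask: np.ndarray) -> "PeakMatrix":
        """Row subset as a new PeakMatrix (order preserved)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return PeakMatrix(
            self.intensities[idx],
            self.observations.iloc[idx],
            self.features,
        )

    def select_features(self, mask: np.ndarray) -> "PeakMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return PeakMatrix(
            self.intensities[:, idx],
            self.observations,
            self.features.iloc[idx],
        )

    def drop_conditioning(self) -> "PeakMatrix":
        """Remove column-conditioning injections (excluded from analysis)."""
        mask = ~self.role_mask(ROLE_CONDITIONING)
        if mask.all():
            return self
        return self.select_observations(mask)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            self.intensities.copy(), self.observations.copy(), self.features.copy()
        )

    def equals(self, other: "PeakMatrix") -> bool:
        return (
            np.array_equal(self.intensities, other.intensities)
            and self.observations.equals(other.observations)
            and self.features.equals(other.features)
        )


# -- I/O -----------------------------------------------------------------


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_peak_table(
    intensity_path: str | Path, metadata_path: str | Path | None = None
) -> PeakMatrix:
    """Load a PeakMatrix from delimited text.

    ``intensity_path`` holds ``sample_id`` in the first column and one
    column per feature.  ``metadata_path`` holds the observation metadata.
    If ``metadata_path`` is None, a single-file layout is assumed where the
    reserved metadata column names are mixed into the intensity table.

    Empty intensity cells are read as 0 (logged); negative or unparseable
    cells raise :class:`FormatError`.  Observations are returned sorted by
    ``run_index``; feature order is preserved as on disk.
    """
    intensity_path = Path(intensity_path)
    # round_trip parsing: written decimal text must reproduce exact doubles
    table = pd.read_csv(
        intensity_path, sep=_delimiter_for(intensity_path), float_precision="round_trip"
    )
    if "sample_id" not in table.columns:
        raise FormatError(
            f"{intensity_path}: first column must be 'sample_id' "
            f"(got {table.columns[0]!r})"
        )

    if metadata_path is None:
        meta_cols = [c for c in OBS_COLUMNS if c in table.columns]
        missing = [c for c in REQUIRED_OBS_COLUMNS if c not in meta_cols]
        if missing:
            raise FormatError(
                f"{intensity_path}: single-file layout missing metadata "
                f"column(s) {missing}"
            )
        meta = table[meta_cols]
        grid = table.drop(columns=meta_cols)
    else:
        metadata_path = Path(metadata_path)
        meta = pd.read_csv(metadata_path, sep=_delimiter_for(metadata_path))
        missing = [c for c in REQUIRED_OBS_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"{metadata_path}: missing metadata column(s) {missing}")
        grid = table.drop(columns=["sample_id"])
        int_ids = set(table["sample_id"].astype(str))
        meta_ids = set(meta["sample_id"].astype(str))
        if int_ids != meta_ids:
            only_int = sorted(int_ids - meta_ids)
            only_meta = sorted(meta_ids - int_ids)
            raise ConsistencyError(
                "sample_id mismatch between intensity and metadata files: "
                f"only in intensities {only_int}, only in metadata {only_meta}"
            )
        # align metadata rows to the intensity file's row order
        meta = (
            meta.assign(sample_id=meta["sample_id"].astype(str))
            .set_index("sample_id")
            .loc[table["sample_id"].astype(str)]
            .reset_index()
        )

    n_empty = int(grid.isna().sum().sum())
    if n_empty:
        logger.info("read_peak_table: %d empty cells read as 0", n_empty)
        grid = grid.fillna(0.0)
    try:
        values = grid.to_numpy(dtype=float)
    except ValueError as exc:
        for col in grid.columns:
            bad = pd.to_numeric(grid[col], errors="coerce").isna() & grid[col].notna()
            if bad.any():
                row = table.loc[bad.idxmax(), "sample_id"]
                raise FormatError(
                    f"unparseable intensity in column {col!r}, sample {row!r}"
                ) from exc
        raise FormatError(str(exc)) from exc
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative intensity in column {grid.columns[j]!r}, "
            f"sample {table['sample_id'].iloc[i]!r}"
        )

    features = pd.DataFrame({"feature_id": [str(c) for c in grid.columns]})
    return PeakMatrix(values, meta, features)


def write_peak_table(matrix: PeakMatrix, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the two-file layout; inverse of :func:`read_peak_table`.

    Values are written as shortest round-tripping decimal text, so a
    read-back reproduces the matrix bit-for-bit.  Returns the intensity and
    metadata paths (``<prefix>_intensities.csv``, ``<prefix>_metadata.csv``).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    int_path = out_prefix.with_name(out_prefix.name + "_intensities.csv")
    meta_path = out_prefix.with_name(out_prefix.name + "_metadata.csv")

    grid = pd.DataFrame(matrix.intensities, columns=matrix.feature_ids)
    grid.insert(0, "sample_id", matrix.sample_ids)
    grid.to_csv(int_path, index=False)
    matrix.observations.to_csv(meta_path, index=False)
    return int_path, meta_path


def validate_layout(matrix: PeakMatrix) -> dict:
    """Advisory report on the acquisition layout (never mutates).

    Lists per-batch QC/experimental counts, the maximal gap (in consecutive
    acquisitions) between QC injections within each batch, batches with no
    QCs, and replicate sets with fewer than three members (ineligible for
    replicate-RSD evaluation).
    """
    obs = matrix.observations
    report: dict = {"batches": [], "ineligible_replicate_sets": [], "warnings": []}
    for b in matrix.batches:
        sub = obs[obs["batch"] == b].reset_index(drop=True)
        roles = sub["role"]
        qc_positions = np.flatnonzero((roles == ROLE_QC).to_numpy())
        n_qc = len(qc_positions)
        n_exp = int((roles == ROLE_EXPERIMENTAL).sum())
        if n_qc == 0:
            max_gap = None
            report["warnings"].append(f"no QCs in batch {b}")
        else:
            # gaps: runs of non-QC observations before/ between/ after QCs
            edges = np.concatenate(([-1], qc_positions, [len(sub)]))
            max_gap = int(np.max(np.diff(edges) - 1))
        report["batches"].append(
            {"batch": int(b), "n_qc": n_qc, "n_experimental": n_exp, "max_qc_gap": max_gap}
        )
    has_set = obs[obs["replicate_set"].notna()]
    for rep_id, members in has_set.groupby("replicate_set"):
        if len(members) < 3:
            report["ineligible_replicate_sets"].append(
                {"replicate_set": str(rep_id), "size": int(len(members))}
            )
    return report
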