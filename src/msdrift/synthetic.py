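"""Synthetic LC-MS run generator with stored ground truth.

Emulates the statistical structure of a multi-batch non-targeted LC-MS
acquisition: several batches with multiplicative between-batch offsets,
nonlinear within-batch signal drift over acquisition order, QC injections
interspersed every few experimental samples, biological replicate sets
randomized across batches, QC levels that diverge from sample levels
(pooled reference material differs from the experimental extracts), QCs
that follow the sample drift only partially, and zero values where the
intensity falls below the limit of detection.

All noise and drift are multiplicative (log-normal): the ratio correction
X' = X * R / C can then remove drift exactly, which makes perfect-recovery
tests possible.  Every stochastic draw flows from a single master seed
through named :class:`numpy.random.SeedSequence` substreams (features,
batch offsets, per-batch drift, replicate assignment, noise), so the same
seed always reproduces the same dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .peak_table import ROLE_CONDITIONING, ROLE_EXPERIMENTAL, ROLE_QC, PeakMatrix

DRIFT_KINDS = ("none", "linear", "smooth", "changepoint")


@dataclass(frozen=True)
class SimConfig:
    """Generative settings; defaults mirror a 7-batch plant-extract run.

    Intensities are baseline x group effect x biological noise x batch
    offset x drift x measurement noise, all factors multiplicative.  QCs
    replace the group/biological terms by a per-feature QC bias and follow
    the batch drift raised to ``qc_drift_attenuation`` (1 = QCs track the
    samples fully, 0 = not at all).  Values below ``lod_threshold`` are
    recorded as 0.
    """

    n_batches: int = 7
    samples_per_batch: int = 24
    qc_every: int = 6  # a QC after every full block of this many samples
    n_features: int = 300
    group_labels: tuple[str, ...] = ("C", "D", "F", "B")
    replicate_size: int = 3
    baseline_log_mean: float = math.log(1e5)
    baseline_log_sd: float = 1.5
    fraction_affected: float = 0.2  # features carrying group differences
    effect_size: float = 0.5  # log-fold sd of group effects
    batch_offset_sd: float = 0.3  # log-sd of per-batch per-feature offsets
    drift_kinds: tuple[str, ...] = ("smooth",)  # cycled over batches
    drift_amplitude: float = 0.4  # fraction of baseline
    qc_bias_sd: float = 0.3  # log-sd of QC level vs sample level
    qc_drift_attenuation: float = 1.0
    biological_sd: float = 0.1  # log-sd between biological replicates
    noise_sd: float = 0.05  # measurement log-sd (experimental samples)
    qc_noise_sd: float | None = None  # measurement log-sd of QCs (default noise_sd)
    lod_threshold: float = 1000.0
    conditioning_block: int = 0  # column-conditioning injections before batch 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_log_sd", "batch_offset_sd", "qc_bias_sd",
                     "biological_sd", "noise_sd", "effect_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.qc_noise_sd is not None and self.qc_noise_sd < 0:
            raise ConfigurationError("qc_noise_sd must be >= 0")
        if self.qc_every < 1:
            raise ConfigurationError("qc_every must be >= 1")
        if not 0 <= self.qc_drift_attenuation <= 1:
            raise ConfigurationError("qc_drift_attenuation must be in [0, 1]")
        if not 0 <= self.fraction_affected <= 1:
            raise ConfigurationError("fraction_affected must be in [0, 1]")
        if self.n_batches < 1 or self.samples_per_batch < 1 or self.n_features < 1:
            raise ConfigurationError("n_batches, samples_per_batch, n_features must be >= 1")
        if self.replicate_size < 1:
            raise ConfigurationError("replicate_size must be >= 1")
        if self.lod_threshold < 0:
            raise ConfigurationError("lod_threshold must be >= 0")
        for kind in self.drift_kinds:
            if kind not in DRIFT_KINDS:
                raise ConfigurationError(
                    f"unknown drift kind {kind!r}; expected one of {DRIFT_KINDS}"
                )

    @property
    def effective_qc_noise_sd(self) -> float:
        return self.noise_sd if self.qc_noise_sd is None else self.qc_noise_sd

    def to_mapping(self) -> dict:
        out = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        kwargs = dict(mapping)
        for key in ("group_labels", "drift_kinds"):
            if key in kwargs and not isinstance(kwargs[key], tuple):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def qc_divergent_config(seed: int = 0, **overrides) -> SimConfig:
    """The QC-divergent scenario: the regime where QC-only correction fails.

    Within-batch drift mixes abrupt level shifts with smooth wander, the
    QCs follow only a fifth of the sample drift, sit at a different level
    per feature, and are noisy enough that a per-batch line through them is
    unreliable -- the conditions under which background (all-observation)
    correction outperforms QC-only correction.
    """
    base = dict(
        qc_drift_attenuation=0.2,
        drift_kinds=("changepoint", "smooth"),
        drift_amplitude=0.5,
        qc_bias_sd=0.3,
        qc_noise_sd=0.45,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SyntheticTruth:
    """Generative ground truth emitted alongside the observed matrix."""

    drift: dict  # batch label -> per-position multiplier
    batch_offsets: np.ndarray  # (n_batches, n_features)
    group_effects: np.ndarray  # (n_features, n_groups) log-fold, group 0 = reference
    qc_bias: np.ndarray  # (n_features,) multiplier
    clean_matrix: np.ndarray  # drift-, offset- and noise-free intensities
    config: SimConfig


# ---------------------------------------------------------------------------
# Drift curves
# ---------------------------------------------------------------------------


def drift_curve(
    kind: str, length: int, amplitude: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Positive multiplier sequence of the requested drift shape.

    ``none``: all ones.  ``linear``: 1 + amplitude*(t - midpoint)/length.
    ``smooth``: exp of a smoothed random walk rescaled to +-amplitude.
    ``changepoint``: a level shift of +-amplitude at a random interior
    position.  Raises if any multiplier would be <= 0.
    """
    if length < 1:
        raise ConfigurationError("drift length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "none":
        return np.ones(length)
    if kind == "linear":
        t = np.arange(1, length + 1, dtype=float)
        curve = 1.0 + amplitude * (t - (length + 1) / 2) / length
    elif kind == "smooth":
        walk = np.cumsum(rng.normal(size=length))
        win = max(3, length // 5)
        kernel = np.ones(win) / win
        smoothed = np.convolve(walk, kernel, mode="same")
        smoothed -= smoothed.mean()
        peak = np.abs(smoothed).max()
        if peak > 0:
            smoothed *= amplitude / peak
        curve = np.exp(smoothed)
    elif kind == "changepoint":
        curve = np.ones(length)
        if length > 1:
            pos = int(rng.integers(1, length))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            curve[pos:] = 1.0 + sign * amplitude
    else:
        raise ConfigurationError(f"unknown drift kind {kind!r}")
    if np.any(curve <= 0):
        raise ConfigurationError(
            f"drift kind {kind!r} with amplitude {amplitude} produces non-positive multipliers"
        )
    return curve


def apply_lod(values: np.ndarray, lod_threshold: float) -> np.ndarray:
    """Censor values below the limit of detection to 0."""
    if lod_threshold < 0:
        raise ConfigurationError("lod_threshold must be >= 0")
    values = np.asarray(values, dtype=float)
    return np.where(values < lod_threshold, 0.0, values)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _batch_layout(cfg: SimConfig) -> list[str]:
    """Within-batch role sequence: qc_every samples, then a QC, repeated."""
    roles: list[str] = []
    placed = 0
    while placed < cfg.samples_per_batch:
        block = min(cfg.qc_every, cfg.samples_per_batch - placed)
        roles.extend([ROLE_EXPERIMENTAL] * block)
        placed += block
        if block == cfg.qc_every:
            roles.append(ROLE_QC)
    return roles


def simulate_dataset(config: SimConfig) -> tuple[PeakMatrix, SyntheticTruth]:
    """Generate an observed PeakMatrix plus its generative ground truth.

    Deterministic for a given ``config.seed``.  Replicate sets of
    ``replicate_size`` are assigned to random acquisition slots across all
    batches (as a randomized design would), cycling through the group
    labels; leftover samples (when the total is not divisible) carry no
    replicate set.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_feat, s_off, s_drift, s_assign, s_noise = ss.spawn(5)
    rng_feat = np.random.default_rng(s_feat)
    rng_off = np.random.default_rng(s_off)
    rng_assign = np.random.default_rng(s_assign)
    rng_noise = np.random.default_rng(s_noise)
    drift_seeds = s_drift.spawn(cfg.n_batches)

    P = cfg.n_features
    G = len(cfg.group_labels)

    baselines = np.exp(rng_feat.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, P))
    affected = rng_feat.random(P) < cfg.fraction_affected
    group_effects = np.zeros((P, G))
    if G > 1:
        draws = rng_feat.normal(0.0, cfg.effect_size, (P, G - 1))
        group_effects[:, 1:] = np.where(affected[:, None], draws, 0.0)
    qc_bias = np.exp(rng_feat.normal(0.0, cfg.qc_bias_sd, P))
    batch_offsets = np.exp(rng_off.normal(0.0, cfg.batch_offset_sd, (cfg.n_batches, P)))

    # replicate-set assignment over all experimental slots
    n_exp = cfg.n_batches * cfg.samples_per_batch
    n_sets = n_exp // cfg.replicate_size
    slot_group = np.full(n_exp, -1)
    slot_set = np.full(n_exp, -1)
    slot_time = np.full(n_exp, -1)
    perm = rng_assign.permutation(n_exp)
    for k in range(n_sets):
        slots = perm[k * cfg.replicate_size : (k + 1) * cfg.replicate_size]
        slot_set[slots] = k
        slot_group[slots] = k % G
        slot_time[slots] = k // G + 1
    leftover = perm[n_sets * cfg.replicate_size :]
    slot_group[leftover] = np.arange(len(leftover)) % G  # group but no set

    layout = _batch_layout(cfg)
    rows: list[dict] = []
    obs_values: list[np.ndarray] = []
    clean_rows: list[np.ndarray] = []
    drift: dict[int, np.ndarray] = {}

    run_index = 0
    for _ in range(cfg.conditioning_block):
        run_index += 1
        rows.append(
            dict(sample_id=f"COND{run_index}", run_index=run_index, batch=1,
                 role=ROLE_CONDITIONING, group=None, replicate_set=None, timepoint=None)
        )
        noise = np.exp(rng_noise.normal(0.0, cfg.effective_qc_noise_sd, P))
        obs_values.append(baselines * qc_bias * noise)
        clean_rows.append(baselines * qc_bias)

    exp_counter = 0
    for b in range(cfg.n_batches):
        batch_label = b + 1
        curve = drift_curve(
            cfg.drift_kinds[b % len(cfg.drift_kinds)],
            len(layout),
            cfg.drift_amplitude,
            np.random.default_rng(drift_seeds[b]),
        )
        drift[batch_label] = curve
        n_qc = 0
        for pos, role in enumerate(layout):
            run_index += 1
            if role == ROLE_QC:
                n_qc += 1
                noise = np.exp(rng_noise.normal(0.0, cfg.effective_qc_noise_sd, P))
                value = (
                    baselines
                    * qc_bias
                    * batch_offsets[b]
                    * curve[pos] ** cfg.qc_drift_attenuation
                    * noise
                )
                rows.append(
                    dict(sample_id=f"B{batch_label}_QC{n_qc}", run_index=run_index,
                         batch=batch_label, role=ROLE_QC, group=None,
                         replicate_set=None, timepoint=None)
                )
                clean_rows.append(baselines * qc_bias)
            else:
                slot = exp_counter
                exp_counter += 1
                g = int(slot_group[slot])
                geff = np.exp(group_effects[:, g])
                bio = np.exp(rng_noise.normal(0.0, cfg.biological_sd, P))
                noise = np.exp(rng_noise.normal(0.0, cfg.noise_sd, P))
                value = (
                    baselines * geff * bio * batch_offsets[b] * curve[pos] * noise
                )
                rep = slot_set[slot]
                rows.append(
                    dict(sample_id=f"B{batch_label}_S{slot + 1}", run_index=run_index,
                         batch=batch_label, role=ROLE_EXPERIMENTAL,
                         group=cfg.group_labels[g],
                         replicate_set=(f"R{rep + 1}" if rep >= 0 else None),
                         timepoint=(int(slot_time[slot]) if rep >= 0 else None))
                )
                clean_rows.append(baselines * geff)
            obs_values.append(value)

    intensities = apply_lod(np.vstack(obs_values), cfg.lod_threshold)
    observations = pd.DataFrame(rows)
    features = pd.DataFrame({"feature_id": [f"F{j + 1}" for j in range(P)]})
    matrix = PeakMatrix(intensities, observations, features)
    truth = SyntheticTruth(
        drift=drift,
        batch_offsets=batch_offsets,
        group_effects=group_effects,
        qc_bias=qc_bias,
        clean_matrix=np.vstack(clean_rows),
        config=cfg,
    )
    return matrix, truth
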