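# msdrift

Batch and run-order drift correction for LC–MS peak-intensity matrices,
including QC-free ("background") correction, with built-in evaluation and
a synthetic drift simulator.

## The problem

Non-targeted LC–MS metabolomics runs are acquired in batches separated by
instrument cleaning and calibration. Recorded intensities drift within a
batch (column contamination, detector response) and jump between batches,
often dominating the biological signal. The standard remedy divides every
intensity by a trend fitted to interspersed pooled-QC injections
(QC-RLSC-style correction). But when the QC material responds differently
from the experimental samples, when drift changes abruptly between QC
injections, or when the few QCs per batch are noisy, QC-based correction
can *inject* artefacts — a per-batch linear regression of noisy QCs can
divide samples by near-zero trend values and blow the data up.

`msdrift` implements both families and the machinery to compare them:

* **Correction model.** For peak *p*, batch *b*, acquisition rank *i*:

  ```
  X'_{p,b,i} = X_{p,b,i} · R_p / C_{p,b,i}
  ```

  where the trend *C* is fitted over acquisition rank by one of: constant
  (mean/median, i.e. C = A_{p,b}), per-batch linear regression
  (C = β_b·i + α_b), moving median of half-width *w*, degree-*n*
  polynomial, penalized cubic smoothing spline (penalty λ, or chosen by
  generalized cross-validation), or tricube-weighted local linear
  regression (LOESS, span α). The rescaling factor R_p restores an
  interpretable intensity scale (first-batch average, all-batch average,
  or 1).
* **Fit scope.** `qc_only` fits the trend to the QC injections;
  `background` fits it to *all* observations (QCs included) — the QC-free
  alternative. Either can be applied per batch (`batchwise`) or to the
  whole run (`global`).
* **Evaluation.** Mean relative standard deviation of biological
  replicate sets (RSD = σ / grand mean, sets of ≥ 3, zero-value
  exclusions), and PCA-MANOVA: Wilks' Λ MANOVA on the first two
  principal-component scores of the autoscaled matrix, giving an F
  statistic for batch separation versus experimental-group separation.
* **Optimization.** Grid search of *w*, *n* or α against mean replicate
  RSD.
* **Simulation.** A generator for multi-batch runs with between-batch
  offsets, nonlinear within-batch drift, QC bias and attenuated QC drift,
  limit-of-detection zeros, and stored ground truth.

## Worked example

Simulate a QC-divergent run (7 batches × 24 samples, QC every 6, 300
features; QCs follow only 20 % of the sample drift), build the working
set, correct with the batch-wise background smoothing spline, and
evaluate:

```
msdrift simulate --seed 2 --scenario qc_divergent --out demo
msdrift filter   --intensities demo_intensities.csv --metadata demo_metadata.csv --out ws
msdrift correct  --intensities ws_intensities.csv --metadata ws_metadata.csv \
                 --trend spline --scope background --per-batch --out corr
msdrift evaluate --intensities corr_intensities.csv --metadata corr_metadata.csv \
                 --original-intensities ws_intensities.csv \
                 --original-metadata ws_metadata.csv --groups C,D --out eval.json
```

prints `mean RSD 12.88 %` and writes

```json
{
  "mean_rsd_percent": 12.884441020606143,
  "n_included_entries": 16797,
  "pca_manova": [
    {"groups": "C-D",   "F": 4.346978982269708, "p": 0.01609659883672694},
    {"groups": "batch", "F": 0.861345966860926, "p": 0.586974231699043}
  ]
}
```

The uncorrected working set on the same run has mean RSD 37.42 % and a
batch F of 94.0 (p ≈ 4e-97): biological replicates disagree by a third of
their intensity and batch membership dominates the variance. After
background spline correction the replicate RSD falls to 12.9 %, batch
separation collapses to insignificance (F = 0.86), and the injected
control-vs-drought difference is detectable (F = 4.3, p = 0.016).

The same flows are available as a library:

```python
import msdrift as md

matrix, truth = md.simulate_dataset(md.qc_divergent_config(seed=2))
ws, _ = md.working_set(matrix)
corrected, factors = md.correct(
    ws, md.TrendSpec(method="spline", scope="background", application="batchwise")
)
print(md.replicate_rsd(corrected, original=ws).mean_rsd_percent)
```

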