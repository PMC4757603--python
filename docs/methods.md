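# Methods

## Correction model

Every correction in `msdrift` is the ratio form

    X'_{p,b,i} = X_{p,b,i} · R_p / C_{p,b,i}

applied cell-wise to a non-negative peak-intensity matrix ordered by
acquisition. The trend C for a peak is estimated per *fit unit* — each
batch independently (`batchwise`) or the full run as one unit (`global`) —
from a *fit scope*: the QC injections alone (`qc_only`) or every
non-conditioning observation (`background`). Within a unit, observations
receive consecutive ranks 1..m by acquisition count (not raw run index),
so gaps left by removed observations do not distort the smoothers, and the
trend is evaluated at every rank of the unit, including ranks outside the
fit subset's span (QC-only trends are evaluated between and beyond QCs by
the fitted model itself, not by step functions).

Zeros encode "not detected": they stay zero under correction and features
whose fit subset is entirely zero in a unit are left uncorrected there
(factors 1, logged), rather than divided by a zero trend.

### Trend methods and their parameters

| method | parameter | default | notes |
|---|---|---|---|
| constant | averaging ∈ {mean, median} | mean | flat trend A_{p,b}; the mean is more efficient on few points, the median robust to outliers |
| linear | — | — | OLS of intensity on rank; C = β_b·i + α_b |
| moving_median | half-width w ≥ 0 (ranks) | — | median over ranks [i−w, i+w], truncated at the unit ends; linear interpolation at non-fit ranks, constant beyond; w=0 reproduces the fit values |
| polynomial | degree n ≥ 1 | — | least squares on ranks rescaled to [−1, 1] for conditioning; n=1 ≡ linear |
| spline | penalty λ > 0 or "auto" | auto | penalized natural cubic spline, see below |
| loess | span α ∈ (0, 1] | — | local linear fit at each rank using the ⌈αm⌉ nearest fit points with tricube weights; no robustness iterations (degree and iteration count are a design choice: degree 1 is stable on small batches) |

All methods are equivariant under shifting and positive scaling of the
fit values, and linear in them except the moving median. The moving
median's truncated-window edge policy keeps C defined everywhere; the
half-width convention means the window holds up to 2w+1 points.

### Smoothing spline

The spline minimizes Σ(y_i − f(x_i))² + λ∫f″(t)²dt over twice-
differentiable f; the minimizer is a natural cubic spline with knots at
the fit ranks and fitted values S·y with S = (I + λK)⁻¹, where K is the
Green–Silverman roughness matrix (K = DᵀW⁻¹D from second differences D
and the tridiagonal Gram matrix W of the second-derivative basis). S is
formed through the eigendecomposition of K, with the two null-space
eigenvalues (straight lines) set exactly to zero, so the fit is exact for
any λ including the λ→∞ limit (the OLS line) and the λ→0 limit
(interpolation). Evaluation between knots uses the natural cubic
interpolant of the fitted values; beyond the knot span the spline is
extended linearly. At least 4 distinct fit ranks are required.

`λ = "auto"` minimizes the generalized cross-validation score
m·‖(I−S)y‖² / (m − tr S)² over a fixed grid of 61 log-spaced penalties,
10⁻⁴..10⁸. Because ranks are consecutive integers the penalty has no
dependence on the intensity scale (both GCV terms scale as y²), so the
grid needs no per-dataset scaling; its extremes reach near-interpolation
and a near-linear fit for any unit size the package targets. An explicit
grid keeps the selection reproducible and lets all features of a unit
share the cached smoother matrices.

### Rescaling and division guards

R_p is the scope-subset average of the feature in the first batch
(`first_batch`), in all batches (`all_batches`, the default — for
background corrections the paper-style choice of reference is open, and
the pooled average is the neutral one), or 1 (`none`, leaving data on a
fold-of-trend scale where the scope average corrects to 1).

Division by a trend near zero is a real failure mode of QC-only
regression corrections, so guarding is explicit: `faithful` (default)
divides by the fitted trend as-is — reproducing the blow-ups — while
flagging cells whose |C| falls below 10⁻⁶ × the unit's median positive
factor; cells with C ≤ 0 cannot yield a meaningful non-negative intensity
and become 0 (flagged). `clamp` substitutes the unit's median positive
factor at all hazardous cells. The two modes differ only at flagged
cells, and flags are preserved in the `CorrectionFactors` object for
audit.

## Filtering

Features are removed before trend estimation when no accurate trend can
be expected: median over QCs equal to zero (half or more of the QCs
recorded nothing) for QC-scope corrections, or median over all
observations equal to zero for background corrections. With an even count
and exactly half zeros the midpoint median a/2 is positive, so such
borderline features are retained (and logged). Outlier observations are
removed only by an explicit id list — the removal the workflow emulates
was a judgment call on inspection, and automating it is out of scope.

## Evaluation

**Replicate RSD.** For each feature and each biological replicate set
with ≥ 3 members, RSD = sd(set values; m−1 denominator) / grand mean,
where the grand mean is the feature's mean over all experimental
observations (a `grand_mean="set"` switch uses the set's own mean
instead; the pooled choice follows the subset-RSD convention). Entries
are excluded — one reason each — when the set is too small, any set value
is zero in the pre-correction data, all set values are zero after
correction, or the grand mean is zero. The headline metric is the
unweighted mean of included entries, reported as a percentage. Because σ
and the grand mean scale together, the metric is invariant to per-feature
rescaling — R_p does not affect it.

**PCA-MANOVA.** Columns are mean-centred and scaled to unit variance
(ddof = 1; zero-variance features dropped), scores come from SVD with the
sign of each component fixed by its largest-magnitude loading, and PCA is
computed over experimental observations only (QCs carry no group).
MANOVA uses Wilks' Λ = det(W)/det(W+B) on the first two score columns,
converted to an F statistic by Rao's approximation — exact for two groups
(where it reduces to the Hotelling T² transform) and for the one-column
degenerate case (classical one-way ANOVA F); for the multi-batch test it
is the standard approximation. Group comparisons restrict the score rows
to the named groups; the batch test uses batch labels of experimental
observations. A separate per-feature QC-RSD diagnostic is provided, since
QCs are excluded from the group tests.

## Parameter optimization

`grid_optimize` evaluates the full pipeline (fit, apply, replicate RSD
against the uncorrected matrix) at every grid value of the method's
parameter and returns the argmin with the full table. Default grids:
w ∈ {1..15}, n ∈ {1..8}, α ∈ {0.05, 0.10, …, 1.00}; λ is not in the grid
because the spline selects it internally by GCV. Ties (within 10⁻¹²)
break towards the smoother model — smaller w or n, larger α — preferring
lower variance when the data cannot distinguish candidates. The protocol
optimizes on the same dataset it evaluates, mirroring the workflow it
reproduces; with a single tuned scalar per method the optimism this
induces is small, but the circularity is inherited, not fixed here.

## Synthetic data

The generator emulates the structure of a multi-batch plant-extract
LC–MS acquisition. Observed intensity is a product of: per-feature
log-normal baseline (log-mean log 10⁵, log-sd 1.5); per-group log-fold
effects on a 20 % subset of features (log-sd 0.5); per-observation
biological noise (log-sd 0.1); per-batch per-feature offsets (log-sd
0.3); a per-batch drift curve over acquisition position (none / linear /
smoothed random walk / changepoint, amplitude as a fraction of baseline);
and measurement noise (log-sd 0.05). QCs replace the group and biological
terms with a per-feature QC bias (log-sd 0.3, the pooled reference
differing from experimental extracts) and follow the batch drift raised
to an attenuation exponent in [0, 1]. Values below the detection limit
(default 1000, a little over 3 log-sds below the median baseline) record
as zero. Defaults are 7 batches × 24 experimental samples with a QC after
every 6, 300 features, replicate sets of 3 assigned to random acquisition
slots across batches as a randomized design would.

Everything is multiplicative by construction, so the ratio correction can
remove drift exactly and perfect-recovery tests are meaningful. All draws
flow from one master seed through named SeedSequence substreams
(features, offsets, per-batch drift, assignment, noise), making datasets
bit-reproducible.

The `qc_divergent` preset is the regime where QC-only correction fails:
attenuation 0.2, alternating changepoint and smooth drift of amplitude
0.5, QC measurement log-sd 0.45. The QC noise level was set so that a
per-batch line through 4 noisy QCs is unreliable enough to produce the
divide-by-near-zero blow-ups characteristic of this failure mode; the
preset is calibrated to reproduce orderings between methods, not any
particular effect size.

**What the simulator does not model:** retention-time drift and peak-shape
changes (assumed fixed upstream by alignment/peak picking),
heteroscedastic or additive detector noise, correlated features,
missing-at-random metadata, and drift that differs per feature (drift is
shared across features within a batch, with per-feature batch offsets on
top). Passing tests therefore demonstrate correctness of the estimators
and the claimed orderings under multiplicative drift — not performance on
any particular real acquisition.

## Numerical choices and degenerate inputs

- Ranks are recomputed per unit; the spline/LOESS operator matrices
  depend only on rank geometry and are cached and shared across features.
- LOESS neighbourhoods smaller than 2 points are rejected; a locally
  singular weighted design falls back to the locally weighted mean.
- Intensity files are written as shortest round-tripping decimal text and
  parsed with round-trip float precision, so write→read is bit-exact.
- Problem sizes in the test-suite sweeps (20 seeds of the full-size
  scenario for the ordering checks; 2–3 batches and tens of features for
  unit tests) were chosen as the smallest sizes at which the checked
  contrasts are decisive.

## Known limitations

- The hybrid scheme weighting QCs more strongly than background
  observations is not implemented.
- Robust (iteratively reweighted) LOESS, kernel smoothers and wavelet
  detrending are out of scope.
- `faithful` guarding deliberately propagates trend pathologies into the
  corrected matrix; users wanting safe output should pass
  `guard="clamp"`.
- MANOVA assumes within-group covariances are comparable; with strongly
  imbalanced or tiny groups the Rao approximation degrades.
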