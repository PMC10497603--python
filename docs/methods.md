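# Methods

## Reflectance calibration and denoising

Raw frames are converted to reflectance per pixel and band,
`R = (I_S − I_D)/(I_w − I_D)`.  Entries where the white and dark frames
coincide within `eps` (default 1e-9 counts) are flagged invalid and set
to zero; the boolean validity mask travels with the cube, and all
spatial statistics downstream (ROI centroids, per-band means) ignore
flagged entries.  Calibration is scale-invariant: multiplying all three
frames by a constant leaves `R` unchanged.

Denoising is a Savitzky–Golay filter along the band axis.  The source
description fixes neither window nor polynomial order; the defaults are
window 11 samples, order 2 — wide enough to suppress shot noise at
sub-nanometre sampling without flattening absorption features — and both
are configurable (`SGConfig`).  Edges are handled by mirror-padding the
spectrum by (window−1)/2 samples (configurable to nearest-value
padding).  The least-squares convolution weights come from
`scipy.signal.savgol_coeffs` and sum to 1 for any valid configuration,
so constant spectra pass through exactly.

## Band grids and resampling

A grid for a spectral range `[lo, hi]` and full bandwidth `w` places
centers at `lo + w/2, lo + 3w/2, …` — non-overlapping windows tiling the
range.  The band count is the nearest integer to `span/w`: this is the
rule that reproduces every published per-range band count for
`w = 10…30 nm`, including the two cells (VISWIR ±7.5, SWIR ±15) where a
strict all-windows-inside rule would come out one band short.  When
`span/w` rounds up, the last window protrudes past the range edge by at
most `w/2`.  The narrowest simulated bandwidth (±2.5 nm) follows an
edge-anchored convention instead (`mode="edge"`: centers at both range
edges, count `span/w + 1`), matching its published counts.

Resampling evaluates the mean integrated reflectance
`R_M(λ_c) = ∫_{λ_a}^{λ_b} R dλ / (λ_b − λ_a)` with λ_a, λ_b the first
and last cube samples inside the window, using the trapezoid rule.
Trapezoid quadrature was chosen over a one-sided Riemann sum because it
preserves constants *and* integrates linear spectra exactly, keeps every
band value inside the min/max of its window samples, and commutes with
pixelwise scaling; a one-sided sum carries an O(Δλ) bias (~5e-4 relative
at 0.5 nm sampling) that would dominate the quadrature-oracle checks.
Windows need at least two samples; emptier windows raise with the
offending band named.  Spectral-response-curve (Gaussian filter-shape)
simulation is out of scope: bands are boxcar means by construction.

## Samples, groups, splits

One fruit-slice image yields one sample: a 20×20-pixel ROI centered on
the valid-pixel centroid (CNN input, bands as channels) and its
per-band spatial mean over unflagged pixels (FNN input).  °Brix groups
use half-open intervals — group 1: y < 10, group 2: 10 ≤ y < 11,
group 3: 11 ≤ y < 12, group 4: 12 ≤ y < 13, group 5: y ≥ 13 — so every
label maps to exactly one group.

Stratified 60/20/20 splits use, within each group of size n:
`test = floor(0.2 n)`, `valid = ceil(0.2 n)`, `train = n − valid − test`,
assigned by a seeded shuffle and concatenated across groups.  This
rounding rule reproduces both published splits (218 → 131/44/43 and
162 → 97/33/32); other rules consistent with those two pairs exist, and
this one is canonical here.

## Regressors

All four model families are built on a small numpy engine
(`specband._nn`) with reverse-mode gradients for parameters and inputs,
verified against central finite differences in the test suite.  No
deep-learning framework is required.

* **Multispectral CNN**: two Conv(64 filters, 'same' padding)→ReLU→BN
  blocks, each followed by max pooling, then two FC→ReLU→BN→Dropout
  blocks and a ReLU-activated scalar head.  Kernels are spatial over the
  ROI (e.g. 1×5) with bands as channels — the only reading consistent
  with the published pool sizes and input shape.  An L2 penalty
  (λ = 1e-10) applies to convolution kernels.
* **Multispectral FNN**: four FC→ReLU→BN→Dropout blocks
  (256/128/64/32) and the scalar head.
* **Signature CNN**: four Conv(64)→ReLU→BN blocks, one average pool,
  two FC→ReLU→BN→Dropout blocks, scalar head.  Its dropout rate is not
  published; 0.2 is used.
* **Signature FNN**: four FC→ReLU→BN blocks (512/256/128/64, no
  dropout) and the scalar head.

Per-range hyperparameters (kernels, pool sizes, FC widths, batch sizes,
learning rates, dropout rates) follow the published selections and are
exposed as presets.  The block ordering FC→ReLU→BN→Dropout follows the
published naming literally.

Training minimizes RMSLE, `sqrt(mean((log1p(ŷ) − log1p(y))²))` (the
standard log1p form; the exact formula is not printed), with Adam at
framework-default moment coefficients and a per-epoch learning rate
`lr_j = lr_0 · exp(−k·j)`, `k = 1e-6` by default.  After each epoch the
validation RMSLE is computed and the best-so-far weights (plus
batch-norm running statistics) are checkpointed; training stops at
`max_epochs` (default 500) or after 100 non-improving epochs, neither of
which is published.  Two numerical choices deserve note: the scalar
head's bias is initialized to the training-label mean so the ReLU head
starts active (a zero-initialized ReLU head can be born dead), and
batches of one sample are skipped because batch statistics are undefined
there.

Metrics are MAE and the conventional coefficient of determination
`R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` with ȳ the mean of the *reference* values —
the form under which R² = 1 iff the fit is perfect.  The source text
reads "mean of the prediction values"; a `literal_ybar` flag implements
that variant for comparison.

## Attribution and selection

The mean of integrated gradients is, per band (and pixel for CNNs),

    MIG = (1/S)(1/M) Σ_samples Σ_{k=1..M} ∇F(R′ + (k/M)(R − R′))

with baseline R′ = 0 (the natural zero of the reflectance scale),
M = 50 path steps, gradients in eval mode.  This **literal** mode is the
default.  As printed, the formula omits the (R − R′) factor of standard
integrated gradients; a **full_ig** mode multiplies the path-averaged
gradient elementwise by (R − R′) per sample before averaging, and
satisfies the completeness identity Σ attributions ≈ F(R) − F(R′) as M
grows.  Completeness is exact only in the M→∞ limit: the right-endpoint
Riemann sum converges O(1/M), with a constant governed by the model's
curvature — small for smooth models, kink-dependent for ReLU networks —
so completeness checks are run on smooth models, per sample (a
sample-averaged output difference can cancel to near zero and make any
relative bound ill-conditioned).

`Score(λ_c)` is the absolute value of the spatial mean of the MIG (CNN)
or `|MIG|` (FNN): bands whose positive and negative pixel attributions
cancel score low by design.  Selection is greedy: repeatedly take the
highest-Score band at least 20 nm from every selected center, stopping
at six.  A spacing of exactly 20 nm is admissible — required by
published co-selections of adjacent ±10 nm bands (570/590, 1170/1190,
490/510 nm) — and score ties break toward the lower wavelength.  A
`positive_only` mode (select among positive-MIG bands only) is included
because that variant was reported tried and inferior; it is off by
default.

## Synthetic data

Real wax-apple cubes are unavailable, so `synthcube` generates the study
conditions: five °Brix groups of 218/162/218/218/218 samples with means
8.65/10.44/11.48/12.52/14.01 and SDs 0.82/0.25/0.23/0.27/0.88, drawn
from ±3 SD truncated normals (group ids are re-derived from the drawn
value, exercising the grouping rule on boundary draws).  Each sample is
a 20×20×Λ cube on a 400–1700 nm, 1 nm grid (the instrument's 0.5/2.5 nm
mixed resolution is not simulated; 1 nm keeps fixtures small and is
configurable):

* a fixed smooth baseline (broad Gaussian bumps plus a
  water-absorption-like dip near 1450 nm);
* a planted effect: Gaussian bands (default centers 530/680/1050 nm,
  width 10 nm, weights 0.9/0.6/0.45) scaled by `(Brix − 11.5)/3` — the
  simplest structure both model families can represent, so recovery
  failures are attributable to the selection method, not capacity;
* a per-sample smooth spectral deviation (SD 0.03, ~30 nm correlation
  length) representing fruit-to-fruit reflectance variability
  uncorrelated with °Brix.  Without it, non-planted bands are
  essentially constant across samples, the regressor's weights on them
  are unidentifiable, and gradient attribution there is arbitrary — an
  ill-posed validation, not a hard one;
* a per-pixel spatial texture offset (SD 0.02, constant across bands)
  and i.i.d. per-pixel sensor noise (SD 0.2 in the recovery
  conditions).

Generation is bitwise-reproducible from the seed (per-sample child RNG
streams), and `iter_samples` streams cubes at constant memory for the
full-size 1 nm grid.

What passing synthetic tests do **not** show: the generator has no
radiative-transfer realism, no nonlinear chemistry–reflectance
relations, no dual-spectrometer resolution discontinuity near
900–1000 nm, and its °Brix information is genuinely confined to a few
bands.  Real-data error levels (the published MAEs around 0.4–0.6 °Brix)
are therefore not reproduced or claimed; the synthetic experiments
validate the *machinery* — grids, splits, training, attribution,
selection — and the recovery experiment validates that the selection
method finds known informative bands far above the hypergeometric
chance level.

## Recovery harness

For each seed: regenerate the dataset, Savitzky–Golay-smooth and
resample to the ±10 nm VISWIR grid (65 bands), train the FNN preset,
compute the literal-mode MIG Score over the training samples, select six
bands, and count planted bands with a selected center within one grid
step (20 nm).  The chance level reported alongside is the expectation of
favorably-placed selections when six bands are drawn uniformly without
replacement (`6 · n_favorable / 65` ≈ 0.74 for three planted bands,
versus the observed 2–3 recovered per seed).

## Pipeline orchestration

Block A trains one model per (range × bandwidth × family) cell; cells
fail independently (logged, others continue), splits are shared within a
cell's range/bandwidth, and per-cell seeds are derived by hashing the
cell identity with the run seed.  Block B extracts one six-band
signature set per eligible model — ±2.5 nm and SWIR are excluded by
default, both having performed worst for multispectral modeling — so the
default grid yields 2 × 3 × 5 = 30 sets.  Block C resamples the original
cubes at each set's centers and retrains the signature architectures,
reusing Block-A's split seed for comparability (whether the original
study re-split is unstated).

Block C's default pairing is **matched**: each signature set is
retrained at its own source bandwidth, giving one cell per set and
reproducing the published 6-row × 5-column table layout with row and
column MAE averages (arithmetic means; full precision internally,
3-decimal rounding for display only).  A **cross** mode retrains every
set at every Block-C bandwidth for the full 150-cell product.  The
prose's alternative bandwidth list (±25…±5) is reachable through
configuration.

## Problem sizes and defaults in tests

Unit and pipeline tests run on reduced synthetic datasets (8–300
samples, 5 nm wavelength step, few training epochs) chosen so the full
suite exercises every code path in minutes on one CPU; the recovery
experiment runs at the full published group sizes (1034 samples, 1 nm
step, five seeds) because its statistical claim depends on them.  The
noise-monotonicity property is tested on single-pixel spectra: with the
20×20 ROI mean, sensor noise is attenuated twentyfold and its effect on
MAE falls below seed-to-seed training variability.

## Known limitations

* Literal-mode MIG averages gradients along a path through low-
  reflectance inputs that are far from the data manifold; attribution
  quality degrades for weakly informative bands, which is visible in
  recovery runs (the weakest planted band is the one occasionally
  missed).
* The numpy engine is CPU-only and single-threaded beyond BLAS; it is
  sized for the published architectures, not for general deep learning.
* ENVI support covers the classic header + raw binary layout with a
  wavelength list; exotic header fields are ignored.
* Overlapping band windows and mixed-bandwidth signature sets are out of
  scope (flagged as future work in the source).
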