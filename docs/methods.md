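# Methods

This note records the models, the defaults and the judgment calls behind
them. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data generator

The generator emulates a three-region plant-matrix authentication study:
`n_classes=3` geographic classes, `n_samples_per_class=8`, `n_replicates=3`
(triplicate measurement is the norm in such campaigns; replicates share a
sample's concentration vector and differ only by instrumental noise).

**NMR.** Each metabolite is a sum of Lorentzian lines — the natural NMR
lineshape — with half-width at half-maximum 0.012 ppm, a typical processed
linewidth at high field. The default library carries the marker compounds of
olive leaf/drupe extracts at their literature shifts: oleuropein/ligstroside
(1.64, 2.80, 3.71, 6.73 ppm), mannitol (3.65, 3.81), glucose (3.37, 4.53),
quinic acid (1.96) and maslinic/oleanolic triterpenes (0.90–1.13). Solvent
residuals (water at 4.79 ppm, methanol at 3.31 ppm) sit inside the regions
the bucketing step excludes. Concentrations are log-normal per class
(positivity guaranteed; class effects act as fold changes) with a
between-sample log-sd of 0.15 — a mild biological variability chosen once as
a realistic within-region spread; the emulated studies report only
qualitative class differences, so the class mean log-concentrations here are
tuning knobs of the simulation, not claims about any real region. Additive
Gaussian noise defaults to 0.2% of the maximum signal.

**EEM.** Fluorophores have Gaussian excitation/emission profiles (standard in
EEM simulation) with unit maximum, so sample scores read as relative
concentrations. Two libraries ship: a drupe set — catechin/epicatechin
(280/315 nm), tocopherols (340/450 nm), phenolic compounds (230/310 nm), the
last requiring the 200–450 nm excitation grid drupes are measured on — and a
leaf "Region B" set — chlorogenic acid (320/435 nm), phenolic compounds
(280 nm excitation, emission shoulder placed at 350 nm since the real band
peaks below the acquired range), tocopherols (360/465 nm). Scatter ridges are
Gaussian in emission: first-order Rayleigh at λ_em = λ_ex, second order at
2λ_ex (1.5× wider), and a Raman band at a fixed Stokes shift of 3400 cm⁻¹
(water-like; the extraction solvent is methanol/water and no shift is
reported, so it is configurable). The ridge sd defaults to 3 nm: scatter
width tracks the monochromator bandpass, and 5 nm slits give a ridge of
roughly 7 nm full width at half maximum. With the default ±10/±15 nm removal
bands this leaves the ridges essentially fully inside the masked bands,
which is the regime scatter removal is designed for.

**Paired two-block datasets.** `generate_fusion_dataset` places the class
signal by preset: `block1` (NMR only), `block2` (EEM only), `both`, or
`complementary` — NMR separates class 0 from class 1 only (class 2 mimics
class 0 there) while EEM separates class 0 from class 2 only, so each block
carries an orthogonal half of the three-class signal and fusion is the only
route to full separation. Ground-truth separability is recorded as Fisher
ratios, computed as trace(S_w⁺ S_b) on 6-PC-compressed blocks: the trace sums
discriminability over all discriminant directions (a single-direction ratio
would not strictly increase under fusion of equal-strength complementary
blocks), and the PC compression keeps the pseudo-inverse stable when
variables outnumber samples.

What the generator does **not** emulate: J-coupling multiplets, pH-dependent
shift drift, peak misalignment across samples, inner-filter effects,
detector saturation, or correlated (non-white) noise. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artifact of real spectra.

## NMR preprocessing

Buckets are left-closed right-open 0.04 ppm intervals anchored at 0.50 ppm;
the trailing 0.02 ppm remainder at 9.98–10.00 ppm is dropped rather than
padded. Bucket values are trapezoidal integrals, computed as differences of
the interpolated cumulative integral so that bucket areas sum exactly to the
integral over the bucketed domain. A bucket is removed whenever its interval
intersects an exclusion region (4.50–5.20 and 3.28–3.40 ppm by default):
4.50 is edge-aligned with the 0.50 anchor but 5.20, 3.28 and 3.40 are not,
and whole-bucket removal guarantees excluded signal never leaks into a
retained bucket. Total-intensity normalization divides each row by its sum
over the *retained* buckets; normalizing before exclusion would only change
each row's scale, which the re-normalization absorbs, but the
after-exclusion order keeps row sums exactly one on the matrix actually
modeled. Replicates enter the models as individual rows; the grouping
metadata is retained so the duplex split can keep them together.

## EEM preprocessing

Scatter masking flags |λ_em − kλ_ex| ≤ band for k = 1, 2, the Raman band at
the configured Stokes shift, and (by default) the physically meaningless
region λ_em < λ_ex below first-order Rayleigh. Bands default to ±10 nm
(Rayleigh 1st, Raman) and ±15 nm (Rayleigh 2nd) — values typical of EEM
scatter-handling practice; the emulated studies do not report theirs.
Interpolation is 1-D shape-preserving PCHIP along the emission mode within
each excitation column; the below-Rayleigh region is set to zero rather than
interpolated (switchable), zero-filled points anchor the fit, values beyond
the observed hull take the nearest observed value, and results are clipped
at zero so interpolation never produces negative intensities. A column with
fewer than two observed points is left missing and logged, never silently
filled. Sample-mode normalization divides each slab by the standard
deviation of its own entries. Unfolding runs the emission index fastest —
an internal constant used identically by `refold`, making the pair an exact
bijection.

## PARAFAC

Fitting is alternating least squares with column-wise non-negative updates
(HALS): each column update is the exact non-negative least-squares minimizer
given the others, so the objective is non-increasing at every step.
Defaults: best of 10 starts (one SVD-based, the rest seeded random),
tolerance 1e-8 on the relative fit change, 2000 iterations maximum;
non-convergence is flagged on the model, never raised. Emission and
excitation loadings are rescaled to unit maximum with the scale pushed into
the scores, and components are ordered by score energy, making outputs
deterministic given the seed. CORCONDIA fits the least-squares Tucker core
given the factors and measures its distance to the superidentity; a
one-component model returns exactly 100 (at convergence the optimal 1×1×1
core is unity by scale optimality). A rank-deficient factor matrix makes the
core unidentifiable and raises with a suggestion to use fewer components;
`fit_parafac` records NaN in that case. `select_components` replaces visual
inspection with a documented rule: the largest component count whose
CORCONDIA stays at or above 80 — a conventional "acceptable consistency"
level, not a value reported by any particular study. Split-half validation
is deliberately out of scope.

## One-class SIMCA

The Q residual limit uses the Jackson–Mudholkar closed form on the residual
eigenvalues; the T² limit uses A(n−1)/(n−A) F₀.₉₅(A, n−A). When the residual
spectrum is numerically zero (data in an exact A-dimensional subspace) the Q
limit falls back to machine epsilon at the data's variance scale, so
zero-residual samples are always accepted. The reduced distance is the
Euclidean combination of the two normalized statistics (a sum form is
available as a switch). The acceptance threshold defaults to the √2 boundary
— the point where both statistics sit exactly at their limits — and is tuned
by exhaustive search over midpoints of adjacent sorted distances, maximizing
sensitivity + specificity with ties broken toward higher sensitivity, then
the smaller threshold. Tuning should use cross-validated target distances
(`loo_distances`); resubstitution distances are optimistically small and
shrink the threshold until test-set sensitivity collapses.

Component selection computes leave-one-out reconstruction RMSECV and
leave-one-out sensitivity (acceptance of the held-out sample at the √2
boundary) per candidate A. Naive projection RMSECV decreases monotonically
with A, so the rule picks the *smallest* A within 1% of the minimum —
adequate when variables far outnumber components, which is the regime of
bucket tables and unfolded EEMs — with exact RMSECV ties resolved by the
higher sensitivity.

The duplex split alternates the two mutually farthest remaining points (or
replicate-group centroids) into calibration first, then test, until the test
set reaches ⌈(1−ratio)·n⌉ rows; distance ties break lexicographically, so
the split is deterministic. Whole replicate groups move together — letting
replicates of one physical sample straddle the split would leak information
and inflate test metrics. The outlier screen flags samples with leverage
above 3(A+1)/n or Q above its 95% limit on an all-data PCA and only ever
*reports* them; removal is the caller's decision.

## ComDim and the multiblock classifier

Block normalization is two-stage as a matter of record-keeping — divide each
point by the square root of the block's sum of squares, then by the
Frobenius norm of the result (an identity after stage one, recorded anyway
so test-set replay applies exactly the divisors used in training). Salience
iteration starts at λ_b = 1, converges when saliences change by less than
1e-10 (500 iterations maximum, per CD), and the eigenvector sign is fixed by
making the largest-magnitude score positive. Each CD's explained variance is
the block energy removed by its deflation over the total normalized block
energy, so per-CD values sum exactly to the cumulative.

Projection of new samples replays the training deflation: per CD, the score
is the salience-weighted combination of the sample's block images on the
stored loadings divided by the CD eigenvalue, and the sample is deflated
with the training loadings — training rows projected through this path
reproduce their training scores exactly.

The one-class classifier takes the CD scores as-is (no re-centering or
scaling beyond the block normalization): SD is the Mahalanobis distance to
the target score cloud, OD the residual sum of squares after the retained
CDs. OD sums the squared residuals of the concatenated blocks by default; a
block-wise variant (each block's residual scaled by its variable count) is
behind a switch, since either reading is defensible. The 95% limits are
moment-matched scaled chi-square fits (g·χ²_h with g, h from the mean and
variance of the training statistic) — the convention of the data-driven
SIMCA family this classifier belongs to — with an empirical-quantile
fallback/switch for degenerate distributions. The number of CDs defaults to
the smallest count reaching 90% cumulative explained variance unless fixed
by the user; the study driver fixes 3, the depth such studies typically
report.

## Study driver

`run_study` executes: simulate → bucket/normalize → scatter removal,
interpolation, variance normalization, unfolding → PARAFAC rank scan →
duplex split (80:20, replicate-grouped, on the jointly normalized blocks) →
per-block SIMCA (LOO component selection capped at 5, LOO-tuned threshold) →
ComDim multiblock one-class classifier (3 CDs, LOO-tuned threshold) →
metrics report. A single study seed fans out to per-stage seeds derived from
(root seed, stage index) alone, so overriding one stage's seed leaves the
others untouched; with the seed fixed the full report is bitwise
reproducible. Omitting the EEM block runs the NMR-only path and records an
explicit notice for the skipped fusion stages.

Problem sizes used by the default study and the acceptance computations —
3 classes × 8 samples × 3 replicates, 30 × 141 × 21 reference cubes,
500-sample Gaussian classes for limit calibration, 20-seed sweeps — were
chosen once as the simulation conditions and are stated in the relevant
docstrings; they keep every check on a single CPU at desk scale.

## Known limitations

- The duplex test set can overshoot ⌈(1−ratio)·n⌉ by up to one group pair,
  since whole groups move together.
- Naive LOO RMSECV is biased toward large A when the variable count is
  small; the 1%-band rule compensates only in the many-variables regime.
- CORCONDIA on nearly noiseless data can stay high for over-factored models
  (the extra component vanishes instead of scrambling the core); rank
  diagnostics are most reliable at realistic noise levels.
- The moment-matched chi-square limits assume unimodal, roughly
  gamma-shaped training statistics; switch to empirical quantiles for
  heavy-tailed data.
- File I/O uses '.'-decimal delimited text only; localized decimal commas
  are rejected with a diagnostic rather than guessed at.
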