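# Methods

This note documents the statistical and cheminformatic procedures
implemented in `qsrrkit`, the conventions frozen where the literature
admits variants, and what the synthetic-data generators do and do not
emulate.

## Structures and curation

SMILES are parsed with RDKit behind the `parse_smiles` contract; the
package stores hydrogen-depleted graphs (element, formal charge,
aromaticity per atom; order per bond). Stereochemistry is stripped before
canonicalization because every descriptor used here is 2D/topological and
stereo-insensitive. Duplicate identity is the canonical structure — not
the molecular formula — so constitutional isomers never merge; merged
records carry the arithmetic mean of their members' retention indices.
Multi-component SMILES (salts, mixtures) are rejected rather than
silently fragment-picked, since none occur in the intended corpora.

## Descriptors

Three descriptors carry the retention model. Vendor implementations
differ in small conventions; the ones used here are frozen in
`qsrrkit/constants.py` (versioned, reported by `qsrrkit --version`):

* **Eta_betaS** — sum over the sigma framework of the hydrogen-depleted
  graph, each bond counted once: 0.5 per bond whose endpoints differ by at
  most 0.3 Pauling electronegativity units, 0.75 otherwise. The per-bond
  (rather than per-atom-endpoint) summation was chosen because it reads
  "all sigma bonds in the molecule" literally and puts the descriptor on
  the scale the built-in calibration's coefficient implies: n-decane gives
  4.5, hence an Eta_betaS term of ≈570 RI units and a predicted RI near
  1000 — the defining RI of decane. The per-atom variant (every bond
  counted twice) would double the scale.
* **MDEC-22** — `n22 / d̄²` over all unordered pairs of secondary carbons
  (carbons with exactly two heavy-atom neighbours), with
  `d̄ = (Π d_ij)^(1/(2·n22))`, the exponent of the original
  molecular-distance-edge formulation (also used by CDK/PaDEL); zero when
  fewer than two secondary carbons exist. The n-butane value (exactly 1)
  is convention-invariant and guards gross errors.
* **MATS1p** — Moran autocorrelation at topological lag 1:
  `[(1/P1) Σ_{d_ij=1} (w_i−w̄)(w_j−w̄)] / [(1/N) Σ_i (w_i−w̄)²]`, with
  carbon-scaled static atomic polarizabilities (CRC values) as weights,
  computed on the hydrogen-depleted graph; implicit hydrogens do not
  contribute. Degenerate cases (zero weight variance, no bonded pair)
  return 0 by convention.

Because no independent implementation of these descriptors is available
as a dependency, the test suite carries brute-force reference
implementations written from the published definitions with an unrelated
code path (networkx shortest paths, separately entered element tables,
explicit pair loops); the engine must agree with them to 1e-6 on a
50-molecule generated probe set.

Matrix-level plumbing: failed computations are explicit missing values
(never zero, never imputed); `filter_constant_missing` removes constant
columns first and then any column containing a missing value, reporting
both counts; `correlation_reduce` is a deterministic greedy
pairwise-|r|-threshold reduction (keep the earlier column) — a declared
stand-in for distance-based pool-reduction algorithms, adequate because
reduction merely pre-conditions variable selection.

## Splitting

`split_train_test` draws a random 70:30 split with the training size
rounded half away from zero (0.70 × 265 = 185.5 → 186/79), after forcing
the compounds with the global minimum and maximum RI into the training
set. Pinning only the two extremes is the minimal reading of "keep low
and high retention in training": it guarantees every test-set prediction
is an interpolation of the calibrated range, consistent with the leverage
applicability-domain philosophy.

## Variable selection (GA-VSS)

Binary chromosomes over descriptor columns; fitness is RMSECV under
5-fold venetian blinds (fold k = every 5th compound starting at k, OLS
refit per fold). Tournament selection (size 2), uniform crossover
(probability 0.5), per-bit mutation (0.01), repair of oversized
chromosomes by random bit clearing, and elitism (the best chromosome
always survives, making the elite fitness non-increasing). Defaults:
population 50, 200 generations, at most 5 descriptors; all configurable,
and fitness evaluations are cached by subset.

After evolution, every sub-subset of the ten best chromosomes is also
evaluated, and the final model is chosen by a **one-standard-error
parsimony rule**: the smallest model whose RMSECV lies within one
fold-level standard error of the best model's RMSECV. A fixed small
percentage band was considered and rejected: the sampling noise of a
cross-validated RMSE at n ≈ 150 is several percent, so chance decoy
columns routinely "improve" RMSECV by 1–3 % and a 2 % band systematically
returns supersets of the true model. The 1-SE rule treats models inside
the CV noise floor as ties and resolves ties toward parsimony — the same
logic as in regularization-path and tree-pruning practice.

The two-stage protocol for vendor-scale pools runs the GA separately per
descriptor block, merges the descriptors appearing in each block's
`merge_top` best models into one pool, and reruns the GA on the pool.

## Calibration and validation

OLS via QR with an explicit rank check (collinear columns are named in
the error). Conventions:

* R² = 1 − SS_res/SS_tot; **RMSEC = √(SS_res/n)** (divisor n, not
  n−p−1), the chemometrics convention that makes RMSEC directly
  comparable with RMSECV/RMSEP;
* standardized coefficients β_j = b_j·s_xj/s_y (sample SDs), used for
  mechanistic interpretation of descriptor contributions;
* deterministic protocols (LOO; venetian blinds = interleaved folds;
  continuous blocks = contiguous chunks in stored row order) pool held-out
  predictions: R²cv = 1 − PRESS/SS_tot;
* Monte Carlo (random 20 % exclusion) and bootstrap (out-of-bag scoring
  only) average the held-out R² and RMSE over iterations (default 1000,
  seeded); bootstrap iterations with an empty out-of-bag set are skipped;
* Y-randomization permutes the response, refits, and reports mean R² and
  RMSE; under the null the mean R² concentrates at k/(n−1);
* external predictivity: **Q²F3 = 1 − [SSE_ext/n_ext]/[SS_tot_train/
  n_train]** and RMSEP = √(SSE_ext/n_ext). The training-variance
  denominator makes the statistic independent of the external set's
  spread.

The frozen `hp5ms` built-in carries the published coefficients
(428.2, 126.7, 13.8, 627.1), n_train = 186, R² = 0.945, RMSEC = 73.8 and
standardized coefficients (0.756, 0.251, 0.205). Its training sum of
squares — needed for Q²F3 against the frozen model — is reconstructed
from the identity SS_tot/n = RMSEC²/(1−R²).

## Applicability domain

Leverages are hat-matrix diagonals `x'(X'X)⁻¹x` with an intercept column
appended; training leverages sum to the parameter count. The warning
leverage is h* = 3p/n with p counting the intercept (4 descriptors'
worth of parameters and 186 training compounds give 0.065). A query at
h_ii = h* is classified out-of-domain (strict inequality for
"reliable"). Standardized residuals divide raw residuals by the training
RMSEC for both training and query compounds, so the ±2 band coincides
with a ±2·RMSEC raw-residual outlier rule; a calibration whose RMSEC is
numerically zero reports exact matches as residual 0 rather than dividing
rounding error by rounding error.

## Retention indices from chromatograms

Temperature-programmed (van den Dool–Kratz): linear interpolation of raw
retention time between bracketing ladder alkanes, RI = 100·[n + (t_r −
t_n)/(t_{n+1} − t_n)]; isothermal (Kovats): the same with logarithms of
dead-time-corrected times. No extrapolation beyond the ladder — out-of-
range times are errors, mirroring the AD philosophy.

## Fold-change statistics

Fold change is after/before on group means (ratio and log2). The group
test is Welch's t by default (a pooled-variance option exists); multiple
testing uses Benjamini–Hochberg step-up adjustment (via statsmodels,
cross-checked in tests against a brute-force step-up oracle).
Classification: significant iff adjusted p < 0.05 **or** VIP > 1 (VIP
scores come from external OPLS-DA software and are consumed, never
computed); direction from the sign of the log2 fold change; a censored
table entry (">0.05", "<1.00") is parsed to NaN and fails its criterion.
The bundled 72-metabolite extrusion table stores the printed group means
and censored p/VIP verbatim; fold changes are recomputed from the means
(one table row prints a fold change of 0 alongside a large mean change —
the recomputed value is used, and the recomputed labels agree with the
curated labels on all 72 rows).

## Synthetic data

All generators are pure functions of parameters + seed.

* **Molecule libraries**: random carbon trees (C2–C12, max degree 4)
  decorated with one functional group (alcohol/acid/ester/amine or none),
  uniqueness enforced on canonical structure. They probe descriptor code
  paths (branching, heteroatoms, degeneracies); they do not sample real
  flavour-compound chemistry (no rings, no aromatics).
* **Planted-signal descriptor data**: k true standard-normal columns
  (optionally rescaled to mimic the real descriptors' means/SDs), decoys
  correlated 0.3 with a random signal column (plausible but
  distinguishable; configurable), Gaussian response noise. The recovery
  experiments use noise sized for a signal R² of 0.95, the regime of the
  real calibration. Real descriptor pools have heavier inter-column
  correlation structure than this; passing recovery tests shows the
  machinery works, not that three descriptors are findable in any given
  vendor pool.
* **Chromatograms**: a linear heating-rate ladder model (default 1.6
  min/carbon, optional seeded monotone jitter) inverted exactly, so
  requested RIs round-trip to 1e-9. No peak shapes, drift, or co-elution.
* **Abundance tables**: log-normal replicates parameterized by arithmetic
  group mean and CV (default 15 %, matching QC-filtered data with CV
  below 20 %); the after-group mean is the before-group mean times
  2^effect. No missingness, batch structure, or normalization artefacts.

## Problem sizes and numerical choices

The test suite runs its heavier experiments at desk scale chosen once:
GA recovery at n = 150 with 3 true + 47 decoy columns, 20 seeded runs at
population 40 / 120 generations; the study-scale battery at n = 265 with
1000-iteration resampling protocols. Tolerances: exact identities
(LOO hat-matrix shortcut, leverage trace, BH oracle) at 1e-10–1e-12;
descriptor/reference agreement at 1e-6; RI round-trips at 1e-9;
stochastic checks (Y-randomization null) at 3 standard errors.

## Known limitations

Only the three model descriptors (plus trivial auxiliaries) are computed
natively; vendor-scale pools enter via CSV. The descriptor conventions
are frozen from the published definitions, not calibrated against any
vendor binary, so absolute values may differ from a particular vendor's
output by a fixed convention (the built-in model's predictions land in
the right retention range for simple metabolites, but exact agreement
with the original calibration data cannot be verified without them).
OPLS-DA/VIP computation, spectral deconvolution, and normalization are
out of scope by design.
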