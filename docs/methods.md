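# Methods

## The model-evaluation procedure

Given observed activities *A*, predictions *P* from one model, and a
pairwise structural similarity matrix, the package computes:

1. **Pairwise SALI**: `SALI_ij = |A_i − A_j| / (1 − sim(i, j))` for every
   unordered pair. Pairs with `sim = 1` (indistinguishable structures,
   including exact duplicates) are excluded from the landscape with a
   logged warning rather than assigned infinite SALI.
2. **Normalization**: eligible SALI values are divided by the landscape
   maximum, mapping them into [0, 1] with the top cliff at exactly 1.
   Optionally an external `reference_max` (typically the training set's
   maximum) is used instead, for cross-set comparability; values may then
   exceed 1 and such pairs belong to every edge set, while the curve
   domain stays [0, 1].
3. **Thresholded graphs**: at threshold X, the edges are the eligible pairs
   with normalized SALI ≥ X and differing observed activity, oriented from
   lower to higher observed activity. The threshold test is closed (≥), so
   X = 1 retains the maximal pair(s) and S(1) is always defined under
   internal normalization.
4. **Orientation score**: each edge contributes +1 if the predictions order
   it the same way as the observations, −1 if reversed, 0 if the
   predictions tie; S(X) is the mean contribution. S is piecewise constant
   in X with breakpoints only at the distinct normalized SALI values.
5. **SCI**: the exact integral of the step function — the sum of
   S-on-interval times interval width over the constant intervals
   `[0, b1], (b1, b2], …, (b_m, 1]`. A grid mode (trapezoidal rule on a
   regular grid, default step 0.01) is retained for comparability with
   threshold-sweep implementations; S(0) and S(1) are computed exactly in
   either mode.

Companion metrics: MAE and Kendall τ-b (tie-adjusted, via SciPy).
`evaluate_model` bundles all five statistics; `s0_tau_regression` fits OLS
of S(0) on τ across a collection of evaluations.

## Conventions at the degenerate corners

These cases are not fixed by the published definitions; the package's
choices are:

- **Observed-activity ties** carry no orientation, so tied pairs are
  excluded from every edge set including X = 0. Consequently S(0) is a
  tie-free (τ-a-like) coefficient; on datasets with no observed ties, no
  predicted ties and no sim = 1 pairs, S(0) equals Kendall τ-b to machine
  precision. This convention also reproduces the characteristic S(1) = −1
  of a model that reverses the top cliff.
- **Predicted ties on an edge** score 0 but stay in the denominator:
  neither correct nor incorrect, and S stays in [−1, 1].
- **Empty edge sets** (possible only under `reference_max` normalization
  when no pair reaches the reference) evaluate to S = 0 with a logged
  warning; `orientation_score` called directly on an empty graph raises
  instead, so the convention is explicit at the library surface.
- **Empty ∩ empty fingerprints** have Tanimoto 1 (identical absence of
  features); such pairs are then excluded by the sim = 1 rule.

Because every S value is an average of ±1/0 terms and the exact integrator
sums products of finite step values and interval widths, SCI ∈ [−1, 1]
holds identically, and SCI is invariant under strictly increasing
transforms of the predictions and under positive affine transforms of the
observations (the activity scale cancels through normalization).

## Similarity

Structural similarity is Tanimoto on hashed linear/branched path
fingerprints (RDKit's path fingerprint), default 2048 bits, paths of 1–7
bonds. Path-fingerprint parameters materially affect SALI values, so they
are carried on every fingerprint and echoed into run manifests. Any other
similarity source can be supplied as a square CSV; it is validated
symmetric within 1e-9, unit-diagonal within 1e-9, entries in [0, 1].

## Train/test assignment

- `random_split`: uniform random draws per compound; the top
  `round(n · test_fraction)` (half up) become test. The compounds holding
  the maximum and minimum observed activity are anchored into training —
  if drawn into test they are swapped with the highest-draw non-extreme
  training compound, the minimal perturbation of the draw — so the model
  never extrapolates beyond the trained activity range; the test activity
  range provably never exceeds the training range.
- `kohonen_split`: a self-organizing map (rectangular grid, Gaussian
  neighborhood, learning rate 0.5 → 0.01 and radius half-the-larger-grid-
  dimension → 0.5, both decaying linearly over 100 presentations per
  compound by default) is trained on a descriptor matrix; each compound
  maps to its best-matching unit and the test quota is apportioned across
  occupied cells proportionally to occupancy (largest fractional
  remainders first, at least one training compound kept per cell), sampled
  uniformly within cells. A `per_cell` mode samples exactly one test
  compound per occupied cell with ≥ 2 members. The SOM is written for this
  package as a standard implementation of the family; the schedules of
  commercial QSAR suites are not public, so numerical agreement with any
  particular product is not a goal — the contract tested is stratification
  plus exact partition.

## The synthetic landscape generator

The generator emulates the *structure* of an efflux-style dataset — a
smooth activity surface punctuated by a few sharp cliffs — without
chemistry:

- compounds are points in a 2-D latent space placed by dart throwing with a
  minimum separation chosen so background similarity never exceeds ~0.7;
- similarity is `exp(−d / 0.5)` of latent distance: 1 only at distance 0,
  and decaying linearly near 0 so background SALI stays bounded;
- observed activity is a linear function of latent position scaled onto
  `activity_range`, default (0, 2) — the span of log10 efflux ratios
  between 1 and 100, matching the convention that efflux ratios are
  log10-transformed before analysis (an explicit `log10` transform step in
  the workflow, since the library itself is scale-agnostic);
- each planted cliff (default 5 of 50 compounds) adds a partner at
  similarity ≥ `cliff_sim_min` (default 0.95) to a background compound,
  with activity displaced by ≥ `cliff_gap_min` (default 1.5). A planted
  pair's SALI is therefore ≥ 1.5/0.05 = 30 while the background
  construction bounds all other pairs well below that, so the planted
  pairs are recoverable as the top-SALI pairs.

`simulate_predictions(quality)` spans the model-quality spectrum: quality
1 returns the observations, −1 their negation, and intermediate values mix
the standardized (possibly negated) signal with seed-deterministic noise —
Gaussian blending or random permutation of a (1 − |quality|) fraction of
values — so expected τ rises monotonically from ≈ −1 through ≈ 0 to ≈ 1.

What the generator does **not** emulate: assay replicate noise,
heteroscedastic measurement error, censored values, correlated chemical
series, or fingerprint-derived similarity geometry (real Tanimoto matrices
are not radial kernels of a 2-D embedding). Tests passing on synthetic
landscapes therefore validate the landscape mathematics and its contracts,
not predictive performance on any real assay. A 20-molecule public-drug
SMILES panel in the test suite exercises the fingerprint path end-to-end.

## Problem sizes and numerics

The statistical test suite and the acceptance script use ensembles of
50–100 landscapes with 40–100 compounds, 100-seed cliff-recovery scans and
1000-seed split-contract scans; these sizes give stable means while
keeping the whole suite in the tens of seconds. The S(0)-vs-τ regression
ensemble uses 60 sets of 100 compounds with quality swept uniformly over
[−1, 1]. Exact integration is closed-form so its only tolerance is float
arithmetic; the grid integrator converges to it at O(step). The
dense-grid oracle in the tests uses step 1e-4 with a 5e-4 agreement band.

## Known limitations

- S(0) diverges from τ-b when observed or predicted ties are frequent
  (tied pairs are excluded from edges but enter τ-b's tie correction).
- With `reference_max` normalization the curve can be identically 0 above
  the largest normalized value; SCI then mixes "no information" zeros with
  scored intervals and should be read alongside the curve itself.
- SALI landscapes, and hence all summary values, are internal to the
  compound set analyzed: the landscape maximum varies by set, so
  cross-set comparisons should use `reference_max` deliberately.
- The SOM split is stochastic in both training and sampling; only its
  contracts (partition, stratification) are guaranteed, not a unique map.
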