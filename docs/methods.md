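# Methods

This note records the modeling choices behind `rmqsar`: the statistical
model, the algorithms, the synthetic data the tests run on, and the
decisions taken where the published QSAR literature leaves details open.

## Model and conventions

The response is `y = log10 IC50` with IC50 in nM; all fits are ordinary
least squares with intercept on *d* named descriptor columns. Throughout,

* `S = sqrt(RSS / (n − d − 1))` — the intercept is counted as a model
  parameter. This convention is pinned by the warning-leverage identity
  `h* = 3(d + 1)/n`, which gives the conventional 0.1019 at d = 8,
  n = 265; a denominator of `n − d` would be inconsistent with it.
* Training `R²` is `1 − RSS/TSS`. Validation/test `R²` is the **squared
  Pearson correlation** of observed vs predicted. The two coincide on
  training data for OLS with intercept (asserted in the tests). The
  Pearson convention for held-out subsets is the one used by the
  Golbraikh–Tropsha external-validation framework; subset `S` keeps the
  `n − d − 1` denominator.
* Solves use QR/SVD, never normal equations; rank is judged against a
  relative singular-value cutoff of 1e−10, and rank-deficient designs are
  rejected with the offending columns named.
* Leverages are diagonal entries of the hat matrix of the
  intercept-augmented design; query leverages use
  `h = x'(X'X)⁻¹x` on the same design.

## Replacement-method search

The RM minimizes `S_train` over d-subsets of a D-column pool without
enumerating C(D, d) candidates. Details the literature leaves open were
fixed as follows:

* **Sweep discipline.** Within a sweep, positions are visited in
  decreasing relative coefficient error `|SE(b)/b|` (re-ranked after each
  accepted replacement); each visited position is frozen for the rest of
  the sweep. Convergence = a full sweep with no accepted replacement;
  `max_sweeps` (50) is a safety cap that in practice never binds, since
  every replacement strictly reduces RSS and no cycling is possible.
* **Acceptance rule.** Strict improvement only; ties among candidates
  break to the lowest pool index, making the search deterministic given
  the seed.
* **Starts.** 30 random full-rank subsets by default. The model-size
  ladder additionally warm-starts each size with the previous optimum
  plus its best single extension; because the extension is chosen as the
  best of D candidates, the training-S ladder is non-increasing in
  practice (asserted as a property test).
* **Candidate scoring.** All D replacement candidates at a position are
  scored in one vectorized pass: with the other columns and intercept
  projected out (QR), each candidate's RSS is the fixed-design RSS minus
  its squared residual correlation with the residual response. The naive
  refit-per-candidate path (`scan="naive"`) defines correctness and the
  suite checks the two agree. Candidates whose residual energy after
  projection falls below 1e−12 of their norm would make the design
  rank-deficient and are skipped.
* **Selection across sizes.** Smallest *d* with validation S within 0.01
  of the ladder minimum — the parsimony rule that prefers an equally
  predictive smaller model.

On clean 25-column pools the search attains the exhaustive C(25,3)
optimum in ≈100% of instances (acceptance benchmark), consistent with
RM's design goal of approaching the full combinatorial search at a tiny
fraction of its cost.

## Balanced subsets splitting

k-means (Euclidean, scikit-learn, `n_init = 10`) on autoscaled
descriptors; autoscaling is on by default because the pool mixes binary
fingerprint bits with continuous descriptors of arbitrary scale.
`k = ⌈N/20⌉` by default — roughly 20 compounds per cluster — since no
standard value exists. Within each cluster, members are sorted by
distance to the centroid and allocated by a proportional (Bresenham)
round-robin whose ties favor train, so the most representative compounds
calibrate the model and every cluster of size ≥ 3 reaches all three
subsets. Global sizes obey floor(N·fraction) with remaining units going
to the largest fractional parts (ties train → val → test); a final
reconciliation pass moves the farthest-from-centroid members of over-full
subsets, preferring donors that keep their cluster covered. At N = 530
and fractions 0.5/0.25/0.25 this yields 265/133/132.

## Validation battery

* **LOO** uses the hat-matrix identity `e_loo = e/(1 − h)`; the n-refit
  oracle is kept in the code base and equality to 1e−8 is a standing
  test. `s_loo = sqrt(PRESS/(n − d − 1))`.
* **Leave-30%-out** draws `n_cases` random holdouts of `round(0.30·n)`
  compounds (80 at n = 265), refits the fixed subset on the remainder,
  and pools all (obs, pred) pairs before computing r² and S — pooling,
  rather than per-case averaging, matches reporting a single statistic
  over many cases. Default 5,000 cases: these statistics are means whose
  Monte-Carlo error is far below the reported precision at that count;
  publication-scale case counts are reachable by config.
* **Y-randomization** permutes the response (identity permutations are
  redrawn), refits the same descriptor subset, and reports *mean* R² and
  S over 2,000 permutations by default, with the pass rule
  `mean(S_rand) > S_train`. Means rather than extremes: the criterion
  compares typical scrambled fits with the real one.
* **Golbraikh–Tropsha.** `k` is the slope of the through-origin
  regression of predictions on observations, `k′` of the swapped
  regression; each `R0²` is the coefficient of determination of its line
  computed on that regression's dependent axis, which makes the block
  exactly symmetric under (obs, pred) exchange. `Rm² = R²(1 − sqrt(R² −
  R0²))` uses the unprimed `R0²`; the sqrt argument is clamped at zero
  because `R0²` can exceed `R²` (and can even be negative) when
  predictions are strongly shrunk. Pass thresholds: 0.1 on
  `1 − R0²/R²` (either variant), slope window [0.85, 1.15] (either
  slope), `Rm² > 0.5`. Note that at moderate signal-to-noise (test
  R² ≈ 0.5) `Rm²` fails by construction — the criteria are designed to
  demand strong external correlation, so synthetic runs at the default
  noise level report `gt_pass = False` while higher-signal fixtures pass.
* **o3** counts training compounds with |residual| strictly greater than
  3·S_train.

## Applicability domain

Leverage: inside iff `h_i < h* = 3(d+1)/n_train`. Standardization:
`s_ik = |x_ik − mean_k| / sd_k` over the model's d training columns
(absolute values — the ≤ 3 comparisons are magnitude rules); inside if
`max s_ik ≤ 3`, else if `min s_ik < 3` the fallback
`s_new = mean(s_ik) + 1.28·sd(s_ik)` decides at ≤ 3, else outside.
`sd(s_ik)` is the sample SD (d − 1 denominator) of the d standardized
values; 1.28 is the standard-normal 90th percentile. Zero-variance
training columns cannot be standardized and are excluded with a warning.
For queries drawn from the training distribution the two definitions
agree on ≈98% of compounds (acceptance check at ≥ 90%).

## Synthetic data generator

The generator emulates a curated kinase-inhibitor dataset: defaults are
530 compounds, a 2,000-column pool, an 8-descriptor planted model, noise
0.8 log units, activity range log10(0.8)–log10(145,000) nM, 60% binary
(fingerprint-like Bernoulli) decoys, 2% constant, 3% near-constant
(modal frequency > 95%), 2% missing-valued columns, and 20 collinear
blocks of 3 affine copies. Signal columns are continuous unit-variance
Gaussians; decoys are independent of the response by construction.

Two choices deserve explanation:

* **Activity scaling.** The clean response `b0 + Σ b_k x_k` is
  affine-mapped so its realized range fills the configured activity
  window *before* noise is added (real curated IC50 sets span their
  printed range by definition). A consequence is that the absolute scale
  of the drawn coefficients cancels — only their ratios survive.
* **Coefficient spread.** Planted |b| are drawn within a < 2× band
  (U(0.75, 1.25), random signs; ≈0.22–0.34 log units effective). In a
  selected published model every retained descriptor carries a
  detectable weight — that is what selection *means* — so the generator
  plants comparable contributions. A wide (10×) spread would place the
  weakest planted descriptor near t ≈ 1 at n = 265 after range
  normalization, i.e. statistically invisible to any method, and would
  test nothing but noise.

What the generator does **not** emulate: descriptor semantics (no SMILES,
no chemistry), correlated activity structure across congeneric series,
heteroscedastic assay noise, and the long-tailed, clumped distributions
of real fingerprint counts. Passing tests therefore demonstrate that the
algorithms recover known structure under realistic dimensions and
contamination — not that any particular chemistry is predictable.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use the smallest sizes at which the asserted property
is stable: 100 instances for the RM-vs-exhaustive benchmark, 20 full
study-geometry runs for descriptor recovery, 2,000 permutations /
2,000–5,000 resampling cases for the validation statistics. The
acceptance script scales the same computations for a single-CPU desk run
(15 RM starts, 40 benchmark instances); all statistics it reports are
means that are stable well below publication-scale case counts.

## Known limitations

* Validation/test R² as Pearson² can differ from a coefficient-of-
  determination convention by a few hundredths when predictions are
  biased; both are defensible and the choice is recorded above.
* The prefilter's collinearity scan is greedy in column order; it
  guarantees the kept set is pairwise below threshold but, like any
  greedy rule, the kept *representative* of a collinear group is simply
  the earliest column.
* The RM sweep discipline implemented here is one faithful reading of
  "replace the coefficient with the largest relative error"; other
  variants (e.g. accepting equal-S replacements) exist in the
  literature. The exhaustive-search benchmark bounds what any variant
  could gain.
* BSM leaves k, the clustered feature space, and the within-cluster
  allocation rule open in the literature; all three are explicit config
  here and the defaults are documented above.
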