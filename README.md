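# rmqsar

Replacement-method multivariable linear regression (MLR) QSAR modeling,
built for datasets like the PLK1 (polo-like kinase-1) inhibitor
collections curated from public bioactivity databases: a few hundred
compounds, IC50 values spanning several orders of magnitude, and a very
large pool of precomputed molecular descriptors (constitutional,
topological, E-state, fingerprint bits) from which a small, interpretable
linear model must be selected and defended.

The package is aimed at QSAR practitioners who already have a
compounds × descriptors table (from PaDEL-class software) and want the
complete modeling workflow — selection, validation, applicability domain,
and classification scoring — as tested, scriptable components rather than
a spreadsheet ritual.

## The model and the method

The response is `log10 IC50` (IC50 in nM). For a chosen size *d* the
model is ordinary least squares with intercept,

    log10 IC50 = b0 + Σ_k b_k x_k + ε,   k = 1..d,

scored by the regression standard deviation `S = sqrt(RSS / (n − d − 1))`.
The pipeline stages are:

1. **Prefilter** — drop descriptors with missing values, constant or
   near-constant columns (modal frequency ≥ 0.95), then one of each
   collinear pair (pairwise r² ≥ 0.998, earlier column kept).
2. **Balanced subsets split (BSM)** — k-means on the autoscaled pool;
   every cluster is spread across train/validation/test (50/25/25), the
   members closest to each centroid calibrating the model. N = 530 gives
   265/133/132.
3. **Replacement method (RM)** — from a random *d*-subset, repeatedly
   replace the descriptor whose coefficient has the largest relative
   error |SE(b)/b| with the pool column that most reduces `S_train`,
   sweeping until no replacement helps; best model over many starts. A
   ladder of sizes d = 1…9 is fit and the smallest *d* whose validation S
   is within 0.01 of the ladder minimum is selected.
4. **Validation** — leave-one-out and leave-30%-out cross-validation,
   Y-randomization (`S_rand > S_train` required), Golbraikh–Tropsha
   external criteria, o3 outlier count (|residual| > 3·S_train).
5. **Applicability domain** — leverage approach (inside iff
   h_i < h* = 3(d+1)/n) and standardization approach
   (max |s_ik| ≤ 3, fallback `s_new = ⟨s_i⟩ + 1.28·σ_si ≤ 3`).
6. **Classification** — IC50 ≤ 1000 nM counts as highly active; Cooper
   statistics (A%, SE, SP) and the Matthews correlation coefficient.

Because the original per-compound descriptor tables of published PLK1
models are not redistributable, the package ships a synthetic-data
generator (`rmqsar.synthetic`) that reproduces the *statistical* shape of
such a dataset — pool size, contamination (constants, near-constants,
missing values, collinear blocks, binary fingerprint-like columns),
activity range 0.8–145,000 nM, and a planted linear signal with known
coefficients — so every stage is testable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic dataset (seed 1), writing tables under `results/`:

```bash
python analysis/01_generate_dataset.py
python analysis/02_prefilter_pool.py
python analysis/03_split_subsets.py
python analysis/04_model_ladder.py
python analysis/05_validation.py
python analysis/06_applicability_domain.py
python analysis/07_classification.py
```

Output of the ladder step:

```
 d  r2_train  s_train  r2_val  s_val  r2_test  s_test  selected
 1     0.100    1.122   0.075  1.097    0.010   1.282     False
 ...
 8     0.523    0.828   0.441  0.874    0.499   0.927      True
 9     0.543    0.812   0.433  0.885    0.477   0.946     False

selected d = 8: log10IC50 = -0.254*E00125 -0.381*E00136 ... +2.280
planted descriptors recovered: 8/8
```

`S_train` falls monotonically with *d* (more descriptors always fit the
training set better), but the validation S bottoms out at d = 8 — the
planted size — and the parsimony rule stops there; all eight planted
columns are recovered from the 1,812-column filtered pool. The validation
step then reports `s_train 0.828` against the generating noise of 0.8
log units, `s_rand 1.181` (scrambled responses fit far worse — the model
is not a chance correlation), and the AD step prints `h* = 0.1019` with
the two AD definitions agreeing on 98.5% of test compounds. The final
classification step scores the test set at the 1000 nM cutoff
(A% = 78.0, MCC = 0.51 for this seed).

The same workflow runs on real data from the shell:

```bash
rmqsar run descriptors.csv activities.csv --d-range 1-9 --out-dir out/
```

or stage by stage (`rmqsar generate|prefilter|split|search|validate|ad|classify`).

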