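# Methods

This note documents the models, parameter choices and numerical decisions
behind `pparqsar`, and what the synthetic-data generators do and do not
emulate.

## Dose-response model suite

All eight continuous families share the form

    m(x) = a · (1 + (c − 1) · F(x; b, d)),

with background `a` (fold-induction at dose 0, ≈ 1 for data normalized to
solvent control), plateau fold-change `c` (the curve saturates at `a·c`),
dose-scale `b` (µM) and dimensionless shape `d`. `F` is a saturating
CDF-like function with F(0) = 0, F(∞) = 1:

| family | F(x) |
|---|---|
| exponential | 1 − exp(−(x/b)^d) |
| inverse exponential | exp(−(b/x)^d) |
| Hill | x^d / (x^d + b^d) |
| log-normal | Φ(d·ln(x/b)) |
| gamma | P(d, d·x/b) (regularized lower incomplete gamma) |
| quadratic exponential | 1 − exp(−(u + d·u²)), u = x/b |
| probit | (Φ(d(x/b − 1)) − Φ(−d)) / (1 − Φ(−d)) |
| logit | as probit with the logistic CDF |

The probit and logit families act on the raw dose axis and are shifted and
renormalized so F(0) = 0 exactly; a log-dose probit would duplicate the
log-normal family. For a ratio-type benchmark response (`bmr`, default 1.5:
the concentration producing 1.5-fold induction over background, the common
positive-classification threshold for luciferase reporter systems), the BMD
solves F(BMD) = (bmr − 1)/(c − 1), which has a closed form for every family.
When the plateau never reaches the BMR (c ≤ bmr) the BMD is reported as
NOT_REACHED (+∞ draws in the posterior). The background in the BMR
definition is the modelled `a`, not the literal solvent-control mean — the
two coincide in expectation since responses are fold-inductions.

### Noise models and likelihood

Each family is fitted under two distributional assumptions (16 candidates in
total): normal noise, y ~ N(m(x), σ), and log-normal noise,
ln y ~ N(ln m(x), σ), so m(x) is the median response in both cases and the
BMD definition is noise-model invariant. Log-normal candidates require
strictly positive responses; when a dataset violates this, the candidate is
assigned zero weight rather than aborting the compound.

### Priors, sampling and model averaging

Parameters are sampled on the unconstrained scale
θ = (ln a, ln(c−1), ln b, ln d, ln σ) with independent normal priors:
ln a ~ N(0, 0.5), ln(c−1) ~ N(ln 20, 1.5) (plateaus of ~30–40-fold are
typical for strong agonists in this assay), ln d ~ N(0, 0.5),
ln σ ~ N(−1, 1.5), and ln b ~ N(ln g, 2.5) where g is the geometric mean
tested concentration. Centring the dose-scale prior on the design makes
noise-free fits equivariant under rescaling of the concentration axis
(multiplying all concentrations by κ multiplies BMD, BMDL, BMDU by κ),
which is verified in the tests.

Each candidate is optimized to its MAP (multi-start Nelder-Mead polished by
BFGS) and sampled with the affine-invariant ensemble sampler (`emcee`,
10 walkers initialized in a tight ball around the MAP). Defaults are 20,000
total draws with the first 10,000 discarded as warmup; tests and the
acceptance script run a reduced 4,000/2,000 protocol, which recovers
generating BMDs with ~10% median absolute relative bias at the assay's 3×3
replicate structure and is the package's chosen trade-off between Monte
Carlo error and runtime. Split-R̂ and bulk ESS per parameter are recorded
per candidate.

Averaging weights are posterior model probabilities from a Laplace
approximation to each candidate's marginal likelihood (equal prior model
weights): log p(y|M) ≈ log p(y|θ̂) + log p(θ̂) + (k/2)·ln 2π − ½·ln|H| with H
the Hessian of the negative log posterior at the MAP. A non-positive-definite
Hessian (flat or ridge-shaped posteriors) falls back to a BIC-style penalty
so the candidate is down-weighted, never fatal. The averaged BMD posterior
is the weight-mixed pool of per-draw closed-form BMDs; BMDL/BMDU default to
its 5th/95th percentiles (the one-sided 95% convention; 2.5/97.5 available
via `quantiles`). Weighted quantiles use the midpoint-interpolation
convention, so an equal mixture of pools symmetric about 1 and 3 has median
exactly 2.

### Trend gate

BMD estimation is only attempted when a one-sided t test on the slope of
biological-replicate mean responses regressed on dose ranks rejects at
α = 0.05. Technical replicates are collapsed first so pseudo-replication
cannot inflate the test; under a flat curve with i.i.d. normal noise the
empirical type-I error matches α (verified by simulation). Rank transform
makes the gate invariant to the (log-spaced) concentration grid.

## Cytotoxicity gating

A concentration is cytotoxic when viability falls below 80% of the untreated
control or at least 10 percentage points below the next smaller tested
concentration. The drop rule is interpreted in absolute percentage points by
default; a `drop_rule="relative"` switch interprets the threshold as percent
of the preceding value, since the points-vs-relative reading is a genuine
ambiguity. Once any concentration is cytotoxic, all higher concentrations
are treated as cytotoxic (prefix rule), so apparent recovery at a higher
dose never extends the usable range. Reporter normalization divides each
well's FLuc/RLuc ratio by the mean solvent-control ratio of the same
biological replicate — each plate carries its own controls, the standard
dual-luciferase convention.

## Descriptors and cleaning

Four blocks are computed from the SMILES as tested (salt forms kept; no
neutralization or desalting):

- `maccs:` — the 166 predefined MACCS substructure keys (binary).
- `ecfp:` — hashed circular fingerprints, radius 3. The bit length is not
  structurally fixed; 2048 is the default and is configurable. Distinct
  substructures can collide on one bit, which is why screening output
  carries a collision-review flag (below).
- `autocorr:` — 2D topological autocorrelations written from the standard
  formulas: Broto-Moreau ATS/AATS (raw), centered ATSC, and Geary GATS at
  lags 1–8, weighted by Kier-Hall valence electron count (dv),
  Gasteiger-Marsili partial charge with hydrogen charges folded into heavy
  atoms (c), tabulated static atomic polarizability (p), and atomic mass
  (m). AATS/GATS are NaN when a molecule has no atom pair at the lag; the
  cleaning cascade removes such columns. Named members such as AATS5dv,
  ATSC5dv, ATSC6c and GATS5p are therefore available as modelling features.
- `phys:` — the RDKit physicochemical descriptor set (~210 features,
  including TPSA).

Cleaning is a fixed, order-stable cascade: (1) drop any column containing a
non-finite value; (2) drop low-variance columns — variance < 1e−8 or a
single value covering ≥ 95% of rows (thresholds chosen on the synthetic
panels; the dominant-value rule is what removes near-constant fingerprint
bits); (3) greedy correlation pruning in column order — a column is dropped
when |Pearson r| > 0.9 against any earlier surviving column. The cascade is
idempotent and emits a (feature, reason) removal manifest. Continuous
survivors are z-scored against the training rows; binary features keep
their 0/1 coding with an identity scaler (the linear model and leverage are
affine-equivariant, and the bounding box is equivalent under z-scoring, so
this choice only affects coefficient units).

## Feature selection

The GA encodes subsets as binary chromosomes. Fitness is
−MAPE_cv(%) − λ·(#selected), where MAPE is computed from 5-fold
cross-validated linear fits on log BMD, scored on back-transformed µM
predictions against observed BMDs. Compounds without an estimable BMD
(gated by trend or NOT_REACHED) are excluded upstream. Folds are
re-randomized for every individual from a child RNG stream derived from
(seed, generation, index), so evaluations are order-independent and a
parallel map would reproduce the serial result. λ defaults to 0.5 MAPE
percentage points per feature — large enough that an uninformative feature
(which cannot buy 0.5 points of CV error) is rejected, small enough not to
mask genuine signal; selected-subset size is non-increasing in λ on a fixed
problem (tested).

Defaults: population 300, tournament size 3, uniform crossover p = 0.75,
per-individual bit-flip mutation p = 0.25 (expected one bit flipped),
elitism 3 (elites keep their recorded fitness, which makes the best-so-far
trace exactly monotone), initial bit density 0.03, stop after 30 generations
or 10 without improvement. Roulette selection, two-point crossover and a
Gaussian-count mutation (flip ⌈|N(0,1)|⌉ random bits) are available behind
the same interface but are not defaults. On planted 2-of-141 problems at
n = 34 the GA recovers the planted pair in ≥ 8/10 seeds, and exhaustive
search over all 1- and 2-feature subsets confirms the pair is CV-optimal.

## QSAR model and validation

The final model is unpenalized least squares on the natural log of the BMD
over the selected standardized descriptors (log base only rescales
coefficients; predictions are invariant). Predictions are exp-transformed,
hence strictly positive. R² = 1 − SS_res/SS_tot, MAE and RMSE are computed
on the µM scale and may make R² negative for bad models. Cross-validation
uses a fixed, documented seed distinct from the GA's internal splits; each
compound is predicted exactly once by a model not trained on it.
y-randomization refits after permuting the response (20 repeats by default)
and reports mean metrics; on any dataset with real signal the permuted cv
R² collapses below zero. A ridge option (`fit(..., ridge=λ)`, slopes
penalized, intercept free) exists but is off by default: with ≤ 10 selected
features per ~30 compounds, shrinkage obscures the coefficient
interpretation that motivates the linear architecture.

The model artifact (JSON) stores feature names, coefficients, intercept,
the raw-scale scaler, the standardized training design snapshot, the
training BMDs, and metadata — everything prediction and AD assessment need.

## Applicability domain

Both criteria operate on the model's selected standardized descriptors
only. The bounding box accepts a row when every feature lies within the
training [min, max] inclusive. Leverage is h = xᵀ(XᵀX)⁻¹x on the training
design without an intercept column (the design is centered by
standardization, so the centroid has h = 0 and training leverages sum to
p); the critical value is h* = 3(p+1)/n — the +1 keeps the conventional
intercept count even though no intercept column enters X, matching the
formula as commonly printed. A compound is in-domain only when both
criteria pass; the verdict object records every intermediate value, and a
singular XᵀX falls back to the pseudo-inverse with a warning rather than
failing a screen. Non-finite descriptor values are automatically
out-of-domain with a reason code.

## Screening

Batch screening featurizes in batches (memory bounded in batch size,
results identical to all-at-once), projects with the stored scaler,
predicts, and assesses the AD. Every input id appears exactly once in the
output; unparseable SMILES become failure records. Records whose selected
circular-fingerprint bits are set *and* carry negative coefficients (i.e.,
the bits pull the prediction toward low BMD) are flagged
`collision_check=True`: a colliding substructure could fake potency, so
such hits warrant manual substructure verification. Ranked output excludes
out-of-domain records, with ties broken by id.

## Synthetic data: what it emulates, what it does not

The curve generator inverts the same eight families used in fitting, so a
noise-free curve passes exactly through (true BMD, 1.5 × background);
defaults mirror the assay design: 7 half-log-spaced concentrations from
0.1 µM, 3 biological × 3 technical replicates, background ≈ 1, plateaus of
~30-fold, normal (additive) or log-normal (multiplicative) well noise.
It does **not** emulate plate effects, within-biological-replicate
correlation, cytotoxicity-truncated tops varying per compound, or
solubility artefacts — so passing recovery tests show correctness of the
estimation machinery under the stated noise model, not robustness to every
real-assay pathology.

The planted-matrix generator produces mixed binary/continuous features
(first `n_binary` columns Bernoulli(0.3), rest standard normal) with a
sparse linear signal on log BMD (default intercept 3.0 ≈ 20 µM) and
optional feature pairs at a requested correlation; it stands in for a
cleaned modelling matrix (34 × 141 by default) but carries none of the
block structure or discreteness of real fingerprints. The PFAS-like SMILES
series are homologous templates (perfluoroalkyl carboxylic/sulfonic acids,
their mono-ether analogues, n:2 fluorotelomer sulfonic acids) — valid
chemistry for exercising featurization and screening, not a reproduction
of any experimental panel.

## Numerical choices and degenerate inputs

- Closed-form BMD inversion throughout; the quadratic-exponential root uses
  the numerically stable form 2L/(1 + √(1+4dL)) as d → 0.
- Empty chromosome → fitness −∞ sentinel; all-candidates-failed → flagged
  result, not an exception; zero-variance columns reaching standardization
  raise, because they indicate a skipped cleaning step.
- Correlation pruning keeps the earlier column of a violating pair — a
  deterministic tie-break; with a fixed input column order the output
  feature set is fixed.
- Seeds: every stochastic component takes an explicit seed; per-candidate
  and per-individual streams are derived so results are independent of
  evaluation order.

## Problem sizes used in tests and the acceptance run

MCMC at 4,000/2,000 (reduced from the 20,000/10,000 defaults); BMD recovery
over 20 curves in tests and 12 in the acceptance script; trend-gate
calibration over 1,000 null curves; GA recovery over 10 (tests) or 5
(acceptance) seeds at population 300; the exhaustive selection oracle
enumerates all 10,011 subsets of size ≤ 2 over 141 features.

## Known limitations

- Laplace weights assume a roughly Gaussian posterior per candidate; for
  weakly identified shape parameters (few dose groups, no plateau) the
  approximation is crude, though failures degrade to down-weighting. WAIC
  weighting would be a drop-in alternative behind `model_average`.
- Ensemble-walker R̂/ESS are computed across walkers of one ensemble, which
  are not independent chains; treat them as mixing indicators, not strict
  convergence guarantees.
- The hand-written autocorrelation descriptors follow the standard formulas
  but specific numeric values depend on conventions (hydrogen folding,
  polarizability table) and will not match other descriptor software
  bit-for-bit; models should be trained and applied with this package's own
  featurization, which is deterministic.
- The trend gate's linear-contrast-on-ranks test is one reasonable choice;
  compounds near the significance boundary may gate differently under other
  monotone-trend tests (e.g. Jonckheere-Terpstra).
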