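# Methods

## Scope and data model

The package benchmarks multiclass SVM classification of neuron morphometry
tables under combinations of feature rescaling, dimensionality reduction,
and kernel choice (classical and quantum).  A table has one row per neuron,
an M-type label from a 14-class vocabulary (six principal-cell types, six
interneuron types, two glial types), and 43 positive-valued scalar features
in the style of L-Measure morphometrics, with `Soma_Surface` as the first
column.  Real NeuroMorpho-derived tables are not redistributable here, so
the package ships a synthetic generator that reproduces the *statistical
shape* the analysis assumes; every result the test suite reports is a
property of the method on that synthetic family, not a claim about real
neurons.

## Synthetic morphometry generator

`SyntheticSpec` fixes the study conditions: `n_neurons` (presets 260 / 626 /
1,143 / 2,080 / 22,691 mirror the five benchmark sample sizes),
`n_classes = 14`, `n_features = 43`, `n_informative = 5`,
uniform class proportions by default, and a root seed.  One seed feeds four
independent child streams (labels, informative-feature choice, feature
draws, artifact injection), so e.g. injecting artifacts never perturbs the
feature draws.

Features are shifted log-normals, reflecting the positivity and right skew
of morphometric lengths/surfaces:

* each *informative* feature assigns every class its own log-location level;
  levels are spaced 2.0 apart in log space against a within-class log-sd of
  0.4 (5 within-class standard deviations, comfortably above the ≥ 1 sd
  separation the generator promises), and the class → level assignment is an
  independent seeded permutation per feature so informative features are not
  redundant copies;
* *nuisance* features are class-independent log-normals with per-feature
  magnitudes.

Artifact injection marks `floor(rate · n)` rows per kind, with the three row
sets disjoint: one missing cell per marked row, `Soma_Surface` set to exactly
0, and outlier rows rewritten to sit 10 robust standard deviations from
their class mean in every feature (the displacement unit is
`max(MAD-based sd, classical sd)` per feature — the classical-sd floor makes
heavy-tailed features register as multivariate outliers under a fitted
covariance while still being ≥ 8 robust sds).  Ground-truth indices are
returned with the table.

What the generator does **not** emulate: realistic marginal distributions of
real L-Measure features, allometric correlations between features, class
imbalance, and label noise.  Because each informative feature separates all
14 classes on its own, the synthetic task is *easier* than real morphometry:
near-perfect accuracies on it demonstrate that the pipeline recovers planted
structure, not that quantum kernels reach any particular accuracy on real
neurons.

## Filtering

Filters run in a fixed order — rows with missing cells, rows with soma
surface exactly 0 (strict equality; 1e-12 survives), then a Mahalanobis
outlier filter — and the combined report reconciles exactly.  Mahalanobis
distances are measured to the global column mean with a Ledoit–Wolf
shrinkage covariance (default, since 43 features dwarf the smaller sample
sizes; plain empirical covariance is available and refuses singular cases).
The cutoff is the chi-squared quantile with `n_features` degrees of freedom
at `1 − alpha`, `alpha = 0.025` by default and configurable — the filter is
dataset-level, not per class.  The chi-squared calibration is exact only for
Gaussian data; on the log-normal synthetic family it is conservative in the
sense that planted 10-sd outliers are always beyond it while the fraction of
clean rows removed stays near the nominal tail.

## Rescalers

Eleven transforms behind one fit/apply interface; all parameterised methods
estimate on training data only.  Conventions worth noting:

* **robust**: `(x − Q1)/(Q3 − Q1)` — the first quartile in the numerator is
  the printed form of this analysis and is kept as the default;
  `center="median"` gives the conventional variant.
* **quantile maps**: the empirical quantile table uses `min(1000, n)`
  uniformly spaced probabilities; CDF values are clamped to
  `[1/(2n), 1 − 1/(2n)]` to avoid infinite normal quantiles.  The normal
  target maps p through `μ + σ·√2·erfinv(2p − 1)` (the exact N(μ, σ²)
  quantile function); the uniform target through `a(1−p) + bp` with
  `a = 0, b = 1` by default.
* **lognormal**: `Φ(ln x / σ)` for `x ≥ 0`, with `F(0) = 0` as the limit
  value and `σ = 1` by default (configurable; the choice is free in this
  formulation).
* **Box-Cox / Yeo-Johnson**: per-feature maximum-likelihood λ via
  `scipy.stats`; Box-Cox refuses non-positive data.  Yeo-Johnson uses the
  standard four-branch definition.
* Constant features pass through unchanged with a warning wherever a
  denominator would vanish.

## Feature selection and extraction

Tree importances are total Gini-impurity decreases normalised to sum to 1
(`Gini = 1 − Σ p_i²`).  Ensembles default to 100 trees, seeded; the
gradient-boosted variant uses XGBoost with total-gain importance.  `top-k`
selection sorts by importance descending with ties broken by ascending
feature index and is a pure function of the importance vector.

The 14 extraction methods are thin adapters over scikit-learn, reduced to 2
components by default.  Methods without an out-of-sample transform (t-SNE,
MDS, the LLE family, Isomap as configured here) are flagged *transductive*:
the benchmark fits them on the full rescaled design matrix before splitting
and logs the leakage caveat loudly, because no non-leaking fold treatment
exists for them.  "ICA with PCA" is interpreted as PCA whitening followed by
FastICA.

## The quantum kernel engine

Encoding: `|psi(x)> = (D(x) H^{⊗n})^reps |0^n>` with
`D(x) = exp(i Σ_S φ_S(x) Π_{i∈S} Z_i)`, one qubit per feature, `reps = 2`
and full pair entanglement by default.  Singleton phases are `φ_i(x) = x_i`
for every encoding; the seven pair phases are listed in the module
docstring.  The "default" product-form map coincides with the zz map on
pairs, and is kept as a distinct name so benchmark rows stay comparable.
The `k11` encoding `π/(3 cos x_i cos x_j)` is singular where a cosine
vanishes; the engine refuses (rather than clamps) and expects the caller to
rescale inputs into a bounded interval first, which every benchmark grid
does.

Because `D` is diagonal, a state needs only a phase table over the `2^n`
basis states (entry for basis state b:
`Σ_i φ_i(x)(−1)^{b_i} + Σ_{(i,j)} φ_ij(x)(−1)^{b_i+b_j}`) and one fast
Walsh–Hadamard transform per repetition — `O(reps · n · 2^n)` amplitude
updates per sample, which the engine counts in
`quantum_kernels.OPS` so the cost model is testable without wall-clock
assertions.  Bit i of the basis index is qubit i's Z bit with qubit 0 least
significant; fidelities are ordering-invariant but the dense-oracle tests in
the suite pin the convention.

Exact mode caches statevectors (blocked against a 2 GiB default memory
budget, recomputing per block above it) and mirrors the upper triangle, so
exact Grams are symmetric to the last bit, unit-diagonal, and PSD up to
eigensolver noise.  Shots mode replaces each off-diagonal entry with a
binomial draw frequency `m/shots` at the exact fidelity (1024 shots by
default, the hardware-realistic setting), fixing the diagonal at 1 — an
unbiased emulation of all-zero-outcome frequency estimation that reproduces
the `p(1−p)/shots` variance law.  `psd_projection` repairs shot-noise
indefiniteness by eigenvalue clipping with diagonal renormalisation and
passes already-PSD matrices through unchanged.

## Quantum kernel alignment

The trainable family replaces the first Hadamard-prepared layer with a
fiducial state `U_λ|0^n>`, one R_y rotation per qubit (a shared scalar λ
broadcasts).  `λ = π/2` reproduces the plain feature map exactly
(`R_y(π/2)|0> = H|0>`), and is the default starting point for training;
`λ = 0` is the trivial fiducial used as a baseline, regression-pinned in the
tests.  This state-preparation reading of the fiducial is an interpretation
choice; alternatives (e.g. appending `U_λ` after the full map) would define
a different but equally valid kernel family.

The alignment loss is the attained soft-margin SVM dual objective
`Σα − ½ ΣΣ α_i α_j y_i y_j K_ij` (SVCLoss); the quadratic program is
delegated to scikit-learn's SVC and the objective assembled from the
returned dual coefficients.  Multiclass problems sum the one-vs-one binary
losses under a shared λ — the reduction is unspecified in this formulation,
and one-vs-one was chosen to match the multiclass SVM itself.  Minimisation
is SPSA with *constant* gains honouring the printed settings (maxiter 10,
a = 0.05, c = 0.05); a decaying-gain variant sits behind
`QKAConfig(gain_decay=True)`.  Each iteration draws a Rademacher direction
and evaluates the objective twice; the trace records every evaluation
(2·maxiter + 2 including the initial and final points) and the
best-evaluated λ is returned, so training can never end worse than it
started.  C defaults to 1.0 everywhere.

`planted_alignment_problem` constructs the diagnostic task for alignment: a
pool of uniform points in [0, 1]² labelled by the top eigenvector of the
double-centred kernel *difference* `K_{π/2} − K_0`, keeping the strongest
half of each side.  By construction the classes cluster under the
Hadamard-equivalent fiducial and anti-cluster under the trivial one, so the
aligned kernel has a genuine margin to gain over `λ = 0`.

## Classical kernels and evaluation protocol

The four classical kernels (linear; RBF `exp(−‖·‖²/2σ²)`; polynomial
`(x·z + a)^b`; sigmoid `tanh(a·x·z − b)`) are emitted as precomputed Grams
through the identical SVM path as the quantum kernels.  Unstated parameters
resolve from data: `1/(2σ²) = 1/(d·Var)`, `a = 1, b = 3` for the
polynomial, `a = 1/d, b = 0` for the sigmoid; all configurable and recorded.

Multiclass SVM is one-vs-one on the precomputed Gram with majority voting;
a pair's decision value of exactly zero (e.g. an all-zero kernel row) votes
the lower class, and vote ties resolve to the lowest class index, so
prediction is fully deterministic.  The protocol is a stratified 80/20
holdout followed by stratified 5-fold cross-validation on the training
partition; the report carries the fold scores, their mean, standard
deviation, and the 95% CI half-width `1.96·sd/√k` (both dispersion measures
are emitted because conventions differ).  Stratification is a deliberate
choice: with 14 classes at the smaller sample sizes, unstratified folds
degenerate.

The benchmark grid crosses rescalers × reducers × algorithms (default
extraction grid: 11 × 14 = 154 cells per algorithm; selection grid:
11 × 3).  Cells that fail — Box-Cox on non-positive data, the k11
singularity, LDA with too many components — are recorded as error rows and
never abort the run.  Exact statevector cells refuse more than 10 qubits or
2,080 samples; these desk-scale presets keep a full grid runnable on one
workstation core and can be lifted in code.

## Problem sizes used in the checks

The shipped test suite exercises: 1–6 qubit engines against dense
matrix-exponential oracles (25 random pairs per encoding per size); a
200-row, 14-class end-to-end run (rank-uniform rescale → decision-tree
top-5 → 5-qubit zz kernel, 5-fold CV); a 300-row artifact-reconciliation
table; 1,000 seeded shot-sampling repeats at 1024 shots; and a 24-point
alignment problem at the printed SPSA settings.  Sample-size trend checks
run the fixed pipeline at n = 100–1,000 with 3-fold CV (3 folds keep the
smallest class usable at n = 100).

## Known limitations

* The synthetic family is easier than real morphometry (see above); absolute
  accuracies do not transfer.
* Shot-sampled Grams model binomial counting noise only — no device noise,
  readout error, or transpilation effects.
* The fiducial ansatz is a single R_y layer; richer covariant ansätze are
  out of scope.
* Transductive embeddings unavoidably leak across folds and are flagged
  rather than fixed.
* Box-Cox cells fail by design on rescaled data containing non-positive
  values; the grid records rather than repairs this.
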