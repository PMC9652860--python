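# Methods

## Setting and data contracts

The pipeline targets small paired-omics tumor cohorts: each sample carries a
protein-expression vector and a phosphosite-expression vector (both
normalized upstream, no missing values), a state label (1 = primary tumor,
2 = metastatic tumor), and observed drug responses as tumor cell growth
inhibition (TCGI, percent).  Candidate kinase→phosphosite relations come
from a static catalogue table using the public kinase–substrate dataset
column names (`KINASE`, `SUB_GENE`, `SUB_MOD_RSD`); live database queries
are out of scope.  Phosphosite identifiers follow the `GENE_RESIDUEPOS`
convention (`GSK3B_S9`) so the catalogue join is deterministic — uploads
using a different site syntax must be mapped before ingestion.

Cohort alignment keeps the intersection of molecules present in every
sample (dropped molecules are logged); imputation is deliberately absent
because the input contract forbids missing values.  A kinase contributes
edges only through the protein layer; substrate sites only through the
phosphosite layer.

## Edge strength

For an edge (kinase u, site v), sample j in state k:

    s_j = (x_ujk − μ_uk)/σ_uk · (x_vjk − μ_vk)/σ_vk

with per-state mean μ and per-state *sample* standard deviation σ
(ddof = 1).  The ddof choice is not arbitrary: with it, the within-state
sum of one edge's strengths equals (n_k − 1) times the within-state Pearson
correlation of the two molecule columns, so the edge matrix decomposes
state-level co-expression into per-sample contributions.  Consequences
used as test invariants:

* positive within-state affine transforms of any molecule leave strengths
  unchanged (≤ 1e-10 numerically);
* negative scaling flips the affected strengths' signs (bit-exact at scale
  −1, rounding-level otherwise);
* a sample sitting exactly at its state mean annihilates every edge through
  that molecule.

Each state group needs ≥ 2 samples for σ; molecules constant within a state
are flagged at statistics time and only become an error if an edge actually
needs them.  New patients are standardized against the **frozen** training
cohort μ, σ of their declared state: predictions are then deterministic per
patient and independent of upload order.  A pooled alternative
(re-estimating statistics with the patient included) is available as
`pooled_reference_stats` / the CLI `--pooled` flag; the state of a new
patient is always an explicit input, never inferred.

## Screening

Two optional, composable pre-filters reduce the candidate edge set:

* **Differential correlation (DCP):** a pair is selected when
  |r₁ − r₂| ≥ 0.5 (within-state Pearson correlations) and the Fisher-z
  two-sided p for the difference is ≤ 0.05 (both thresholds configurable;
  each state needs ≥ 4 samples).  No multiple-testing correction is applied
  across candidates — the screen is a pre-filter, not an inference.
* **Response correlation:** keep edges with |r(strength, TCGI)| above a
  threshold, or the top-m by |r| with a deterministic tie-break
  (|r| descending, then edge id ascending).

Both default to off; a deployment can also restrict candidates to a fixed
reference edge list (plain text, one edge id per line).

## Edge-biomarker selection

Defaults (all configurable in `SelectionConfig`): 100 random train/test
splits at test fraction 0.3, stratified on state so neither side of a split
is single-state; α grid 0.0–1.0 in steps of 0.1; λ per α chosen by 5-fold
cross-validation over a 100-point log-spaced path from λ_max (the smallest
λ zeroing all coefficients; computed with α floored at 1e-3 so a
ridge-leaning grid still gets a finite path) down to λ_max·1e-3; features
standardized within each training set before fitting, with coefficients
mapped back to the original edge-strength scale.  The globally
minimum-test-MSE (split, α, λ) refit defines the selected edges (nonzero
coefficients).  An alternative aggregate rule — pick the α with the
smallest *median* test MSE over splits, then its best split — is available
(`mse_rule="median_per_alpha"`) but not the default, since the minimum-MSE
reading matches the selection rule as stated.  The entire (split, α) trace
(chosen λ, test MSE, support size) is retained in the result, and a fixed
seed yields a bit-identical result.

The split/test-fraction/fold/α-step values beyond the 100 repeats are
conventions chosen here and documented as defaults; nothing in the
procedure depends on them structurally.

## Elastic-net solver

Objective: (1/2n)·Σ(y − β₀ − Xβ)² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²).  The solver
is cyclic coordinate descent on the Gram formulation (cost per sweep
independent of n), numba-compiled, with the standard path-solver devices:
warm starts along the descending λ path, an incrementally maintained
gradient vector (O(p) per coordinate update and per KKT evaluation),
active-set sweeps between full sweeps, and — for cross-validation paths
only — early path exit once the support can interpolate the training fold
(df ≥ n_fold − 1), where further path points are interpolating noise.
Convergence is declared on the KKT subgradient residual, not just on
coefficient stagnation.  CV paths run at tolerance 1e-5–1e-6 (scaled by the
response SD); the refits that define supports and final models run at
1e-8–1e-10.  λ = 0 is solved exactly by (minimum-norm) least squares.
Correctness is established in the tests against three independent oracles:
the closed-form normal equations in the λ→0 limit, a direct KKT-residual
check (< 1e-6), and scikit-learn's `ElasticNet` on identical problems.

## Drug model and evaluation

The final per-drug model refits on *all* cohort samples at the selection's
(α, λ), restricted to the selected edges, and stores its feature
standardization constants so prediction is self-contained.  "R-squared" in
evaluation output is the squared Pearson correlation between predicted and
observed TCGI (with the two-sided t-based p-value, df = n − 2); the
coefficient of determination is reported separately (`cod`) because the two
differ for biased predictions.  Predictions are not clipped to [0, 100] by
default — shrinkage naturally produces a narrower predicted scale than the
observed one — with clipping available behind a flag.

## Synthetic cohorts

`SynthConfig` defaults define the reference study conditions: 31 samples
(16 primary / 15 metastatic), 20 kinases, a 53-relation catalogue with
3 informative edges of coefficients (3, −2, 1.5) among 50 decoys,
within-state kinase–site correlation 0.7 for informative pairs, expression
measurement noise SD 0.05 on roughly unit-scale profiles, response noise
SD 0.1, TCGI intercept 50%.  Kinase profiles are per-state standard-normal
latents mapped through per-(molecule, state) affine transforms (baseline
~N(10, 2), scale ~U(0.8, 1.2)); an informative site is
ρ·z_kinase + √(1−ρ²)·ε so its true within-state correlation is exactly ρ;
decoy sites are independent; the protein layer also carries independent
profiles for the substrate genes so the join is actually exercised.

TCGI is linear in the cohort's *computed* edge strengths for the
informative edges plus Gaussian noise.  Tying the response to the
pipeline's own feature definition is intentional: the planted optimum then
lies inside the fitted model class, so a recovery failure indicts the
pipeline, not model mismatch.  The flip side bounds what passing tests
show: real cohorts offer no such guarantee — true response–pathway
relationships are not linear in z-score products, catalogues are incomplete
and noisy, and proteome-scale dimensionality, batch effects and missingness
are all absent from the generator by design.  Recovery rates measured here
are upper bounds on, not estimates of, real-data performance.

## Numerical and degenerate-input policy

Zero-variance molecules raise typed errors only where standardization is
actually required; zero-variance inputs to correlation raise
`DegenerateInputError`; |r| = 1 inputs to Fisher's z are clipped just inside
(−1, 1).  Ties in the λ path CV pick the largest λ; ties in the global MSE
rule pick the earliest (split, α) record.  All randomness flows from a
single integer seed through `numpy.random.default_rng`; the solver is fully
deterministic (cyclic sweeps, no random coordinate order), so equal seeds
give byte-identical artifacts.

## Problem sizes used in the checks

The verification suite runs the full default selection (100 splits × 11 α ×
5-fold CV × 100-λ paths) on cohorts of n = 31–44 samples and 53 candidate
edges, across 50 seeds for the recovery-rate criterion and 15 seeds per
response-noise level {1.0, 0.3, 0.1} for the noise-monotonicity check; the
permutation validation of the Pearson p-value uses 200 000 permutations per
instance at n = 50–120, where the t null is in its validity regime.

## Known limitations

* The catalogue is trusted as given: no confidence weighting, no de novo
  kinase–substrate inference, no merging policy across source databases.
* Selection MSE is an optimistically biased estimate of generalization
  error (the minimum over many fits); no nested cross-validation is
  performed, matching the procedure as specified.
* Exactly two states are supported; the state of a prediction-time patient
  must be declared.
* The elastic-net λ path and α grid are finite; a true optimum between grid
  points is approximated by its nearest grid neighbor.
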