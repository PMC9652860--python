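# edgeqnet

Kinase–substrate **edge biomarkers** for predicting tumor drug response from
paired proteomic and phosphoproteomic profiles.

Single-molecule ("node") biomarkers often fail on heterogeneous tumor
cohorts; the interactions *between* molecules carry discriminative signal
that individual abundances miss.  `edgeqnet` implements an edge-biomarker
pipeline for small two-state tumor cohorts (state 1 = primary, state 2 =
metastatic): it converts each catalogued kinase→phosphosite relation into a
per-sample quantitative feature, selects the predictive edges with a
repeated-split elastic net, and fits per-drug regression models for tumor
cell growth inhibition (TCGI, percent) — the drug-response readout of
miniPDX-style assays.

## The model

**Edge strength.**  For kinase *u* (protein layer), substrate phosphosite
*v* (phosphosite layer), sample *j* in state *k*:

```
edge⟨u−v⟩ₖ(j) = (x_ujk − μ_uk)/σ_uk · (x_vjk − μ_vk)/σ_vk
```

where μ and σ are the mean and sample standard deviation (ddof = 1) of the
molecule within state *k*.  The feature is the product of two within-state
z-scores: positive when kinase and substrate deviate from their state
baselines together, negative when they deviate oppositely.  Summed over the
samples of one state it equals (n_k − 1) · r, the within-state Pearson
correlation — the edge matrix is an additive per-sample decomposition of
co-expression, which the test suite verifies to 1e-10.

**Edge-biomarker selection.**  Candidate edges (catalogue relations whose
kinase is measured at protein level and whose site is measured at
phosphosite level, optionally pre-screened by differential correlation
between states or by correlation with drug response) enter a repeated-split
search: 100 random stratified train/test splits; on each split an elastic
net

```
min  (1/2n)·Σⱼ (yⱼ − β₀ − xⱼ·β)²  +  λ·( α‖β‖₁ + (1−α)/2·‖β‖₂² )
```

is tuned over α ∈ {0.0, 0.1, …, 1.0}, with λ chosen per α by 5-fold
cross-validation over a 100-point descending λ path.  The fit with the
smallest held-out test MSE across all (split, α, λ) combinations defines the
edge biomarkers: its nonzero-coefficient edges.

**Drug model.**  The final per-drug model refits the elastic net at the
selected (α, λ) on the full cohort, restricted to the selected edges.  New
patients are standardized against the *frozen* training-cohort μ, σ of their
declared state and scored as β₀ + x·β.  Model quality is reported as the
Pearson correlation between predicted and observed TCGI, its square, and
the two-sided p-value.

## Worked example

The package ships a synthetic-cohort generator with planted ground truth, so
the whole pipeline can be exercised end to end:

```bash
cat > demo.yaml <<'YAML'
out_dir: demo_out
seed: 42
simulate:
  n_samples: 31
selection:
  n_splits: 100
YAML
edgeqnet run --config demo.yaml
```

which logs:

```
INFO edgeqnet: wrote 31 samples × 53 edges
INFO edgeqnet: selected 8 edges (alpha=0.90, lambda=0.024, test MSE=0.003097)
INFO edgeqnet: trained drugA model on 8 features
INFO edgeqnet: r=1.000 R²=1.000 p=1.2e-53 (n=31)
```

The simulated cohort plants 3 informative edges (true coefficients 3, −2,
1.5) among 50 decoys.  `demo_out/selection.json` shows the selection
recovered all three with near-true coefficients (2.961, −1.969, 1.483) plus
five decoys shrunk to |β| ≤ 0.02; `demo_out/evaluation.json` reports the
training-cohort fit (r² = 0.9997).  Stage-by-stage equivalents
(`simulate`, `transform`, `dcp`, `select`, `train`, `predict`, `evaluate`)
are available as separate subcommands; `edgeqnet --help` lists them.

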