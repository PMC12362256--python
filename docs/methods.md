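# Methods

## Model and procedure

The package tests *conditional* association between a taxon and an outcome:
the taxon is null when the outcome is independent of its leaf-level counts
given every other feature. The test statistic is the coefficient of
determination of a global association test on a beta-diversity distance
matrix, and the null distribution is generated by permuting only the tested
taxon's leaf columns.

Given counts **Z** (n samples × m leaf features), a distance matrix
**D** is computed, Gower-centered to **G** = J(−½D²)J with J = I − 11′/n,
and partitioned against a design matrix **X** through the orthogonal
projector **H** onto **X**'s column space:

SS_T = tr(**G**), SS_A = tr(**HG**), R² = SS_A/SS_T.

Because **G** is double-centered, the intercept column contributes nothing
to tr(**HG**); this is asserted by test. For a taxon *t*, B datasets
**Z**ᵇ are formed by permuting the columns of 𝓛(*t*) across samples,
distances and R²_b are recomputed in full, and the empirical p-value
compares R²_b with the original R².

### Engines

- **PERMANOVA** — group, categorical, or continuous outcomes enter the
  design; with covariates the statistic is the sequential (covariates-first)
  partial R², (tr(H_full G) − tr(H_cov G))/tr(G).
- **Kernel score (MiRKAT-style)** — the outcome is fitted on covariates
  alone under the null; with residuals r = X − μ̂₀ the score statistic is
  Q = r′**G**r/(2φ). The squared kernel statistic is proportional to an R²,
  so the scale-free analogue r′**G**r/(tr(**G**)·r′r) is used as the
  engine's R²; the proportionality constant is a convention and is
  irrelevant to the test because r and φ are fixed across permutations
  (only the microbiome side changes). Null fits: least squares for
  continuous outcomes (φ = residual variance), logistic regression for
  binary (φ = 1, score-test convention), and a null proportional-hazards
  fit for survival, where the residuals are martingale residuals
  (Nelson–Aalen with no covariates, Cox otherwise) and φ = 1.

With several candidate distance metrics, the maximum R² is taken per
dataset (original and each permuted copy) before comparison. The
alternative — combining per-metric p-values — is not implemented; applying
the max to R² keeps the permutation comparison one-dimensional and mirrors
how omnibus kernel tests combine metrics.

### Tie rule

The natural estimate p̂ = (1/B)Σ I(R² − R²_b < 0) returns p̂ = 0 for a
taxon whose permutation cannot change **D** at all (e.g. constant leaf
columns), which is anti-conservative in the degenerate limit. The default
is therefore the add-one, tie-inclusive rule
p̂ = (1 + #{R²_b ≥ R²})/(B + 1), which is valid at finite B
(P(p̂ ≤ α) ≤ α under exchangeability) and returns p̂ = 1 in the degenerate
case. The strict rule remains available as `tie_rule="strict"`; both
behaviors are asserted in the test suite.

### Permutation scope

"Permuting the taxon's columns" is ambiguous between independent
per-column permutations and one shared row permutation of the whole leaf
block. Both are implemented (`permute_mode="per_column"` default,
`"joint"` preserves within-taxon correlation); column multisets are
preserved and untouched columns are bit-identical either way, so permuted
tables can never create zero-total samples. Permutations are global across
samples (never stratified by group) and the outcome is never permuted.
The RNG is a counter-based substream scheme: each taxon's stream is keyed
on (master seed, taxon name), so results are independent of evaluation
order and duplicates reproduce exactly.

## Distances

Bray–Curtis and Jaccard are computed on raw counts / presence sets via
scipy's pairwise machinery; no rarefaction is performed (column
permutation preserves column multisets, so zero-total samples in permuted
data indicate bad input and are a hard error). UniFrac uses a cached
leaf-by-branch incidence matrix: per-sample branch loads are one sparse
matrix product, and each weighted-UniFrac matrix is a weighted L1 pairwise
reduction — this matters because the conditional test recomputes the
distance matrix B times per taxon. Weighted UniFrac defaults to the
unnormalized variant (`normalized=True` divides by Σ l_b(p_i(b)+p_j(b))).
Unrooted Newick input keeps its basal polytomy as the root; no midpoint
re-rooting is applied, and UniFrac values are therefore root-dependent but
deterministic. A feature with nonzero counts that is missing from the tree
is an error, never silently pruned.

Semimetric distances can give **G** negative eigenvalues; R² is reported
as computed (it can leave [0,1]) and PCoA reports negative eigenvalues
while omitting their axes. No positive-semidefinite truncation is applied
by default: the conditional test compares like with like across permuted
datasets, and truncation would add a nonlinearity.

## Synthetic data generator

The generator emulates a two-group 16S cohort: per sample,
p ~ Dirichlet(θ·base) and counts ~ Multinomial(depth, p); group-1 samples
additionally receive Poisson(λ) reads on each leaf of a chosen spiked
taxon (`per_asv` default; `shared_draw` adds one draw per sample across
the block). Spiking is additive after the multinomial draw, so group-1
totals drift upward by the spike mass; group-0 totals equal the depth
exactly.

Defaults: 31 samples per group, depth 48,765 reads, concentration sum
θ = 62, m = 200 leaves. The base composition is log-normal
(σ = 3.5 by default), normalized to the simplex; at m = 200 this yields a
family-level skew of roughly 41% for the top family and ~0.02% at the
median (the generator reports the achieved shares so other profiles can be
selected). The tree is a random bifurcating rooted tree with Exponential(1)
branch lengths, and the taxonomy is obtained by cutting it at seven nested
depth quantiles, so every leaf carries a full kingdom-to-species lineage.

What this emulates — and what it does not: Dirichlet-multinomial
overdispersion, extreme abundance skew, and spike-in group differences are
represented; real-data features such as structural zeros beyond the DM,
per-taxon phylogenetic signal in abundance, batch effects, and
compositional biases of library preparation are not. Passing calibration
and power tests therefore demonstrate correctness of the procedure under
the DM model, not robustness to those artefacts.

The survival generator draws exponential event times with log-hazard
linear in a taxon's standardized relative abundance and applies
independent Uniform(0, u) censoring, with u solved by bisection so the
expected censoring fraction matches the request.

## Study sizes used in the shipped analyses

The calibration study (`run_calibration_study`, also driven by
`scripts/acceptance.py`) uses 100 null datasets with B = 99 permutations
at the default design above; the power study uses 20 datasets per λ in
{0, 10, 70} on a family holding ≈3% of counts. One synthetic tree and base
composition are shared by all datasets of a study, mirroring a fixed real
phylogeny. The family under test is chosen deterministically as the one
(≥2 leaves) whose base share is closest to the 3% target.

## Numerical choices

- Projectors use the pseudo-inverse, so rank-deficient designs degrade
  gracefully; independently, `build_design` drops linearly dependent
  columns with a warning before fitting.
- Double centering is performed by row/column mean subtraction, not by
  forming J; Gower row-sum validation uses a tolerance scaled by the
  matrix magnitude.
- tr(**HG**) is evaluated as Σ H∘G (Hadamard sum), valid for symmetric H.
- Unweighted UniFrac clamps −1e-17-scale float residue at zero when two
  supports coincide.
- The global PERMANOVA p-value (outside CAT) permutes sample labels and
  uses the add-one correction; degenerate degrees of freedom are an error.
- Perfect separation in the logistic null fit is an error advising
  covariate removal, detected both from statsmodels and from fitted
  probabilities within 1e-10 of {0, 1}.

## Known limitations

- p-values are unadjusted; taxa in one tree are correlated hypotheses and
  multiplicity control is deliberately left to the caller.
- The conditional character of the test is relative to the permutation
  scheme: a taxon whose counts are an exact copy of a sibling's still
  rejects when its own distance contribution is systematically aligned
  with the outcome, because only the tested block varies across permuted
  datasets. Conservatism materializes when the taxon's conditional
  contribution is small against its own sampling noise (the noisy
  child-genus case covered in the test suite).
- The kernel engine provides no analytic (Davies-type) p-values; inference
  is by the permutation scheme only.
- Correlated/repeated-measures designs and generalized (α-family) UniFrac
  are out of scope.
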