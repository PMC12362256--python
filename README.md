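# catmicro

Conditional association testing for microbiome count data.

## The problem

Microbiome studies routinely find that a phenotype (treatment response,
survival, a continuous trait) is globally associated with community
composition, via tests such as PERMANOVA or kernel-machine (MiRKAT-style)
score tests on beta-diversity distances. Those tests say *that* the
community matters, not *which* taxa matter. Marginal per-taxon tests
(Mann-Whitney, differential-abundance models) answer the wrong follow-up
question: because taxa are correlated and nested in a taxonomy, a marginal
hit at the genus level drags its family, order and class along with it, and
a taxon whose signal merely duplicates its neighbors' still looks
important.

`catmicro` implements **CAT**, a conditional association test. A taxon is
*conditionally null* when the outcome is independent of it given all other
features. CAT probes this by destroying only that taxon's sample alignment
— permuting the counts of its leaf-level descendants (ASVs/OTUs) across
samples — and measuring how much the global-association R² drops.

## The statistic

For a distance matrix **D** with Gower-centered **G** = J(−½D²)J and a
design matrix **X** with projector **H**:

    SS_T = tr(G),   SS_A = tr(HG),   R² = SS_A / SS_T

For a taxon *t* with leaf set 𝓛(t), CAT:

1. computes R² on the original count matrix **Z**;
2. builds B permuted matrices **Z**ᵇ by permuting the columns in 𝓛(t);
3. recomputes the distances and R²_b for each;
4. reports p̂ = (1 + #{R²_b ≥ R²}) / (B + 1).

Instead of PERMANOVA, a kernel score engine can drive step 1/3: with
null-model residuals r = X − μ̂₀ (least squares, logistic, or martingale
residuals from a null proportional-hazards fit), the scale-free analogue
r′Gr / (tr(G)·r′r) replaces R², which extends the test to survival
outcomes. With several candidate distances, the per-dataset maximum R²
is used.

Distances: Bray-Curtis, Jaccard, unweighted/weighted UniFrac (on a rooted
phylogeny with branch lengths), Euclidean.

## Worked example

`examples/conditional_test.py` simulates a two-group study (31 samples per
group, Dirichlet-multinomial counts at depth 48,765 over a 200-leaf
synthetic phylogeny) in which one family receives Poisson(70) extra reads
per leaf in group 1, then runs CAT (weighted UniFrac, PERMANOVA engine,
B = 199) on the spiked family and an untouched control family:

```
      taxon  n_leaves  r2_original  r2_perm_mean  p_value
family:T383        27     0.107625      0.007969    0.005
family:T233         2     0.107625      0.118065    1.000
```

Permuting the spiked family's leaves collapses R² from 0.108 to 0.008 on
average — it carries group information no other feature supplies — so its
p-value is small. The control family is exchangeable across samples; its
permuted R² values straddle the original and CAT does not reject.

The other examples cover the global tests themselves
(`global_tests.py`), survival outcomes via martingale residuals
(`survival_outcome.py`), and null calibration (`null_calibration.py`).

## Command line

A thin CLI wraps the library:

```
catmicro simulate  --m 200 --seed 3 --out data/
catmicro global    --counts data/counts.tsv --metadata data/metadata.tsv \
                   --outcome group --distance wunifrac --tree data/tree.nwk \
                   --seed 7 --out global.tsv
catmicro cat       --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
                   --tree data/tree.nwk --metadata data/metadata.tsv \
                   --outcome group --distance wunifrac \
                   --taxa family:T48 --permutations 999 --seed 7 --out cat.tsv
catmicro calibrate --spike-lambda 0 10 70 --n-datasets 100 --seed 1 --out rates.tsv
```

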