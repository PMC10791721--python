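# gradientscope

Macroscale functional-connectome gradient analysis: from parcellated
resting-state time series to trait associations, with a synthetic cohort
generator so every stage can be exercised end to end without any imaging
data.

## The problem

Resting-state functional connectivity can be summarized by *gradients*: each
cortical parcel's connectivity profile (its row of the parcel × parcel
Pearson correlation matrix) is embedded into a low-dimensional space, and a
parcel's coordinate along the first component — the principal gradient —
places it on a continuum from unimodal sensory cortex to transmodal
default-mode cortex. How compressed or expanded this hierarchy is per
person, and how the distance between specific functional networks (above
all the visual and default-mode networks) varies, can then be related to
behavioural traits such as autistic-like traits (AQ, 0–50) and sensory
sensitivity (GSQ, 0–168).

`gradientscope` implements that pipeline:

1. **Connectome** — Pearson correlation per subject; group connectome by
   Fisher-z averaging, `r̄ = tanh(mean(atanh r))`, diagonal excluded.
2. **Gradients** — each connectome row is sparsified to its top 5% entries
   (sparsity 0.95), a cosine-similarity affinity is built from the
   sparsified profiles, and PCA of the column-centred affinity yields ten
   gradients with explained-variance fractions. Individual embeddings are
   aligned to the group reference by orthogonal Procrustes (rotation +
   reflection, no scaling).
3. **Segregation metrics** — per subject: network median distance on
   gradient 1, gradient range and SD, KDE-based network peak distance,
   eccentricity (mean distance from the origin of the gradient-1–3 space),
   and within-/between-network dispersion.
4. **Association** — Spearman rank correlations of every metric with every
   trait over all 21 network pairs (42 tests per metric family), Bonferroni
   control (0.05 / 42 ≈ 0.0012), OLS models with age, gender, FD and DVARS
   motion covariates, and median-split grouping.
5. **Synthetic cohorts** — trait totals with item-level AQ/GSQ responses
   that reproduce the totals exactly, two-pole graded connectomes with a
   planted trait–expansion coupling, and motion traces calibrated to a
   target framewise displacement.

The gradient extractor is a scikit-learn transformer: `GradientEmbedding`
(`fit` on a group matrix, `transform` subject matrices into the aligned
space) composes with sklearn pipelines and `clone`/`get_params`.

## Worked example

```python
from gradientscope import CohortSpec, RunConfig, simulate_cohort
from gradientscope.pipeline import analyze_cohort

spec = CohortSpec(n_subjects=60, n_parcels=100, planted_spearman=0.7, seed=42)
cohort = simulate_cohort(spec, include_motion=False)
results = analyze_cohort(cohort.matrices, cohort.partition,
                         cohort.participants, RunConfig())

ev = results.group_gradients.explained_variance
print(f"variance explained by gradients 1-3: "
      f"{ev[0]:.3f}, {ev[1]:.3f}, {ev[2]:.3f}")
fam = results.grid.family("median_distance")
cell = fam[(fam.network_a == "Vis") & (fam.network_b == "Default")]
for _, row in cell.iterrows():
    print(f"Vis-Default median distance vs {row.trait}: "
          f"rho_s = {row.rho_s:.3f}, p = {row.p:.2e}, "
          f"Bonferroni-significant: {row.significant}")
```

Output:

```
variance explained by gradients 1-3: 0.124, 0.104, 0.083
Vis-Default median distance vs aq_total: rho_s = 0.320, p = 1.27e-02, Bonferroni-significant: False
Vis-Default median distance vs gsq_total: rho_s = 0.707, p = 2.62e-10, Bonferroni-significant: True
```

The cohort was generated with a strong planted rank correlation (0.7)
between the sensory-sensitivity-like trait and the visual–default
separation; the pipeline recovers it and flags the cell at the
Bonferroni-adjusted threshold, while the AQ-like trait — which couples to
the geometry only through its modest correlation with GSQ — stays below it.

A command-line interface wraps the same steps:

```bash
gradientscope generate-cohort --out cohort/ --seed 3 --subjects 60 --parcels 100
gradientscope run --data cohort/ --out results/
gradientscope gradients --matrix results/group_matrix.tsv --out g.tsv
```

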