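# phenoforest

Annotation-driven discovery of cell populations in high-dimensional
cytometry.

Clustering tools for flow and mass cytometry usually return anonymous
cluster ids that must be matched across samples and deciphered by hand.
`phenoforest` instead produces *interpretable phenotype labels* — ordered
marker/level strings such as `CD4bright CD8- PD-1dim` — for every cell in
every sample, together with the standardized per-sample thresholds that
define them and a sample × phenotype count matrix ready for differential-
abundance modelling. Phenotypes are retained only when they are
rediscovered independently in enough samples, which filters methodological
artefacts and makes populations comparable across samples, panels and even
studies (via targeted re-extraction with pre-specified marker
combinations).

## Method in brief

For each experimental unit (by default one sample) with expression matrix
`X[cells, markers]`:

1. **Annotation forest.** Enumerate every gating strategy of ≤ 3 markers:
   a node gates each marker *m* whose margin rejects unimodality under the
   dip test (p < 0.25), at the antimode midpoints of its taut-string
   density; children are event subsets between gates (recursion stops at
   depth 3 or < 500 events). Each gating is weighted
   ω(N) = Q(N)·P(N)·D(N), with Q = Π(1−p) along the strategy,
   P = |N|/P_m the share of the marker's effective root population, and
   D = 1/d_depth. The normalized per-marker Σω is the *depth score*
   DS_m ∈ [0,1]; markers with median DS across units above 0.01 are
   selected.
2. **Standardized thresholds.** Per selected marker: the boundary count is
   fixed by majority vote across units, standard locations are rank-wise
   medians over conforming units, and non-conforming units are reconciled
   by distance matching (surplus boundaries deleted, missing ones imputed
   at the shifted standard).
3. **Discovery.** Random partition forests (no depth limit, random choice
   among multimodal markers, leaves unimodal or < 25 cells) propose
   candidate populations; leaves are scored by size ×
   Π_m p_dip·e^{−|τ₃|}·e^{−|τ₄−0.1226|} (trimmed L-moment ratios) and a
   greedy disjoint selection across trees partitions the unit. Selected
   leaves are annotated against the thresholds; phenotypes occurring in at
   least a threshold number of units (elbow of the greatest convex
   minorant of the occurrence distribution) are kept.
4. **Counting and testing.** Every cell gets a label by direct
   thresholding; counts c_{i,k} for sample *i* and phenotype *k* feed a
   binomial GLMM, logit(μ_{i,k}) = β₀ + β₁·Responderᵢ + ξᵢ, per phenotype
   (Bonferroni-adjusted Wald tests), or the joint PFDA model over all
   phenotypes matching a partial annotation with the one-sided test of
   H₁: β_R + (1/k*)Σβ_j > 0.

The dip statistic and the taut-string estimator are implemented exactly in
this package (numba-accelerated, LP-oracle validated); `docs/methods.md`
documents the algorithms, parameter defaults and limitations.

## Worked example

```python
import pandas as pd
import phenoforest as pf
from phenoforest.io_core import ExperimentDesign
from phenoforest.pipeline import PipelineConfig, run_discover

exp = pf.simulate_gaussian_experiment(5, n_samples=3, n_obs=5000, seed=7)
design = ExperimentDesign(
    pd.DataFrame({"sample": [s.sample_id for s in exp.samples]})
)
res = run_discover(exp.samples, design, PipelineConfig(n_trees=4, seed=1))
print(res.selected_phenotypes)
print(res.count_matrix.counts)
```

prints the five discovered phenotype strings and their counts
(`examples/01_discover_phenotypes.py` is this script with commentary; its
actual output):

```
selected phenotypes:
   V1+ V10+ V2+ V3+ V4+ V5+ V6+ V7+ V8+
   V1+ V10+ V2- V3- V4- V5+ V6- V7+ V8-
   V1+ V10- V2+ V3+ V4+ V5+ V6+ V7+ V8-
   V1- V10- V2+ V3+ V4- V5- V6+ V7- V8+
   V1- V10- V2- V3+ V4- V5+ V6+ V7- V8-

          V1+ V10+ V2+ V3+ V4+ V5+ V6+ V7+ V8+  ...  V1- V10- V2- V3+ V4- V5+ V6+ V7- V8-
sample01                                   775  ...                                   808
sample02                                   770  ...                                   828
sample03                                   865  ...                                   797

annotated fraction: 0.988
adjusted Rand index vs generating components (annotated subset): 1.0000
```

— one column per down-selected phenotype, one row per sample, entries
exact cell counts; the per-cell labels agree with the generating mixture
components at an adjusted Rand index of 1.000 on the annotated 98.8% of
cells. (Marker V9 happened to separate no component pair in this draw and
is dropped by the depth-score screen.) The other scripts under `examples/` demonstrate the density
machinery, targeted extraction on held-out samples, the GLMM/PFDA tests,
and the landmark transformation for annotation embeddings.

A thin command line mirrors the library:
`phenoforest simulate|discover|target|stats|embed --help`.

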