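# Methods

`phenoforest` discovers and annotates cell populations in high-dimensional
cytometry data (flow or mass cytometry; any cells × markers matrix of
pre-gated, pre-transformed intensities). Its guiding idea is that a cell
population worth reporting should be describable by thresholding a small
number of markers — "CD4 bright, CD8 −, PD-1 dim, …" — and should be
rediscovered independently in most samples of an experiment. The method
therefore (1) derives standardized per-sample annotation thresholds from
one-dimensional modality analysis, (2) discovers candidate populations with
randomized partition forests, and (3) keeps only phenotypes that recur
across samples, counting cells for those phenotypes exactly.

## One-dimensional machinery

**Dip test.** Unimodality of a marker margin is screened with the dip
statistic: the smallest sup-norm distance between the empirical CDF and any
unimodal CDF (nondecreasing, convex up to a mode, concave after it, with an
atom permitted at the mode). We compute the dip exactly by minimising, over
all mode placements, the band-fitting cost of a convex prefix and a concave
suffix joined at a free mode vertex; one-sided costs are greatest-convex-
minorant / least-concave-majorant gaps, the junction feasibility is a
concave piecewise-linear margin maximised by ternary search, and a
level-certificate sweep with incremental line envelopes (Li Chao trees)
prunes the split space. The result is exact to an absolute tolerance of
1e-8 and is validated in the test suite against a linear-programming oracle
that solves the defining minimax problem directly on small samples.

Ties are collapsed to atoms of the empirical distribution; this is the
mathematically exact dip of the observed distribution (an atom at the mode
can absorb tied mass), which can be smaller than the value obtained by
treating ties as infinitesimally separated points. Inside the pipeline ties
are broken upstream by a deterministic rank-preserving ramp of relative
magnitude 1e-9, so the distinction never matters there.

P-values come from a packaged Monte-Carlo quantile table of the dip under
the uniform null (30 sample sizes from 4 to 50 000, 500–20 000 replicates
per size, fixed seed; `scripts/make_dip_table.py` regenerates it).
Interpolation is linear in log n on sqrt(n)-scaled quantiles; sizes beyond
the table reuse its last row under sqrt(n) scaling. A seeded Monte-Carlo
fallback is available for direct simulation.

**Screening tiers.** Gating decisions only need to know whether the dip
p-value is below the 0.25 screen threshold, and the p-value itself enters
only through the gating quality Q = Π(1−p). For margins larger than 512
events the pipeline therefore uses certified bounds before the exact
statistic: a coarse-grid chord-violation bound from below (if its p-value
is already under 0.005 the margin is declared multimodal with that
conservative p-value) and a constructive unimodal fit from above (if its
p-value reaches the threshold the margin is declared unimodal). A tighter
bracket follows, and only genuinely borderline margins reach the exact
search. The decision is always exact; the reported p-value of a gated
margin can be conservative by at most 0.005 (0.02 via the bracket rule),
which bounds the induced bias on Q by the same amount. The public
`dip_test` function always computes the exact statistic.

**Taut string.** Gate locations come from the taut-string density: the
shortest path through a sup-norm tube of radius r around the empirical CDF
(gates at data midpoints, endpoints pinned), whose derivative is a
piecewise-constant density with the minimal number of modes consistent
with the tube. The default radius is 0.4/sqrt(n); the scale 0.4 is the
smallest for which a single Gaussian sample of n = 1000 is fitted
unimodally in at least 99% of seeded draws, which maximises sensitivity to
minor modes subject to that calibration. A fixed global radius is used
rather than a locally adaptive multiresolution tube; it is exposed as a
parameter (`radius`, `radius_scale`) for callers who need a different
smoothness trade-off. Components whose mass is below roughly 2r (≈
0.8/sqrt(n)) are invisible to the string at the root of a gating tree;
they become discoverable deeper in the recursion where their relative mass
grows. Gates are the midpoints of antimodal components; markers whose
string shows more than four gates at a node are treated as non-gateable
there.

## Gating forests and thresholds

**Annotation forest.** Per experimental unit (one sample by default;
samples sharing a design `unit` value are concatenated) the pipeline
enumerates every gating strategy of at most three distinct markers: a node
gates every active marker whose within-bounds margin rejects unimodality
(dip p < 0.25), children are the event subsets between consecutive gates,
and recursion stops at depth 3 or below 500 events. Events outside the
per-marker expression bounds (by default the 5th percentile of per-sample
1st percentiles and the 95th percentile of per-sample 99th percentiles)
are excluded from density estimation and assigned to the extreme children.
Each gating is weighted by ω = Q·P·D (strategy quality, share of the
marker's effective root population, reciprocal gating count at the depth);
the normalized per-marker ω sums are the depth scores, and markers whose
median depth score across units exceeds 0.01 are selected. Nodes with
25–500 events are not expanded.

**Boundary standardization.** Per selected marker the number of boundaries
is fixed by majority vote across units (ties favour the smaller count; a
supervised override list can force counts or locations), standard locations
are rank-wise medians over conforming units, and every unit is reconciled
by nearest-standard matching: each unit boundary prefers its nearest
standard, only the closest match per standard is kept, surplus boundaries
are deleted without rematching, and unmatched standards are imputed at the
standard location shifted by the unit's mean matched offset (preserving
unit-specific shifts). With an imputation hierarchy, standards are computed
within hierarchy classes where possible and globally otherwise.

**Discovery forests.** Partition trees split like the annotation forest
but unconstrained in depth, re-allowing markers, choosing the split marker
uniformly at random among the multimodal candidates (seeded), and stopping
at unimodal-or-<25-cell leaves. Each leaf is scored by
size × Π_m p_dip,m · exp(−|τ3,m|) · exp(−|τ4,m − 0.1226|), where τ3, τ4 are
trimmed (t = 1) sample L-moment ratios of the margin; 0.1226 is the
L-kurtosis of the Gaussian, kept as the homogeneity reference constant.
The exact functional form of the score is a design choice of this package;
its ingredients (margin dip p-values and trimmed L-moments) are what
matters, and the form is fixed and unit-tested. A greedy weighted set
packing then selects disjoint leaves across trees (score-descending, ties
to larger leaves, then tree/leaf id), and each selected leaf is annotated
by comparing margin medians with the unit's reconciled thresholds (a
median exactly on a boundary takes the lower level). The default forest
size is 100 trees per unit; the benchmarks below use smaller forests
because clean mixtures saturate quickly.

**Down-selection and counting.** Phenotypes are matched across units by
exact annotation-string equality. With more than four samples, the
occurrence threshold is placed at the elbow of the greatest convex
minorant of the occurrence distribution (number of phenotypes per
occurrence value, normalized, restricted to occurrences between
max(2, 0.05n) and min(n−1, 0.95n) and to the observed support; vertical
chord distance). Every cell of every sample receives a phenotype by direct
thresholding, independent of leaf membership; counts for down-selected
phenotypes are exact tallies, the remainder is reported under a reserved
label. The same thresholding supports targeted extraction of pre-specified
(possibly partial or level-coarsened) phenotypes on new data.

## Statistics

Per-phenotype differential abundance uses a logit-link binomial GLMM with
a Gaussian random intercept per subject, fitted by maximum likelihood with
adaptive Gauss–Hermite quadrature (25 nodes; each group's integral is
recentred at its posterior mode, which keeps the quadrature accurate for
large cell totals), a Wald test on the responder coefficient and
Bonferroni adjustment (BH available). A beta-binomial fixed-effect
fallback is used — and flagged — when the mixed fit fails. The suite
cross-checks the fixed effects against lme4's Laplace fit on shared data
and calibrates the type-I error under simulated overdispersed nulls.

The PFDA model stacks all phenotypes matching a partial annotation
(reference-level parameterization: intercept, responder main effect,
cluster main effects and cluster × responder interactions for all but the
first cluster, observation-level random intercept) and tests one-sided
whether the responder effect averaged over clusters is positive; the
contrast is invariant to the cluster ordering and to the choice of
reference level.

## Synthetic benchmarks

The generator reproduces the evaluation conditions the method was designed
under: 10-dimensional Gaussian mixtures whose component means have entries
0 ("not expressed") or 8 ("expressed"), distinct across components;
covariances with variances uniform in [1, 2] and correlation from a
normalized Wishart-style construction (W Wᵀ with standard-normal W),
resampled per sample and component; per-sample integer-rounded N(0, 1/2)
mean translations; component counts multinomial with 25 000 cells per
sample. Cluster abundances follow a fixed 127-entry reference vector
(dyadic blocks from 0.1425 down to 0.002226562) truncated to the requested
number of clusters with the residual mass spread uniformly. The responder
benchmark uses two fixed 125-component weight vectors in which one
component doubles from 0.0011 to 0.0022 between non-responders and
responders, all other weights proportionally reduced; ten of twenty
samples are responders. A non-Gaussian variant maps every margin through
Γ(1 + |x/4|), which folds and compresses the scale while preserving the
two-level structure. What the generator does not emulate: batch effects,
spillover, debris/doublets, rare-population skew beyond the weight design,
or marker correlation structure of real panels — passing benchmarks shows
faithful recovery of well-separated mixture structure, not robustness to
those artefacts.

Evaluation follows the same design: adjusted Rand index of per-cell
phenotype labels against the generating components, restricted to cells
carrying a down-selected phenotype (filtered cells share one reserved
label); the "top cluster" is the smallest-p phenotype under the
per-phenotype GLMM, evaluated by the binary ARI against the predictive
component and by the 5-fold cross-validated AUC of a univariate logistic
model on its frequency.

### Problem sizes used by the tests and the acceptance script

The acceptance script runs the cluster-recovery benchmarks at 5 and 45
clusters, 3 samples × 10 000 cells, two replicates per setting, 5
discovery trees per unit, and reports the median ARI (Gaussian and
Γ-transformed). The test suite runs the same benchmarks at one replicate
per setting; the responder benchmark runs one iteration per variant at the
full 20 × 25 000-cell design with 2 discovery trees per unit (the design's
predictive component, at 27 cells per non-responder sample, sits just
above the 25-cell leaf floor, so the cell count cannot be reduced without
changing the science; the forest size can, because the clean mixture
saturates leaf selection quickly). Null-calibration tests use 150–250
simulated replicates.

## Numerical choices and degenerate inputs

- Dip: exact within 1e-8 absolute; statistic clamped to [1/(2n), 0.25];
  fewer than 4 events is an error that gating code treats as unimodal.
- Taut string: requires 25 events and a nonzero range; exact ties get the
  deterministic 1e-9-relative ramp.
- Boundary reconciliation: non-increasing location collisions are resolved
  by re-sorting and separating exact ties by 1e-9 of the location scale.
- Depth-score normalization: if no marker is ever gated in a unit all its
  scores are zero (the unit then contributes zeros to marker selection).
- GLMM: optimizer fixed (L-BFGS-B, numeric gradients, 500 iterations);
  log-sigma bounded in [−8, 3]; identical data give identical fits.
  Complete separation falls through to the flagged beta-binomial fit.
- GCM elbow: with four or fewer samples the threshold is 1; an empty
  restricted occurrence range falls back to the lower range bound.
- Annotation ties: a value exactly on a threshold takes the lower level.

## Known limitations

- The fixed-radius taut string cannot resolve components below ~0.8/√n of
  a node's mass at that node; rare populations are found only once the
  recursion concentrates them.
- Phenotype matching is exact string equality; there is no fuzzy matching
  across panels beyond explicit level coarsening in targeted extraction.
- Greedy leaf selection is not an optimal set packing (the toy-instance
  test shows agreement where exhaustive search is feasible).
- The GLMM's Wald test is slightly anticonservative at very small subject
  counts, as the calibration tests document.
- FCS support covers list-mode 2.0/3.0/3.1 files with float, double or
  fixed-width integer events, without compensation or transformation;
  input is assumed pre-gated and pre-transformed.
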