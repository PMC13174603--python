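# Methods

This note records the models, conventions and numerical choices behind
`devgeom`, in the order the pipeline runs, together with the reasoning for
choices that were genuinely open.

## Synthetic cohorts

The generator emulates a two-group developmental category-localizer study:
children (ages drawn uniformly on 5–12) and adults (20–29), three runs,
five categories (faces, bodies, pseudowords, places, objects) each with
two subcategories, measured in two regions (VLPFC, VTC) of both
hemispheres with 500 vertices per region by default (analyses are
correlation-based and scale-free in vertex count; tests use 40–200).

For subject *s*, run *r*, subcategory *u* of category *c*:

```
pattern = T                         shared regional template
        + s_anim · A                if c ∈ {faces, bodies}
        + s_anim · I                if c ∈ {places, objects}
        + s_word · W                if c = pseudowords
        + amp · s_c · h_c · m_c     category-selective vertex bump
        + 0.25 · s_c · D_u          subcategory identity
        + E_{s,u}                   subject idiosyncrasy, SD σ_subj
        + ε                         run noise, SD σ_run (default 1)
```

where `s_c` is the category's block strength (`s_anim` for the four
animate/inanimate categories, `s_word` for pseudowords), `m_c` a disjoint
per-category indicator over a `selective_fraction` (default 8%) of
vertices, `amp` the selectivity amplitude (default 3 t-units per unit
strength) and `h_c` a hemispheric multiplier `2·rh_bias_c` (RH) or
`2·(1−rh_bias_c)` (LH). Default right-hemisphere shares put pseudowords
leftward (0.35) and faces rightward (0.62), the canonical localizer
lateralization. Strengths are set per group x hemisphere x region; the
defaults plant strong bilateral animate–inanimate structure in VTC for
both groups, an animacy axis in right VLPFC that sharpens from childhood
(0.5) to adulthood (1.0), and an early, strong word axis in left VLPFC
(0.8 → 1.0).

Two properties are engineered deliberately:

- **Exact null.** Every category-specific term scales with the category's
  block strength, so a cohort with all strengths at zero is exactly
  structureless — within-category and between-category cross-run
  correlations share one expectation, which is what makes the type-I
  calibration tests meaningful.
- **Analytic optimum.** The shared components (template, animate,
  inanimate, word, subcategory directions) are centered, orthogonalized
  against the selective masks and each other, and scaled to unit SD within
  each hemisphere x region. The realized expected similarity matrix is
  then a deterministic function of the strengths alone, so the generating
  partition is exactly the best-fitting binary model and two regions
  generated with equal strengths share the same expected similarity
  structure. With fewer than ~25 vertices the basis cannot be completed
  and the generator falls back to centering only.

Synthetic "t-values" are the pattern values themselves — no GLM is
simulated, because every downstream statistic consumes t-maps as given.
What the generator does **not** emulate: hemodynamics, spatial
autocorrelation beyond the block covariance, inter-subject anatomical
variability (all subjects share one vertex index space), or realistic
absolute correlation magnitudes (the shared template inflates them).
Passing tests therefore certify the analysis machinery and its
calibration, not the effect sizes one should expect from real cortex.

## Cross-validated similarity

LORO folds correlate the held-out run against the mean of the remaining
runs (higher training-side SNR than run-vs-run, which is available behind
`pairwise_runs=True`). Fold correlations are averaged in raw *r* by
default (`fisher_average=True` switches to z-space averaging), then
symmetrized as (M + Mᵀ)/2; since symmetrization is linear, averaging then
symmetrizing equals symmetrizing per fold then averaging. Block statistics
exclude the diagonal (reliability is reported separately). A zero-variance
pattern raises an error naming the run and condition.

## Partition models

Candidate families over the five categories: `full_bipartition` (15
two-group covers), `disjoint_pairs` (90 unordered pairs of disjoint
non-empty subsets), and `partial_pairs` (the 75 pairs whose union leaves
at least one category out — provided because a fixed 75-model family is a
useful benchmark size; note 90 = 15 + 75). Scoring correlates the 15
unique cells (diagonal included — within-group coherence includes
reliability, and a similarity matrix numerically equal to the model then
scores exactly 1; `include_diagonal=False` is available). Binary {1, 0}
coding is presentation-only: Pearson scores are invariant to affine
recoding. Ranks sort by descending score with ties broken by the
canonical enumeration order; percentile = rank / N. Canonical names list
the group containing the first category in fixed order F, B, W, P, O
(e.g. `FB_WPO`, `FBPO_W`).

## Geometry

PCA embeds the run-averaged item patterns (10 subcategories by default, so
"distances among faces only" is well defined; a 5-category mode exists),
z-scored across vertices and centered across items; component signs are
fixed by making the largest-magnitude loading positive. PCA is fitted per
owner (subject or group mean), never jointly across groups — cross-group
comparison always goes through Procrustes, mirroring an analysis that
aligns rather than co-embeds.

Full Procrustes (translation, uniform scale, orthogonal rotation with
reflection permitted) minimizes the residual via SVD of the
cross-covariance; the reported distance is the classical normalized
disparity 1 − (Σ singular values)², which is invariant to similarity
transforms of the source. The group template is a generalized-Procrustes
mean: all configurations are aligned to the current unit-norm mean and
re-averaged until the mean moves < 1e−8 (max 100 iterations). Dispersion
is the mean Procrustes distance to the template. Convex-hull area uses the
first two components and rejects collinear configurations.

## Decoding

One observation per subject x category (run-averaged pattern). The
classifier is a hinge-loss linear SVC with fixed C = 1 (regularization was
unspecified in the designs this implements; no hyperparameter search by
design), features standardized with training-fold statistics only.
Cluster targets (k = 2..5) are derived inside each LOSO fold from the
training group's mean patterns — average linkage on correlation distance,
ties broken by category order — so the held-out subject never informs its
own targets.

The permutation null reassigns which category receives which training
label (one bijection per permutation, shared by all subjects) and always
evaluates against the true targets. For balanced 5-way targets the null
accuracy has expectation exactly 0.2: under a uniform random permutation
every (predicted label, true label) pairing has marginal probability 1/5.
Applying the bijection to both training and test labels would leave
accuracy unchanged, which is why the training-side convention is the
meaningful one. P-values use the add-one convention
(1 + #{null ≥ true}) / (1 + n_permutations).

## Stability and coupling

Split matrices are the per-fold LORO matrices (symmetrized), one per
held-out run: with 3 runs, stability averages 3 split pairs and coupling
9 cross-region combinations, over the 15 unique cells. Signed distance to
the identity line is (stability − coupling)/√2, positive when internal
coherence dominates. Category-level coordinates restrict the correlation
to a category's row (its diagonal cell plus 4 between-category cells).
Displacement significance uses a group-label permutation null (the
parametric alternative was not clearly preferable; permutation makes the
fewest assumptions) with the add-one convention.

**Known bias.** LORO folds of the same runs share noise (fold *i*'s
training mean contains fold *j*'s test run), which inflates within-region
stability relative to cross-region coupling at any finite noise level.
The property "matched regions ⇒ stability = coupling" therefore holds
exactly only for split matrices built from disjoint run sets, and that is
how the test suite asserts it (a 4-run cohort split {1,2} vs {3,4}).
Users comparing stability to coupling on 3-run data should expect a
positive offset of this origin on top of any real effect.

## Topography

Suprathreshold counting is strict (t > threshold, default 2.5). A vertex
may be suprathreshold for several category contrasts, so area shares use
per-category counts over summed counts rather than a winner-take-all
partition (winner-take-all is a documented alternative). LI = RH/(RH+LH),
undefined (error) when both counts are zero. Profile vectors carry their
ROI and category orderings and refuse to correlate mismatched orderings
rather than silently reordering.

## Tissue and gene expression

Age groups are kids 5–10, teens 11–17, young adults 18–24, adults 25–54
(inclusive); ages outside [5, 54] are rejected because aging is a distinct
process from development. The R1 trajectory is saturating-exponential
growth, base + range·(1 − exp(−(age−5)/τ)) with τ = 8 y — lifespan
maturation curves plateau in adulthood, and a non-saturating line would
give the 25–54 bin an unrealistically large within-bin spread. The 'dip'
trajectory subtracts a Gaussian depression (depth 0.05 1/s, centre 18 y,
width 2.5 y) sized so the dip-age mean genuinely sits below both flanks.
MTV passes through a logistic squash so values stay strictly inside
(0, 1). Voxel deviations follow a fixed standardized quantile grid: ROI
means track the trajectory exactly in the noiseless limit and the
inter-voxel SD equals its target exactly, which makes parameter-recovery
tests sharp. Per-voxel R1 covaries with 1/WVF at a group-specific slope
(children 1.0, adults 0.7, steeper in children).

The factorial ANOVA is balanced two-way between-subjects with partitioned
sums of squares and partial η² = SS_effect/(SS_effect + SS_error);
unbalanced designs are rejected with a clear error (repeated-measures and
mixed designs are out of scope, which also means the lobe x age
interaction here needs larger cells than a paired design would). The
adolescence window for gene-set normalization is the open interval
(11, 20) years (configurable); each gene is divided by its window mean —
so its window mean maps to 1 exactly — before set-averaging. The packaged
myelin gene list is PLP1, PLLP, MAG, MBP, CA2, PMP22, MAL, ERMN, OMG.

## Shared statistics

Two-tailed p throughout. Welch t with Satterthwaite df and Cohen's d on
the pooled SD; paired t reports dz = mean/SD; correlation comparison uses
the Fisher-z two-sample z statistic (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)); BH-FDR adjusted p-values are monotone-enforced step-up values.

## Problem sizes and determinism

Default pipeline scale is 10 + 10 subjects, 200 vertices, 100 decoding
permutations — a desk-scale configuration chosen so the full run completes
in minutes while every statistic remains well-posed; test cohorts are
smaller still (40–120 vertices, 4–10 subjects, 25–100 Monte-Carlo
replicates). All randomness flows from named seeds through
`numpy.random.SeedSequence` spawning, so identical configs reproduce all
outputs bit-identically; the degraded-orthogonalization fallback, ROI
assignment and subcategory naming are all deterministic.

## Limitations

- Vertex correspondence across subjects is assumed (shared index space);
  real data would need a common surface space first.
- Absolute similarity magnitudes in synthetic cohorts are inflated by the
  shared regional template; contrasts and orderings are the calibrated
  quantities.
- No searchlight or vertex-resolved variants; whole-ROI patterns only.
- The stability–coupling plane inherits the shared-noise bias described
  above whenever splits reuse runs.
- Equivalence-style claims (e.g. "statistically indistinguishable tissue
  metrics") are supported only by non-significant Welch tests, not a
  formal equivalence procedure.
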