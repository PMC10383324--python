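# Methods

This note records the statistical model behind `egopath`, the choices made
where the procedure admitted more than one reasonable reading, and what the
synthetic generator does and does not emulate.

## Contrasts

The pipeline's elementary quantity is the per-protein contrast
`logFC_i = log2(mean_case_i / mean_control_i)`, with means taken over
non-missing replicates of the **linear-scale** intensities.  Log base 2 is
the proteomics convention and makes the 1.5× filter threshold
`|logFC| > log2 1.5 ≈ 0.585`.  Averaging on the linear scale (arithmetic
mean, then log of the ratio) is the default because label-free
quantification tools report linear intensities; `summary="log-mean"`
switches to the mean of log intensities (equivalent to a geometric-mean
ratio) for users who prefer shift-invariance on the log scale.  A protein
needs ≥ 2 non-missing replicates in both groups; otherwise its contrast is
flagged missing and the protein drops out of filters and of permutation
backgrounds.  No imputation is performed anywhere.

The fold filter uses a strict inequality ("more than 1.5 times"), with an
ulp-scale tolerance (1e−12 relative) so that a ratio of exactly 1.5 — or
1/1.5, whose log differs from −log2(1.5) in the last floating-point bit —
is never selected.

## Ego-module statistic

For seed protein *i* the module is `{i} ∪ neighbors(i) ∩ background`,
where the background is the set of proteins with a valid contrast.  The
module statistic is the arithmetic mean (and sample SD, ddof = 1; SD ≡ 0
for singleton modules) of member logFCs.

**Null model.** "Random modules of the same size" is implemented as random
protein **sets** of equal size drawn uniformly without replacement from the
background, independently for every seed protein.  Same-size random
*ego-modules* may not exist for every observed size, which would make that
reading infeasible in general; it is still available as `null="ego"`
(uniform over matching-size ego modules when at least 50 exist, falling
back to random sets otherwise).

**Empirical p.** The mean statistic is tested two-sided by distance from
the null center; the SD upper-tailed; the between-contrast module Pearson
correlation two-sided.  Sampled nulls use the add-one convention
`p = (count + 1)/(n_perm + 1)`, which never returns 0; when the number of
same-size subsets does not exceed `n_perm` the null switches to exhaustive
enumeration with exact counting `p = count / n_subsets` (the observed set
is itself enumerated, so p > 0).

**Null center.** For subset means the null expectation has a closed form —
the background mean (each drawn position is marginally uniform over the
background) — and the implementation centers the two-sided distance there
rather than at the sampled null's own mean.  The plug-in center is an
estimate whose jitter biases sampled p-values relative to their exhaustive
counterparts whenever the rejection boundary crosses a dense region of the
null; the analytic center removes that bias and makes sampled and
exhaustive p-values estimates of the same quantity.  It also gives exact
shift equivariance: adding a constant to every logFC moves observed and
center equally and leaves the p-value unchanged (tie comparisons carry a
1e−9 tolerance to absorb float jitter).  The module correlation null has no
such closed form and uses the sample mean of the null correlations.

**Selection.** A protein is "differential" for a contrast when its
module-mean p < α (default 0.05; no threshold is canonical, so it is
configuration).  The SD p-value is reported but does not enter selection.
Between-contrast sets select seeds by module-correlation p < α.  No
multiple-testing correction is applied across seeds — the procedure is a
screen, not a family of confirmatory tests — and this is deliberate;
downstream users can apply FDR control to the emitted p column.  Seeds
measured but absent from the interaction network are listed as
`untestable`, never silently dropped.

## Signed pathway activity

`A(P) = Σ_j s_j · logFC_j` over members with a valid contrast, `s_j = −1`
for repressors.  Members without a valid contrast are skipped and the used
count reported.  The null draws random same-size sets from the background;
the pathway's **sign multiset is carried into each draw** and assigned to
the drawn proteins uniformly at random, preserving the repressor fraction
under the null (`null_signs="all-positive"` gives the simpler all-+1
null).  The two-sided p uses the analytic center
`(Σ_j s_j) · mean(background)`.  In exhaustive mode every subset is
enumerated once; with mixed signs the assignment onto each subset is a
seeded random draw, since no canonical assignment exists.  Repressor
annotations are input data (the signed GMT dialect); the package does not
query pathway databases.

## Behavioral scoring

Spontaneous alternation counts overlapping windows of three consecutive
arm entries containing three distinct arms; the denominator `entries − 2`
is exactly the number of such windows, so the score lives in [0, 100].
Same-arm re-entries are legitimate entries: they occur in real mazes, they
break alternation windows, and they count in the denominator.  The
recognition index is `t_novel / (t_novel + t_familiar)`; records with
total exploration below 5 s are excluded, not scored.  Group comparison is
one-way ANOVA with Fisher's LSD on the pooled within-group variance
(t with N − k df); variance homogeneity uses the Brown–Forsythe variant of
Levene's test (absolute deviations from group medians; `center="mean"`
gives the classic form).  Zero pooled within-group variance is flagged
degenerate and p collapses to the smallest representable positive value
when means differ.

## Synthetic generator

The generator emulates the target study design: three groups (control
first) × 10 replicates over 200 proteins by default.

* **Network:** Erdős–Rényi G(n, p) with `p = mean_degree/(n − 1)`, default
  mean degree 6.  Only first-neighbor adjacency enters the statistic, so no
  richer topology (scale-free degree, clustering) is modeled.
* **Abundances:** `exp(baseline_i + shift_{i,g} + ε)` with per-protein
  baselines ~ N(8, 1.5²) and i.i.d. replicate noise ε ~ N(0, 0.35²) on the
  natural-log scale — a ~35% replicate CV, typical of label-free
  quantification.  A planted module adds δ to the seed **and its direct
  neighbors** in one non-control group; a planted pathway adds +shift to
  activators and −shift to repressors.  The control group never carries a
  shift (attempting to plant one is a configuration error).
* **Pathways:** random member sets (default 20 sets of 10) with
  `round(size × repressor_fraction)` repressors, rounding half up.
* **Behavior:** arm sequences never re-enter the arm just left, and each
  subsequent entry completes an alternation with probability exactly
  `alternation_prob` — giving the closed-form oracle
  `E[alternation %] = 100 p` used by the tests.  Real mice do re-enter
  arms; the scoring function handles such sequences, the generator simply
  does not emit them.  Exploration totals are exponential (default scale
  22.41 s puts ~20% of animals under the 5 s exclusion threshold) and are
  split novel/familiar by a Beta fraction with mean `novelty_preference`
  and concentration 20.
* **Reproducibility:** all randomness descends from one scenario seed
  through fixed named sub-streams (`numpy` `SeedSequence` spawn keys), so
  artifacts are bit-reproducible and independent of generation order.

**What passing tests show — and don't.** The generator draws i.i.d.
Gaussian log-noise with no missing values by default, no
intensity-dependent variance, no batch structure, and no correlation
between interaction topology and abundance.  Null calibration and
planted-effect recovery under these conditions validate the inference
machinery, not its behavior under real LC-MS artifacts (missingness not at
random, shared-peptide effects, normalization error).

## Problem sizes and numerical choices

Calibration checks run at the design size (200 proteins × 2 contrasts, 999
permutations per seed protein; 500 pathways × 2 contrasts for uniformity),
and recovery checks at 60–100 proteins × 100 replicate studies — sizes at
which the permutation machinery is exercised end to end in seconds.
Planted recovery uses δ = 3 × noise_sd for modules and a unit per-member
shift for pathways.  Ranking for "top seed" breaks p-value ties (the
floor 1/(n_perm+1) is shared by every saturating seed) by the null
z-score `|mean − null_mean| / null_sd`.  Hierarchical clustering rows are
sorted by protein id before linkage, making leaf order deterministic and
input-order invariant; average linkage on Euclidean distances over logFC
rows, zero distances allowed.

## Known limitations

* Identifier namespaces must already agree across the abundance table,
  edge list and gene sets; no id mapping is attempted and mismatches
  surface as unmapped-id warnings or lookup errors.
* The module statistic treats the network as unweighted and undirected;
  edge confidence scores, if present in the input columns, are ignored.
* The exhaustive pathway null with mixed signs is exhaustive over subsets
  but not over sign assignments.
* Pathway and module p-values are marginal; no joint or hierarchical
  control across the two levels is attempted.
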