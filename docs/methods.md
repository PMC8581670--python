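# Methods

## What the package computes

`scnkit` analyzes group differences in the *structural covariance
network* (SCN) of the cerebral cortex. Nodes are atlas regions (by
default 360, split 180 per hemisphere); the edge weight between two
regions is the Pearson correlation, across the subjects of one group, of
their mean cortical thickness (CT) after nuisance removal. The analysis
proceeds in fixed stages:

1. **Residualization.** For every region, CT is regressed by ordinary
   least squares on an intercept plus nuisance covariates — by default
   age (years), sex (F=0/M=1 indicator) and the subject's overall mean
   CT (the unweighted mean of all regional values). Residuals carry
   forward. The fit is pooled across all subjects by default; a
   `per_group` scope refits within each group (unstable below ~15
   subjects with three covariates, hence not the default).
2. **Network construction.** Per group, the N×N Pearson matrix of the
   residuals is thresholded to a fixed edge density (*sparsity*, default
   15% of the N(N−1)/2 region pairs) and binarized. Ranking is by signed
   r by default (retain the most positive correlations — the dominant
   convention for CT covariance); an `absolute` rule is available and
   recorded in the run manifest. The retained edge count is
   `round(s·N(N−1)/2)` with Python's round-half-to-even; at N=360 and
   s=0.15 that is exactly 9,693. Ties at the cutoff are broken by
   lexicographic region index, so replicated runs are bit-identical.
3. **Efficiency metrics.** Global efficiency
   `GE = (1/(N(N−1))) Σ_{i≠j} 1/L_ij` uses unweighted shortest-path
   lengths with disconnected pairs contributing 0, so disconnected
   graphs are handled without special cases. Local efficiency is the
   mean over nodes of the GE of each node's neighbour-induced subgraph
   (centre excluded; nodes with fewer than two neighbours contribute 0).
   Normalized efficiencies divide by the mean GE/LE of `n_random`
   (default 100) degree-preserving rewirings of the same network, and a
   network is flagged small-world when `nLE > 1` and `|nGE − 1| ≤ 0.1`.
   The 0.1 tolerance quantifies the qualitative criterion "nGE ≈ 1"; it
   is a documented package convention, not a community standard.
4. **Permutation inference.** Between-group metric differences are
   tested by group reallocation: each of K (default 1,000) replicates
   shuffles the subjects' prepared regional vectors between the two
   groups (sizes preserved), rebuilds both networks at the same
   sparsity, and recomputes the difference. Significance follows the
   one-tailed 95th-percentile critical-value rule at α = 0.05; an
   add-one p-value `(1 + #{null ≥ obs})/(K + 1)` is reported alongside
   and can never be exactly zero. Nodal-degree comparisons reuse the
   same relabeling stream (one shuffle drives all regions, preserving
   cross-region dependence) and are Benjamini–Hochberg corrected across
   the full atlas.
5. **Morphometry statistics.** ANCOVA (OLS partial F for the group
   factor) on per-subject global metrics with age, sex and total
   intracranial volume as covariates; post-hoc two-sided t-tests on
   covariate-adjusted values, Welch by default (pooled optional — the
   correct historical convention is not recoverable, so both exist).
   Spearman rank correlations (midrank ties) between morphological
   features and clinical scores form one BH-FDR family across all
   feature-by-scale pairs with at least 5 complete observations.

## Design choices that were genuinely open

- **Residualization scope.** Whether the regression is fitted pooled or
  within group is not a settled convention; pooled is the default
  because group-wise fits with 12 subjects and 3 covariates are
  unstable. Both are supported and the choice is logged.
- **Signed vs. absolute thresholding** is likewise unstated in much of
  the literature; signed is the default, absolute is a switch.
- **Permutation units.** Residuals are computed once on the observed
  data and then permuted; a strict mode that re-residualizes within each
  relabeled split would couple the stages and is intentionally not the
  default (the permuted unit is the subject's prepared vector).
- **Tail direction.** One-tailed tests need a declared direction; when
  none is configured the direction of the observed difference is used
  and the result is flagged `post-hoc-directional`, so a reader can
  distinguish confirmatory from exploratory calls.
- **p-floor arithmetic.** With K replicates the smallest attainable
  add-one p is 1/(K+1); BH across m regions therefore cannot produce
  q < α unless K is large enough (`1/(K+1) ≤ α·rank/m`). Choose K
  accordingly for nodal analyses (K=1,000 at m=360 supports q≈0.017 for
  a top-6 region).

## The synthetic cohort generator

No regional data are deposited for the population the package targets
(a monogenic SHANK3-deficient autism group, an idiopathic autism group
and typically developing controls, 12/24/25 subjects after exclusions),
so the generator emulates the study conditions with a known ground
truth:

- **Planted covariance.** Each group's regional CT is multivariate
  normal with `Σ = δI + ρA`, where A is a planted adjacency (ring
  lattice for the regular-shifted monogenic group; Watts–Strogatz-style
  small-world graphs at β = 0.2/0.3 for the other two; uniform random
  graphs available) and `δ = ρ·max_degree + noise_sd²`. Diagonal
  dominance (Gershgorin) guarantees positive definiteness with no
  eigenvalue repair. Consequence worth knowing: the edge-level
  correlation is `ρ/δ ≤ 1/max_degree`, so dense planted graphs
  necessarily carry weak pairwise signal; recovery experiments use
  sparse planted graphs (k = 2–4) with small noise, where the planted
  correlations separate cleanly from sampling noise.
- **Covariate effects.** Age is uniform on 2–8 years (the emulated
  cohorts average ~4–5 years), sex is Bernoulli at each group's observed
  ratio (6:6, 20:4, 19:6 M:F), intracranial volume is normal
  (1.35·10⁶ ± 1.2·10⁵ mm³). Linear effects (defaults −0.02 mm/year,
  +0.01 mm for male sex, 10⁻⁸ mm/mm³) plus a per-subject **global
  thickness factor** (SD 0.45 mm) are added to a 2.81 mm baseline with
  group offsets +0.15 (SHANK3) and −0.23 (ASD) mm, emulating the
  reported global means 2.96/2.58/2.81 mm. The global factor is what
  gives "overall mean CT" real work to do as a covariate: it induces the
  shared variance across regions that residualization must remove
  before edge-level structure is visible.
- **Global surface metrics.** Fractal dimension, sulcus depth and
  gyrification are drawn per group at the reported means/SDs,
  independent of the network structure (they exist so the ANCOVA stage
  has realistic inputs, not to encode signal).
- **Clinical scores.** ADOS-2 and Griffiths domain scores (and a general
  developmental quotient) are strictly increasing sigmoid transforms of
  a latent variable with correlation `latent_r` (default 0.62) to the
  standardized thickness of one designated region; ADOS scales are
  negatively linked (higher severity, lower development). Because
  Spearman correlation is invariant under monotone maps, the expected
  rank correlation is `(6/π)·asin(latent_r/2) ≈ 0.60` at the default —
  the scale of the strongest clinical association the pipeline is meant
  to detect. Group-specific score offsets are *not* separately modelled;
  the monotone link is the planted signal. Scores are generated only for
  the two clinical groups; controls carry missing values, which the
  correlation stage tolerates and flags.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions, hemispheric symmetry of covariance, non-Gaussian
thickness distributions, scanner/site effects, motion artefacts, or any
image-domain property. Passing tests therefore demonstrate that the
pipeline is correct and calibrated under its own distributional
assumption (pairwise linear correlation); they do not validate the
biological claims one might make from real data.

## Numerical choices

- Shortest paths: level-synchronous BFS from all sources at once (one
  boolean matrix product per level). Verified in tests against a
  separately coded Floyd–Warshall oracle to 1e-12 and against networkx.
- Degenerate inputs: constant regions get zero correlations with a
  logged warning (hard-fail configurable); graphs whose random-ensemble
  mean efficiency is zero report NaN normalized values, never
  infinities; rewiring proposals that would create self-loops or
  multi-edges are rejected and retried, with a 100×n_swaps attempt cap
  so rigid graphs terminate.
- Serialization uses `%.17g` and round-trip float parsing, so
  write-then-read is exact; sex is encoded M/F on disk and F=0/M=1 in
  regressions.
- A single master seed spawns per-stage substreams
  (`numpy.random.SeedSequence`), making full runs byte-reproducible
  (run logs deliberately carry no timestamps).

## Problem sizes used in the shipped studies

The calibration and recovery studies run at reduced scale, chosen so the
suite completes on a desktop: type-I error uses 60 regions, groups of
12/24, K = 200 and 500 simulated null datasets (binomial 3-SE band
around 0.05 is ±0.029); edge recovery uses one 500-subject group on 36
regions; the nodal power study uses 60 regions, 500 subjects per group,
K = 499 and 100 datasets. Full-scale runs (360 regions, K = 1,000,
n_random = 100) are supported by the same code paths and are what the
CLI defaults execute.

## Known limitations

- Binary undirected networks only: no weighted, partial-correlation or
  regularized-precision variants, and no betweenness/clustering/
  modularity/rich-club metrics.
- The normalization ensemble treats the rewired mean as a point
  estimate; no confidence interval on nGE/nLE is propagated.
- Permuting prepared residuals (rather than re-residualizing per
  replicate) is exact only when nuisance effects are group-independent;
  the strict mode exists for sensitivity analyses.
- The generator's clinical link ties all scales to a single region;
  multi-region or domain-specific links are out of scope.
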