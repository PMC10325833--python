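# Methods

## Community typing

Typing operates on relative genus abundances after removing taxa whose
mean relative abundance across samples is below 0.01% (strictly below;
retained rows are *not* renormalised by the filter — the distance layer
renormalises internally, keeping the filter side-effect free and the
renormalisation point single and auditable).

**Distance.** Between two regularised profiles p′ and q′ the distance is
sqrt(JSD(p′, q′)) with JSD(p, q) = H((p+q)/2) − (H(p)+H(q))/2 and H the
Shannon entropy in nats (so JSD ≤ ln 2). The square root is a true metric
(the triangle inequality is property-tested). Profiles are regularised by
adding a 1e-10 pseudocount and renormalising; this also absorbs the
sub-unit row sums left by the abundance filter. The scalar `jsd` function
itself evaluates the entropy formula exactly (0·ln 0 = 0), so analytic
values such as ln 2 on disjoint supports hold to machine precision.

**Clustering.** k-medoids over the distance matrix. Instances with at most
300 candidate medoid sets are solved exactly by enumeration; larger
instances (including the n = 83 cohort for every k ≥ 2 searched) use the
classical PAM BUILD + best-improvement SWAP local search with full swap
neighbourhood. All ties break toward the lowest sample index, making the
result deterministic given the matrix. The exact path exists because SWAP
local optima differ from the global optimum on a small percentage of tiny
instances, and for tiny problems enumeration is both cheaper and stronger;
any global optimum is a fortiori a SWAP-stable solution.

**Model selection.** k is searched over 2..6 (the search range is a
package default; it can be widened) and chosen to maximise the
Calinski–Harabasz index in distance form: with ordered-pair sums,
W = Σ_clusters (1/(2 n_c)) Σ_{i,j∈c} d²ᵢⱼ, T = (1/(2n)) Σ_{i,j} d²ᵢⱼ,
B = T − W and CH = (B/(k−1)) / (W/(n−k)). On Euclidean distances this
equals the familiar centroid-based index (tested against scikit-learn's
implementation); W = 0 with distinct clusters returns +inf. Ties in CH
break toward smaller k.

**Silhouette significance.** The observed statistic is the mean silhouette
width of the CH-optimal clustering (silhouette values via scikit-learn on
the precomputed matrix; members of singleton clusters score 0). Null
datasets are formed by independently permuting each taxon column across
samples — this preserves every taxon's marginal distribution while
destroying the inter-taxon covariation that clustering relies on — and are
pushed through the identical distance/PAM/CH pipeline. The p-value is the
add-one permutation estimate (1 + #{null ≥ observed}) / (1 + n_null) with
n_null = 99 by default; under the single-component null design the
rejection rate at α = 0.05 is verified to sit in [0.01, 0.12].

**BCA and drivers.** Between-class analysis column-centres the data
(centring only by default; a `scale` flag standardises, since whether the
original analysis scaled is unknowable from the description), eigen-
decomposes the class-size-weighted covariance of class means (via SVD of
√w·G, rank ≤ k−1) and projects samples onto the axes; the between-inertia
ratio is the class-mean inertia over total inertia. Each type's driver is
the taxon maximising (mean abundance inside − mean abundance outside),
ties broken lexicographically. Types are named E1..Ek (gut) or O1..Ok
(oral) by descending cluster size, as the source numbering convention is
unstated.

## Core microbiome

Presence is abundance strictly greater than zero (no detection floor is
defined anywhere, so none is imposed). A taxon is core at a site when its
prevalence is ≥ the 30% minimum-incidence threshold — the boundary is
inclusive because only taxa *below* the criterion are described as
individual variability; at n = 83 this keeps 25/83 ≈ 0.3012 and drops
24/83 ≈ 0.2892. The cross-site core is the plain intersection of the
per-site cores, reported in gut-table order. (Note that a reported core
inventory can be arithmetically incompatible with a plain intersection —
e.g. a 63-taxon shared core cannot be a subset of a 60-taxon oral core —
so the intersection is this package's documented definition, applied
uniformly rather than reverse-engineering any particular published count.)

## Cross-site statistics

Spearman rho uses mid-ranks (vectorised rank-then-correlate, verified
against `scipy.stats.spearmanr` including ties), with two-sided p-values
from the t approximation appropriate at n ≈ 83; exact enumeration is not
attempted. Constant columns have undefined rho and are reported as missing
with a log entry. Benjamini–Hochberg adjustment is applied across all
pairs of a call, and the headline "significant" flag uses BH at α = 0.05
(raw-p star flags at 0.05/0.01 are also emitted, since the original
marking convention does not state a correction).

Taxon-profile heatmap inputs: each taxon-at-a-site is an object whose
coordinates are its abundances across the shared subjects; Euclidean
distances between these profiles feed UPGMA (scipy average linkage), with
a recorded leaf order and a Newick export (tie merges follow scipy's
deterministic ordering). Both the rho matrix and 1 − rho are exportable,
clearly labelled, since "correlation as a distance" conflates the two.

Bray–Curtis dissimilarity BC = 1 − 2Σmin(x,y)/(Σx+Σy) (scipy), PCoA by
Gower double-centering of −d²/2 and symmetric eigen-decomposition;
negative eigenvalues are reported but never embedded, and explained
fractions are relative to the positive inertia (agrees with scikit-bio's
implementation to 1e-8). PERMANOVA uses the pseudo-F
(SS_between/(k−1))/(SS_within/(n−k)) with SS terms from squared
distances, free label permutation (no strata are defined by the design)
and the add-one p estimate; it is seedable and deterministic, with
scikit-bio's statistic as the test oracle. Kruskal–Wallis is scipy's
mid-rank implementation wrapped to return H = 0, p = 1 when all values are
identical.

## Functional projection

Full phylogenetic metagenome prediction (ancestral-state reconstruction,
NSTI) is out of scope; the package declares a linear surrogate: pathway
abundance = relative abundances × gene-copy matrix. This keeps the
downstream statistics — log₁₀(mean + 1e-12) ranking (the epsilon keeps
zero pathways finite and last; global rescaling shifts all scores equally
and never reorders), Kruskal–Wallis type enrichment with BH control, and
Spearman taxon–pathway grids — operating on exactly the kind of table a
full predictor would produce, while the synthetic reference gives them
controllable ground truth. The representative type of a significant
pathway is the type with the highest mean abundance.

## Synthetic cohort generator

The generator emulates the study design so every stage has ground truth:

- **n = 83 paired subjects**, one gut and one oral sample each.
- **Mixture structure**: three components per site drawn from weights
  (0.34, 0.33, 0.33) — near-equal because the source proportions are
  unpublished. Each component is a Dirichlet over the site's genus panel
  with the component's driver concentration multiplied by a boost of 15
  (total base concentration ≈ 29, so a boosted driver has an expected
  relative abundance around 40% in its own type and ~4% elsewhere — a
  dominant driver genus, as community types show, while leaving enough
  within-type variation that recovery is non-trivial).
- **Depth**: negative-binomial with mean 66,902 and dispersion 10
  (CV ≈ 0.32); only a mean depth is reported by the design, and depth
  variation is what makes prevalence filtering non-trivial.
- **Cross-site coupling**: the four shared core taxa carry a per-subject
  mean-one lognormal factor exp(σZ − σ²/2), σ = 1.2, multiplying that
  taxon's Dirichlet concentration at both sites — inducing positive rank
  correlation without dictating marginals.
- **Core and rare blocks**: twelve shared taxa at concentration ~0.8 are
  effectively always detected at depth ~67k (planted core); twenty taxa
  are zero-inflated with per-sample presence probability 0.15 (< 0.3), so
  the 30% prevalence filter has true negatives.
- **Panels**: ~165 gut and ~135 oral taxa (real genus names plus
  PAC-style placeholder ids) with geometrically decaying concentrations,
  so a realistic tail falls under the 0.01% abundance filter.
- **Seeding**: one integer seed feeds a SeedSequence with one substream
  for cohort-level draws (labels, latent factors) and one per
  subject-site, so adding subjects never reshuffles earlier samples and
  identical seeds give byte-identical tables.

What the generator does **not** emulate: phylogenetic correlation between
related genera, taxonomy misassignment, chimeras, read-level error, or
compositional interactions beyond the Dirichlet's negative correlation.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and calibrated under the planted model, not that the
original biological effect sizes are reproduced.

## Problem sizes and defaults

Pipeline defaults: k searched in 2..6, 99 silhouette nulls, 999 PERMANOVA
permutations, α = 0.05, BH correction — one run of the full paired
pipeline at n = 83 takes a few seconds on one CPU. Calibration checks use
200 cohort replicates (silhouette null, PERMANOVA) and 500 replicates
(Kruskal–Wallis); the PAM-versus-enumeration check uses 50 random
instances with n ≤ 8, k ≤ 3. The acceptance script's recovery sweep uses
10 seeds at the full n = 83 design.

## Known limitations

- `preset("gut-paper")`, `preset("oral-paper")` and `preset("study")`
  return the same paired design (the cohort specification is inherently
  paired); the site-specific names only signal which site a caller
  intends to type.
- The BIOM reader covers the BIOM 2.x HDF5 observation-matrix layout
  (read-only) and ignores sample metadata.
- The Spearman p-values rely on the t approximation, adequate at n ≈ 83
  but not for very small cohorts.
- PERMANOVA supports free permutations only (no restricted designs).
- The gene-copy surrogate is linear by construction; it cannot express
  phylogenetic weighting of gene content.
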