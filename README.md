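# orogut

Paired gut–oral microbiome analysis: community typing (enterotypes and
orotypes), prevalence-based core-microbiome extraction, cross-site
correlation, and functional pathway projection, with a synthetic
paired-cohort generator that plants ground truth for every stage.

## The problem

Gut microbial communities can be stratified into a few discrete
configurations ("enterotypes"), each dominated by a driver genus; oral
communities can be typed the same way ("orotypes"). Given genus-level 16S
abundance tables for the gut and the mouth of the same subjects, this
package answers four questions:

1. **How many community types does each site have, and which genus drives
   each type?** Samples are clustered on relative genus abundances with the
   square-root Jensen–Shannon divergence (a true metric; JSD is bounded by
   ln 2) and partitioning around medoids (PAM). The cluster number k is
   chosen by maximising the Calinski–Harabasz index
   CH = (B/(k−1)) / (W/(n−k)), computed in a distance-only form. The
   significance of the optimal clustering is judged by comparing its mean
   silhouette width s̄ = mean((bᵢ−aᵢ)/max(aᵢ,bᵢ)) against clusterings of
   null datasets in which each taxon is independently permuted across
   samples. Between-class analysis (BCA) and per-type driver taxa (the
   genus most over-represented in each cluster) support the typing.
2. **Which taxa form the core microbiome?** A taxon is core at a site when
   detected in ≥ 30% of samples (the minimum-incidence criterion); the
   cross-site core is the intersection of the per-site cores.
3. **Do the same taxa co-vary between sites?** Spearman correlation of each
   core taxon's gut versus oral abundance across subjects, with
   Benjamini–Hochberg control; plus Euclidean taxon-profile clustering
   (UPGMA), Bray–Curtis PCoA and PERMANOVA of the typed communities.
4. **What functions do the types imply?** A declared linear gene-copy
   surrogate for 16S-based metagenome prediction: pathway abundance =
   relative abundance × gene copies summed over taxa, followed by
   log-mean ranking, per-type Kruskal–Wallis enrichment and taxon–pathway
   correlation.

Because the original cohort's sequencing data is not required, a synthetic
generator reproduces the study design: 83 paired subjects, mean sequencing
depth 66,902 (negative-binomial), three Dirichlet-multinomial community
types per site built around the driver genera *Bifidobacterium* /
*Ruminococcus* / *Prevotella* (gut) and *Neisseria* / *Prevotella* /
*Streptococcus* (oral), four cross-site coupled core taxa
(*Eubacterium*_g11, *Actinomyces*, *Atopobium*, *Enterococcus*), a
universally prevalent core block and a sparse rare block.

## Worked example

```python
import dataclasses
from orogut import *
from orogut.synthetic_cohort import preset

spec = dataclasses.replace(preset("study"), seed=42)
cohort, truth = generate_cohort(spec)

gut = filter_low_abundance(to_relative(cohort.gut))   # drop mean < 0.01%
solution, p = null_silhouette_test(gut, (2, 6), n_null=99, seed=0, site="gut")
drivers, _ = identify_drivers(gut, solution)
print(f"chosen k = {solution.k}")
print(f"CH by k  = { {k: round(v, 1) for k, v in solution.ch_by_k.items()} }")
print(f"mean silhouette = {solution.mean_silhouette:.3f} (null p = {p})")
print(f"drivers = {drivers}")

core = core_intersection(core_filter(to_relative(cohort.gut), 0.30),
                         core_filter(to_relative(cohort.oral), 0.30))
print(f"shared core = {len(core.core)}")
df = same_taxon_cross_site(cohort, core)
print(df[df.significant][["taxon", "rho", "p_adjusted"]].round(4))
```

Output:

```
chosen k = 3
CH by k  = {2: 18.3, 3: 24.1, 4: 16.7, 5: 12.9, 6: 10.7}
mean silhouette = 0.249 (null p = 0.01)
drivers = {'E2': 'Bifidobacterium', 'E3': 'Ruminococcus', 'E1': 'Prevotella'}
shared core = 25
          taxon    rho  p_adjusted
Eubacterium_g11 0.4663      0.0001
    Actinomyces 0.5299      0.0000
      Atopobium 0.4709      0.0001
   Enterococcus 0.6308      0.0000
```

The CH profile peaks at k = 3, so the gut cohort is typed into three
enterotypes, one per planted driver genus; the silhouette null test rejects
"no clustering" at its minimum attainable p (1/(1+99)). The 30% prevalence
filter yields a 25-genus shared core, and exactly the four planted coupled
taxa come out positively correlated between gut and oral abundance after
BH adjustment.

The same analysis is available from the shell: `orogut run --preset study
--seed 42 --out run/` (plus `simulate`, `type`, `core`, `correlate`,
`pathways` sub-commands); every stage writes TSV/JSON artifacts and a
machine-readable `report.json`.

## Layout

- `orogut.abundance_io` — TSV/BIOM tables, validation, normalisation, pairing
- `orogut.synthetic_cohort` — paired-cohort generator, presets, gene-copy refs
- `orogut.community_typing` — sqrt-JSD, PAM, CH, silhouette null, BCA, drivers
- `orogut.core_microbiome` — prevalence, 30% core filter, cross-site core
- `orogut.cross_site_stats` — Spearman/BH, UPGMA, Bray–Curtis, PCoA, PERMANOVA, KW
- `orogut.function_projection` — gene-copy projection, ranking, enrichment
- `orogut.pipeline` / `orogut.cli` — orchestration and the `orogut` command

See `docs/methods.md` for the models, defaults and their rationale.
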