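# commdecay

Distance decay of parasite community similarity with host phylogenetic
and geographic distance.

`commdecay` is an analysis toolkit for surveys of metazoan parasite
communities across related host species (the motivating system is
helminths of deep-sea grenadiers sampled by trawl on a submarine rise).
It asks a classic macroecological question in two "spaces" at once: as
two host species become more distant — phylogenetically (p-distance
between marker sequences) or geographically (km between capture sites) —
how quickly does the similarity of their parasite assemblages decay?

The pipeline covers:

* **Community descriptors** — per-host richness/total abundance
  (infracommunity) and per-species presence, prevalence and mean
  abundance over all examined hosts (component community).
* **Beta diversity** — Jaccard similarity on presence/absence,
  Bray–Curtis on prevalence or mean abundance.
* **Host distances** — uncorrected p-distances with pairwise deletion
  from an equal-length marker alignment; haversine great-circle
  distances between sites (R = 6371.0088 km).
* **Multivariate tests** — one-way PERMANOVA (pseudo-F, label
  permutation), pairwise PERMANOVA with Bonferroni adjustment, PERMDISP
  dispersion homogeneity with Anderson's negative-eigenvalue correction,
  PCoA ordination, UPGMA dendrograms.
* **Distance decay** — for every species pair, one multiple regression
  of `ln(S + ε)` on (p-distance, km), with standardized effect sizes and
  Mantel-style permutation p values that respect the non-independence of
  pairwise rows.
* **Richness GLMs** — Poisson and negative-binomial log-link models of
  per-host richness on fish length and species, AIC ranking and
  likelihood-ratio tests.
* **Accumulation curve** — cumulative taxa vs hosts examined with a
  permutation 95% band.
* **Synthetic assemblages** — a generator with known phylogeny-driven
  and geography-driven occurrence decay, so the whole chain can be
  exercised and validated with no field data.

The central statistic: for species pair (i, j) with similarity S_ij,

    ln(S_ij + ε) = β₀ + β_phy · d_phylo(i,j) + β_geo · d_geo(i,j) + e_ij

with permutation inference on the slope t statistics under joint
permutation of species labels in the similarity matrix (999 permutations
by default; p = (1 + count)/(1 + n_perm), so the floor is 0.001).

## Worked example

Simulate a survey-scale dataset and run the whole chain:

```sh
commdecay simulate --seed 9 --out data/
commdecay run-all --infections data/infections.csv --sites data/sites.csv \
    --alignment data/alignment.fasta --hosts data/hosts.csv \
    --permutations 999 --seed 1 --out results/
```

or drive it from Python:

```python
from commdecay import SimulationConfig, generate_dataset
from commdecay.descriptors import component_profiles
from commdecay.distances import p_distance_matrix, geographic_distance_matrix
from commdecay.decay import build_decay_table, permutation_regression_test

ds = generate_dataset(SimulationConfig(seed=3))
profiles = component_profiles(ds.infections)
table = build_decay_table(
    profiles, "jaccard_presence",
    p_distance_matrix(ds.alignment),
    geographic_distance_matrix(ds.sites, ds.site_of_species),
    epsilon=0.01,
)
fit = permutation_regression_test(table, n_perm=999, seed=1)
print(f"R2={fit.r2:.3f} slope_phylo={fit.slope_phylo:.2f} "
      f"p_perm_phylo={fit.p_perm_phylo:.3f} p_perm_geo={fit.p_perm_geo:.3f}")
```

which prints

```
R2=0.429 slope_phylo=-9.17 p_perm_phylo=0.002 p_perm_geo=0.737
```

Read: across the 28 species pairs, 43% of the variance in log Jaccard
similarity is explained; similarity decays steeply with phylogenetic
distance (negative slope, permutation p = 0.002) and shows no geographic
signal (p = 0.74) — exactly the phylogeny-only decay injected by the
default generator (`lambda_phylo = 8` per unit p-distance,
`lambda_geo = 0`). On the same dataset the infracommunity-level
PERMANOVA gives pseudo-F = 9.88 (p = 0.001) for species differences in
assemblage composition, while PERMDISP finds no dispersion differences
(F = 1.00, p = 0.46), so the PERMANOVA signal reflects location, not
spread.

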