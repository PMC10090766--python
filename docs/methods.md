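# Methods

`commdecay` implements a complete analysis chain for surveys of
metazoan parasite communities across related host species sampled at a
set of localities, organised around a distance-decay question: does the
similarity of two host species' parasite assemblages decline with their
phylogenetic distance and/or the geographic distance between their
capture sites?

## Data model

A dataset is three plain-text files. The infection table is a long CSV
(one row per host individual × parasite taxon with a count); uninfected
hosts are declared with `count=0` rows and retained, because community
descriptors include them while infracommunity-level multivariate tests
exclude them. Sites are decimal-degree coordinates. The host marker
alignment is a pre-aligned FASTA with one equal-length sequence per
species (alignment itself is out of scope; inputs arrive trimmed).

## Community descriptors

Infracommunity descriptors are per-host richness and total abundance.
Component-community descriptors are per-species vectors of
presence/absence, prevalence and mean abundance, with the number of
*examined* conspecific hosts (infected + uninfected) as denominator —
mean abundance sensu Bush, not mean intensity. Morphologically
indistinguishable taxa can be merged through an explicit user-supplied
merge map; nothing is merged automatically.

## Similarity and distance

* **Jaccard similarity** `a/(a+b+c)` on presence/absence; two empty
  communities are defined as identical (J = 1) but this case is excluded
  downstream because uninfected hosts are dropped first.
* **Bray–Curtis similarity** `1 − Σ|x−y| / Σ(x+y)` on prevalence or mean
  abundance vectors.
* **Uncorrected p-distance** between host sequences: mismatches over
  compared sites, with pairwise deletion of any site where either
  sequence has a gap or `N`. No substitution-model correction is applied
  — at congeneric divergences the proportion of differing sites is the
  quantity of interest, and model-corrected distances are deliberately
  out of scope.
* **Geographic distance**: haversine great-circle distance on a sphere
  of mean radius 6371.0088 km. Ellipsoidal geodesics would change the
  distances by well under 1% at the few-hundred-km scale of a regional
  survey and are not used. Each species is assigned one site by majority
  vote among its individuals (a single stray individual caught elsewhere
  is treated as captured with its conspecifics), overridable by passing
  an explicit species→site map.

Log-transformed similarity `ln(S + ε)` feeds the decay regressions.
`ε` defaults to 0 at the operation level with a hard error on `S = 0`,
so the handling of species pairs that share no taxa is an explicit
decision; the orchestrated pipeline sets `ε = 0.01` once, which places
zero-overlap pairs about one natural-log unit below a 3%-similarity
pair rather than at −∞.

## Multivariate tests

All are computed from their defining sums of squares rather than wrapped
from another package, so the permutation machinery is uniform and fully
seeded; scipy/scikit-bio implementations serve as independent
cross-checks in the test suite.

* **PERMANOVA** (one-way): `SS_T = Σ_{i<j} d²_ij / N`, within-group
  analogues per group, pseudo-F from the between/within mean squares.
  The p value permutes individual labels; with the
  `(1 + count)/(1 + n_perm)` convention, 999 permutations floor at
  p = 0.001. Pairwise comparisons run the same test on each two-group
  submatrix with Bonferroni adjustment (`min(1, p × n_pairs)`).
* **PERMDISP**: observations are embedded by principal coordinates
  keeping negative-eigenvalue axes as imaginary coordinates; the
  distance of a point to its group centroid subtracts the imaginary
  contribution and clamps at zero (Anderson's correction). Distances are
  multiplied by `sqrt(n_g/(n_g−1))`: distances to a centroid fitted from
  few points are biased low, and without this adjustment the test is
  anticonservative when group sizes are very unequal. F comes from a
  one-way ANOVA on these distances (parametric p from the F
  distribution) and the permutation p relabels the distances across
  groups. Group centroids (not spatial medians) are used.
* **PCoA / classical scaling**: Gower double-centering and
  eigendecomposition; coordinates from positive eigenvalues only;
  Kruskal stress-1 of the retained configuration is reported as a
  diagnostic only.
* **UPGMA**: iterative merging of the cluster pair with minimal mean
  cross-pair dissimilarity; ties break on the lexicographically smallest
  (label, label) pair so the merge sequence is deterministic.

## Distance-decay regressions

For each unordered species pair the decay table holds the similarity
(one of three metrics: Jaccard on presence, Bray–Curtis on prevalence,
Bray–Curtis on mean abundance), its log transform, the p-distance and
the geographic distance. One OLS fits log-similarity on both predictors
jointly (statsmodels). "Effect size" is reported as the absolute
standardized partial coefficient `|β_j|·sd(x_j)/sd(y)` — the
interpretation most consistent with the magnitudes such analyses report;
partial η² would be an alternative reading and is not computed.

Because every species enters S−1 pairs, the 28 rows of an 8-species
table are not independent and parametric p values are optimistic. The
permutation test therefore defaults to Mantel-style joint permutation of
species labels in the similarity matrix (preserving the pairwise
dependence structure), with plain row permutation available for
comparison; both are two-sided on the slope t statistics. Sidedness is
deliberately two-sided since a decay hypothesis could be tested
one-sided, halving p — users can do that themselves.

## Richness GLMs

Log-link count GLMs of per-host richness on fish length (hosts without a
measurement dropped listwise) and on species (treatment-coded). Fits go
through statsmodels IRLS. The negative binomial uses the
`variance = μ + μ²/k` parameterisation; `k` is profiled on a log grid
(0.01–100, 17 points) and refined by bounded scalar minimisation, and
counts as a parameter in the AIC. Poisson vs negative-binomial ranking
is by AIC alone; predictor significance is a likelihood-ratio χ² between
nested Poisson fits. Host sex is recorded but not modelled (field
samples are typically heavily sex-biased).

## Accumulation curve

Distinct-taxon count against hosts examined, averaged over random
orderings (default 1000), with the empirical 2.5/97.5 percentile
envelope as the 95% band — a percentile band, not a Gaussian
approximation, since the permutation distribution is skewed near the
asymptote. Uninfected hosts are excluded by default; a pooled curve
across host species is produced (per-species curves are available but
need larger samples to be informative).

## Synthetic assemblage generator

The generator reproduces the design of a single-region deep-sea survey
and is the substrate for every end-to-end test. Defaults: 8 host
species with (3, 5, 6, 8, 7, 12, 4, 7) = 52 examined individuals, 8
sites in a 1.5° × 6° box, a 585 bp marker, 35 candidate parasite taxa
(40% digenean / 31% cestode / 29% nematode), and ~11.5% of hosts forced
uninfected — matching the scale of the motivating survey (52 hosts, 46
infected, 35 taxa, 984 worms). `mean_abundance = 2.0` with
`nb_dispersion k = 0.7` was set by a tuning run so the expected grand
total of parasite individuals lands near a thousand.

Host phylogeny is a Yule tree (unit-rate pure birth, ultrametric)
rescaled to `tree_depth = 0.12` expected substitutions/site root-to-tip,
with sequences evolved under Jukes–Cantor closed form per branch —
giving congeneric-scale p-distances of roughly 0.01–0.25. Occurrence of
taxon *t* in species *s* is Bernoulli with
`p = p0 · exp(−λ_phylo · d_phylo(s, a_t)) · exp(−λ_geo · d_geo(s, a_t))`
where `a_t` is the taxon's affinity species/site; counts where a taxon
occurs are negative binomial per host. Decay therefore enters at the
species (occurrence) level, and abundance-based similarity inherits it.
The default sets `λ_phylo = 8` per unit p-distance and `λ_geo = 0`,
emulating the phylogeny-only decay signature in presence/absence data;
a single occurrence-level (λ_phylo, λ_geo) pair cannot simultaneously
produce a geographic effect on abundance-based similarity that is absent
from presence-based similarity, so the default reproduces the
presence/absence pattern and geographic decay is opt-in via `λ_geo`.

What the generator does *not* emulate: parasite life cycles and
intermediate hosts, within-site environmental gradients, taxon-specific
dispersion, detection error in necropsy, and correlated affinities among
related parasites. Passing tests therefore demonstrate correctness of
the statistical machinery under a known generative model, not that real
assemblages satisfy that model.

## Test-scenario parameterisation

Simulation-based checks use deliberately chosen problem sizes:

* Type-I calibration of the decay permutation tests runs 500 replicates
  of the survey-scale null generator (`λ_phylo = λ_geo = 0`) with 99
  permutations per test.
* PERMDISP calibration uses a fully exchangeable null — every taxon
  present in every species (`p0 = 1`) and 20 hosts per species — because
  with species-level occurrence sampling the dispersion null is
  genuinely false in almost every replicate (each species' realized
  taxon set differs, so realized dispersions differ; the reference R
  implementation rejects ~30% of such replicates, ours ~18%). A type-I
  rate is only meaningful where the null holds, and PERMDISP is
  additionally known to be liberal with groups of only 3–8 observations
  even on clean Euclidean data.
* Recovery uses a dense-fauna strong-decay regime (100 candidate taxa,
  `λ_phylo = 12`, `p0 = 0.7`), which yields presence/absence decay of
  R² ≈ 0.5–0.6 at 28 pairs — the regime where a Mantel-style test at
  199 permutations can resolve p ≤ 0.01. At the sparser survey-scale
  default (35 taxa) the injected signal is recovered in sign essentially
  always but reaches p ≤ 0.01 in only ~a third of replicates; that
  power limitation is a property of 8-species Mantel designs, not of the
  implementation.

## Known limitations

* PERMDISP retains some anticonservatism for very small, very unbalanced
  groups; treat dispersion p values near 0.05 with caution at survey
  scale (as any PERMDISP user should).
* The decay regressions assume a single linear trend on the log scale;
  no exponential/nonlinear decay models are fitted.
* p-distances are uncorrected by design; saturation at deep divergences
  would compress the predictor axis.
* The epsilon offset for zero similarity is a genuine analytical choice:
  results for datasets with many zero-overlap pairs depend on it, and
  the package refuses to choose silently at the operation level.
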