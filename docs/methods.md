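# Methods

## Scope and data model

The package analyses small mapped forest plots. A plot is a `StemMap`: a
rectangular extent (default 20 m × 20 m) and a list of trees, each with
plot-local coordinates (origin at the southwest corner, boundaries
inclusive), a species code and a DBH in cm. Only stems with DBH ≥ 5 cm
enter any computation — the standard eligibility floor for structural and
basal-area work in inventory practice; the reader counts and logs excluded
smaller stems so the filter is auditable.

## Spatial structural indices

All four indices are neighborhood statistics over the k nearest neighbors
of each reference tree, k = 4 by default (the classical structural-group
size; per-tree values then live on {0, ¼, ½, ¾, 1}).

- **Uniform angle W.** Neighbor azimuths are sorted; for each circularly
  adjacent pair of rays the smaller angle between them (≤ 180°) is
  compared with the standard angle α₀ = 72° (= 360°/5, the conventional
  value for k = 4); W is the fraction of angles below α₀. A square
  lattice gives 0, a tight one-sided cluster 1; under complete spatial
  randomness the stand mean sits near 0.5 (our Monte-Carlo calibration
  over 200 stands of 500 trees gives ≈ 0.495).
- **Dominance U.** Fraction of neighbors with strictly larger DBH; equal
  DBH counts zero, making the statistic deterministic. This orientation
  (high U = suppressed reference tree) is one of two defensible readings;
  it is exposed as `orientation` and trivially flips. U is a rank
  statistic: any strictly increasing transform of DBH leaves it unchanged.
- **Mingling M.** Fraction of hetero-specific neighbors.
- **Crowding C.** Fraction of neighbors whose crowns overlap the
  reference crown; a neighbor counts when distance < r_i + r_j strictly.
  Crown radii come from a linear DBH model r = c₀ + c₁·DBH with defaults
  c₀ = 0.5 m, c₁ = 0.05 m/cm — a generic closure in the range of
  published subtropical crown allometries, chosen because the data model
  carries only DBH. Both coefficients are config.

**Edge handling.** Plot edges truncate neighborhoods, so three policies
are provided: a buffer strip (default 5 m — edge trees serve as neighbors
but not as references), toroidal wrapping (appropriate for stationary
synthetic stands; also makes the indices exactly translation-invariant),
and none. Field data should use the buffer; all synthetic-study analyses
here use the torus. Neighbor ties in distance are broken toward the
lexicographically smaller tree id so results are reproducible; the
nearest-neighbor search is validated against an exhaustive all-pairs
oracle.

## Diameter (non-spatial) indices

CV is the sample (n−1) standard deviation of DBH over its mean. Skewness
defaults to the population-moment estimator g₁ = m₃/m₂^{3/2}; b₁ and the
bias-adjusted G₁ are selectable because statistical software disagrees on
which of the three "skewness" denotes, and the choice matters at n ≈ 50.
The Gini coefficient is computed on per-tree basal areas π(DBH/200)² by
the sorted-index formula Σ(2i−n−1)x₍ᵢ₎/(nΣx), which is checked to 1e−12
against the mean-absolute-difference definition. Shannon H uses 5-cm
diameter classes anchored at the 5-cm eligibility floor (half-open
intervals), natural logarithm; a species-based Shannon is available as an
optional mode but is not part of the default index set, which is
size-based throughout.

## Carbon accounting

Tree biomass is the power law B = a·DBHᵇ (kg, cm), summed over
stem/branch/leaf/root components when the species entry is split; species
missing from the allometry or carbon-fraction tables fall back to a
mandatory default entry with a logged warning — a 35-species stand will
never have models for every species. Tree-layer carbon is
Σ B·(carbon fraction) scaled by 10⁴/plot-area and kg→Mg. Shrub, herb and
litter pools convert subplot harvests: per-subplot dry-mass density
(kg·m⁻²), averaged within a pool, × 10 → Mg·ha⁻¹, × pool carbon fraction.
Soil stock is Σᵢ SOCᵢ·BDᵢ·Dᵢ·10 in g·m⁻² over layers (SOC in g·kg⁻¹, BD
in g·cm⁻³, D in cm), with /100 to Mg·ha⁻¹; the equation is linear in each
factor and additive over layers, and both properties are tested. Totals
are exact component sums; every pool is reported in Mg C ha⁻¹ (soil also
in its native g·m⁻²). The shipped allometry coefficients and carbon
fractions are a documented synthetic default set in the range of
published subtropical values — placeholders for user-supplied config, not
fitted models.

## Classification stage

Indices are natural-log transformed for normality; a column whose minimum
is ≤ 0 (skewness can be negative) is first shifted by 1 − min and the
shift recorded — a silent failure here would corrupt every downstream
distance. The redundancy filter visits index pairs with |Pearson r| ≥ 0.9
in descending |r| and drops the lower-priority member while both are
present; the default priority is GC, C, W, M, SK, H, CV, U. GC precedes
CV because the two are near-duplicate descriptions of size inequality and
GC is the basal-area-weighted one; among spatial indices crowding ranks
first because it is the only index carrying stand-density information;
dominance ranks last because the between-stand mean of a rank statistic
concentrates tightly around 0.5 and carries little signal. PCA is an
eigen-decomposition of the correlation matrix with a deterministic sign
convention (largest-magnitude loading positive); scores reconstruct the
standardized data exactly. Plots are clustered by Ward linkage on the
leading PC scores and the tree is cut at k = 3; labels are renumbered by
descending cluster mean of PC1 so numbering is stable under row
permutation. k-means with a fixed seed is available as an alternative.

The PC set used for clustering is the smallest covering **90%** of the
variance. An 80% rule was considered and rejected: with 13 plots it
typically truncates to two PCs after the redundancy filter, and the Ward
cut is then frequently dominated by the noise direction contributed by
the dominance index (50-seed median recovery ARI 0.75 at 80% versus 1.00
at 90% on the synthetic study). The threshold is config-exposed.

Cross-type comparisons use one-way ANOVA with Tukey–Kramer
studentized-range p-values (valid for the unequal type sizes 4/5/4) and
an insert-and-absorb compact letter display at α = 0.05. An all-constant
variable is reported as F undefined with a degenerate flag rather than an
error.

## Association stage

Plot distances are Euclidean on z-scored variables (so indices on
different scales weigh equally); the metric is config. The Mantel
statistic is the Pearson correlation of the two upper-triangle vectors;
the null permutes the plot labels of the second matrix (rows and columns
simultaneously), and p = (1 + #{r* ≥ r})/(1 + n_perm), one-sided greater
by default with 999 permutations and a mandatory seed. An exact mode
enumerates all n! relabelings for small n and is used to validate the
sampled p. Under independent random matrices the test rejects at the
nominal 5% level (checked over 1,000 replicates). The Pearson correlation
matrix uses two-sided t-distribution p-values on n−2 df; constant columns
yield flagged NaNs. No multiplicity adjustment is applied by default
across the structure × pool Mantel grid; Benjamini–Hochberg is available
via a flag.

## Synthetic-stand generator

The generator emulates the reference study design: 13 plots of
20 m × 20 m in three latent structural types of sizes 4, 5 and 4; stem
densities spanning 700–1,650 ha⁻¹; DBH from a Weibull shifted to 5 cm and
truncated at 62 cm (inverse-CDF sampling, so no rejection loop); about 35
woody species with geometric abundances dominated by one species (the
pine analogue). Species labels optionally copy the nearest
already-labelled neighbor with probability `mingling_control`, creating
conspecific patches that tune M. Point patterns: binomial (CSR), Thomas
cluster process (parents Poisson, Gaussian offspring wrapped onto the
plot torus to preserve stationarity), or a jittered lattice; an optional
hardcore spacing (default 0.3 m) thins biologically impossible
near-coincident stems and raises an explicit error when the requested
density is infeasible under it.

The three type templates plant the contrasts the classification stage is
supposed to find: Type I — dense tight Thomas clusters with a strongly
right-skewed, wide DBH distribution (high spatial *and* non-spatial
diversity, and distinctly the highest crowding); Type II — looser, thinner
clusters with a narrow symmetric DBH distribution (high spatial, low
non-spatial); Type III — low-density jittered lattice with a narrow DBH
distribution (low both). Planted effect sizes are calibration knobs of
the synthetic world, not estimates of any field system.

Understory coupling: log shrub and herb dry-mass density (kg·m⁻²) is
linear in the stand crowding mean with slope β_under = −2 (crowded
canopies shade out the understory); litter density is 0.8 × the canopy
leaf-biomass density; topsoil SOC rises with herb biomass at
2 g·kg⁻¹ per Mg·ha⁻¹ (the deeper 20–40 cm layer has a lower base and half
the coupling, so SOC declines with depth in expectation). All noise is
log-normal so masses and concentrations stay positive — consistent with
the log-transform step downstream. Three subplots per pool mimic the
field protocol (2 m × 2 m for shrubs, 1 m × 1 m for herbs and litter).
Every generator output is bit-reproducible from its seed.

**What the generator does not emulate:** spatial autocorrelation of tree
size (DBH marks are i.i.d. by default, so planted U contrasts are absent
and U̅ hovers near 0.5), height structure, climate or successional
dynamics, soil chemistry beyond SOC/BD, and measurement error in the
stem map itself. Passing the recovery tests therefore shows the pipeline
is correct and well-calibrated on data with the study's statistical
shape; it does not validate the ecological conclusions on real forests.

## Problem sizes and numerical choices

The validation suite uses: 100 random maps (≤ 200 trees) for the
nearest-neighbor oracle; 200 CSR stands of 500 trees for the index
calibration; 1,000 replicates at 99 permutations for the Mantel null and
1,000 for the ANOVA null; 50 study seeds for the end-to-end recovery;
200 stands for the coupling regression. These sizes give Monte-Carlo
error comfortably inside the stated bands while keeping the whole suite
around a minute of CPU.

Degenerate inputs raise typed errors early: coincident tree coordinates,
≤ k trees, zero-variance DBH for skewness, all-zero basal areas,
overlapping soil layers, missing pools, constant columns under
z-scoring. Distance ties in neighbor selection break by tree id;
equal-DBH neighbors contribute zero to dominance; a crown-touching
neighbor (distance exactly the radius sum) does not count as crowding.
Permutation p-values use the add-one convention (1 + hits)/(1 + n_perm),
so p is never zero and is exact under exchangeability.

## Known limitations

With 13 plots the Ward cut is sensitive to single-plot noise; the
recovery distribution over seeds has a long lower tail (median ARI 1.0,
occasional seeds near 0.5) and k = 3 is an input, not an inference. The
redundancy filter interacts with strongly contrasted data: planted
between-type differences inflate pairwise index correlations above 0.9,
so more columns drop in the synthetic world than one would expect on
field data. The crowding index saturates near 1 in dense clustered
stands, compressing contrast at the top of its range. Litter is coupled
to standing leaf biomass by a fixed ratio rather than a turnover model.
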