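# Methods

## Data model

The unit of observation is a *band set*: the set of distinct PCR fragment
lengths (base pairs, positive integers) an accession shows at an SSR
locus. An empty set is missing data (failed amplification). Allele
identity is the exact integer fragment size; no cross-run binning window
is applied. Band sets are recoded to a 0/1 matrix with one column per
observed (locus, allele) pair; a missing cell becomes an all-zero locus
block tracked in a separate mask, so the conversion round-trips except
that "missing" and "no allele observed anywhere" coincide for an
all-missing locus.

Accession metadata (species group, population, province, longitude,
latitude) is joined by accession id. Every accession belongs to exactly
one population and every population to one species group; the three
grouping modes (`overall`, `by_species`, `by_population`) drive all
group-wise statistics.

## Allele frequencies and diversity statistics

Because the target taxa are polyploid and band dosage is unobservable,
frequencies use the **band-count estimator**: each non-missing accession
contributes its full band set once, and the frequency of allele *a* in a
group at a locus is carriers(*a*) divided by the total band observations.
Vectors sum to one by construction. A codominant-diploid mode is not the
default precisely because >2 bands per accession occur.

Per group × locus cell, from the frequency vector `p`:
`Na = #{p_i > 0}`, `Ne = 1/Σp_i²`, `I = −Σ p_i ln p_i` (nats, 0·ln 0 = 0),
`He = 1 − Σp_i²`, and `Ho` = fraction of non-missing accessions with ≥ 2
bands. `PIC = 1 − Σp_i² − Σ_{i<j} 2p_i²p_j²` is computed once per locus on
frequencies pooled over the whole collection (the PowerMarker convention),
never averaged over groups.

**Averaging order.** Statistics are computed on the group × locus grid
first and then averaged — over groups for the per-locus table, over loci
for the per-group table, over the whole grid for the collection row. A
cell with zero scored accessions contributes a zero row to these means by
default. This is the GenAlEx convention and the reason published SSR
tables show fractional `N`/`Na` and mean `Ne` below 1 (a value impossible
for any defined frequency vector); an `undefined="exclude"` mode drops
such cells and records the effective denominator instead. The per-locus
`N` is the mean number of scored accessions per group — with heavy
amplification failure it sits far below the census size.

## Differentiation

Squared Euclidean distances between binary allele profiles (equivalently,
band mismatch counts) feed an Excoffier-style AMOVA. Sums of squares for
any stratification are obtained from pairwise distances
(`SS(set) = Σ_{i<j} d²_ij / |set|`), variance components by equating
observed to expected mean squares with the standard unequal-size
coefficients, and Phi statistics as component ratios. Negative components
(sampling noise) are truncated to zero before percentages and Phi ratios;
the raw components stay in the output table. With one stratification
column the result is PhiPT (among/within); with two, PhiCT / PhiSC /
PhiST with the usual three permutation schemes (whole populations among
groups; accessions among populations within their group; accessions
across everything). Permutation p-values use `(1 + exceedances) /
(1 + n_perm)`; permutations default to 999 with a mandatory seed in the
pipeline configuration.

Pairwise `Fst` between two groups is the two-group PhiPT, truncated at
zero (and exactly equal to the two-group AMOVA Phi — asserted in tests).
Gene flow uses the island-model estimator `Nm = (1 − Fst)/(4·Fst)`;
non-positive `Fst` maps to `inf` rather than an error.

**Missing-pair imputation.** Loci scored in only one accession of a pair
are excluded and the mismatch count rescaled by (total columns / shared
columns). Pairs sharing *no* scored locus are undefined; under realistic
missingness (~45%) a handful of such pairs occur, and variance partitions
need complete matrices, so the AMOVA/Fst path mean-imputes them from the
defined off-diagonal distances (count warned). `genetic_distance` keeps
them as NaN unless `undefined="mean"` is requested.

Geographic distance is the haversine great circle (Earth radius 6371 km)
between population centroids (accession coordinates averaged per
population). The Mantel statistic is the Pearson correlation over
lower-triangle entries; the one-sided p permutes rows and columns of one
matrix jointly. Null calibration (rejection rate 0.05 ± 0.02 at α = 0.05
over 500 independent random matrix pairs) is part of the acceptance
suite.

## Trees and ordination

The default accession distance is Dice (Nei–Li) on the binary profiles —
the customary choice for banded marker data; Jaccard and simple matching
are available. Neighbor joining follows Saitou–Nei with the Q-criterion;
tied minima resolve to the lexicographically smallest label pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sibling edge so path lengths are preserved. On additive matrices the
generating tree is recovered exactly (tested). Trees are scikit-bio
`TreeNode`s, so Newick serialization (with quoting) and re-parsing are
inherited.

"PCA" of SSR band data is implemented as classical PCoA on the genetic
distance matrix: Gower double-centering of `−½d²` and eigendecomposition.
Axes are eigenvectors scaled by the square root of their eigenvalues;
percent variance is computed over positive eigenvalues only, and negative
eigenvalue mass (non-Euclidean input) is reported, not corrected.

## LDSS core collections

The reduction rule: find the globally closest retained pair (ties in
lexicographic pair order); remove the member whose removal loses fewer
*collection-unique* alleles (bands carried by no other retained
accession); break ties by higher mean similarity to the remaining set,
then by larger accession id. The choice of victim is the one degree of
freedom the strategy description leaves open; preserving unique alleles
maximizes the retention rate the method is evaluated on, and the full
rule is deterministic across runs and platforms (asserted, including
exact equivalence with an independently coded brute-force oracle for
n ≤ 12).

The ladder continues each rung from the previous rung's members, so cores
are nested and `Ra` is monotone non-increasing; an independent
(non-nested) mode restarts each rung from the full bank. Default rung
sizes are `floor(ratio·n + 0.5)` with an explicit `sizes=` override,
since published core sizes do not always follow one rounding rule. The
selected core maximizes `He`, with `I` then `Ne` as tie-breakers —
gene diversity is the primary objective and the first rung wins ties, so
monotone-decreasing ladders keep the largest core. Validation compares
the 18 (or however many) per-locus values of each statistic between core
and original with Welch's two-sample t-test (equal variances not
assumed), α = 0.05: non-significance means the core preserves the
diversity profile.

## Synthetic data generator

The generator emulates a germplasm survey of a predominantly selfing herb
sampled over a ~2000 km range: `n_species` strongly diverged groups, each
with `pops_per_species` local populations of `accessions_per_pop`
accessions, genotyped at `n_loci` multi-allelic loci.

Frequencies follow the **Balding–Nichols** construction, chosen because
its divergence parameter *is* the expected Fst, giving clean truth for
recovery tests: ancestral vectors are flat Dirichlet draws over the
locus's allele count (uniform in `alleles_per_locus`, default 8–30);
species vectors are `Dirichlet(p·(1−θ)/θ)` at `θ = fst_species` (default
0.35); population vectors likewise at `fst_pop` (default 0.15). Each
accession draws two allele copies from its population vector and
collapses to a single band with probability `inbreeding_f` (default 0.97,
reproducing observed heterozygosity near 0.016 with gene diversity near
0.5 — band collapse is the simplest mechanism matching Ho ≈ 0 without a
selfing pedigree). Cells are masked missing i.i.d. at `missing_rate`
(default 0.45, the failure rate implied by per-locus sample sizes around
22 against ~44 accessions per species group in surveys of this kind; no
informative missingness mechanism is modelled).

**Isolation by distance.** With finite `ibd_scale`, populations within a
species are visited in a nearest-neighbour chain from the population
closest to the species centre, each drifting from its predecessor with
step divergence `θ(d) = 1 − (1 − fst_pop)^(d/ibd_scale)` over the gap `d`
km — divergence, measured as `−ln(1−θ)`, accumulates linearly with
distance, and `ibd_scale` (default 500 km) is the distance at which it
equals `fst_pop`. This guarantees a positive expected Mantel correlation.
With `ibd_scale=None` populations are drawn independently from the
species vector (star topology): drift is independent of position and the
Mantel correlation is centred on zero — this is also the configuration
whose pairwise-Fst expectation equals `fst_pop`, used by the recovery
tests. Population placement is a random scatter around species centres by
default; `layout="linear"` spaces them on a west–east transect, the
geometry used for the IBD power study (chain order then matches
geographic order, which a 2D scatter only approximates).

What the generator does *not* emulate: mutation models (SMM/IAM),
linkage, coalescent genealogies, uneven sampling, allele-size
constraints, or genotyping artefacts beyond i.i.d. dropout. Passing
recovery tests therefore shows the estimators are correct under the
stated model, not that real surveys meet its assumptions.

## Problem sizes and numerical choices

Simulation studies in the test and acceptance suites use: 660 accessions
× 50 loci for Fst recovery (tolerance ±0.05 around θ = 0.2), 320 × 40 for
the AMOVA share (±0.07 around 30%), 50 replicate 80-accession transects
for IBD power (≥ 90% detection at α = 0.05), and 500 replicate 20-label
matrix pairs at 999 permutations for Mantel calibration — sizes at which
each check runs in seconds while sampling noise stays well inside the
stated tolerances. Frequency vectors are validated to sum to 1 within
1e-9; symmetry is enforced to machine precision; minimum-distance ties
use an absolute 1e-12 window; Dirichlet concentrations are floored at
1e-6 to avoid degenerate draws near fixation.

## Known limitations

- PhiPT on band data is a variance ratio on presence/absence profiles; it
  tracks, but is not identical to, allele-frequency Fst estimators
  (Weir–Cockerham), and shows the usual slight downward finite-sampling
  bias visible in the AMOVA recovery (≈ 0.28 at θ = 0.3).
- Mean-imputing undefined pairs is neutral in expectation but slightly
  shrinks between-group contrasts when undefined pairs concentrate in one
  group.
- The bundled reference tables carry only printed (rounded) values; the
  underlying raw genotype matrix of the motivating survey is not public,
  so group-level results for that collection cannot be recomputed here.
- Bootstrap support for NJ trees and rarefaction-corrected allelic
  richness are out of scope.
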