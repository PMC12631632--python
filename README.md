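# ssrcore

Population-genetic analysis and core-collection construction for
band-coded SSR (microsatellite) germplasm surveys.

Surveys of wild and cultivated medicinal plants — the motivating case is a
collection of 175 *Polygonatum* (Polygonati Rhizoma) accessions from 35
Chinese populations genotyped at 18 fluorescent SSR loci — typically score
each accession at each locus as a *band set*: the set of PCR fragment
lengths observed. Because the material is often polyploid and highly
selfing, the data are analysed as allele presence/absence rather than
diploid genotypes. `ssrcore` implements the complete analysis chain for
such data:

- **Diversity** per group × locus from band-count allele frequencies
  `p`: observed alleles `Na`, effective alleles `Ne = 1/Σp²`, Shannon's
  `I = −Σp ln p`, observed heterozygosity `Ho` (share of multi-band
  accessions), gene diversity `He = 1 − Σp²`, and Botstein's polymorphic
  information content `PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²`.
- **Differentiation** via AMOVA on squared distances between binary
  allele profiles: hierarchical variance components with permutation
  p-values, pairwise `Φ`-based `Fst`, and island-model gene flow
  `Nm = (1 − Fst)/(4 Fst)`; Mantel tests of genetic against great-circle
  geographic distance (isolation by distance).
- **Trees and ordination**: Dice/Jaccard/simple-matching distances,
  Saitou–Nei neighbor joining with Newick export, classical PCoA.
- **Core collections** by least-distance stepwise sampling (LDSS): the
  closest pair of retained accessions is found and the more redundant
  member removed, down a ladder of sampling ratios; each rung is scored
  by diversity and allele retention `Ra = 100 · Na_core / Na_full`, and
  the core maximizing `He` (then `I`, `Ne`) is selected and validated by
  Welch t-tests across loci plus PCoA/NJ overlays.
- **Synthetic data**: a Balding–Nichols generator of hierarchically
  structured band data (species → populations → accessions) with tunable
  divergence, inbreeding, missingness and isolation by distance, used for
  parameter-recovery and power studies.

## Worked example

```python
from ssrcore import (SimConfig, simulate_dataset, diversity_table,
                     pairwise_fst, LdssConfig, build_ladder, select_core)

cfg = SimConfig(n_species=3, pops_per_species=4, accessions_per_pop=6,
                n_loci=12, inbreeding_f=1.0, missing_rate=0.1, seed=7)
ds, truth = simulate_dataset(cfg)
print(ds)
# GenotypeDataset(72 accessions, 12 loci, 12 populations)

summ = diversity_table(ds, "by_species")
print(summ.to_locus_table().round(3).tail(1).to_string())
#            N     Na    Ne      I   Ho     He    PIC
# Mean  21.778  3.333  2.30  0.883  0.0  0.503  0.733

fst, p = pairwise_fst(ds, "species", n_perm=99, seed=7)
print(fst.round(3).to_string())
#        SPA    SPB    SPC
# SPA  0.000  0.438  0.416
# SPB  0.438  0.000  0.339
# SPC  0.416  0.339  0.000

ladder = build_ladder(ds, LdssConfig(target_ratios=(0.6, 0.45, 0.3)))
print(ladder.to_frame().round(3).to_string())
#             size  ratio       N     Na     Ne      I   Ho     He      Ra
# collection
# Original      72  100.0  21.778  3.333  2.300  0.883  0.0  0.503  100.00
# C43           43   60.0  13.028  3.194  2.420  0.922  0.0  0.531   95.83
# C32           32   45.0   9.639  3.111  2.509  0.941  0.0  0.547   93.33
# C22           22   30.0   6.667  2.833  2.418  0.897  0.0  0.539   85.00

chosen = select_core(ladder)
print(chosen.name, chosen.ra)   # C32 93.33
```

The mean row reads as in a standard survey table: on average 3.3 alleles
per locus per species group, effective allele count 2.3, gene diversity
0.50, and `Ho = 0` because the simulation was fully inbred. The pairwise
`Fst` around 0.34–0.48 reflects the strong between-species divergence of
the generator. Down the LDSS ladder the allele count `Na` necessarily
falls, while `Ne`, `I` and `He` *rise* as redundant accessions are
discarded, peaking here at the 45% rung — which is therefore selected,
with 93% of alleles retained.

The same analyses run from the shell (`ssrcore simulate | diversity |
diff | tree | pcoa | core | run`); `ssrcore run --config run.yaml` drives
the full pipeline and writes TSV/JSON/Newick outputs plus a seed log.

## Bundled reference tables

`ssrcore.datasets` ships the published per-marker diversity table and
core ladder of the 175-accession Polygonati Rhizoma survey (the raw
genotypes are not public). They serve as worked inputs for the
summarizing, gene-flow and core-selection routines and as
internal-consistency fixtures.

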