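# kinnet

Kinship analysis for small, partially sampled wild populations genotyped
at codominant microsatellite loci — built around the situation a field
team faces after years of monitoring a small island population of a
long-lived, live-bearing marine predator: a few dozen photo-identified
adults of which most but not all were biopsy-sampled, near-complete
annual samples of newborn cohorts from several nursery sites, and 14–16
polymorphic microsatellites as the only genetic handle on who is related
to whom, who bred with whom, and whether the small population is
inbreeding.

The package implements the full analysis chain as a tested library:

* **Marker QC** — allele frequencies, observed and unbiased expected
  heterozygosity, exact conditional Hardy–Weinberg tests (enumeration or
  Monte Carlo), null-allele estimators (Chakraborty, Brookfield-1) with a
  homozygote-excess test, genotypic linkage-disequilibrium permutation
  tests, Holm sequential-Bonferroni correction, duplicate-genotype
  detection, locus filtering.
* **Pairwise relatedness** — maximum-likelihood estimation of the
  Cotterman coefficients (k0, k1, k2) over the simplex, relatedness
  r = k1/2 + k2, classification of every dyad into unrelated (U),
  half-sib (HS), full-sib (FS) or parent–offspring (PO) by likelihood,
  and a simulation-based significance test.
* **Genetic network** — a graph whose edges are the first-order dyads
  (PO/FS/HS) weighted by r, degree distributions, and a permutation test
  of within- vs between-group mean relatedness.
* **Parentage and sibship** — LOD-score assignment of offspring to
  sampled candidate parents at a simulated strict-95% Delta threshold,
  then full-likelihood sibship reconstruction by simulated annealing with
  latent (unsampled) parents marginalised exactly over the bipartite
  mother × father family graph, parental-genotype reconstruction by
  max-product message passing, breeder counting, and litter tabulation
  (polyandry, male reproductive skew, nursery fidelity).
* **Inbreeding** — internal relatedness IR = (2H − Σf)/(2N − Σf) per
  individual, a Monte Carlo random-mating null for the mean offspring
  IR, a ≥5-allele locus-subset robustness check, and IR-vs-size /
  stage / cohort summaries.
* **Synthetic data** — a ground-truthed pedigree simulator (biennial
  polyandrous females, skewed male success, nursery fidelity, genotyping
  error, heritable null alleles) so that every stage is testable without
  any external data.

## Worked example

The `analysis/` scripts run the whole chain on the study-shaped
synthetic dataset (85 sampled individuals: 33 adults, 52 juveniles in 29
litters from 41 true breeders; 16 loci, two carrying planted null
alleles):

```
$ python analysis/01_simulate_population.py
wrote 85 sampled individuals (33 adults, 52 juveniles) at 16 loci to results/fixture
planted null-allele loci: LS15, Cli107; outgroup adult: B4

$ python analysis/02_marker_qc.py
16 loci screened; He range 0.458-0.890, 2-13 alleles per locus
null-allele suspects dropped: ['LS15', 'Cli107']
duplicate multilocus genotypes: 0

$ python analysis/03_relatedness_network.py
adult dyads: 528; mean R = 0.063 +/- 0.121
first-order (PO/FS/HS) fraction of dyads: 13.1%
network: 25 significant first-order edges; degree 1.5 +/- 0.6; isolated: ['B4', 'M02']
group relatedness test (residency): p = 5e-05; (sex): p = 0.4077

$ python analysis/04_parentage.py
strict-95% Delta thresholds: mothers 11.28, fathers 5.55
39/52 juveniles assigned to at least one sampled parent: {'father_only': 27,
'unassigned': 13, 'pair': 8, 'mother_only': 4}
sibship replicate agreement: 0.997
breeders: 4+18 mothers, 9+10 fathers, total 41
31 litters; polyandry among multi-young litters: 70% (7/10); fathers with
multiple litters: 63%

$ python analysis/05_inbreeding.py
mean IR: offspring -0.005, adults -0.058
random-mating null (1000 iterations): simulated mean -0.009, one-sided p = 0.413
>= 5-allele subset (12 loci): mean offspring IR -0.004
IR ~ length: slope -0.00031, R^2 0.045, p 0.051
stage ANOVA: F 1.87, p 0.160; cohort ANOVA: F 2.31, p 0.089
```

Reading these numbers: QC recovers exactly the two loci simulated with
null alleles (homozygote excess after Holm correction) and drops them.
Among the adults, mean pairwise relatedness is low (R ≈ 0.06) yet an
eighth of all dyads are first-order relatives, and the significance-
screened network connects every planted family member (the unrelated
outgroup female B4 is isolated; M02's parent–offspring tie was called HS
— a genotyping-error artefact — and pruned by the conservative screen).
Within-residency-group relatedness exceeds between-group relatedness
(p < 0.001) because families were planted inside groups; sexes do not
differ. Parentage assigns 39 of 52 juveniles to at least one sampled
adult; sibship reconstruction then partitions all juveniles into
maternal and paternal families, and the breeder count — sampled parents
plus genotype-reconstructed latent parents — totals 41, matching the
planted truth exactly (cell-by-cell: 22 mothers vs 21 true, 19 fathers
vs 20 true). The three annealing replicates agree on 99.7% of offspring
pairs. The juveniles are not inbred by construction, and the IR test
agrees: observed mean IR is indistinguishable from the random-mating
null, on the full panel and on the high-diversity locus subset alike.

The same stages are exposed as a CLI (`kinnet qc`, `kinnet relate`,
`kinnet network`, `kinnet parentage`, `kinnet inbreeding`,
`kinnet simulate`) for use on real GenePop/CSV data.

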