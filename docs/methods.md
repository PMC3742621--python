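# Methods

`kinnet` reconstructs kinship structure in a small, partially sampled wild
population genotyped at codominant microsatellite loci. The pipeline has
five stages — marker QC, pairwise relatedness, genetic-network analysis,
parentage/sibship reconstruction, and internal-relatedness inbreeding
tests — plus a ground-truthed pedigree simulator used for all testing.
This note records the models, the numerical choices, and the places where
the design was genuinely open.

## Genotype model and marker QC

Genotypes are unordered diploid allele pairs (integer fragment sizes);
a cell is wholly typed or wholly missing (half-calls are rejected at
parse time). Allele codes are opaque: no size binning or stutter
modelling is attempted — binning belongs to the genotyping platform.

Expected heterozygosity uses the small-sample unbiased estimator
`He = 2n/(2n−1) · (1 − Σp²)` because the sample sizes this package is
aimed at are tens of individuals. `Fis = 1 − Ho/He` (undefined at
monomorphic loci).

The Hardy–Weinberg test is the exact conditional test given allele
counts, ordering genotype configurations by their Levene conditional
probability. The configuration space is enumerated lazily; past a cap
(default 2·10⁵ tables — chosen so that the exact path never costs more
than a few seconds) the test switches to Monte Carlo re-pairing of gene
copies with the add-one rule `p = (b+1)/(m+1)`, which cannot return
p = 0. The null-allele screen pairs two frequency estimators
(Chakraborty `((He−Ho)/(He+Ho))` and Brookfield-1 `((He−Ho)/(1+He))`)
with a one-sided conditional test of heterozygote deficit; flags are
raised per locus (not per allele-size class — same decision on data of
this shape, far simpler). Linkage disequilibrium uses the genotypic
G-statistic with a column-permutation null. Multiple testing across loci
uses Holm's sequential Bonferroni.

Both permutation/MC tests are exact but discrete: when the contingency
table is very sparse (few individuals, many genotype classes) large tie
classes of permutations share one statistic value and the p-values
become conservative (never anti-conservative). In our simulations the
genotypic LD test is visibly conservative at ~40 individuals with
5-allele loci and calibrated at ~100 individuals; calibration checks are
run in the latter regime.

## Pairwise relatedness

A dyad's genotypes are modelled through the Cotterman coefficients
(k0, k1, k2) — the probabilities of sharing 0/1/2 alleles identical by
descent — with relatedness `r = k1/2 + k2`. The per-locus likelihood is
`k0·P0 + k1·P1 + k2·P2` with P0 the product of HWE genotype
probabilities, P2 the shared-genotype probability, and P1 routing one
allele through a uniformly chosen allele of the partner (verified against
exhaustive enumeration of ordered IBD configurations to 1e-12).

The ML estimate scans a fixed simplex lattice (step 0.02) and polishes
the best point with SLSQP — deterministic by construction. The four
pedigree hypotheses U (1,0,0), HS (0.5,0.5,0), FS (0.25,0.5,0.25), PO
(0,1,0) are compared by likelihood; ties break toward the less related
category (conservative network construction). Genotyping error is not
modelled at this stage (it is modelled in the parentage stage); loci are
used pairwise-complete. Frequencies default to all genotyped individuals.

Because the ML estimate lives on the closed simplex, `r̂ ≥ 0`: for truly
unrelated dyads the mean of `r̂` is positive (≈ 0.04 at 14 loci with 10
equifrequent alleles in our simulations). This boundary bias is a
property of the estimator, not a defect of the implementation; tests on
unrelated dyads should expect it.

The significance test for a dyad simulates genotype pairs under a null
category (respecting the dyad's typed-locus pattern) and compares the
observed log-likelihood ratio against the simulated distribution. For
network construction over hundreds of dyads, a pooled null is simulated
once per category with per-locus samples stored separately, so each
dyad's null conditions on its own typing pattern; Holm correction across
dyads then controls the family-wise rate of false first-order edges.
Without this screen, roughly 5–10% of unrelated dyads are called HS by
the maximum-likelihood category alone — over ~500 dyads that is dozens
of spurious edges.

## Genetic network

Nodes are individuals, edges only first-order calls (PO/FS/HS) weighted
by r̂; isolated nodes are kept (an unconnected individual is a finding).
Degree summaries include isolated nodes. The within- vs between-group
relatedness test permutes group labels over individuals (statistic:
mean within-group dyadic r minus mean between-group), two-sided with the
add-one rule; 20 000 permutations by default so p < 0.001 is resolvable.
The sex comparison is the same machinery with sex as the label. Note
that with unlinked markers, avuncular and grandparent–grandchild dyads
(r = 0.25) carry exactly the HS IBD profile and are expected to appear
as HS edges; they are genuine close kin, not errors.

## Parentage assignment

Candidate parents are scored with a LOD: the log ratio of P(offspring |
candidate is a parent, co-parent from the gene pool) to P(offspring |
both parents from the gene pool). Genotyping error is a per-individual
per-locus probability *e* (default 0.01) that the observed genotype is an
independent HWE draw; with the error model a Mendelian mismatch costs
`log(1−(1−e)²)` rather than −∞. Assignment confidence uses Delta (best
minus second-best LOD), thresholded by simulation: offspring are
simulated with the true parent present among the candidates with the
stated prior probability, and the critical Delta is the smallest value
at which the requested fraction (default 95%) of above-threshold
assignments are correct. Assignments additionally require a positive
LOD. Strict assignments become hard constraints downstream.

## Sibship reconstruction

The configuration is a pair of partitions of the offspring — maternal
families and paternal families — each family headed by a sampled
candidate or a latent parent; polygamy is allowed for both sexes (a
monogamous run is just a configuration constraint the search never has
reason to respect, and can be imposed by the caller via candidates).

**Likelihood.** The score marginalises every latent head's multilocus
genotype exactly. Families form a bipartite graph (mothers × fathers)
whose edges are matings; each edge carries, per locus, the product over
its offspring of `(1−e)·P(g_o | g_m, g_f) + e·P(g_o)`. Sampled heads
enter through a genotype prior putting mass 1−e on the observed genotype
and e on an HWE draw; latent heads use the HWE prior. Acyclic components
are eliminated leaf-to-root with per-locus rescaling (cost: one G×G
mat-vec per mating per locus). Components with cycles — which real
mating systems produce (polyandrous litters plus males siring litters of
several females) — are scored on their maximum-evidence spanning tree
(edges ranked by offspring count): each cut mating's joint factor
`φ(g_m, g_f)` is replaced by `A(g_m)·B(g_f)/P(g_o)`, the rank-1
approximation that preserves both single-parent marginals exactly, so a
cut edge still channels evidence to each of its parents; only the
residual mother–father coupling of that one mating is dropped.

**Priors.** Attaching a sampled head contributes
`log(p/(1−p)) − log(n_candidates)` where p is the prior probability that
the true parent is among the candidates (defaults 0.5 for fathers, 0.25
for mothers). The number of families per side follows a finite-pool
prior: each offspring's parent is a uniform draw from a pool of N
parents of that sex, giving `Σ_{j<k} log(N−j)` for k families (softened
beyond N so transient search states stay finite). Without this term,
merging two latent families is prior-free and a stochastic search will
collect spurious merges simply by maximising over the many unrelated
pairs whose likelihood ratio is accidentally positive. N is the
investigator's estimate of the breeding population per sex — the same
quantity COLONY-style analyses ask for. The library default is
candidates + offspring (agnostic); the study-shaped analysis passes
~1.5× the photo-identification census by sex.

**Search.** Simulated annealing over moves {move one offspring between
families, merge two families, split a family, swap a family's head
between a sampled candidate and latent}, geometric cooling, steps scaled
to offspring² (default 12·n², minimum 4000), followed by a steepest-
ascent polish; replicate runs (default 3) use independent seeds and the
best replicate is reported together with the cross-replicate pairwise
partition agreement. A brute-force oracle enumerates all partition pairs
for ≤6 offspring with the same score and is required (in tests) to match
the annealer.

**Parental genotypes.** Latent heads' genotypes are reconstructed by
two-pass max-product message passing on the same component trees, giving
per-locus max-marginals; all genotypes tying the optimum within
tolerance are reported as an ambiguity set.

**Counting.** The number of breeders is the count of distinct sampled
parents with ≥1 assigned offspring plus distinct non-empty latent
families per sex. Litters are (mother reference × cohort year) groups
with their sire sets; offspring of unknown cohort are listed separately
and excluded from cycle statistics. The polyandry fraction is multi-sire
multi-young litters over multi-young litters.

## Internal relatedness

`IR = (2H − Σf) / (2N − Σf)` over the typed polymorphic loci of one
individual, where H counts homozygous loci and Σf sums the population
frequencies of the 2N carried allele copies; IR ∈ [−1, 1] and equals 1
iff fully homozygous. Under equifrequent alleles E[IR] tracks the
pedigree inbreeding coefficient F (checked at F = 0 and 0.25).

The random-mating null draws (male, female) pairs uniformly with
replacement from the sampled adults, produces one Mendelian offspring
per pair (loci missing in either parent skipped), and compares the
observed mean offspring IR with the simulated means over (default) 1000
iterations; one-sided p (inbreeding = elevated IR) with the add-one
rule, two-sided available.

The reference gene pool for IR matters: if allele frequencies are
estimated on a sample that *includes* the tested offspring, each
individual's own alleles inflate its carried-allele frequencies and bias
its IR downward relative to simulated offspring that are not part of the
frequency sample — enough to destroy the calibration of the null test.
The analysis therefore estimates frequencies from the sampled adults
when running the null; the function accepts any frequency table and the
choice is the caller's.

The ≥5-allele locus-subset recomputation guards against low-diversity
loci inflating IR; the IR-vs-length regression and the stage/cohort
ANOVAs are ordinary least squares / one-way ANOVA summaries, nothing
more.

One definitional caution: 0.25 is the expected IR for offspring whose
parents are related at r = 0.5 (full siblings or parent–offspring);
offspring of half-sibling matings expect F = 0.125. The package uses the
standard definition throughout.

## Synthetic data

The simulator emulates the study system the package is aimed at: a
small adult pool with biennial female breeding (annual and mixed cycles
available), litters of 1–13 pups from a decreasing size distribution,
1–3 sires per litter with polyandry in most multi-pup litters, male
reproductive success concentrated by Dirichlet-weighted sire sampling
(one concentration knob), nursery-site fidelity, partial adult sampling
and near-complete juvenile sampling, 16 loci with 2–15 alleles per locus
(Dirichlet "empirical-like" frequency profiles or equifrequent), 1%
genotyping error, optional heritable null alleles at designated loci
(null heterozygotes appear homozygous, null/null homozygotes appear
missing), and optional random missingness.

`make_study_fixture` builds a deterministic study-shaped dataset: 33
sampled adults — ten parent+two-offspring family trios, one
parent–offspring pair, one unrelated outgroup female — and 52 sampled
juveniles in 29 litters (2006–2009, four nursery sites) from 41 true
breeders of whom 12 are sampled (4 mothers, 8 fathers); 9 litters are
multi-young, 7 of them polyandrous, and 10 of the 20 fathers sire more
than one litter; loci `LS15` and `Cli107` carry planted null alleles
(frequencies 0.25 and 0.20). The breeding template is fixed; genotypes,
metadata and observation noise are seeded. The same seed yields
byte-identical files.

What the simulator does *not* emulate: population substructure,
linkage between loci, allele-size homoplasy and stutter, age-dependent
sampling bias, and survival/movement dynamics. Tests passing on this
generator demonstrate correctness of the algorithms under the stated
model, not robustness to those real-data complications.

## Problem sizes and tolerances used in tests

Simulation-based tests use 14 loci × 10 equifrequent alleles unless
stated; recovery tests use 500 dyads (relatedness) and 500 offspring / 30
candidates (parentage); sibship recovery uses 10 families of sizes 2–6
with 3 annealing replicates; the exhaustive sibship oracle runs at ≤6
offspring; null-calibration checks use 200 replicate datasets per test
with a KS test at α = 0.01; the IR analytic-expectation check uses
10 000 simulated offspring at 20 loci (tolerance ±0.02). MC p-values
everywhere use the add-one rule; annealing and all simulations are
seeded and deterministic given the seed.
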