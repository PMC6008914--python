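# Methods

## Scientific setting

In populations where deaf individuals preferentially marry one another
(phenotypic assortative mating), recessive deafness alleles at a common
locus are brought together far more often than under random mating.  DFNB1
— the GJB2/GJB6 region encoding connexins 26 and 30 — is the canonical
case: where both partners are homozygous at the same locus every child is
deaf (a *non-complementary* mating), while partners deaf for different
genetic or non-genetic reasons produce hearing children (*complementary*
mating).  Combined with relaxed selection (deaf couples marrying and
reproducing at ordinary rates) and, in South Asia, high consanguinity,
this mechanism is predicted to raise the frequency of the commonest
recessive deafness alleles generation over generation.  The package
implements the full accounting used to examine this in real families —
variant registry, stratified frequencies, mating classification,
two-generation contrast, significance testing, protein profiling — plus a
simulator of the mechanism itself.

## Accounting conventions

* **Denominators.**  Allele frequencies are counted over `2N` chromosomes,
  `N` = sampled individuals in the stratum.  Triallelic calls contribute
  three variant alleles against the unchanged `2N`; digenic calls
  contribute one allele to each gene's tally.  This is the only convention
  under which the reference cohort's per-stratum totals (e.g. 125 variant
  alleles / 236 chromosomes among deaf-by-deaf mates) cohere, so it is
  used package-wide.  Unsampled individuals (genotype `.`) never enter a
  denominator.
* **Effect classes.**  Every variant carries a curated class —
  pathogenic-recessive, pathogenic-dominant, polymorphism, or
  novel-uncertain — that is data, never inferred.  "Pathogenic" tallies
  include the dominant and novel-uncertain classes ("pathogenic mutations
  including the novel variants").  Two borderline GJB2 variants, N62S and
  E147K, default to polymorphism with a configuration switch to
  pathogenic-recessive; several published control-population summaries are
  consistent only with the switch on, so it is exposed rather than decided.
* **Carriers.**  A carrier holds ≥1 pathogenic (incl. novel) allele but is
  not biallelic-pathogenic at any single gene; one heterozygous pathogenic
  allele at each of two genes (digenic) still counts as carriage at each
  gene.  Allele basis divides carried pathogenic alleles by `2N`;
  individual basis divides carriers by `N`.
* **Rounding.**  Internal computation is full precision; display is
  decimal half-up (2 decimals for frequencies, 1–2 for relative
  increases).  Some historically printed figures were truncated rather
  than rounded (52.96 for 125/236 = 52.9661); tests and comparisons use a
  0.01–0.011 tolerance at these points rather than chasing an unstated
  rounding path.

## Mating classification

Families are grouped by offspring phenotype (I all deaf, II all hearing,
III mixed, IV childless; an offspring of unknown phenotype is an error,
not a guess) and, independently, by an eight-way partner genotype cell
with precedence digenic > both-partner GJB2 cells > single-partner GJB2 >
single-partner GJB6 > none.  "Biallelic" means ≥2 pathogenic/novel GJB2
alleles (homozygous or compound heterozygous); polymorphism-only genotypes
count as non-carrier, and a dominant heterozygote (R75Q, R184Q) is
genotype-positive but not biallelic.  A triallelic call with a single
pathogenic allele (W24X/T55T/R127H) is therefore heterozygous for cell
purposes.  Families with an unsampled partner are assigned from the
available partner and flagged, mirroring the footnoted cells of the source
cross-tabulation.  A deaf child carrying exactly one pathogenic allele is
annotated as a pseudo-dominant transmission pattern rather than given a
separate class.

DXN families, where phenotypic complementarity cannot be read off the
offspring, are stratified by mating consanguinity; per stratum the package
reports family counts, affected-offspring rates and the fraction of
families with ≥1 pathogenic/novel-positive partner.

## Two-generation contrast

Only families contributing ≥1 sampled offspring enter the contrast; the
parental pool is their sampled partners, the offspring pool their sampled
children, both under the `2N` convention over GJB2 ∪ GJB6 pathogenic
(incl. novel) alleles.  The relative increase is
`100·(q_off − q_par)/q_par`, undefined (and reported as such) at
`q_par = 0`.  Under Mendelian transmission with flat fertility this
quantity is mean-zero (allele-frequency martingale) — verified over 500
simulated replicate cohorts; a strictly positive mean requires a mechanism
such as over-fertile, allele-enriched deaf×deaf families inside a mixed
cohort, which is exactly the relaxed-selection scenario.  Note that at
complete assortment a sampled cohort is all-DXD and the within-cohort
contrast loses its lever arm; the effect is strongest when DXD and DXN
families are sampled together, as in the study design the package mirrors.

## Chi-square homogeneity

Pearson `Σ(O−E)²/E` with `E_ij = row_i·col_j/grand` and `df = k−1` for a
k×2 table, p from the chi-square survival function, no Yates correction (a
2×2 device; the choice is recorded in the result metadata).  Type-I error
is calibrated on 2000 simulated homogeneous tables at the study's margins
(0.05 ± 0.02).  Recomputing the study's four-stratum table gives 58.22
against a printed 58.21 (rounding path unstated) and an expected
DXD-positive cell of 85.01; the printed expected counts for the control
row (124.88/205.12) are inconsistent with the margin formula (118.87/
211.13) and the package reports its own recomputation alongside the
printed value without asserting either as ground truth.

## Protein property profiling

All twelve descriptors are computed from sequence with bundled, sourced
constant tables (`protparam_data.py`): Expasy average residue masses
(MW = Σ masses + one water), per-residue atomic compositions (+3 atoms for
the terminal water), Bjellqvist pK set with residue-specific terminal
corrections (pI by bisection on [0, 14] to 1e-4; the modeled net charge is
strictly decreasing in pH so bisection is exact to tolerance), Gill–von
Hippel 280-nm extinction (Trp 5500, Tyr 1490, cystine 125; the
all-cystine form exceeds the all-reduced form by 125·⌊nCys/2⌋),
N-end-rule half-life lookup (mammalian reticulocytes), Guruprasad DIWV
dipeptide weights (instability = (10/L)·Σ weights; order-sensitive by
construction), Ikai aliphatic index and Kyte–Doolittle GRAVY (both
composition-only, hence permutation-invariant).  Biopython's
`ProteinAnalysis` is used in the test-suite as an independent cross-check,
never as the implementation.

The bundled connexin-26 sequence is the canonical 226-residue human
protein; its computed profile reproduces the full published native
parameter set (MW 26215, pI 9.11, 18/27 charged residues, 3721 atoms,
52410/51910 extinction, instability 42.8, aliphatic 98.67, GRAVY 0.288),
which doubles as a sequence-identity check.  No authoritative connexin-30
sequence ships with the package: `cx30_synthetic.fasta` is a clearly
labelled synthetic surrogate (the verified connexin core — which conserves
the variant reference residues Q57, E101, R104 — extended to the
documented 261-residue length by an invented hydrophilic tail).  Cx30
results are therefore reported only as mutant-minus-native deltas, which
are scaffold-independent for mass (exactly the residue-mass difference:
+28.06, −0.98, −19.05 Da for Q57R/E101Q/R104H) and for charge counts
(+1 positive, −1 negative, −1 positive); absolute Cx30 values are
computed but never compared against published ones.

## Forward simulator

One major recessive locus (rendered as a pseudo-GJB2 genotype in emitted
cohorts) plus `H` unlinked heterogeneity recessive loci and a non-genetic
deafness probability ε.  Each generation: phenotype (deaf iff homozygous
at any locus, or non-genetically with ε), viability weight `s` on the deaf
phenotype, mating-pool formation in which each deaf individual assorts
with probability `A` (assorting deaf pair among themselves; everyone else
mates at random — every individual mates exactly once, which is what makes
allele frequency a martingale when `s = f_dd = 1`), fertility weight
`f_dd` on deaf×deaf pairs, Mendelian transmission, and consanguinity as
F-inflated autozygosity: a fraction `C` of matings is consanguineous and
their offspring are autozygous per locus with probability `F`, giving
offspring homozygosity `q² + F·q(1−q)` exactly.

Two engines share the parameter set.  The deterministic recursion is the
infinite-population limit, exact for a single locus; with `H > 0` each
locus is updated with the others folded into an independent background
deafness probability, ignoring the cross-locus gametic disequilibrium that
assortment builds (the individual-based engine carries it, so the engines
are compared only at `H = 0`).  The individual-based engine is fully
seeded (identical parameters + seed ⇒ byte-identical cohort files) and
emits two-generation families — DXD where both sampled partners are deaf,
DXN where one is — together with a truth record of every latent genotype.

Defaults mirror a high-consanguinity South Asian setting in which the
major locus explains roughly a third of recessive deafness: q0 = 0.02,
four heterogeneity loci at 0.02, ε = 0.2, A = 0.9, C = 0.3, F = 1/16
(first cousins), flat fitness and fertility unless a scenario sets
otherwise; population 10⁴ for the individual-based engine.  All are
configuration-exposed and none is fit to data.  Consanguinity is modelled
through F rather than explicit cousin pedigrees because the two-generation
output dialect cannot carry deeper loops — a documented limitation.

## What the synthetic data do and do not show

The reference cohorts encode the published genotype inventories and
marginal classifications exactly, so passing tests show the accounting,
classification and testing machinery reproduces the published summaries
from the same inputs.  They do not validate the underlying laboratory
genotyping, and per-individual quantities that were never published
(raw-data cohort frequencies such as 36.98/38.67, overall carrier rates)
are treated as worked-example inputs only, not as reconstruction targets.
The published inventory for DXN hearing partners totals 9 variant alleles
while the stratum summary reports 19/86; the fixture encodes the inventory
verbatim and the package reports the discrepancy rather than reconciling
it.  Simulated cohorts emulate family structure, assortment, consanguinity
and heterogeneity but not ascertainment bias, variable fertility within
mating type, or genotyping error; conclusions about those features cannot
be drawn from passing tests.

## Problem sizes

The test-suite's stochastic checks use deliberately modest sizes chosen
for tight Monte-Carlo bounds at interactive runtimes: 500 replicate
trajectories (N = 400) for martingale neutrality, 200 replicates
(N = 2000) for engine agreement within 3 SE plus an O(1/N) finite-size
allowance, 2000 tables for chi-square calibration, and N = 40–60k single
generations for the autozygosity formula at 3-sigma binomial tolerance.
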