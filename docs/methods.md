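# Methods

`vcqtl` implements variance-component QTL linkage mapping and epistasis
analysis for two-generation crosses between diverged strains (the motivating
system is wild × domesticated Atlantic salmon reared in common-garden
experiments), together with a gene-drop simulator that reproduces the
statistical structure of such experiments.  This note records the models,
the numerical choices, and what the simulator does and does not emulate.

## Data model

A dataset is a semicolon-separated table with seven fixed columns
(individual, dam, sire, family, cross type, length in cm, weight in g),
optional `replicate` and `sex` columns, and one column per SNP marker
(two-character diploid genotypes, `00`/empty = missing).  Founders are rows
without parents.  A 3-column linkage map (marker, chromosome, cM on the
female map, 0-based from the chromosome start) and an optional parent
metadata table (strain, wild/domesticated origin, sex) complete the inputs.
Parent origin is resolved from explicit metadata first, then from the
cross-type labels (`wild`, `domesticated`, `hybrid-DW`, `hybrid-WD`, dam
origin first); conflicting labels are an error.

Parentage is re-checked by Mendelian exclusion: for each offspring, the
markers at which no assignment of its two alleles to the dam and sire is
possible.  Missing calls are skipped and counted.  The default exclusion
rule removes an offspring at ≥ 3 conflicting markers, which tolerates rare
genotyping error while catching true mis-assignment; a simulated dataset
without genotyping error always yields an empty conflict list.

## Phasing and gametic transmission probabilities

Within each family, every offspring allele descends from one of four
parental haplotypes.  For each parent (pooled over all of its mates, so
half-sib groups get a single consistent haplotype labelling) and each
chromosome:

1. The allele transmitted by the parent to each offspring is derived by
   exclusion at each marker where it is unambiguous given the mate's
   genotype.
2. Heterozygous markers are chained into a phase: each offspring votes on
   the orientation of marker *j* through its nearest previous informative
   marker *j′*, with weight 1 − 2r(d) where r is the Haldane recombination
   fraction over d = pos(j) − pos(j′).  The weight is the expected
   correctness margin of a single vote, so long gaps are automatically
   down-weighted.  A simple adjacent-marker majority vote is unreliable
   here because two parents sharing a heterozygous genotype leave few
   doubly-informative offspring.
3. Orientations are then relaxed by a few deterministic sweeps of an
   Ising-style refinement: marker *j* is flipped when the sum of its
   weighted agreement couplings with all other markers of its phase block
   is negative.
4. A link whose net weighted evidence is below 3 starts a new *phase
   block*: with (for example) two heterozygous markers 90 cM apart and ~30
   offspring, no algorithm can orient the pair reliably, and committing to
   a guess corrupts downstream interpolation.  Blocks keep labels internally
   consistent; across blocks the labelling is arbitrary and interpolation
   never bridges a block boundary.

Ties are broken toward the alphabetically first allele, making the whole
procedure deterministic.  Homozygous markers carry confidence 0.5 (both
labellings equivalent).

Multipoint transmission probabilities P(haplotype 1 at x) are interpolated
between the nearest informative flanking markers with the Haldane map
function r(d) = (1 − e^(−2d/100))/2.  With both flanks observed the
conditional is f(h_L→1)·f(1→h_R) normalised over the two states; with one
flank it is 1 − r or r; with none it is 0.5.  Because transmission along a
chromosome is Markov and uninformative markers carry no signal, this equals
the full multipoint conditional — verified exactly against exhaustive
gamete-path enumeration in the test-suite.  Markers at which the parent is
heterozygous but the transmission is ambiguous (both parents share the same
heterozygous genotype and the offspring is heterozygous) are treated as
uninformative; their partial information is deliberately ignored for
simplicity, at a small cost in effective information.

## IBD and kinship matrices

The locus-specific IBD matrix holds pairwise expected *fractions of alleles
shared identical by descent* (full sibs average 0.5 at a random locus, half
sibs 0.25, parent–offspring exactly 0.5, founders of different strains 0,
diagonal 1 for the non-inbred two-generation design).  It is assembled from
the gametic design matrix W (one column per parental haplotype, entries
p/√2 and (1−p)/√2) as WW′ with the diagonal set to 1, then PSD-repaired by
clipping eigenvalues below 1e−8 before factorisation.  The pedigree kinship
matrix is the standard additive relationship from the tabular method (same
scale: full sibs 0.5); for model fitting the offspring sub-matrix is used in
its exact low-rank form BB′ + I/2 (B holding 0.5 in each offspring's dam and
sire columns), which keeps REML trace computations cheap.

Both scales are consistent, so a variance component multiplying either
matrix is interpretable as the corresponding variance on the phenotype
scale; any residual scale convention is absorbed into the component.

## Mixed models and the genome scan

The per-position model is y = Xβ + a + q + e with cov(a) = Va·K (pedigree
kinship), cov(q) = Vq·Q(position) (locus IBD), cov(e) = Ve·I; fixed effects
are strain-cross and replicate (sex optional; individuals missing a
required phenotype or covariate are dropped listwise).  The "adjusted
profile likelihood profiled over random effects" of the Gaussian
hierarchical-GLM formulation coincides with the restricted (REML)
likelihood, which is what the package maximises:

* **AI-REML** (average-information updates, step-halving, a multiplicative
  EM-flavoured fallback, non-negativity floor at 1e−8·var(y)) for all
  *reported* fits — per-QTL Va/Vq ± sd (sds from the inverse AI matrix),
  the joint multi-QTL model, and origin-split fits.  Components may be
  supplied dense or as factor-plus-diagonal, and the factor path is exact
  (per-element diagonals enter the score and trace terms exactly).
  Cross-checked against `statsmodels` MixedLM on the random-intercept
  special case to 1e−3.
* **Exact two-component eigen-REML** for the no-QTL model: one
  eigendecomposition of K reduces REML to a one-dimensional profile over
  Va/Ve.  Heritability is H2 = Va/(Va+Ve) from this model.
* **The scan statistic** is a two-stage profiled LR: with V0 = Va₀K + Ve₀I
  fixed from the null fit, each position's covariance s·V0 + Vq·Q is
  profiled over (s, Vq) after a one-off eigenrotation of Q against V0.  The
  1-D profile over the variance ratio uses a fixed 38-point log grid
  (including 0) with one parabolic refinement step — the *same* statistic
  for observed and permuted data, which is what makes the permutation
  thresholds valid.  LR is floored at 0 (the boundary null).

Genome-wide thresholds follow the permutation approach: phenotype records
(with their covariate rows) are permuted across offspring *within each
full-sib family*, preserving the family/polygenic structure while
destroying within-family marker–phenotype linkage; the 95th/99th
percentiles of the per-permutation genome-wide maximum LR give the 5%/1%
thresholds (an across-family scheme is available).  Nominal per-position
p-values, when requested, use the 50:50 χ²(0):χ²(1) boundary mixture;
genome-wide inference always uses permutation.  Significant regions are
reported as the span of grid positions exceeding the 5% threshold on a
chromosome, with the peak position.

Explained variance is reported under **both** conventions —
100·Vq/(Va+Vq+Ve) ("% phenotypic") and 100·Vq/(Va+Vq) ("% genetic") —
because the field's tables are routinely ambiguous about the denominator.
The relative contribution of domesticated vs wild parents at a QTL splits
the gametic design into origin-specific column blocks with separate
variances; the contribution is 100·Vq_dom/(Vq_dom+Vq_wild).

**A caution on the joint multi-QTL model.**  With ~30 families and a sparse
map, every locus-specific IBD matrix shares the kinship matrix's
between-family block pattern, so the joint model (kinship + several IBD
terms) has a long likelihood ridge between Va and the Vq's.  REML estimates
wander along this ridge and are truncated at Va ≥ 0, which biases the
cumulative "share of genetic variance" upward and makes it unstable between
replicate datasets (seed-to-seed spread above 15 percentage points even
when fitted with the true transmission indicators).  The package reports
the estimates as defined, but single-dataset cumulative shares at this
design scale should be read as rough indications, not stable quantities.

## Family-based fixed-effect and epistasis models

For one parent, z = p − ½ (centred haplotype-1 probability) is the design
column at a locus; the coefficient of z in y = α + zq + e is the allelic
substitution effect q (average difference between offspring inheriting
haplotype 1 vs 2).  With ≥ 2 mates a fixed mate effect is added; the
single-mate case reduces exactly to the plain model.  Loci where a parent
segregates nothing are skipped.

*Gene-by-parent interaction* (half-sib groups, shared parent with ≥ 2 mates
of ≥ 15 phenotyped offspring each; smaller mates are dropped and reported):
the common-allelic-effect model y ~ mate + z is compared with the
mate-specific model y ~ mate + z:mate by LR = n·log(RSS₀/RSS₁), with
χ²(m−1) nominal p for m mates.  Per-mate effects are reported so sign flips
between half-sib families are visible.  The interaction's share of
phenotypic variance is its sum of squares over the within-family-centred
total sum of squares (deviations from each family's own mean), ×100 —
i.e. a share of the variance *within the respective families*, not of the
between-family spread.

*Gene-by-gene interaction* (within full-sib family): for every pair of
locus contrasts (dam or sire, any two loci on different chromosomes or
≥ 50 cM apart — closer pairs are confounded with a single segregating QTL),
the two-locus main-effects model is compared with the model adding the
product column, LR = n·log(RSS₀/RSS₁), χ²(1) nominal p.  The scan is
batched through closed-form Gram-matrix algebra (the ~10⁴ pairs per family
make per-fit OLS machinery impractical); rank-deficient pairs are skipped
and counted.

*Genome-wide significance* for both interaction scans uses a conservative
max-statistic parametric resampling under the no-interaction null: data are
regenerated from the null fitted values (family or mate means) plus
Gaussian residuals (or permuted residuals), the maximum interaction LR over
all tested pairs/loci is recomputed each time, and the genome-wide p is the
(+1-corrected) fraction of null maxima at or above the observed maximum,
with its Monte-Carlo SE; when the observed maximum beats every resample the
value 1/(n+1) is reported as an upper bound.

*Sex linkage*: the dataset-level scan reuses the variance-component scan
with sex coded F=0/M=1 as the response (a linear model on a binary trait, a
documented simplification).  The per-family mode tests each family's
within-family allelic contrasts at every marker of a chromosome and counts
the family when its best p beats a Šidák-corrected 5% level (correcting for
the markers × parents tested on that chromosome); single-sex families are
excluded and counted.

## The simulator

`simulate` performs a gene drop through a configurable two-generation
mating design: founder haplotypes drawn per strain from Balding–Nichols
drifted allele frequencies (drift parameter 0.1 by default) around shared
ancestral frequencies, clipped to an informativeness floor (0.2 by default)
that stands in for the study's marker ascertainment ("SNPs heterozygous in
the parents were prioritised"); meiosis with Poisson crossovers (mean =
map length in Morgans, uniform positions, fair-coin start — the Haldane
model); phenotypes as strain means + replicate and sex effects + additive
QTLs (one Gaussian effect per founder haplotype, scaled to the target
offspring-level variance, optionally with an origin-biased share) + a
pedigree-exact polygenic term (founder values plus Mendelian-sampling
deviations, matching the kinship factorisation used in fitting) +
gene-by-parent interaction terms (a sign-flipping allelic effect of a
shared parent, with magnitude derived from the requested share of
within-family variance; the request is treated as the *observed* SS ratio,
so the derivation subtracts the (m−1)-degree-of-freedom noise term that the
ratio's numerator absorbs, and the carrier's mates are made homozygous at
the interaction marker so the contrast is fully observable —
maximal-information ascertainment) + Gaussian residuals.  Phenotypes are floored just
above zero (weights and lengths are positive).  The hidden truth channel
(true gametes, QTL genotype values, breeding values) never enters the
public files.

The default genome is 29 chromosomes (22 of 90 cM, 7 of 60 cM) with
markers every 30 cM — 109 markers, matching the sparse genome-wide panel
of the motivating studies.  Phenotypic sex is sire-transmitted at
configurable loci (emulating the salmon sex-determination region and its
chromosome mobility), and recorded for a configurable fraction of
offspring.

Presets `dataset1`–`dataset4` reproduce the four study designs: family
counts per cross type (29/41/29/35, totalling 134), parent sharing that
yields 107 distinct wild and 73 distinct domesticated parents and the
half-sib groups the epistasis models need, offspring counts
(2000/2400/1128/1400), strain compositions, phenotype means and standard
deviations, heritabilities (0.22/0.19/0.07/0.28 for weight), cumulative QTL
variance shares, and gene-by-parent interaction loci with within-family
shares spanning 2.5–16.4%.  Three calibration rules are derived from the
model structure: preset QTL and interaction loci sit at marker positions
(off-marker loci would attenuate every fitted quantity); polygenic and
residual variances account for the fact that half of each QTL's variance is
Mendelian-sampling variance that loads on the residual when no QTL term is
fitted; and a parent carrying a configured interaction is made heterozygous
at that locus, otherwise the effect is unobservable in a fraction of runs.

What the simulator does **not** emulate: linkage disequilibrium and allele
sharing between strains beyond the drift model, sex-specific recombination
maps, selection, genotyping error (a flat missing/flip rate can be added
but defaults to zero), non-Gaussian phenotype tails, and common-environment
(tank) effects beyond the replicate factor.  Passing tests therefore
demonstrate correctness of the inference machinery under the declared
generative model, not robustness to these real-data complications.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded per run;
simulator output is byte-identical across runs with the same
configuration.  PSD repair clips eigenvalues at 1e−8; REML convergence is
|ΔlogL| < 1e−6 with a 100-iteration cap and explicit convergence/boundary
flags; collinear fixed-effect columns are pruned deterministically and
factor levels with fewer than two individuals are merged into the reference
with a warning.  Permutation and resampling runs are reproducible from
their seeds; the CLI serialises the resolved configuration (with a hash)
into every output directory.

Problem sizes in the test-suite and acceptance script are chosen to keep
the full runs in the minutes range: calibration uses 200 null replicates of
a 12-family × 12-offspring design with 200 permutations each; parameter
recovery uses 50 replicates of 20 families × 50 offspring on an
informative 10-cM map; the preset-scale model fits (n ≈ 2000) average 4–6
replicate simulations.
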