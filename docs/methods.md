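# Methods

## Scope and data model

The package analyses two kinds of input. Barcode data are per-locus
aligned nucleotide matrices (`LocusAlignment`) with an accession→species
map; genotype data are accession × SNP matrices (`GenotypeMatrix`) of
single-character calls over `{A,C,G,T}` plus `.` for missing and the
two-allele IUPAC letters (`R,Y,S,W,K,M`) for heterozygous calls. All
file I/O is 1-based for genomic positions, as genotype reports print
them; internal indexing is 0-based. Sequence alignment itself, ML tree
inference and read-level variant calling are out of scope: alignments
arrive aligned, ML trees arrive as Newick, genotypes arrive called.

## Distances and the barcoding gap

K2P distances are computed per pair with **pairwise deletion**: each
pair is compared only at sites where both characters are plain
nucleotides, so gaps, `N` and ambiguity codes act as missing data. This
matches the default behaviour of the common distance tools and keeps
gappy spacer loci (one of the shipped locus profiles contains a long
indel region) usable; complete deletion would discard most of their
sites. The deletion convention is echoed in the output headers because
published analyses do not always state it.

A distance is *undefined* when a log argument is non-positive
(saturation) or no sites are comparable. Undefined pairs are carried as
NaN, excluded from summaries and counted in a diagnostics field — never
silently replaced by a cap, which would bias the means.

The summary partitions all defined pairwise distances into intraspecific
(conspecific pairs; species with a single accession contribute nothing)
and interspecific lists. The intra/inter ratio is computed from the
**unrounded** means; rounding (4 decimals for means, 3 significant
figures for the ratio) happens only in formatting. The barcoding-gap
histogram reports an overlap flag (some intraspecific distance ≥ some
interspecific distance), the qualitative definition of an imperfect gap.

## Diversity statistics

Segregating sites count columns with ≥ 2 distinct plain nucleotides;
indel columns never count and are reported separately, matching the
convention of the standard DNA-polymorphism software. π is the mean
per-site p-distance over all pairs, each pair over its own comparable
sites. For Tajima's D, Π (mean pairwise differences, absolute scale) is
taken as π × alignment length — the pairwise-deletion rescaling; for
complete alignments this is exactly the mean raw difference count. D
uses the standard constants and is undefined (with a reason string) for
S = 0 or n < 4. Significance testing of D is not implemented.

## Identification tests

Best match assigns each query the species of its nearest non-self
neighbour; the full tied set at the minimal distance is reported, and a
tie that spans species (or mixes conspecific and heterospecific
neighbours) is *ambiguous* — ties are never broken by input order.
Queries from singleton species are excluded from the denominators: no
conspecific match exists, so including them would deflate rates by a
fixed, uninformative amount. Best close match adds a distance cutoff,
by default the 95th percentile (linear interpolation) of all
intraspecific distances — the convention of the standard barcode-testing
program, which names no cutoff in most published methods sections — and
the threshold used is always echoed in the output. As the threshold
goes to infinity, best close match reduces exactly to best match (a
tested identity). The aggregate "BBA" table is implemented as the
combined best-match / best-close-match rate table across markers and
marker combinations; the underlying program's acronym is not defined
operationally in the literature we follow, so the table is labelled by
what it contains.

## Trees and monophyly

Neighbor joining follows Saitou–Nei with the Studier–Keppler criterion
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·). Ties in Q are broken by the
lexicographically smallest index pair in the current node ordering, so
the algorithm is deterministic with no hidden state; negative
branch-length estimates are clamped to zero. On additive matrices the
generating topology and branch lengths are recovered exactly (tested to
1e-9 on random 8-leaf trees). Bootstrap resamples alignment columns
with replacement and scores each internal bipartition of the original
tree by the percentage of replicate trees containing it; saturated
resamples (undefined distances) are redrawn.

Monophyly is evaluated on the unrooted tree: a species is monophyletic
iff its leaf set is one side of some bipartition, which equals rooted
clade-hood under every rooting outside the species' subtree (verified by
brute force in tests). Singleton species are trivially monophyletic and
are flagged; the headline rate counts **all** species (published
per-species discrimination percentages imply singletons are counted),
while `rate_multi_only` restricts to species with ≥ 2 accessions. No
bootstrap-support threshold is applied to the monophyly verdicts.

## Genotype filtering and the diagnostic key

Site statistics count alleles over non-missing calls, with a
heterozygous IUPAC call contributing half a count to each of its two
alleles; this keeps frequencies summing to one when het calls exist and
reduces exactly to the printed major-allele frequencies on the
all-homozygous shipped panel. Printed-precision frequencies use half-up
rounding to 5 decimals. The quality filter retains sites with major
allele frequency ≤ 0.95 **and** missing fraction ≤ 0.05 **and**
heterozygous fraction ≤ 0.20 (the thresholds of the original GBS
screening) and is idempotent.

A site is *diagnostic* for a species when the species' observed allele
set is non-empty and disjoint from the union of all other species'
allele sets, after expanding heterozygous calls to both alleles and
ignoring missing calls. This is the weakest rule consistent with every
row of the shipped panel, including the rows with within-species
polymorphism; all 30 printed sites satisfy it and no stricter rule
(e.g. fixed differences) would keep them all. Classification of a new
sample casts one vote per key site for every species whose private
alleles intersect the sample's call; the verdict is the plurality
species, with ties and zero votes left unclassified.

## Fst

Genotype calls are treated as haploid alleles — the target taxa are
inbred selfing lines and the shipped panel is purely homozygous — so
heterozygous calls are dropped at that locus for that accession. Nei's
Gst per locus is (Hₜ − Hₛ)/Hₜ; Weir–Cockerham θ uses the haploid
variance components. Multi-locus values combine by ratio of sums
(numerators and denominators summed over loci before dividing), with the
mean-of-ratios also reported because the original analysis tool's exact
convention is not verifiable. Raw (possibly slightly negative) and
clamped values are both kept.

The two estimators measure related but distinct quantities when only two
populations are sampled: in the large-sample limit θ ≈ 2G/(1+G), so
Gst is compressed relative to θ except near 0 and 1. θ was verified to
recover the parametric Fst of a two-deme island-model simulation
(Beta-distributed deme frequencies with known variance); numerical
concordance between the estimators is asserted only in the
weak-differentiation regime where it actually holds. The island-model
identity Nm = (1 − Fst)/(4 Fst) is provided as a naive equilibrium
diagnostic only — it is not a coalescent migration estimate.

## Synthetic data

The generator evolves sequences along a star-of-stars phylogeny under
the K2P process: root → species ancestors (branch =
`interspecific_divergence`, default 0.004 substitutions/site) → tips
(branch = `intraspecific_diversity`/2, default 0.002 between
conspecifics), with transition/transversion rate ratio `kappa`
(default 2). Star trees were chosen over random coalescent genealogies
because they make the expected intra- and interspecific distances
analytically available (conspecific pairs: the configured diversity;
heterospecific pairs: 2×divergence + diversity), which is what the
calibration tests check. Defaults mirror the motivating study's shape:
17 species, 84 accessions (2–9 per species), locus lengths
437/712/582/688 bp; distances land in the published ~0.001–0.005 intra /
~0.009 inter range. Gene flow is modelled as whole-locus lineage
replacement with probability `m` per accession per locus, mirroring
horizontal transfer of a barcode between hybridizing species; events are
recorded as ground truth.

GBS-like matrices plant `n_diagnostic` sites (one cycling target species
with a private allele, optional third-allele exceptions in non-target
species), `n_background` shared polymorphisms whose per-species
frequencies are drawn independently and pulled toward the pooled mean by
`m` (allele-frequency homogenization under gene flow, which makes mean
Fst strictly decreasing in `m`), and `n_monomorphic` uniform sites;
defaults (30/2378/3930 with a 5/3/6-accession, 3-species design) match
the study scale of 6338 raw → 2408 filtered SNPs. Missing and
heterozygous calls are injected per cell at configurable rates (defaults
0.02/0.02, below the filter thresholds).

What the generator does **not** emulate: recombination and linkage,
indel evolution, rate variation across sites, read-level GBS artefacts,
and non-star species trees (so no deep paraphyly except through gene
flow). Passing tests therefore demonstrate correctness of the
statistics and the qualitative response to gene flow, not performance on
the full messiness of real herbarium-grade data.

## Numerical choices and degenerate inputs

Undefined values are NaN plus an explicit reason or counter, never
silent zeros. Ratios are computed from unrounded means; rounding is
formatting. Distance ties in matching report the full tied set; Q-matrix
ties in NJ use the documented lexicographic rule. Alignments must be
non-empty and rectangular; genotype calls outside the alphabet, duplicate
accessions and unlabeled accessions raise typed errors
(`AlignmentLengthError`, `GenotypeFormatError`, `LabelingError`).
Every stochastic routine takes a mandatory seed and is byte-reproducible.

## Test problem sizes

Oracle-equivalence suites run ≥ 20 randomized small instances per
statistic (alignments up to ~30 × 500). The coalescent calibration of
Tajima's D uses 500 neutral replicates at n = 25, θ = 5, asserting the
replicate mean lies within ±0.15 of zero; π recovery uses n = 20,
L = 5000 within 15%; the Fst–migration monotonicity check averages 50
replicates per migration level at 150 loci. These sizes give stable
verdicts for the seeded runs while keeping the default suite fast.

## Known limitations

Gst's two-population compression (above); Π's pairwise-deletion
rescaling is an approximation when missingness is very uneven across
sequences; bootstrap supports are attached only to bipartitions present
in the original tree; the island-model Nm assumes equilibrium and equal
deme sizes; the diagnostic-key vote weights all sites equally regardless
of allele frequency.
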