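# Methods

This note documents the models and procedures implemented in `jvscan`,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken
where the design was genuinely open.

## The biological system being modelled

A hermaphroditic planarian carries four chromosome pairs. Chromosome 1
— the largest, over 40% of the genome — harbours two haplotype classes,
J and V, that stay heterozygous through prolonged inbreeding. Three
observations define the system: (i) meiotic crossovers on chromosome 1
are almost absent (a total genetic length of roughly 0.5 cM against
hundreds of megabases of physical length), consistent with three large
(>20 Mb) nested inversions; (ii) both homozygotes (J/J and V/V zygotes)
die early, so in populations carrying the system every adult is J/V —
a balanced lethal that locks heterozygosity; (iii) the haplotypes have
diverged long enough to date, and divergence is stratified by
inversion, indicating stepwise recombination arrest (evolutionary
strata). The package implements the genotype-level analyses that detect
and quantify each signature.

## Coordinates and containers

All coordinates are 0-based half-open; VCF positions are converted on
read/write. Genotypes are small-int codes (0 hom-ref, 1 het, 2 hom-alt,
−1 missing); haploid gamete calls use 0/1 for the two alleles, 2 for a
heterozygous call in a haploid cell (an amplification artefact), −1 for
missing. Windows tile each chromosome exactly; the final window is
truncated.

## Single-gamete crossover calling

**Marker filtering.** A marker enters phasing iff it is heterozygous in
the parent, segregates (both alleles observed among non-missing gamete
calls, assessed only when ≥3 informative calls exist — the threshold is
declared, not derived), is ≥200 bp from its nearest neighbour (every
member of a closer cluster is dropped, since such clusters usually
reflect collapsed repeats), and is never called heterozygous in a sperm
cell. Heterozygous calls surviving in oocytes at retained markers are
set to missing. All rules are evaluated on the input marker set, so
their order is irrelevant.

**Phasing by minimum recombination.** The phase is the per-marker
allele→haplotype mapping minimising the total number of haplotype
switches summed over gametes. Between two *consecutive informative*
calls of one gamete at markers i < j, a switch occurs iff
`call_i ⊕ call_j ≠ phase_i ⊕ phase_j`; the objective therefore depends
on the phase only through XOR constraints along "edges" (i, j), with
edge span j−i bounded by the longest missing run plus one. The minimum
is found **exactly** by a sliding-window dynamic programme whose state
holds the phases of the last `span+1` markers (cost O(M·2^span); at 5%
missingness the span rarely exceeds 6–8). When missing data make the
window infeasible (state space × instance size beyond ~4×10⁷), a
seeded local search over single-marker and suffix flips takes over.
We chose the DP over a pure hill-climb because the stated contract is
the *minimum*, and the DP attains it provably; the package's own
validation (`jvscan.validation.mpr_oracle_agreement`) compares the
search against brute-force enumeration on random instances of ≤20
markers × ≤10 gametes and agrees in 100% of cases. The phase is
canonicalised so that the first marker of each chromosome maps its
reference allele to J; a global J/V relabelling is an equivalent
optimum and changes no downstream count.

**Imputation.** An informative call is corrected only when *every*
other informative marker in its centred 5-marker window carries the
opposite haplotype. A plain majority vote (3-of-5) would also flip
genuine track-boundary markers whenever a genotyping error sits within
two markers of a true breakpoint, displacing the called interval off
the truth; the unique-supporter rule corrects isolated flips — the only
error mode the symmetric-error model produces in isolation — without
moving boundaries. Windows shrink symmetrically at chromosome ends,
which preserves short terminal tracks. Missing calls are filled by a
strict majority of the four surrounding informative markers; ties stay
missing.

**Crossover vs gene conversion.** Maximal constant-haplotype tracks are
computed per gamete per chromosome; a track's span is the distance from
its first to its last informative marker (marker-to-marker, not
extrapolated into unobserved flanks — conservative, and the only span a
genotype bin can support). An internal track spanning <1% of the
chromosome length, flanked on both sides by the other haplotype, is one
gene-conversion event (shortest first; its flanks then merge and spans
are recomputed). Every remaining track boundary is one crossover,
localised to the interval between the flanking informative markers. A
sub-threshold track at a chromosome end has only one flank — conversion
requires two switches — and counts as a crossover. The 1% rule is
applied in physical bp: a bp threshold can never promote a short
(tens-of-kb) conversion tract to a crossover pair, whereas a
marker-count rule could when two markers fall inside one tract.

**What recovery means.** On simulated data the package scores itself
two ways (`jvscan.validation`). *Detection*: a true breakpoint lies
inside some called event's interval. *Strict*: it lies inside a called
crossover interval. The two differ for crossover pairs closer than
about 1% of the chromosome plus two marker spacings: their short
intervening track is — correctly, per the classification rule — called
a conversion, and a pair whose middle track touches only one marker is
absorbed by imputation (a single off-haplotype marker is 50-fold more
likely to be a genotyping error than a double crossover at these
rates). Both rates use as denominator the breakpoints between the
outermost retained markers; breakpoints beyond them produce no
genotypic signal and are unobservable to any method (both totals are
reported). Under the standard validation conditions (100 gametes × 200
markers, 1 Morgan, 0.5% error, 5% missing, pooled over 10 replicate
datasets) detection recovery is ≈96–97%, strict recovery ≈93–94%, and
false crossovers ≈0.02–0.04 per gamete. With genotyping error present,
a conversion tract with an error in its immediate flank can very rarely
(≈1 per 2,000 tracts) be misread as a crossover pair; error-free tracts
never are.

## Scaffold assignment from chromosome capture

Depths are normalised per sample to a length-weighted mean of 1 (length
weighting keeps short scaffolds from dominating the scale). A
chromosome claims a scaffold iff (reproducibility) the normalised depth
reaches `detect_floor` = 0.2 in ≥ `min_samples` = 2 of its samples and
(specificity) the median depth over its samples is ≥ `enrichment` = 5
times the median over all other samples. One claimant → that code;
none → 0; several → 5. The three thresholds are this package's own
calibration of the reproducibility/specificity principle — a
diploid-level signal must clear whole-genome-amplification background —
and are exposed as CLI flags. Medians, not means, are used across
samples so a single contaminated capture cannot carry a claim. When an
independent contact-based (Hi-C) assignment exists, conflicts with
confident depth codes are resolved in favour of the contact map and
reported.

## Linkage mapping

Marker filters for an F2 intercross: parents homozygous for opposite
alleles, call rate ≥98% of segregants, ≥200 bp spacing, and 1:2:1
segregation by chi-square at α = 0.001. Replicate samples of one
segregant are merged beforehand (consensus by default; first-occurrence
behind a flag). The recombination fraction for a marker pair is the
maximum-likelihood estimate under the intercross likelihood, obtained
by EM over the 3×3 genotype table: all classes except the double
heterozygote determine their recombinant-gamete count; the double
heterozygote contributes 2r²/((1−r)²+r²) expected recombinant gametes.
EM is iterated to |Δr| < 10⁻⁸ from r₀ = 0.25. For the locked
chromosome's real cross (heterozygous × homozygous parents) a backcross
coding is provided: segregants are scored het/hom and r is the direct
recombinant fraction — both codings must be selected explicitly.
Groups are single-linkage components under r ≤ 0.35 and LOD ≥ 3;
ordering is greedy nearest-neighbour seriation refined by 2-opt;
distances use Haldane (d = −50·ln(1−2r) cM) by default, Kosambi
optionally (no interference is simulated, so Haldane is the matching
model). On the synthetic cross (93 segregants, 20 markers per
chromosome) the suppressed chromosome's group collapses to ≈0–1 cM —
the expectation is 2·93·0.005 ≈ 1 recombinant gamete, i.e. about
0.5 cM, with Poisson scatter.

## Population scans

Site filters (presence ≥ 0.75, MAF ≥ 0.04, maximum observed
heterozygosity 0.99) are computed on the input panel, making the filter
idempotent. The >80%-heterozygosity window scan counts, per 10-kb
window, sites at which *strictly more* than 80% of non-missing
genotypes are het; missing genotypes are excluded from the denominator
(declared choice). Ho is the mean per-site het fraction; He the mean
per-site 2p̂(1−p̂) — the plain plug-in by default, with the unbiased
2n/(2n−1) factor behind a flag (the plug-in He is biased low by
He/(2n), so diagonal comparisons at small n should use the unbiased
variant). IBS distance is 1 − mean allele sharing (1 / 0.5 / 0 for
identical genotypes / one shared allele / none) over jointly genotyped
sites, with an average-linkage dendrogram. F<sub>ST</sub> is Hudson's
estimator in the sample-corrected per-site form, combined genome-wide
as a ratio of averages (sum of numerators over sum of denominators),
which is the estimator-of-choice for its insensitivity to rare
variants. The J/V classifier calls an individual J/V when its het
fraction across a chromosome-1 J/V marker panel is ≥0.8, J/J when
≤0.2, and unclassified otherwise or below 20 genotyped panel markers.

## Haplotype-biased expression

Allele counts are summed over all exonic biallelic variants of a gene;
the null of equal expression is tested with the exact binomial
two-sided p at proportion ½, using the minimum-likelihood convention
(sum of probabilities of outcomes no more likely than observed) —
the standard exact definition; doubling-the-smaller-tail is available
behind a flag. Bonferroni multiplies by the number of genes tested in
the run (per tissue when a tissue column is present) and caps at 1.
The exact test is conservative: its size at α = 0.05 is ≈0.04 at depth
200, and power at bias 0.95 with depth 200 is ≈1.

## Strata dating

The de novo mutation rate is estimated at genotype level: candidates
are offspring alleles absent from both parents at callable sites, and
µ = candidates / (2 × callable sites × offspring). Read-level filters
(depth, strand bias) are out of scope and would only lower the
candidate count. Divergence between phased J and V coding sequences
uses Nei–Gojobori (1986) counting: per-codon synonymous site fractions
(mutations to stop codons counted as nonsynonymous), differences in
multi-substitution codons averaged over all minimal mutational paths
(paths through stops excluded when any stop-free path exists), site
counts averaged over the two sequences, and the Jukes–Cantor correction
d = −¾·ln(1−4p/3), undefined (flagged) at p ≥ 0.75. The implementation
is cross-checked in the test suite against an independent NG86
implementation. A stratum's age is **T = dS/(2µ)** generations: after
recombination stops, both haplotypes accumulate substitutions
independently, so pairwise synonymous divergence grows at 2µ per site
per generation. The factor 2 and µ are surfaced in output metadata.
The premature-stop scan counts a CDS once if any in-frame TAA/TAG/TGA
occurs before its final codon, grouped by chromosome and haplotype.

## Phenotype statistics

For n = 4 the five-number summary is lossless under the
inclusive-median quartile convention (Q1 = (x₁+x₂)/2, Q3 = (x₃+x₄)/2):
x₂ = 2Q1 − min and x₃ = 2Q3 − max, with the consistency check
median = (x₂+x₃)/2 to within 0.005 (the rounding of printed values).
This convention was selected because it exactly reproduces both printed
summaries of the knockdown experiment, where the common
linear-interpolation convention does not; the convention used is
reported in the output. The comparison is a two-sided two-sample
Student t-test with pooled variance (df = n₁+n₂−2); Welch is available
but not the default, since the source analysis specifies Student's
test.

## The synthetic-data generators

The generators define the study conditions; their defaults are the
stated design wherever one is stated.

* **Genome fixture**: four chromosomes of 333/120/100/90 Mb; three
  chromosome-1 inversions of 80/60/90 Mb (strata 1/2/3) — a desk-scale
  analogue with the right proportions.
* **Parent**: heterozygous markers placed uniformly within segments,
  with per-segment density proportional to divergence — per-stratum
  defaults {s1: 0.0064, s2: 0.0052, s3: 0.0090} substitutions/site
  (the values the clock implies at µ = 10⁻⁸ and ages 320k/260k/450k
  generations) against a background of 0.001. Marker count per
  chromosome defaults to 200.
* **Gametes**: crossover counts are Poisson with mean equal to the
  chromosome's map length (defaults 0.005 Morgans for suppressed
  chromosome 1 — the 0.5 cM figure — and 0.9/1.1/0.8 Morgans for
  chromosomes 2–4); breakpoints uniform, at half-integer coordinates so
  they never coincide with a marker. No crossover interference is
  modelled — this keeps every expectation analytic — so close double
  crossovers occur at the full Poisson rate, more often than in real
  meiosis. An optional telomere-restricted map places breakpoints only
  in the terminal fraction of the chromosome (default off; the real
  extent of residual telomeric exchange is not quantified). Gene
  conversions are Poisson (0.2 per gamete per chromosome, a scientist's
  round figure; the rate is not reported in the source system) with a
  fixed 50-kb tract — 0.015–0.055% of a chromosome, safely below the 1%
  classification threshold. Genotyping error is a symmetric allele flip
  (0.5%) and missingness 5%, independent per cell — no error
  clustering, no allelic dropout bias, so real single-cell data are
  harder than these tests imply.
* **Populations**: balanced-lethal populations are heterozygous at
  every chromosome-1 marker before any error injection; other
  chromosomes and panmictic populations draw two alleles independently
  at the given frequency (Hardy–Weinberg). The island-panel generator
  additionally makes non-locked islands nearly fixed for the J allele
  at chromosome-1 markers (alt frequency 0.02), emulating J/J-fixed
  populations. No linkage disequilibrium, drift history or migration is
  simulated.
* **Chromosome capture**: a scaffold's depth is lognormal around 1 in
  samples of its true chromosome and around 0.01 otherwise; a sample is
  contaminated (carries a second chromosome's full signal) with the
  stated probability. Contamination variates are drawn unconditionally
  so runs at different rates share one random stream and the
  contaminated sets are nested — this makes the
  ambiguity-vs-contamination monotonicity a property of the model, not
  of the draw.
* **F2**: each segregant is the union of two independent F1 gametes
  drawn under the map; parents are homozygous-opposite at every marker
  (markers violating this are excluded with a warning when parents are
  supplied).
* **Expression**: a gene's depth is split evenly across its variants;
  each variant's J count is binomial at the gene's true bias.
* **Diverged CDS**: the ancestor is built from fourfold-degenerate
  codon families whose first two positions have no synonymous
  alternative (GCN/GGN/GTN/CCN/ACN/TCN), so every synonymous site is a
  third position; each haplotype's third positions evolve under
  Jukes–Cantor for the stated number of generations. This isolates the
  synonymous clock; real coding sequence with nonsynonymous divergence
  and selection would estimate dS with more variance.

Everything is a pure function of (config, seed); fixed seeds reproduce
byte-identical outputs.

## Validation sizes

The self-validation used throughout the test suite and
`scripts/acceptance.py` runs at the design's own sizes: 45 sperm + 28
oocytes for the suppression contrast; 100 gametes × 200 markers × 10
replicate datasets for recovery; 200 random instances for the
phasing-vs-enumeration oracle; 28 individuals × 500 sites/chromosome
for the heterozygosity signature; 2,000 genes at depth 200 for test
size and power; 333,334 codons (≥1 Mb) per stratum for the clock
round-trip; 93 segregants × 80 markers for the map.

## Known limitations

* The phasing DP's exactness guarantee degrades to a local search when
  missing runs exceed the state-space budget; at ≤10% missingness this
  is never observed at the scales above.
* Crossover pairs closer than ~1% of a chromosome are, by the
  classification rule itself, indistinguishable from gene conversions;
  they are detected but not counted as crossovers (see "What recovery
  means").
* The mutation-rate estimator has no read-level error model; on raw
  variant calls it returns an upper bound.
* The Nei–Gojobori dS saturates at p ≥ 0.75 and is flagged, not
  extrapolated.
* The generators' independence assumptions (no interference, no LD, no
  error clustering) make synthetic data cleaner than real data in known
  ways listed above; passing recovery tests bounds algorithmic error,
  not data-quality error.
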