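# Methods

`dustair` re-implements, as a tested pipeline, the statistical workflow of a
settled-dust airborne-microbiome comparison of pig stables, the associated
farmers' homes, and suburban homes. The pipeline starts from an OTU count
table (taxa × samples), sample metadata and consensus taxonomy; upstream
read processing (merging, alignment, chimera removal, OTU clustering,
classification) is out of scope. Because the deposited sequencing data are
not required, a synthetic-study generator reproduces the design's
statistical structure so that every stage can be exercised, calibrated and
tested end to end.

## The analysis model

**QC filtering.** Four rules, applied in a fixed order and logged:

1. *Singletons*: an OTU whose total count across all samples equals exactly
   1 is removed. (A count of 1 in each of two samples — total 2 — is kept;
   an all-zero row is untouched by this rule and dropped only by a final
   empty-row cleanup, which keeps richness well defined.)
2. *Non-target taxa*: an OTU is removed iff its **domain** is Archaea,
   Eukaryota or unknown, its **class** is Chloroplast, or its **family** is
   Mitochondrion — case-insensitive, each rule scoped to its own rank, so a
   genus labelled "unknown" under domain Bacteria survives.
3. *Contaminants*: with all negative controls pooled, an OTU is removed iff
   its maximum count over control samples **strictly** exceeds its maximum
   over real samples. The strict inequality protects genuinely abundant OTUs
   whose reads leak into blanks through tag-switching (index misassignment);
   a tie keeps the OTU. Control columns are dropped afterwards.
4. *Depth*: samples with fewer than 8000 reads are removed; analyses of
   between-sample structure then rarefy the survivors to exactly 8000 reads.

Rarefaction draws each column from the multivariate hypergeometric
distribution on its counts (subsampling **without** replacement), so column
totals equal the target depth exactly and no OTU exceeds its input count.

**Technical replicates.** Replicate pairs are checked by average-linkage
hierarchical clustering of Bray–Curtis dissimilarities on the rarefied
table: a pair is concordant iff its two members are joined as two singleton
leaves (each other's first merge partner). Average linkage is the common
default for community data; the linkage is recorded in the report. After the
check, each replicate group is collapsed to its lexicographically first
sample id — a deterministic stand-in for an arbitrary choice.

**Alpha diversity.** Richness is the number of OTUs with count > 0; the
Shannon index is H = −Σ pᵢ ln pᵢ in natural-log units (H ≤ ln richness).
By default alpha diversity is computed on the filtered, unrarefied table;
a switch (`alpha_on_rarefied`) computes it after rarefaction instead, since
the original workflow does not state which table its diversity estimates
used.

**Group contrasts.** All two-group comparisons use the two-sided Wilcoxon
rank-sum test with midranks: the exact null distribution when n+m ≤ 20 with
no ties, otherwise the normal approximation with tie and continuity
corrections. If both samples are one identical constant the comparison is
flagged degenerate with p = 1. Effect magnitude is the Hodges–Lehmann
estimator — the median of all pairwise between-group differences — reported
signed and as |HL|. Significance level is 0.05 throughout.

**qPCR quantification.** A least-squares standard curve
Ct = slope·log₁₀(copies) + intercept converts Ct values to copies per
reaction (efficiency 10^(−1/slope) − 1 is derived and a non-negative slope
is flagged invalid). Copies are scaled by a single configurable dilution
factor — standing in for the template-to-filter volume chain, which the
original workflow does not print — and divided by the collector's exposure
area (0.0209 m²) to give 16S copies per m².

**Beta diversity.** Bray–Curtis dissimilarity BC = Σ|x−y| / Σ(x+y) on the
rarefied table. ANOSIM ranks all M = n(n−1)/2 dissimilarities (midranks on
ties) and computes R = (r̄_between − r̄_within)/(M/2) ∈ [−1, 1]; the p-value
is the permutation tail (1 + #{R_perm ≥ R_obs})/(1 + n_permutations) under
random relabelling with group sizes fixed (default 999 permutations,
seeded). R is invariant to any strictly monotone transform of the
dissimilarities, and the implementation is cross-checked against an
exhaustive-enumeration oracle and against scikit-bio.

**Differential abundance.** The Monte-Carlo Dirichlet / centered-log-ratio
procedure: counts are first aggregated to the chosen rank (phylum, order,
family or genus; mass unclassified at that rank is pooled under
"unclassified"), then for each of 128 instances a composition is drawn per
sample from Dirichlet(counts + 0.5) and CLR-transformed
(clr(p)ᵢ = ln pᵢ − mean ln p). Within every instance each taxon gets a
Wilcoxon rank-sum p across the two groups (midrank normal approximation —
CLR draws are continuous and group sizes ≥ 10) and the difference of
group-median CLR values. Reported per taxon: the median over instances of
that difference (positive = higher in the first group), the expected p
(mean over instances), and the Benjamini–Hochberg adjustment of the
expected p across taxa at that rank. Effects are also given on the log₂
scale via log₂FD = median_clr_diff / ln 2 — the documented conversion
between the two scales, defined from the same CLR draws. Instances and
prior are the customary defaults of this family of methods. Seasons are
pooled within an environment by default; a stratified option exists.
Group-level composition bar-table summaries weight every sample equally
(unweighted mean of per-sample fractions), so deep samples do not dominate.

**Matched stable–home transfer ranking.** For every farm with both samples
present, the Bray–Curtis dissimilarity between the farmer's home and the
farmer's own stable is ranked (ascending, midranks) among that home's
dissimilarities to *all* stables in the same season stratum; rank 1 means
the home is most similar to its own stable. Ranking within season avoids
cross-season dissimilarity inflation; a farm complete in both seasons
reports its better (minimum) rank, and this per-farm minimum is recorded in
the output together with the number of strata it is a minimum over — a
best-of-k record attains rank 1 with null probability 1 − (1 − 1/m)^k, and
the summary's exact tail test uses exactly that per-record probability, so
the rank-1 count test stays calibrated on two-season designs. (A `pooled`
alternative ranks each matched dissimilarity within the pooled non-matching
dissimilarities.) The summary reports k, the number of rank-1 pairs among
n, with the exact tail probability P(X ≥ k) of the Poisson-binomial sum
over the per-record success probabilities (exact convolution, which reduces
to the plain binomial tail for equal sizes and single-season records), plus
a goodness-of-fit test of the rank
distribution against uniformity: a chi-square over the m rank categories
with a seeded Monte-Carlo null (10 000 draws) when all sizes are equal and
m ≤ 20, otherwise a chi-square over deciles of (rank − ½)/m. The GOF test is
calibrated for single-season designs; the best-of-two-seasons rank is
stochastically smaller than uniform by construction, so on a two-season
study the binomial tail on rank-1 counts is the primary test. "More similar
than non-associated pairs" is operationalised as rank = 1.

## The synthetic study generator

The generator emulates the design: group sizes 43/43/40/41/50/50 per
environment × season (267 study samples), 10 negative controls, 15
technical replicate pairs, and a qPCR panel of 10 samples per group.

**Count model.** Dirichlet–multinomial: each environment has a base
composition over K = 300 OTUs and a concentration θ; a sample's composition
is p ~ Dirichlet(θ·base), its reads multinomial(depth, p) with depth
log-normal (log₁₀ mean 4.3, sd 0.12 — median ≈ 20 000 reads). The original
workflow states no count model; Dirichlet–multinomial is the standard
choice for overdispersed community counts.

**Environment structure.** OTUs are partitioned into taxonomy blocks
(Firmicutes, Proteobacteria, Actinobacteria, Bacteroidetes, a non-target
block of Archaea/Eukaryota/unknown/Chloroplast/Mitochondrion lineages, and
a contaminant block of classic reagent genera). Base compositions come from
three latent sources, each a per-block power-law over a fixed per-source
permutation of OTUs:

* *stable source* — steep (decay 1.35), Firmicutes mass 0.75;
* *background source* — broad and even (decay 0.65), Firmicutes mass 0.35;
  the farm home is the equal mixture of stable source and background,
  giving Firmicutes mass 0.55 and the full long tail of low-abundance OTUs;
* *suburban source* — support restricted to 30% of OTUs per block
  (decay 1.25), Firmicutes mass 0.35.

Concentrations are stable 60, farm home 250, suburban 80. These shape and
noise parameters are free choices, calibrated once, jointly, so that the
generator's own documented contracts hold: within-group Bray–Curtis ≈
0.3–0.6; mean richness ordered farm home > stable > suburban; Shannon
ordered farm home > suburban > stable; Firmicutes fraction ordered stable >
farm home > suburban; ANOSIM separation of stable vs suburban exceeding
stable vs farm home; and a farm-specific pairing signal detectable at
transfer fractions ≥ 0.5 (below). The farm-home concentration is the
largest because the matched-pair signal must survive the home's own
sampling noise; the stable concentration is the smallest so that stables
differ enough from each other for "own stable" to be identifiable at all.

**Seasons.** Season labels follow the design's month ranges. Only the
suburban profile has a composition season shift: its winter composition is
flattened (multiplicative tilt base^(−0.25), renormalised), giving greater
winter richness/diversity and a suburban-only seasonal ANOSIM signal. Only
the stable has an absolute-abundance season shift (+0.25/−0.25 log₁₀ in
summer/winter).

**Absolute abundance.** Per-sample true 16S copies per m² are log-normal
with log₁₀ means 8.5 (stable), 7.0 (farm home), 4.5 (suburban), sd 0.5 —
a stable-to-home gap ≥ 1 order of magnitude and ≈ 4 orders from stable to
suburban. The qPCR measurement adds log-normal noise (sd 0.15 log₁₀).

**Transfer.** A farm home's expected composition is
(1−τ)·home_base + τ·(realized composition of that farm's own stable), using
the *post-noise* stable composition so that τ > 0 produces farm-specific
pairing signal rather than mere environment-level similarity. The default
is τ = 0 — the study's conclusion of no discernible direct transfer. Homes
without a same-season stable partner (the design has 41 summer homes but 40
summer stables) receive no transfer component and are recorded in the truth
file.

**Controls, contamination, replicates.** Negative controls carry Poisson
reads (level 500) for each planted contaminant OTU plus tag-switched reads
drawn from the pooled real-sample composition at 0.5% of the mean depth.
Real samples carry low-level reagent contamination as a depth-independent
additive Poisson count (mean 2 reads per contaminant OTU) — reagent
contaminants enter from the kit, not the dust, so their counts do not scale
with sample depth; this also guarantees the strict-exceedance condition the
contaminant filter needs, which the generator verifies and enforces with a
configuration error otherwise. Technical replicates resample a tightly
jittered copy of the original sample's realized composition
(Dirichlet(p/replicate_noise), default 0.002) at a fresh depth. Collection
days are log-normal around 14, clipped to 7–73, generated but unused by the
default analyses.

**Determinism.** All randomness is split off the master seed through named
child streams (depths, compositions, abundance, replicates, controls, qPCR,
collection days; the pipeline adds streams for rarefaction, ANOSIM,
differential abundance and the transfer GOF), so toggling one stage never
perturbs another's draws and identical configs give byte-identical outputs.

**What the generator does not emulate.** Read-level errors, chimeras,
per-OTU sequence identity, batch effects, sample-to-sample tag-switching,
real taxonomic covariance structure, and the physics of dust settling.
Passing tests therefore demonstrate that the *statistical machinery* is
correct and well calibrated under the design's structure — not that the
pipeline's numerical outputs would match any particular real dataset.

## Problem sizes used by the tests and acceptance script

The calibration/power checks run at reduced but informative sizes chosen as
a matter of experimental design: the transfer calibration uses 30 farm
pairs over 100 (null) and 20 (power) seeded studies; differential-abundance
recovery uses an 8× planted effect with 30 vs 30 samples over 50 runs and a
200-taxon null with 20 vs 20 samples over 100 runs; the ordering checks run
50 full default studies. `scripts/acceptance.py` runs one full default
study (267 samples) end to end.

## Known limitations

* ANOSIM R values on default synthetic data saturate near 1 for the
  stable/suburban and farm/suburban contrasts — the simulated environments
  separate more cleanly than real dust communities; only the *ordering* of
  R values is a modelled feature.
* The per-farm minimum-over-seasons rank concentrates low ranks even under
  the null; the rank-1 binomial test corrects for this (above), but the
  uniformity GOF does not — on two-season designs it is anti-conservative
  and should be read against the per-season records.
* The qPCR volume/dilution arithmetic is a single configurable factor; the
  absolute scale of copies per m² is only as meaningful as that factor.
* BH adjustment treats the per-taxon expected p-values as the test's
  p-values, as the underlying Monte-Carlo method does; FDR control is
  verified empirically under the null in the test suite, not proven.
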