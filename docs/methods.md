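# Methods

This note documents the models, estimators, numerical choices and
limitations behind `transinv`. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Neutral trans-species sharing model

Two populations of diploid sizes N1, N2 split from an ancestor of size Na,
t generations ago, no migration; two gametes are sampled per population.
Time is continuous; a pair of lineages in a population of size N coalesces
at rate 1/(2N) per generation. Sampling two gametes per population is an
upper bound on the sharing probability: larger samples lengthen the time to
the MRCA, adding private polymorphisms faster than shared ones.

**Shared polymorphisms.** A mutation segregates in both samples iff it
subtends exactly one gamete of each pair. Both pairs must therefore reach
the ancestral population uncoalesced — probability
exp(−t/(2N1))·exp(−t/(2N2)) — and, given that, exchangeability of the four
entering lineages makes the expected length of ancestral branches subtending
one gamete per population (4/6)·2Na·... = (4/3)Na (of the 2Na expected
two-descendant branch length, 4 of 6 pairs are mixed). Hence

    E[shared] = exp(−((N1+N2)/(N1·N2))·t/2) · (4/3)·µ·Na

— exact under the model, not an approximation.

**Total polymorphisms, plain form.** Ignoring daughter-phase coalescence,
the genealogy has four branches of length t plus a 4-lineage ancestral tree
of expected length 4Na(1 + 1/2 + 1/3) = 22Na/3:

    E[total] = (22/3)·µ·Na + 4·t·µ,

valid for t small relative to the daughter sizes. The ratio

    fraction = 2·exp(−((N1+N2)/(N1·N2))·t/2) / (11 + 6·t/Na)

is 2/11 at t = 0 and is what `trans_poly_fraction` returns.

**Refined form.** `trans_poly_fraction_refined` replaces the denominator by
the exact expected tree length: each daughter contributes
t + 2N_i(1 − e^(−t/(2N_i))), and the ancestral phase is entered by
K ∈ {2,3,4} lineages with probabilities given by the two independent pair
survival indicators, contributing 4Na·Σ_{i<K} 1/i in expectation. The
numerator is unchanged (a shared polymorphism is impossible once either pair
has coalesced), so refined ≥ plain for t > 0 and both → 2/11 as t → 0.
With equal sizes and τ = t/(2N) the refined form evaluates, at
τ = 0.28/0.15/0.80/0.47 and 1.14/1.16/2.10/1.27, to
0.087/0.122/0.024/0.054 and 0.011/0.010/0.001/0.008 (the test suite pins
this grid): even at τ ≈ 0.3 under half the panmictic supremum, and ~1% by
one coalescent unit — the quantitative basis for calling neutral
trans-specific segregation of several inversions improbable.

**Monte-Carlo oracle.** `simulate_partition` simulates the 2+2 genealogy per
locus (vectorized over loci: explicit case enumeration for K = 2, 3, 4 with
uniformly chosen merge pairs), drops Poisson(µ·branch length) infinite-sites
mutations, and classifies mutations by the gamete set they subtend (shared /
private to either sample / fixed difference). The partition is reported
per locus (components sum to the locus count); a locus with mutations of
several classes — rare at the small per-locus rates used — is assigned by a
uniformly drawn mutation. Agreement: the refined form sits within the
Monte-Carlo standard error out to τ = 2; the plain form's O(τ²) bias is
visible beyond τ ≈ 0.3.

Default per-locus mutation rates: 1e-6 in the closed-form worked examples;
1e-7 (≈ a 100 bp locus at avian per-site rates) where the simulator is
compared to the plain form, keeping the comparison inside that form's
validity regime.

## Divergence and dating

π and d_xy are computed from unphased dosages, each diploid contributing two
chromosomes (neither statistic depends on phase). Per site with k alternate
alleles among n called chromosomes, π uses k(n−k)/C(n,2) (distinct pairs);
d_xy uses p_x(1−p_y) + p_y(1−p_x) (cross-group pairs). Sites with fewer than
4 called chromosomes in a compared set are skipped; per-site scaling divides
by an explicit, caller-supplied callable-site count so the denominator is
auditable rather than a by-product of filtering. d_a = d_xy − (π_x+π_y)/2
may be negative for very recent splits and is reported unclipped (clipping
is applied only to the Weir–Cockerham F_ST fed to the distance regressions).
t = d_a/(2µ) with µ = 2.45e-9 per site and year by default;
τ = d_xy/θ − 1, θ = (π_x+π_y)/2. On synthetic two-population data the
median t̂ over 20 replicates (10 diploids/population, 2000 unlinked loci of
100 bp, θ = 0.005/site) recovers the true split within 15% and τ̂ within
20% (acceptance suite).

## Inversion scan and karyotyping

Windowed F_ST uses the Hudson estimator in the Bhatia ratio-of-averages
form: per-site numerator (p1−p2)² − p1q1/(n1−1) − p2q2/(n2−1) and
denominator p1q2 + p2q1, summed within each window. Defaults are 10 kb
windows with 2 kb steps; the synthetic benchmarks use 200 kb/50 kb because
their locus density (1 locus per 4–10 kb) is RAD-like rather than WGS-like.
The span runs from the first to the last window above the threshold;
thresholds and buffers are configuration values, in practice chosen post
hoc per chromosome (typical megabase-scale choices fall around thresholds
of 0.4-0.95 with 0.5-1 Mb buffers). Weir–Cockerham θ is used only for the single-locus
(karyotype-as-genotype) F_ST in the IBD/IBE module, mirroring the distinct
estimator conventions of the two pipeline stages.

Karyotyping mean-imputes missing dosages, centers/scales, takes PC1 by SVD,
and clusters scores with a deterministic 1-D k-means (k = 3, centers seeded
at min/median/max — no random initialization, so calls are reproducible and
order-invariant). Cluster order maps to AA/AD/DD; the PC1 sign is
canonicalized (majority homokaryotype cluster negative); polarity remains
provisional until outgroup polarization. Two degeneracy guards replace
visual inspection: (i) an empty cluster or adjacent centers closer than
2× the mean within-cluster spread ⇒ "no inversion" (non-trimodal PC1);
(ii) because plain population structure can also yield three separated PC1
clusters, the middle cluster must be heterozygous (mean het > 0.6) at sites
where the outer clusters differ in frequency by > 0.5 — true
heterokaryotypes carry one haplotype from each pool there, while an
intermediate population can reach at most 2pq = 0.5. Samples farther than
0.45× the adjacent-center gap from every center are left unassigned.

Validation: per-sample heterozygosity inside vs. outside the span with a
one-sided label-permutation test of the heterokaryotype excess, and mean
per-site F_IS = 1 − H_obs/H_exp with the sample-size-corrected
H_exp = 2p̂q̂·2n/(2n−1), monomorphic sites skipped. For Z-linked spans the
heterozygosity/HWE computations take males only (females carry one Z).

## Polarization and trees

A variant is "shared with the outgroup" for a homokaryotype class when it
segregates (0 < freq < 1) in the class and the outgroup carries the
alternate allele (segregating or fixed). The exact sharing rule is this
package's operationalization; it is deliberately insensitive to outgroup
frequency. Counts are tallied in non-overlapping 50-SNP windows over sites
segregating in either class; the class with significantly higher sharing
(two-sided sign test over windows, p < 0.05) is called ancestral, otherwise
the span is reported "unpolarized" rather than force-called — the honest
outcome for sex-chromosome spans where repeated rearrangements depress
sharing in both arrangements. Neighbor joining (Saitou–Nei, via scikit-bio)
over collinear d_xy gives the species-tree proxy; over inverted-region d_xy
between homokaryotype groups it gives the trans-species evidence (groups
cluster by arrangement, not population).

## Unfolded SFS statistics

θ_W = S/a_n, θ_π = Σ i(n−i)ξ_i / C(n,2), θ_H = Σ i²ξ_i / C(n,2),
θ_L = Σ iξ_i/(n−1). Tajima's D follows the 1989 variance; Fu & Li's D and F
(unfolded, using derived singletons) use the corrected constants of
Simonsen et al. (1995); Fay & Wu's H is reported **only in the normalized
form** of Zeng et al. (2006) — comparable across groups of different S —
and Zeng's E per the same paper. The SFS is built on a fixed n = 2×group
size; sites with missing genotypes or an unpolarizable ancestral state are
skipped and counted. Statistics are undefined (NaN, never 0) at S = 0.
Under neutral constant-size simulation all five statistics average within
3 SE of zero (acceptance suite); note a mean-zero check does not pin down
the variance constants, which are instead locked by the θ-identity tests
and the published formulas.

## IBD / IBE

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km. Inversions are treated as single biallelic loci with genotype
counts (AA, AD, DD); pairwise Weir–Cockerham θ is clipped at 0. The MRM is
OLS on the vectorized lower triangles (raw F_ST, untransformed — the
F_ST/(1−F_ST) linearization is deliberately not applied); significance by
jointly permuting rows/columns of the response matrix (seeded; p-values use
the add-one rule, so p ∈ (0,1] and the test is slightly conservative). VIF
per predictor; relative importance by LMG (mean R² increment over all
predictor orderings), which sums exactly to the total R². The SNP-null
procedure fits the same MRM to each collinear SNP's |Δ frequency| matrix
(MAF > 0.01), ranks the inversion's coefficient two-sidedly in the null
coefficient distribution, and multiplies by the number of chromosomes
tested (capped at 1). The inversion-vs-collinear slope contrast is a
stacked OLS with a distance×region interaction; its output carries a
non-independence caveat because each population enters many pairs, so the
nominal p-value is anti-conservative. Type-I error of the MRM permutation
test and of the SNP-null empirical p is inside the binomial 95% band at
α = 0.05 over 500 null simulations (acceptance suite).

Variance partitioning between region and species identity via transformed
mixed models, and spatially explicit random fields, are out of scope; the
LMG decomposition on the MRM is the variance-explained summary offered here.

## Synthetic-data generator

Unlinked loci (no intra-locus recombination) drawn from a continuous-time
coalescent on a population tree, times in units of 2N generations,
infinite-sites mutations at θ/2 per site per unit time. The inverted region
is two arrangement pools, panmictic across populations (recombination
suppression makes the arrangement, not the population, the relevant deme),
splitting τ_inv ago; the derived pool star-coalesces onto a single founder
at τ_inv (the bottleneck that makes polarization learnable); optional
symmetric lineage exchange between pools stands in for gene conversion.
Individuals draw two arrangement haplotypes at Hardy–Weinberg proportions
from their population's derived frequency. The outgroup attaches above the
ingroup root. Missing genotypes are sprayed uniformly. A Z-linked mode
gives females a single haplotype to exercise the males-only filters.

Standard scenario: 6 populations (10 diploids each) in two radiations,
splits 0.1/0.25/0.5, θ = 0.005/site, 100 bp loci, τ_inv = 1, a monotone
derived-frequency cline 1.0 → 0.0 along the sampling arc with the tree
interleaving geography (so close relatives can be fixed for alternative
arrangements — the configuration that yields clean F_ST scans — and
collinear differentiation is decoupled from the cline), outgroup at τ = 2,
2% missing data. The outgroup depth is a deliberate compromise: deep enough
to predate the arrangement split, shallow enough that incomplete lineage
sorting leaves measurable outgroup sharing, since the generator's
infinite-sites model has no homoplasy to supply sharing the way recurrent
mutation does in real data. Precipitation is a linear function of derived
frequency plus Gaussian noise; temperature is independent noise.

What the benchmarks show — and do not. Passing recovery tests on this
generator demonstrates correctness of the estimators and the
detection→genotyping→polarization→dating chain under the model's own
assumptions (free recombination between loci, panmictic arrangement pools,
clean splits, no gene flow, no reference bias, genotype calls without
error). They do not establish robustness to postspeciation introgression,
low-coverage genotype-likelihood bias (real scans showed divergence-time
inflation at low coverage — this package sidesteps it by consuming called
genotypes), linked selection, or reference-genome artifacts.

## Numerical/degenerate-input conventions

Windows with no informative site carry NaN F_ST and never enter span calls;
a span call with no window above threshold is a no-call, not an error.
Groups below 4 chromosomes raise a typed error. τ is undefined (error) at
zero mean diversity. F_IS is NaN when every site is monomorphic. The
heterozygosity contrast is NaN without heterokaryotypes. All stochastic
operations take explicit integer seeds (numpy Generator); identical seeds
give byte-identical outputs.

## Problem sizes

Test-suite simulations use 6×10 diploids with 800 collinear + 400 inverted
loci for pipeline recovery, 20 replicates × 2000 loci for dating, 2×10⁵
loci for the Monte-Carlo/closed-form comparisons and 500 replicates for the
calibration checks — sizes at which every targeted tolerance is resolvable
with margin while the whole suite stays desk-scale.
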