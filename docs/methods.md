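# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Wright–Fisher selection simulator (`wf_sim`)

**Model.** A single biallelic locus in a randomly mating diploid
population. Generation 0 holds the initial frequency p0. Each subsequent
generation applies (i) deterministic viability selection while the
generation index is within the selection duration, with genotype
fitnesses 1+s, 1+hs, 1 (h = 0.5 by default, i.e. genic selection), so
p′ = p(p(1+s) + q(1+hs))/w̄; then (ii) binomial resampling of 2N alleles.
N follows the founding-bottleneck history: the bottleneck size for the
first 10 generations, the expanded size for the remaining generations of
the 534-generation span (≈16,000 years at 30 y/generation). 0 and 1 are
absorbing; fixation is assessed at the final generation, which equals
"ever fixed" because 1 is absorbing.

**Order of operations.** Selection-then-sampling is the standard viability
WF scheme; the order is a documented convention, not derivable from the
fixation-proportion definition alone. Selection counts from the start of
the simulation ("duration d" = the first d generations, bottleneck
included); `after_bottleneck_only=True` restricts it to post-bottleneck
generations for the scenario in which selection begins only after the
founding event.

**Grid.** The default grid is 5 bottleneck sizes (100–500) × 5 expanded
sizes (2,000–10,000) × 8 durations (67–534) × 4 coefficients
(0, 0.001, 0.01, 0.1) × 14 starting frequencies (0.30–0.95 step 0.05) =
11,200 cells at 100 replicates per cell. Cells sharing a demography are
simulated as one flat vector of independent replicates with one
counter-based child seed per demography block (`SeedSequence.spawn`),
which keeps grids bit-reproducible for a given seed and axes while
avoiding per-cell stream overhead.

**Oracle.** `exact_fixation_probability` propagates the allele-count
distribution through per-generation binomial transition matrices
(selection applied to the expected frequency first), exactly handling the
time-inhomogeneous size schedule. It refuses populations with
2·max(N) > 200; the simulator is validated against it on a small-N
lattice of (s, h, p0). Note the neutral martingale gives equality
P(ever fixed) = p0 only over absorption-complete horizons; over a fixed
finite horizon it gives the bound P(fixed by t) ≤ p0, which is what the
534-generation grid's neutral rows are checked against.

## PBS selection scan (`pbs_scan`)

Per-site pairwise F_ST uses the Weir–Cockerham (1984) moment estimator in
its allele-count (haploid ANOVA) form: with allele sample sizes n_i and
alt frequencies p_i, θ̂ = (MSP − MSG)/(MSP + (n_c − 1)MSG). Negative
estimates are retained — they correspond to negative branch lengths after
T = −ln(1 − F_ST) — and only the upper boundary is clamped (to 1 − 1e−12)
before the log transform. Hudson's estimator is available
(`estimator="hudson"`) for sensitivity. Monomorphic-overall sites are
undefined and dropped from both window and background (counted in a log
message).

PBS for the focal branch is (T_AB + T_AC − T_BC)/2; the three per-branch
values at a site sum to (T_AB + T_AC + T_BC)/2, an identity used as a
self-check. The genome background (mean, SD) is taken over all
defined-PBS sites including the focal window, matching a background
defined as the plain genome-wide average. Z-scores are computed for sites
within ±500 kb of the focal region; p-values are one-sided (upper tail;
selection lengthens the branch) and Bonferroni-multiplied by the number
of focal-window sites with defined PBS. Sidedness and the Bonferroni
denominator are both configurable because reasonable alternatives exist;
the defaults above are the documented choice.

## TMRCA estimator (`tmrca`)

**Filter.** Usable sites are high-quality ancestor-reconstruction sites
(47,820 of the 48,408-base region by default) at which no ancestral-
haplogroup haplotype carries a non-ancestor allele; a derived-haplotype
difference at such a site is a derived-exclusive mutation, as the
infinite-sites model requires. With no ancestral haplotypes supplied the
filter degenerates to the quality mask, with a logged warning.

**Estimate.** Differences are counted at filter-passing sites, but the
per-site divergence fraction divides by the full high-quality base count:
the infinite-sites rule discards *mutations*, while the calibration
divergence A_HC is itself a fraction per high-quality base, so the two
denominators must match for the units to cancel. (Dividing by the
filtered-site count instead would inflate the estimate by the ratio of
the two counts, a few percent on typical data.) The point estimate is
TMRCA = M/A_HC × 2 T_HC, where A_HC/(2 T_HC) is the per-lineage yearly
substitution rate; defaults A_HC = 0.00829 and T_HC = 6,500,000 y.

**Interval.** The default 95% CI is a normal approximation on the mean of
per-haplotype TMRCA values (±1.96·SD/√n), which treats lineages as
independent — exact under the star-genealogy generator, anticonservative
under correlated (coalescent) genealogies; see Limitations. A
Poisson-count interval (`ci_method="poisson"`) is provided as the
alternative; the published interval's construction is not specified
precisely enough to reproduce, so neither method claims to emulate it.

**Sensitivity.** TMRCA is linear in T_HC with M and A_HC held fixed, so
the threshold at which the estimate equals a reference age r is the
closed form T* = r·T_HC/TMRCA; the curve over [5, 7] My and the threshold
are both reported, with an out-of-range flag when r is not attainable on
the interval.

## Haplogroups and core haplotypes (`haplogroups`)

Classification uses only the tag SNP (default rs174537, T = ancestral,
G = derived); any other or missing base is "unclassified" and excluded
from proportions. Proportions can be grouped by population or
local-ancestry label; `unambiguous_only` keeps samples whose haplotypes
all share one label (the homozygous-ancestry restriction). Report
percentages are rounded to 2 decimals; raw fractions are retained.

Core haplotypes are consensus strings over the region's variant
positions: a capital base where all non-missing haplotypes of the
category agree (threshold configurable, default 1.0 = "all"), otherwise
"n"; positions missing in more than half a category are emitted as "n"
with a warning. Oppositely fixed sites between two core strings are
positions capital in both with different bases (optionally excluding the
tag position); positions capital in exactly one string are reported
separately as weaker candidates. The published eight category strings
(38 variant positions, tag at base 10) ship as a packaged TSV.

## Trees and networks (`phylo_net`)

Identical sequences are collapsed with multiplicities; haplotypes with
count ≤ 3 are removed unless protected (archaic lineages, the ancestor
outgroup). Pairwise differences are Hamming counts over mutually
non-missing positions, including invariant columns when present.

Neighbor joining follows Saitou–Nei with two documented conventions: Q-
criterion ties break to the lowest index pair, and negative branch
lengths are clamped to zero with the deficit moved to the sibling edge.
NJ is exact on additive matrices, which the tests exploit as an oracle
(random additive trees with integer branch lengths must be reproduced
exactly). Trees are rooted by splitting the outgroup's edge at its
midpoint.

Bootstraps resample alignment columns with replacement; each replicate's
difference matrix is assembled from precomputed per-column-pattern
difference components, so 500 replicates cost little more than one.
The consensus is dendropy's majority-rule (>50%) consensus with support
percentages; tie handling at exactly 50% follows dendropy's ordering
rather than a greedy extended-majority completion (ties do not arise in
the seeded test conditions). The full-data NJ tree is annotated with the
same bootstrap clade frequencies and carries the branch lengths.

The haplotype network is a minimum spanning network: all MST edges plus
every non-tree pair whose direct Hamming distance equals the bottleneck
(maximum) edge weight on their MST path, so alternative equally
parsimonious links are retained. This is a deliberate substitute for
statistical-parsimony networks, whose probability cutoff is
under-specified; node multiplicities and mutation-count edge labels are
reported identically.

## Latitude cline (`cline`)

OLS with intercept on proportion ~ admixture + latitude; inference is the
two-sided t test on the latitude coefficient. Proportions are regressed
untransformed by default (logit optional). A constant admixture column is
dropped (coefficient reported as 0) rather than passed to a singular
design; near-collinear covariates (|corr| > 0.999) are an error. The
empirical outlier p of a focal site is the fraction of genome-wide
per-site regression p-values strictly smaller than the focal one — ties
count as not smaller, and the denominator is the full background set even
when it contains the focal site.

## Synthetic data (`synthetic_data`)

**Haplogroup alignments.** One region of 48,408 contiguous sites
(48,408 = total, 47,820 high-quality) with a random ancestor sequence.
The ancestral-cluster founder equals the ancestor (the ancestral
haplogroup matches nonhuman primates); the derived-cluster founder
carries the derived tag allele plus stem mutations drawn as
Poisson((tmrca_all − tmrca_derived) × rate × L_total), with rate =
a_hc/(2 t_hc) per site per year and default tmrca_all = 1,300,000 y
(an ancient-polymorphism root age comfortably older than the derived
cluster). Within each cluster the genealogy is a star by default: each
haplotype accrues private Poisson(depth × rate × L_hq) mutations on
distinct high-quality sites (global infinite-sites bookkeeping; budget
exhaustion is an explicit error). A Kingman-coalescent genealogy
(rescaled so the root sits exactly at the cluster age) is available via
`genealogy="coalescent"`; the star model is the default because the
divergence estimator averages independent lineage divergences and nominal
CI behaviour under the star model is the cleanest reference point.

Cluster-defining shared mutations (tag SNP and derived stem) are placed
at sites *outside* the high-quality mask. This is a deliberate design
choice: the estimator counts derived-exclusive mutations at high-quality
sites, and any shared stem mutation there would shift every haplotype's
divergence equally (one shared mutation ≈ +33,000 y at defaults), making
"true TMRCA" ambiguous between the cluster age and the stem age. With
stem mutations masked, `tmrca_derived` is exactly the estimand;
`stem_in_high_quality=True` reproduces the biased regime for study.
Archaic lineages branch from the respective cluster founder at a
configurable time (default 650,000 y) and accrue private mutations for
that depth, which places them intermediate between the clusters in
networks and trees.

**Allele-count panels.** Per site, a shared ancestral frequency uniform
on (0.05, 0.95); per population, a Balding–Nichols draw
Beta(p(1−F)/F, (1−p)(1−F)/F) with per-population differentiation F
(default 0.01, a within-continent scale); then binomial allele counts at
100 diploids per population. Sites are spaced 10 kb apart so a ±500 kb
focal window contains ~112 of the 10,000 sites and the rest form the
genome background. An optional sweep site adds a fixed frequency shift
(default scenario +0.5) to the focal population before sampling.

**Cline tables.** Latitude uniform on 10–70°, European admixture uniform
on 0–0.5, proportion = 0.1 + 0.01·latitude − 0.2·admixture + N(0, 0.02),
clipped to [0, 1]; 40 populations. The slope 0.01/degree matches the
order of the observed Siberian cline; the admixture coefficient is
negative because European admixture dilutes the ancestral haplogroup.

**What the generators do not emulate.** No recombination within the
region (the block is treated as non-recombining, as the TMRCA
calculation assumes), no sequencing error or genotype likelihoods, no
linkage between panel sites, no shared drift topology among the three
panel populations (F is independent per population), and cline noise is
Gaussian rather than binomial in haplotype counts. Passing tests
therefore validate the estimators under their own model assumptions;
they do not certify behaviour under recombination, correlated
genealogies or ascertainment bias in real cohorts.

## Problem sizes used in the test suite

Test and acceptance runs use the study-scale settings wherever they are
cheap (the full 11,200-cell grid at 100 replicates, 200 alignment
replicates at the 48,408-site region, 500-replicate bootstrap and cline
nulls) and small-N settings where an exact oracle exists (Markov-chain
comparisons at N ≤ 5, 20,000 replicates). Monte-Carlo assertions use
3-standard-error bounds around analytically known values.

## Known limitations

- The published cohort-derived numbers (PBS = 0.33 at rs174537, the
  688,474-y TMRCA with its 635,978–743,052 CI, 97.44% ancestral among
  386 Native American haplotypes, the Siberian β = 0.01016) require the
  original genomes and are used here only to parameterise synthetic truth
  and recovery tests.
- CI coverage of the TMRCA estimator is nominal under the star
  genealogy; under `genealogy="coalescent"` lineage divergences are
  correlated and the normal interval undercovers (reported by the tests'
  machinery when run in that mode, not asserted).
- The W–C estimator is applied to allele counts (haploid ANOVA form)
  rather than genotype tables; with genotype data and inbreeding the
  full diploid estimator would differ.
- The empirical cline null in `analysis/06` uses drift-only site
  frequencies; a real genome-wide null would inherit the cohort's spatial
  autocorrelation structure.
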