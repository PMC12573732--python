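# Methods

`aphidqtl` re-implements, as a tested library, the quantitative-genetics
inference chain used to map host-plant acceptance in a pea-aphid
(*Acyrthosiphon pisum*) F2 host-race cross: synthetic cross generation,
marker QC and linkage mapping under female-only recombination, Marey-map
rearrangement analysis, single-QTL genome scans, regional heritability
mapping, analytic detection power, and chemosensory-gene enrichment.
This note records the models, the defaults and why, the numerical
choices, and the known limitations.

## The cross model

The design is an F2 intercross between two clonal host races
(alfalfa-adapted and pea-adapted), with four chromosomes
(A1 172 cM / 160 Mb, A2 112 cM / 130 Mb, A3 114 cM / 135 Mb,
X 204 cM / 133 Mb) and 192 F2 clones by default. Grandparents are
homozygous for alternative alleles at informative markers (allele A =
alfalfa race), so both F1s are heterozygous with known coupling phase.

Pea-aphid males have achiasmatic meiosis: the father transmits one
intact haplotype per chromosome. Each simulated F2 therefore combines a
recombinant maternal gamete — crossovers drawn from a no-interference
Poisson process on the cM scale, count mean = length/100, which makes
the generator Haldane-consistent and gives the estimators a closed-form
target — with one paternal F1 haplotype chosen by a fair coin per
autosome. Crossover interference is deliberately out of scope.

**X chromosome.** Males are X0, so the father is modelled as
hemizygous: a single fixed X haplotype genome-wide. X markers then
segregate in two genotype classes (AA, AB), all statistics treat the X
as a 2-class (1-df) chromosome, and the male X haplotype is fixed to
the alfalfa allele. The source study mapped the X but did not describe
its genotype coding; this pseudo-backcross convention is this package's
choice, not an inherited one.

**Genotyping error** is a symmetric single-step confusion
(AA↔AB, AB↔either homozygote, never AA↔BB in one step) at rate
ε = 0.001 by default; double miscalls are rare in RAD data. Missing
calls are injected independently at 2% by default. QC-violating
markers can be injected: monomorphic-across-races markers,
heterozygous-F0 markers, and distorted markers whose F2 column is
redrawn i.i.d. from (0.40, 0.50, 0.10) — a distortion strong enough
that the chi-square filter at p < 0.001 detects it essentially always
at n = 192 (the X analogue uses (0.75, 0.25)).

## Phenotypes

The assay structure mirrors the study: 17 observation timepoints by
4 clonal replicates per plant. Four trait families are emulated, with
target genome-wide heritabilities set to the published posterior means
(acceptance of pea 0.097, acceptance of alfalfa 0.299, survival on pea
0.388, survival on alfalfa 0.148).

Two generation modes:

- **direct** — clone mean = Σ QTL effects (codes −1/0/+1, dominance on
  the heterozygote) + a genomically structured polygenic value
  (random marker effects, rescaled) + Gaussian noise scaled so the
  heritability of clone means equals the target h². The raw Gaussian
  value is emitted as `liability`; `acceptance` is its logistic
  transform (monotone, hence equivalent for rank-based scans, and in
  [0, 1]); `survival_steps` truncates at the 17-step maximum, which
  creates the spike at the upper bound; `survival_count` thresholds
  four replicate draws.
- **mechanistic** — per replicate and timestep, death by a cloglog
  hazard (default per-step death probability 0.01, shifted
  multiplicatively by the genetic value) and probing-given-alive by a
  clone-level logistic liability; acceptance = probing/alive
  observations pooled over replicates (missing when no alive
  observation), survival = mean time-steps alive, count = replicates
  alive at the end.

The target h² is defined on the latent (liability) scale. Nonlinear
observation maps (logistic, truncation, counts) shrink observable-scale
heritability; tests that assert h² recovery therefore use the Gaussian
clone mean. This is also why the pipeline's reported heritabilities for
transformed traits sit below their latent targets.

## Marker QC and linkage mapping

QC applies, in order: (1) the parentage rule — both F0s of one race
homozygous for one allele, both F0s of the other race for the other,
both F1s heterozygous (evaluated on available genotypes and flagged
`imputed_parentage` when F0/F1 calls are missing); (2) removal of
all-missing columns; (3) a segregation-distortion chi-square against
1:2:1 (2 df) on autosomes or 1:1 (1 df) on the X, at p < 0.001;
(4) redundancy collapse — markers agreeing at every jointly observed
individual are one signature; the representative is the least-missing
member.

Under known coupling phase and male achiasmy, the two-locus F2
likelihood reduces to a backcross-like form: each genotype pair is
parental, recombinant, phase-uninformative (a heterozygous autosomal
genotype paired with an X marker), or impossible (AA with BB at a
linked marker would need a paternal switch). The ML female
recombination fraction is r̂ = n_rec/(n_par + n_rec), capped at 0.5,
with LOD = n_par·log10(2(1−r̂)) + n_rec·log10(2r̂). Impossible cells
are excluded from the likelihood and reported as conflicts; they are
also how apparent male recombination is diagnosed in real-format data.
Pairs with fewer than 10 informative F2s are flagged `low_support`.

Grouping is single-linkage on the LOD graph at a threshold, with
groups below a size limit dissolved and singletons re-attached to
their best group when that LOD reaches a join threshold; a threshold
scan reports group count against threshold so the user can find the
plateau that yields the expected four groups. Ordering minimizes the
sum of adjacent r̂ by greedy chaining plus 2-opt from randomized
starts, repeated (default 10 runs); markers whose aligned rank range
exceeds 2 positions across runs are removed as unstable. Orientation
follows physical position where available. Map distances are Haldane,
d = −50·ln(1−2r̂) cM, matching the generator; adjacent r̂ ≥ 0.5 is
capped at 50 cM and flagged. Co-segregating markers share a position.

Error screening computes, per genotype, the posterior odds that the
observed call is wrong (from the genotype-probability HMM with the
error rate in the emission) over the prior odds ε/(1−ε), on log10
scale; markers whose maximum exceeds 5 are removed. Chromosomes with
fewer than three markers are flagged `too_sparse`.

## Marey maps and inversions

For each chromosome the cM-ordered physical positions are segmented at
persistent direction changes and at physical jumps above 2 Mb, short
segments (< 5 markers) are merged into the physically closer neighbor,
and neighbors continuing one trend are coalesced unless another block
owns the skipped territory. Orientation is the sign of the within-block
Spearman correlation (short ambiguous blocks inherit a neighbor's
sign); block ids are ranks in physical order. Recombination-suppressed
regions are maximal runs of ≥ 3 markers at one map position spanning
≥ 2 Mb.

The minimum number of inversion events is the signed-reversal distance
to the identity, computed exactly by iterative-deepening search with
the admissible breakpoint bound ⌈b/2⌉; translocation moves are not
allowed because the biological claim counts inversions. The search is
bounded at 10 blocks; coarser segmentation is required beyond that.

## Genome scans

Genotype probabilities come from a forward–backward HMM whose hidden
state is (maternal allele, paternal haplotype): maternal transitions
follow Haldane recombination over each interval, the paternal state is
constant per chromosome (a two-chain mixture on autosomes, one chain on
the X), and emissions use the single-step confusion at ε. The
evaluation grid adds pseudo-positions every 1 cM by default.
Observations impossible under a chain zero that chain's likelihood; if
every chain dies (a genotyping conflict), the offending emission is
skipped rather than producing NaNs.

The **nonparametric scan** generalizes Kruskal–Wallis to soft genotype
assignments: with midranks R_i and posterior weights p_ig,
H = 12/(N(N+1))·Σ_g S_g²/n_g − 3(N+1) with the usual tie correction,
and LOD = H/(2 ln 10). At a fully informative typed marker this equals
the standard Kruskal–Wallis statistic exactly (tested to 1e-10).

The **two-part scan** models a spike at the trait's maximum: per
genotype class a spike probability π_g and, among non-spike clones, a
Normal(μ_g, σ) with shared σ. At pseudo-positions the fit is by EM
over the genotype mixture (tolerance 1e-8 on the log-likelihood, max
200 iterations, vectorized across positions) rather than imputation,
so results are deterministic and testable against the closed-form
marker ML. The joint LOD is the scan statistic; spike-only and
quantitative-only component LODs are reported alongside.

Significance uses permutation of trait values across individuals
(default 1000 permutations), with the threshold the 95th percentile of
genome-wide maxima computed as a type-7 (linear-interpolation)
empirical quantile so thresholds are reproducible. Support intervals
are 1.5-LOD drops expanded to flanking markers; variance explained is
PVE = 1 − 10^(−(2/n)·LOD).

## Regional heritability mapping

Relatedness matrices are VanRaden's first method on 0/2 codes with
observed allele frequencies (≈ 0.5 in an F2): W = X − 2p̂, K =
WW′/(2Σp̂(1−p̂)), monomorphic SNPs dropped, missing genotypes
mean-imputed, and a 1e-6 ridge for numerical positive
semi-definiteness. On simulated data the mean diagonal sits slightly
below 1 because 2-class X markers contribute 2/3 of an autosomal
marker's expected self-relatedness.

Windows are 20 cM with a 10 cM slide, plus a terminal window anchored
at (length − 20 cM) when the tiling stops short; windows with < 3 SNPs
are skipped. With the study's map lengths this convention yields 59
windows; the published count is 57 under an unstated convention, and no
attempt is made to force agreement.

The two-random-term model (window matrix + rest-of-genome matrix +
residual) is fitted by REML with the residual scale profiled out and
L-BFGS-B on the log variance ratios, with deterministic restarts;
components at the parameter-space boundary are reported as zero and
flagged. The binomial survival count (out of 4) uses penalized
quasi-likelihood on the logit scale: iterate the working response and
weights, Gaussian REML on the working response each cycle, until
variance estimates move < 1e-5; boundary counts get the ±0.5
continuity adjustment at initialization. The source analysis fitted
Bayesian models; REML/PQL keeps the same covariance structure while
being seed-free and unit-testable. Point estimates are not expected to
match posterior means numerically, and PQL variance components for
4-trial counts are attenuated (a known PQL property); the large-count
limit, where PQL matches a Gaussian fit on log-odds, is tested instead.

The window permutation test permutes rows and columns of the regional
matrix jointly, leaving the trait and the background matrix fixed, so
overall heritability is preserved under the null; the cutoff is the
95th percentile of permuted Vr — a deliberately lenient, suggestive
criterion with no multiple-testing correction. The observed fit uses
the same optimizer effort as the permuted fits so that observed and
null Vr are exchangeable; calibration tests hold to 2–10% exceedance
on a pure-noise trait. One caveat is inherent to the method: when the
trait carries genome-wide signal, the unpermuted window matrix is
correlated with the background matrix through linkage, part of the
background signal loads on Vr, and the test becomes anticonservative.
This matches its published use as a suggestive screen, not a
family-wise test.

## Detection power

The likelihood-ratio test at the marker nearest a QTL is noncentral
chi-square under the alternative. A QTL of heritability h² sits on
average half a marker interval from the nearest marker; with Haldane
r over spacing/2 the variance seen at the marker is h²·(1−2r)². The
default noncentrality is the expected LRT,
λ = −n·ln(1 − h²(1−2r)²), compared with the upper-α quantile of the
1-df central chi-square. This choice was validated two ways: it
reproduces the published six-value power table for the study design
(n = 192, 0.8 cM, α = 0.01) within ±0.006, and it agrees with a
50,000-replicate Monte-Carlo of the actual F2 marker LRT within
±0.004. The Wald form n·h²/(1−h²) and the small-effect form n·h², and
a 2-df (additive + dominance) variant, are exposed for comparison;
the cited method's own convention is not printed in the source, so the
printed values and the simulation jointly adjudicated the default.
For q equal-effect QTL the per-QTL h² is total/q. h² = 0 returns α
exactly.

## Gene–region enrichment

Genes are single positions (midpoints); containment is half-open
[start, end) in bp, 0-based internally, with Mb-scale tables converted
at a 10 kb grain so two-decimal coordinates round-trip. Overlapping
regions are merged only for the deduplicated union count, never in
per-region reports. Subset enrichment resamples the subset without
replacement among all listed genes (default 10,000 draws) — matching a
design where outlier chemosensory genes are resampled among all
chemosensory genes, not repositioned genome-wide — with
p = (1 + #{null ≥ obs})/(B + 1). Category enrichment is Fisher's exact
test; the two-sided p uses the minimum-likelihood rule, both one-sided
tails are reported, and the odds ratio is the conditional-ML estimate.
A zero margin returns p = 1 with the odds ratio undefined. On the
printed counts (39 of 60 in-region chemosensory genes are ORs, 70 of
179 overall) the test reproduces the published p ≈ 6.4e-07.

## Pipeline and reproducibility

The pipeline derives one child seed per stage by hashing the stage name
against the master seed (CRC-32, kept below 2³¹), so toggling a stage
never shifts another stage's randomness; identical master seeds give
byte-identical reports. Full-scale defaults mirror the study (192 F2s,
ε = 0.001, distortion p = 0.001, 1000 scan and RHM permutations,
20/10 cM windows, 10,000 enrichment resamples, power at
n = 192/0.8 cM/α = 0.01). The test suite runs everything at reduced
problem sizes chosen to keep each check sharp — e.g. 100-permutation
thresholds, 80–100 outer replicates for calibration bands, 96 or 64
individuals for REML-heavy loops, 50 replicates for map-length
recovery — and those sizes are stated in the tests themselves.

## What the simulations do and do not show

The generator reproduces the design's statistical skeleton: achiasmatic
transmission, Mendelian segregation with injected QC violations,
Haldane-consistent recombination, spiked survival phenotypes, and
clustered gene positions. It does not attempt read-level data,
endosymbiont effects, clonal population structure, crossover
interference, or real linkage disequilibrium with the reference
assembly. Passing tests therefore demonstrate correctness of the
statistical machinery on data satisfying the stated model, not fidelity
to any particular real dataset; published real-data summaries (total
map length, marker counts, QTL positions, posterior heritabilities)
require the deposited reads and are not reproduced here.
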