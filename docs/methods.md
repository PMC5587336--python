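# Methods

This note documents the models behind `admixkit`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices a maintainer would want spelled out.

## Genotype substrate

All statistics consume a SNP × sample dosage matrix counting copies of the
*counted* allele (the PLINK .bim A1 column). The polarity convention is
fixed once in `genio` because f-statistics are invariant to allele
relabeling but frequencies are not. Genetic positions live in Morgans
internally; centimorgan columns are converted at the file boundary, and an
all-zero map is imputed at 1 cM/Mb with a warning. Dataset merging keys on
SNP id (array practice), harmonizes allele labels by swap and/or strand
complement, drops strand-ambiguous A/T and C/G sites and unresolvable
mismatches, and reports counts per category. Missing data use one sentinel
(−9) across ploidies; files carry each format's native code.

## Synthetic-data generator

Population divergence uses Balding–Nichols beta drift: a branch with
differentiation `F` maps an ancestral frequency `p` to a
`Beta(p(1−F)/F, (1−p)(1−F)/F)` draw — mean `p`, variance `F·p(1−p)`. The
closed-form moments make downstream oracles exact, which is why this model
was chosen over generation-by-generation Wright–Fisher. Nested trees of
branches (needed for f4-style statistics, which require shared internal
drift) are supported via `drift_tree_freqs`. Ancestral frequencies default
to Uniform(0.05, 0.95), a deliberately crude emulation of SNP-array
ascertainment toward common variants.

Admixture `g` generations ago with proportion `α` is simulated at the
haplotype level: breakpoints are laid down as cumulative Exponential(rate
g) increments — an exact Poisson process whose per-tract draws are iid
Exp(g) — and each tract is independently assigned source 1 with
probability α. Consequences used as oracles: mean ancestry is α, ancestry
autocovariance decays as `exp(−g·d)`, and tract lengths are exactly
exponential. Diploids are two independent haplotypes. This haploid-mosaic
shortcut (not a full pedigree) produces the admixture-LD signal the dating
module estimates at negligible cost; the classic g-vs-(g+1) convention
ambiguity of pedigree time is absorbed into recovery tolerances (≤ 1
generation).

Whole-genome-amplification artifacts are modelled as clustered allelic
drop-out: per individual, physical tracts (exponential lengths, mean 2 Mb
by default, expected genome fraction = `rate`) lose one strand — every
heterozygote in a tract becomes the same randomly chosen homozygote. This
reproduces the "hemizygous stretch" failure mode: observed heterozygosity
shrinks by the drop-out rate while allele frequencies stay unbiased in
expectation.

What the generator does **not** emulate: coalescent ancestry (no
linked-drift LD within sources; background LD is absent, so `d_min` in the
dating module matters less here than on real data), mutation, selection,
real ascertainment schemes, and genotyping error beyond missingness and
drop-out. Passing tests therefore demonstrate correctness of the
estimators under the stated models, not robustness to every artifact of
real array data.

## QC transforms

Missingness filtering removes SNPs first, then individuals, recomputing
individual call rates on the surviving SNPs; default thresholds 0.9/0.9
(configurable). Haploidization maps 0→0, 2→1 and resolves heterozygotes by
a fair seeded coin; it is frequency-preserving in expectation even under
drop-out, because a drop-out tract keeps one strand and haploidization
would have picked either with equal probability. Chimeric pseudo-diploids
pair haploid genomes randomly within populations (odd sample dropped,
singleton populations dropped with a warning); a site missing in either
haploid parent is set missing — conservative. Pairing is random because
ROH and diversity statistics are pairing-invariant in expectation; the
chimera is distributed as a random union of gametes, so its expected
heterozygosity is `2p(1−p)`.

## f-statistics

Implemented exactly as the frequency moments listed in the README, with
the unbiased within-population correction `h/n`, `h = n p̂(1−p̂)/(n−1)`,
subtracted for f2 (both populations) and f3 (target only); f4 and D need
no correction because their two factors involve disjoint populations.
Corrections are on by default for f2/f3 and an `uncorrected` mode exists
for oracle tests. SNPs with an undefined frequency in any involved
population are dropped per statistic (complete case), and counts are
reported. A heterozygosity-normalized f3 variant (ratio of sums against
the target's unbiased heterozygosity) is available behind a flag; the
plain covariance form is the default.

Standard errors use the weighted delete-one-block jackknife with
contiguous 5 cM map blocks (fallback: 500-SNP chunks when the map is
degenerate), block SNP counts as weights, and the standard unequal-weight
variance formula. Ratio statistics (D, f4-ratio, normalized f3) jackknife
the ratio itself, deleting each block from numerator and denominator
simultaneously. |Z| > 3 is flagged as conventionally significant; stricter
cutoffs are the caller's choice.

With a small number of blocks the null Z is t-distributed (~g−1 df), not
normal: at 20 blocks the true |Z| > 1.96 rate is ≈ 0.065, and calibration
experiments at 100 blocks recover 0.050. Calibration bands in the tests
should be read with that in mind.

## F_ST and the pseudo-unadmixed correction

Weir & Cockerham's θ̂ is computed from the 1984 variance components per
SNP and combined as a ratio of sums (lower bias than averaging per-SNP
ratios); small negative estimates are reported as computed and floored at
zero only inside UPGMA clustering. Wright's `(H_T − H_S)/H_T` operates on
frequency vectors (also ratio of sums), which lets it run on corrected
frequencies where no genotypes exist.

A caution worth recording: for two populations drifted independently from
a common ancestor, both estimators converge to the *mean* per-branch F,
not the summed path length — f2 is branch-additive, F_ST is not (it
normalizes by total heterozygosity). Calibration tests assert θ̂ ≈ F for
symmetric sisters at branch F each.

The pseudo-unadmixed construction inverts the mixture equation
`p_un = (p_t − α·p_d)/(1−α)`, clips to [0,1] and reports the clip count.
It amplifies sampling noise by roughly `(1+α²)/(1−α)²` (≈ 4× at α = 0.45),
so corrected-F_ST comparisons are only informative when panel sizes make
that floor small relative to the drift signal; the demo uses n = 100
reference / 60 target diploids for this reason. α defaults to the
f4-ratio estimate.

UPGMA uses average linkage on the (floored) distance matrix; branch
lengths are half the merge-height differences, so the tree is ultrametric.

## Admixture dating

The weighted-LD statistic for a SNP pair (i, j) on one chromosome is
`côv(dosage_i, dosage_j) · δ_i δ_j` with δ the frequency difference
between the two reference populations; pairs are binned by genetic
distance (defaults: d_min 0.5 cM to suppress short-range LD, d_max 30 cM,
bin width 0.1 cM) and the curve is fitted by pair-count-weighted least
squares to `A·exp(−g·d) + c`, multi-start over g ∈ {5, 20, 50, 150} with
the best-SSE winner (a two-exponential model is available and is reported
oldest event first). The target is haploidized first by default so
drop-out cannot fake LD. Covariances handle missing data pairwise and
require ≥ 2 observed individuals per pair.

Leave-one-chromosome-out jackknife (pair counts as weights) gives the SE
of g and of the amplitude; both the amplitude Z (signal significance) and
the date Z are reported because published tables are ambiguous about which
their Z means. Recovery tests tolerate the ≤ 1-generation pulse-time
convention offset; recovery tests also confirm insensitivity of ĝ to
d_min over 0.3–1.0 cM. Years = g × generation time (default 30 y).

## Diversity

ROH uses the PLINK-style scan with all parameters exposed: 50-SNP windows
(≤ 1 het, ≤ 5 missing), SNP eligibility at ≥ 5% of spanning windows
passing, and segment thresholds of ≥ 25 SNPs, ≥ 0.5 Mb, ≥ 1 SNP/50 kb
density, ≤ 100 kb internal gap. The 0.5 Mb floor (not kb) is the sensible
reading for array-density data — kb-scale runs are undetectable at ~1
SNP/10 kb — and length-bin summaries default to
{0.5–1, 1–2, 2–4, 4–8, >8} Mb. ROH is meant to run on the chimeric
dataset when drop-out is plausible.

Rarefaction evaluates the absence probability `Q = C(N−N_i, g)/C(N, g)` as
an exact telescoping product (no log-gamma rounding), so all three
statistics match exhaustive subset enumeration to ~1e−15. Loci where any
involved population has fewer than g observed copies are dropped per locus
and counted. Allelic richness is provably non-decreasing in g; private
and shared-private richness are **not** monotone in general (focal
presence saturates while absence elsewhere keeps falling), and a test
pins that behavior to the enumeration oracle. The 5-SNP haplotype variant
requires haploidized input (diploid phase is unknown), drops
missing-containing haplotypes per locus, and feeds the same rarefaction
machinery.

Expected heterozygosity is reported with the unbiased `n/(n−1)` factor;
on chimeric data it is robust to drop-out while naive observed
heterozygosity shrinks by the drop-out rate — the motivation for the
chimera construction.

## Distances and Mantel

Geographic distances are haversine great circles (Earth radius 6371 km).
Linguistic distances map each population to a root-to-leaf classification
path and score a pair by the level of their lowest common ancestor
(defaults 4/3/2/1 from root to language, 0 for identical paths; the
scheme is user-configurable since no canonical values exist). The Mantel
test is classical Pearson on upper-triangle entries (Spearman behind a
flag), one-sided greater, with `p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)`
and joint row/column permutation of the second matrix, seeded. An
independent implementation (scikit-bio) cross-checks r in the test suite.

## Determinism and problem sizes

Every stochastic component takes a seed or `numpy.random.Generator`; the
pipeline stamps outputs with version, seed and config hash, and identical
configs reproduce byte-identical files. Test and acceptance problem sizes
were chosen as the smallest that leave comfortable statistical margins:
20k SNPs × 20 blocks for null calibrations (500 replicates), 50k SNPs for
f4-ratio recovery (100 replicates per α ∈ {0.15, 0.45, 0.70}), 8
chromosomes × 1 Morgan × 4k SNPs with n = 30 targets for dating recovery
(50 replicates per g ∈ {7, 19, 56}), and the demo pipeline at 6 × 3k SNPs
with n = 100/60.

## Known limitations

- No VCF input, imputation, liftover, or sex chromosomes; merging is
  id-based, not positional.
- One weighted-LD estimator (covariance form); no multi-reference
  significance scan or LD pre-test battery; no model-based clustering or
  PCA; no qpAdm/qpGraph-style graph fitting.
- The generator's independence assumptions (no background LD, no
  ascertainment model beyond the uniform frequency window) make some real
  -data failure modes invisible to the test suite; see the generator
  section.
- f3 on very drifted targets can be positive despite admixture (bounded
  correction, standard limitation of the statistic); the normalized
  variant does not change this.
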