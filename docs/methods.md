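# Methods

This note documents the models and procedures `panelbias` implements, the
defaults and why, the numerical conventions, and what the synthetic data do
and do not establish about real data.

## Data model

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with a missing
marker (−1), stored per sample × site together with variant coordinates and
one population label per sample. Phase is discarded on input: every
statistic here (frequencies, dosage r², F_ST, f3/f4, PCA, the admixture
likelihood) is a function of dosages only. Internally BED intervals are
0-based half-open and VCF positions 1-based; a 1-based position *p* lies in
interval [s, e) iff s < p ≤ e. Multi-allelic records are always dropped on
VCF input (with a logged count), indels optionally, sex chromosomes
(labels X/Y/chrX/chrY) by default.

## Synthetic structured populations

The generator is a two-level Balding-Nichols hierarchy. Ancestral
frequencies are uniform on [0.05, 0.5] (the floor keeps most sites
polymorphic; leaf-level monomorphic sites still arise through drift and all
downstream code handles them). Each branch with drift parameter F ∈ (0,1)
transforms a parent frequency p into a Beta(p(1−F)/F, (1−p)(1−F)/F) draw:
mean p, variance F·p(1−p), i.e. F is the branch's expected F_ST-like
divergence. Unadmixed individuals draw genotypes Binomial(2, p_pop);
admixed individuals draw each of their two allele copies independently from
a source population chosen with the mixing proportions — admixture acts at
the allele-copy level, matching diploid sampling, so a "50/50" individual
has realized ancestry tightly concentrated at 0.5 across many sites.

Defaults (the `studylike` configuration): 5 super-populations × 3
populations, 30 diploids per population, 20,000 SNPs, drift 0.08 between
and 0.01 within super-populations, one 70/30 admixed group. These mirror a
continental-scale human panel — five super-populations, within-continent
F_ST of a few percent, between-continent around 0.1–0.2 — at a size that
runs in seconds.

LD blocks: within each run of `block_len` consecutive sites, sites
2..block_len are copies of the first site's column, each entry resampled
from its population's frequency at that site with probability `noise`
(noise 1 restores the original distribution; noise 0 gives r² = 1 blocks).
This is a caricature of haplotype structure — blocks have hard edges and no
recombination gradient — sufficient for testing pruning behavior, not for
estimating real LD decay. Coordinates are either evenly spaced
("genome-like") or packed into gene-like clusters separated by large gaps
("exome-like"); cluster span 10 kb and gap 500 kb by default, matching the
scale of transcriptionally dense regions versus intergenic space.

Ascertainment: a panel of n sites takes a `fraction_aims` share from the
top decile of an informativeness ranking — across-population variance of
the pooled-minor-allele frequency, or |Δp| for a named population pair —
and the remainder uniformly at random. The AIM fraction of real arrays is
not identifiable from published sources; 0.8 is the package default for the
bias experiments and is a free parameter, not an estimate.

One root seed drives everything; each operation (frequencies, genotypes,
LD injection, coordinates, ascertainment) uses its own child stream
(`SeedSequence(seed, spawn_key=(op,))`), so outputs are bit-reproducible
and adding a stage does not perturb the others.

## Panel construction and QC

The dispersed genome scheme excludes 5 Mb at each chromosome end, tiles the
remaining span into full 10 kb stretches (a trailing partial stretch is
discarded; under this whole-stretch tiling the embedded GRCh37 autosome
lengths give a cumulative 68,651,478 bp ≈ 68.7 Mb),
and keeps the first 258 bp of each stretch. Coverage qualification keeps
regions whose minimum cohort coverage is strictly above 10× with zero
MAPQ0 (multi-mappable) reads. The carrier filter is symmetric: both alleles
must be carried by ≥ 10 individuals (alt carrier: dosage > 0; ref carrier:
dosage < 2; missing excluded) — the upper arm removes near-fixed alternate
alleles, the reference-error signature. The inbreeding coefficient is
recomputed from genotypes as F = 1 − obs_het/exp_het with exp_het =
2p̂(1−p̂) (monomorphic ⇒ F = 0), and sites with F < −0.5 (excess
heterozygosity, the Hardy-Weinberg violation signature of spurious calls in
unrelated cohorts) are dropped. Array-style site matching is by
(chrom, pos) only — manifests can be strand-flipped, so allele identity is
deliberately not required. All filters touch site membership only, never
dosages, and are idempotent.

## LD pruning

Greedy windowed pruning on squared Pearson correlation of dosages
(composite LD; computed over pairwise-complete entries, 0 by convention for
constant vectors or < 2 complete pairs). The window is physical — the
maximal run of surviving SNPs within `window_kb` of the window's first
SNP — and the step between windows counts surviving SNPs, mirroring the
mixed units of the standard `--indep-pairwise` protocol (defaults
10,000 kb / 10 SNPs / r² 0.1). Within a window the highest-r² pair above
threshold is resolved first by removing the lower-MAF member (tie: the
later-positioned), which keeps the more informative marker and makes the
procedure deterministic; equivalence is guaranteed against this documented
greedy rule (tested against a naive brute-force transcription), not
bit-for-bit against any particular external tool, whose internal pair order
is unspecified. Monomorphic sites are removed first with a logged count.

## F_ST, f3, f4, block jackknife

F_ST uses the Hudson estimator in ratio-of-averages form with the
finite-sample corrections p̂(1−p̂)/(n−1) in the numerator (allele counts
n = 2 × non-missing individuals). Negative estimates are reported as
computed. Sites monomorphic across a pair (D_j = 0) are excluded; sites
with n < 2 in any involved population are skipped per statistic, not
globally. The estimator choice is a package decision — external PCA
packages do not document theirs — and Weir-Cockerham is intentionally left
out of scope rather than half-supported.

f3(C; A, B) subtracts c(1−c)/(n_C−1) per site (the unbiased
heterozygosity correction for the sampling noise of c²); it is reported
unnormalized — no division by the heterozygosity of C — because the
analyses here interpret raw sign and magnitude. f4 needs no correction.
Both use a weighted delete-one-block jackknife: with total weight W, block
weights w_j, overall estimate T and leave-one-out estimates T₋ⱼ,

```
h_j = W / w_j
T_J = g·T − Σ_j (1 − w_j/W)·T₋ⱼ
var = (1/g) Σ_j (h_j·T − (h_j−1)·T₋ⱼ − T_J)² / (h_j − 1)
```

(the unequal-block-size form; with equal blocks it reduces to the textbook
delete-one jackknife). Blocks are contiguous 5 Mb coordinate windows per
chromosome, falling back to 100 equal-count contiguous blocks when
coordinates are absent or collapse into a single block; block size follows
standard jackknife practice for human-scale LD. Z = estimate/SE; SE = 0
yields a ±inf sentinel, never NaN. For F_ST the jackknife is applied to the
ratio of block sums.

A caveat the tests encode: the correction assumes the two populations are
*independently sampled*. Literally duplicating one sample set under two
labels removes that sampling noise, and the estimator then returns exactly
−1/(n_alleles−1) with SE 0 — the "identical populations ⇒ 0" limit holds
for independent samples from one panmictic population, which is what the
acceptance checks simulate.

## PCA

Each site column is mean-imputed at missing entries (unbiased under
missing-at-random), centered by its mean μ and scaled by √(p̂(1−p̂)) with
p̂ = μ/2 — no pseudo-count by default (a flag enables the +1/+2 variant);
the scaling weights sites by the variance a binomial draw at that frequency
would have, so drifted sites are not drowned out. Columns with p̂(1−p̂) = 0
*or* zero empirical variance (e.g. all-heterozygote columns) are dropped
with a logged count. The decomposition is `eigh` of the sample × sample
covariance divided by the site count; eigenvalues descend, eigenvectors
have unit norm with the largest-magnitude entry positive (a deterministic
sign convention). Outlier removal iterates: flag samples > σ standard
deviations from the mean on any of the top-k components (defaults σ = 6,
k = 10), remove, refit; stop when an iteration removes nobody or after
max_iter = 5 iterations (the threshold is standard; the iteration cap is a
package choice, as published protocols do not state one).

## Admixture model

The likelihood is the standard binomial mixture: ℓ(Q,F) = Σ_{ij observed}
[g_ij ln(Σ_k q_ik f_kj) + (2−g_ij) ln(Σ_k q_ik(1−f_kj))]. Fitting is plain
EM from seeded random initialization (Q rows flat-Dirichlet, F uniform on
(0.05, 0.95)); the E-step responsibilities reduce to matrix products, the
updates are the classical ratio-of-expected-counts, and the per-iteration
log-likelihood is non-decreasing (asserted in tests). Plain EM rather than
quasi-Newton acceleration is a deliberate trade: at desk scale the extra
iterations are cheap and the correctness argument is simpler. F is clamped
to [1e−6, 1−1e−6] to keep the likelihood finite; K = 1 has the closed form
F = mean dosage / 2. Convergence: Δℓ < 1e−4 or 2,000 iterations.

Model choice uses masked-entry cross-validation: observed genotype *cells*
are partitioned into folds (re-randomized up to 10 times if a fold would
empty a sample or site); per fold and K the model is refit with multiple
seeded restarts (best log-likelihood kept) and the fold error is the mean
squared difference between held-out dosage and prediction 2·(QF). Absolute
CV errors are panel-dependent, so curves are also reported relative to the
worst-fitting K. The default K range is 3–10; 20 restarts mirrors common
practice of 20 independently seeded runs. Ties in the argmin go to the
smaller K; a minimum at the range boundary is flagged with a warning.
Component labels are arbitrary: evaluation against planted truth uses the
best column permutation by total-variation distance.

## MAF-variance diagnostic and panel comparison

Per site, the minor allele is defined on the *pooled* sample (count-weighted
mean frequency ≤ 0.5; tie keeps the alternate allele), each population's
frequency of that allele is reported (it may individually exceed 0.5), and
the across-population sample variance (n_pops − 1 denominator) is the
diagnostic. Pooled-minor rather than per-population folding keeps the
number a variance of the *same* allele's frequency — per-population folding
would conflate allele switching with differentiation. The sample-variance
choice is material at small population counts and is recorded in the report
metadata. Sites with fewer than two populations of data are skipped with a
count.

Panel comparisons report: elementwise F_ST difference matrices
(panel − reference, antisymmetric under swap), Pearson correlation between
matched triad f3 vectors, leading-eigenvalue ratios, mean MAF variance, and
relative CV curves on the shared K range. Report TSVs are written with a
fixed float format so reruns are byte-identical; density plots use scipy's
Gaussian KDE with its default bandwidth rule (plots are illustrative — all
assertions run on the underlying numbers).

## The bias experiment

`experiments.ascertainment_bias_experiment` runs one seed of the headline
contrast on the studylike hierarchy (without the admixed group — the
contrast concerns unadmixed structure): a 5,000-site ascertained panel
versus a same-sized uniform random panel, against the full 20,000-site set
as f3 reference. The ascertained panel is a composite, as real arrays are:
half its sites drawn with 80% AIM share from the overall MAF-variance
ranking, half with 80% AIM share from the |Δp| ranking of one specific
between-super-population pair. The contrast-specific half matters: purely
variance-ranked ascertainment inflates all triads roughly proportionally,
which scale-invariant Pearson correlation cannot see; discovery-panel
specificity is what makes the f3 distortion non-uniform across triads, and
is the mechanism the array literature blames for it.

## What the synthetic results do and do not show

Passing the directional suite shows the *estimators respond to
ascertainment the way the theory predicts* under Balding-Nichols drift with
independent sites. The simulator has no recombination, no mutation-rate or
functional-class heterogeneity, no selection (the mechanism behind
exome-specific F_ST shifts in real data), hard-edged LD, and drift that is
exchangeable across branches of the same level. Effect *sizes* measured
here therefore do not transfer to real panels; directions and orderings
are the claims under test. Problem sizes throughout (20,000 sites, 30
diploids per population, 20 seeds for the directional suite, 2,000 sites
for EM recovery) were chosen as the smallest at which the expected effects
are comfortably resolved by the jackknife/Monte-Carlo error of the
statistics involved.

## Known limitations

- No BCF, genotype likelihoods, imputed-dosage fields or indels; VCF output
  is a minimal GT-only v4.2 dialect.
- Weir-Cockerham F_ST, haplotype-phase r², VIF pruning, Tracy-Widom
  statistics, f4-ratio admixture proportions and graph fitting are out of
  scope.
- The EM fit can hit flat likelihood regions near convergence; restarts are
  the intended remedy and the CV machinery keeps the best of them.
- `PED/MAP` export is dosage-faithful but not guaranteed bit-exact against
  any particular consumer's dialect expectations.
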