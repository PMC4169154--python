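# Methods

`mosaicqtl` implements the analysis chain for multiparent outbred mouse
populations such as the Diversity Outbred (DO): probabilistic reconstruction
of founder diplotypes from genotyping-array data, founder-dosage and SNP
imputation, kinship-corrected genome scans, genome-wide significance, and
the power/type-I simulation machinery used to plan such studies.  This note
records the models, their assumptions, the tunable parameters, and the
numerical and design choices that were genuinely open.

## Diplotype state space

With F founders (default 8, coded A–H) the latent state at a locus is the
unordered pair of founder haplotypes: F homozygous and F(F−1)/2 heterozygous
diplotypes, 36 for F=8.  States are ordered homozygotes-first (founder
order) then heterozygotes lexicographically; every array in the package uses
this ordering, chosen once for reproducible serialization.  Parent-of-origin
is ignored (no 64-state model), and X-chromosome dosage compensation is out
of scope.

## Breeding simulator

Genomes are simulated on the cM map with a no-interference (Poisson)
crossover process: per meiosis, crossover count ~ Poisson(L/100) with
uniform positions, no obligate chiasma, no interference.  Interference would
thin small intervals but does not change the linear accumulation of
ancestry switches, which is the property downstream methods rely on.

Generation 1 is seeded with random founder mosaics
(`founding_switch_rate` = 2.0 ancestry switches per Morgan per haplotype,
labels uniform over founders).  This approximates the funnel-bred founding
animals of a real heterogeneous stock, whose genomes already interleave all
eight founders; it keeps founder representation balanced at the founding
generation, which whole-founder F1 seeding does not (we measured per-founder
genome shares drifting ±2.5 percentage points under F1 seeding versus
±0.5–0.7 under mosaic seeding — for comparison, the real DO cohort's median
founder contributions span 10.6–13.2%).  Setting the rate to 0 recovers
literal F1 seeding (every G1 animal heterozygous everywhere), used by some
idealized tests.  Later generations form 175 random mating pairs (full-sib
pairs re-drawn), each pair contributing equally — the equal-contribution
design that roughly doubles effective population size.

What the simulator does **not** emulate: crossover interference, real
pre-CC funnel bookkeeping, selection and the documented chromosome-2 WSB
excess, X-chromosome inheritance, and real array artifacts beyond the
configurable call-error/no-call/cluster models.  A green test on simulated
data therefore establishes internal consistency of the methods under the
stated generative model, not robustness to every failure mode of real
arrays.

### Array observation models

Calls: per true state, a multinomial over {A,H,B,N} — expected call at
1 − 2·err − ncall (defaults err = 0.01, ncall = 0.01), the two wrong calls
at err each, and a state-specific no-call rate (`state_no_call`) to emulate
probes where one founder's alleles fail to hybridize; N is always treated
as an informative outcome.  Intensities: per state and marker, independent
Gaussians on polar coordinates (θ, ρ) with conforming markers collapsing
all 36 states onto three canonical centers (θ ≈ 0.12/0.50/0.88, ρ = 1) and
a configurable fraction (default 15%) of "nonconforming" markers where one
founder's ρ is displaced, splitting the clusters to six.

### Phenotypes

`PhenoSimConfig` builds y = QTL + polygenic + error.  The QTL term is
+a / 0 / −a for minor-homozygous / heterozygous / major-homozygous animals,
with the minor allele carried by 1–4 founders.  The polygenic term is
multivariate normal with covariance proportional to the kinship matrix; the
error is iid normal.  The generic defaults give each background component
unit variance.  The **power study** instead fixes the *total* background
variance to 1, split equally (0.5 + 0.5): with that normalization the
reference cell (n = 600, minor allele in 2 founders, a = 0.5) explains
~9% of phenotypic variance and reproduces the published power value, and
the variance-explained axis of the power-vs-variance summary is consistent
with its stated anchor points (20% at n = 200, 5% at n = 1000).  The two
normalizations cannot both hold; the package treats variance bookkeeping
explicitly and reports empirical variance explained
(var(QTL term)/var(y)) per replicate.

## Haplotype reconstruction HMM

The chain over markers has transition matrices built from the genetic map
and the outbreeding generation G.  Per haplotype, ancestry switches over d
Morgans with probability 1 − exp(−λd), landing uniformly on the F founders;
λ = G·r/(2·L) with r the genome-wide ancestry-switch accumulation per
generation (default 23.9) and L the full autosomal genetic length
(14.41 M).  λ is a per-Morgan density and deliberately does not depend on
how much of the genome a given marker map covers.  The diplotype transition
is the product of two independent haplotype chains mapped onto unordered
pairs; d = 0 gives the identity, d → ∞ the equilibrium (1/64 per
homozygote, 1/32 per heterozygote).  Transition parameters are never
re-estimated in EM — fitting them empirically makes reconstructions switch
implausibly often.

Two emission models: a per-marker per-state multinomial over {A,H,B,N}
(initialized at 0.97 on the expected call, 0.01 elsewhere), and a product
of two univariate Gaussians on (θ, ρ) with per-marker per-state means and
variances, initialized from a BIC-selected Gaussian mixture (diagonal
covariance, k = 1..9) with states assigned to the cluster nearest their
founder/F1 reference samples.  Reference intensities are first
quantile-normalized onto the study cohort per marker.

EM alternates scaled forward–backward E-steps (per sample per chromosome)
with M-steps pooling posterior-weighted sufficient statistics across
samples per marker (soft assignments, not hard).  Numerical guards:
emission variance floor 1e-4, multinomial floor 1e-4 with renormalization,
per-step scaling in forward–backward with a uniform fallback for all-zero
rows.  Iterations stop when |ΔLL| < |LL₀|/1000 (default) or at 100
iterations.  Below ~100 samples the per-marker M-step is under-determined
and the package warns.

Marginal reconstruction takes the per-marker argmax (ties → lowest state
index, flagged).  Phasing assigns each marker's unordered pair to two
strands by dynamic programming over the two orientations, minimizing total
strand switches; this can undercount true recombination (switches between
markers with identical unordered pairs are invisible), which is the known
behavior of parsimony phasing.  Breakpoints are placed at bp midpoints
between flanking markers.  Reconstruction quality is density-limited: at
~1–2 cM spacing call-based reconstructions track truth well; at 5+ cM
spacing the posterior is diffuse and dosages shrink toward 2/F.

## Dosage and SNP imputation

Founder dosage d(h) = Σ_s p(s)·N_h(s) (always summing to 2).  At an
off-array SNP the diplotype posterior is the unweighted mean of the two
flanking markers' posteriors (nearest marker beyond the ends); the SNP
dosage is g = Σ_h d(h)·G(h) with G(h) the founder-carries-reference
indicator, clipped to [0,2].  SNPs in the same inter-marker interval
(half-open [left, right) by bp) with the same strain distribution pattern
get one regression, broadcast to the group; collapsing is exactly
statistic-preserving.  Monomorphic SDPs are flagged and scored LOD 0.

## Kinship

k_ie is the marker-average cosine similarity of the 8-dimensional founder
dosage vectors; the diagonal is exactly 1 and entries lie in [0,1].  Note
the baseline for unrelated animals is ~0.3–0.45, not 0 — this is an
expected-allele-sharing similarity, not a centered genomic relationship
matrix.  The matrix is an average of per-marker Gram matrices and hence
PSD in exact arithmetic; the mixed-model code still adds 1e-8–1e-10 jitter
before factorizations.  Leave-one-chromosome-out (LOCO) variants drop the
scanned chromosome so the polygenic term does not absorb the locus under
test; with the long haplotype blocks of simulated populations this matters
a great deal (detection power ~0.94 with LOCO versus ~0.6 with global
kinship in the reference cell).

## Genome scans

All models share y = covariates + locus term + γ + ε, cov(γ) = σ_g²K.
Variance components are estimated once per phenotype under the null
(no locus term) by 1-D profile maximum likelihood over
h = σ_g²/(σ_g²+σ_e²) on the eigendecomposition of K, then held fixed
across loci; each locus is a GLS fit on the whitened data and
LOD = (n/2)·log10(RSS₀/RSS₁).  ML (not REML) ratios are used, with total
variance profiled out.  p-values come from χ² asymptotics at the model's
stated df: 35 (full; the 36 posterior columns sum to 1 and alias the
intercept), 7 (additive haplotype; dosages sum to 2), 1 (additive SNP).
Rank deficiency at a locus is handled by minimum-norm solutions, so
constant predictors score LOD 0 rather than erroring.  With K ∝ I the
whole procedure reduces exactly to OLS.  The user-facing `scan()` refits
the null per LOCO chromosome; the batch simulation path estimates h once
per phenotype on the global kinship and whitens per chromosome by Cholesky
— the difference is numerically negligible and the batch form is ~3×
cheaper.  Founder effects at a locus are reported centered to mean zero
across the eight founders; centering is idempotent and resolves the
dosage-sum aliasing for display.

## Significance and support intervals

Bonferroni: −log10(α/n_tests).  Permutation: phenotype rows (with their
covariates, as a unit) are permuted against genotypes; each permuted set is
scanned with a plain linear model *without* the kinship term, and the
threshold is the empirical (1−α) "higher" quantile of the autosomal maximum
statistic.  Omitting the kinship term makes the thresholds slightly
conservative for the mixed-model scan (our type-I estimate at the α = 0.05
threshold runs ~0.035–0.05), which is the accepted trade for making
1000 permutations affordable.  X-chromosome thresholds are out of scope;
maxima are taken over autosomes.

The 95% support interval transforms the LOD curve to 10^LOD (rescaled by
its maximum for overflow safety), integrates by trapezoids between marker
positions, and grows the interval outward from the peak, absorbing the
larger flanking trapezoid first, until 95% of the area is covered;
endpoints land on marker positions.  An HPD-style variant (absorb segments
in decreasing area order) is available behind a flag; for unimodal curves
the two coincide.  Flat curves return the whole chromosome, flagged.

## Power and type-I studies

A pool of ~1100 simulated G8 genomes on a 500-marker autosomal map stands
in for the real reconstructed cohort.  Per replicate: draw n genomes
without replacement, plant a QTL at a random autosomal marker (for the SNP
model, at a random table SNP with the requested minor-founder count),
build the phenotype as above, scan with the LOCO kinship-adjusted model,
and declare detection when the maximum LOD clears the genome-wide
threshold within 5 Mb of the truth.  Thresholds are calibrated once per
sample size and model as the 0.95 quantile of maximum LODs from plain
linear-model scans of iid N(0,1) phenotypes (default 300 nulls).  The
synthetic SNP table carries one candidate SNP per marker per minor-allele
count 1–4, so the causal variant is always tested — the best case, as with
a fully imputed genome.

Known scale limitations, measured and documented rather than patched: at
500-marker density the genome-wide null maximum of 35-df full-model scans
(LOD ≈ 17) does not exceed the causal-locus signal (LOD ≈ 19), so the full
model retains substantial power here (~0.7–0.8), whereas at real array
density (~7700 markers) its null maximum overtakes the signal and power
collapses to ≈ 0.  Similarly the 1-df SNP scan is nearly saturated at this
density (power ≈ 0.99 versus 0.91 at genome scale).  The 5-Mb detection
window is comparable to the 500-marker spacing, which costs a few points
of power to localization at every cell.

The power-vs-variance summary fits a logistic regression of
replicate-level detection on percent variance explained (statsmodels GLM,
binomial family), one curve per sample size.

## Defaults worth knowing

| parameter | default | where |
|---|---|---|
| founders F | 8 (A–H) | `FounderPanel` |
| mating pairs / generations | 175 / 8 | `BreedingConfig` |
| founding switch rate | 2.0 /Morgan | `BreedingConfig` |
| ancestry-switch rate r | 23.9 events/generation | `hmm.DEFAULT_EVENTS_PER_GENERATION` |
| genome length | 14.41 Morgans | `hmm.GENOME_LENGTH_MORGANS` |
| call error / no-call | 0.01 / 0.01 | `ArrayNoiseModel` |
| EM tolerance / max iter | |LL₀|/1000 / 100 | `em_fit` |
| variance / multinomial floors | 1e-4 | `hmm` |
| permutations / α | 1000 / 0.05 | `significance` |
| power replicates / null scans | 200 / 300 | `power` |
| detection window | 5 Mb | `power.WINDOW_BP` |
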