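# Methods

`beeadmix` re-implements, as a tested and reusable pipeline, the
genotype-likelihood analysis used to characterize ancestry and genetic
diversity in Africanized honey bees (*Apis mellifera*): admixture
proportions and cluster allele frequencies estimated directly from
genotype likelihoods, PCA on posterior-mean genotypes, genome-wide
diversity from a folded site frequency spectrum with block-jackknife
errors, and maternal-lineage (mitotype) classification from a
Kimura 2-parameter neighbor-joining phylogeny.  Every stage is driven by
a synthetic-data generator, so the whole pipeline is verifiable without
any external sequence data.

## The admixture model

For individual *i* at biallelic site *j*, the expected minor-allele
frequency under *K* ancestral clusters is

    h_ij = Σ_k q_ik f_kj ,

with Q (N×K, rows on the simplex) the ancestry proportions and F (K×M)
the cluster allele frequencies.  Rather than calling genotypes, the
likelihood marginalizes the unknown genotype g ∈ {0,1,2} against its
genotype likelihood triplet GL_ij(g):

    ℓ(Q, F) = Σ_ij log Σ_g GL_ij(g) · C(2,g) h_ij^g (1−h_ij)^(2−g).

This is the NGSadmix formulation; it is robust at low or uneven depth
because sequencing uncertainty propagates through GL rather than being
collapsed into a hard call.

**EM.**  Treating each allele copy's ancestral origin and the genotype as
missing data gives closed-form updates: the E-step computes genotype
posteriors γ_g ∝ GL(g)·Binom(g; 2, h) and per-copy responsibilities
(q_ik f_kj / h_ij for a minor copy from cluster k; q_ik(1−f_kj)/(1−h_ij)
for a major copy); the M-step re-estimates f′_kj as the expected fraction
of minor copies among copies from k at j, and q′_ik as the expected
fraction of individual i's copies drawn from k.  Each sweep is monotone
in ℓ (assertable with `assert_monotone=True`).  Individual-sites with no
reads carry the flat triplet (1,1,1); their likelihood term is constant,
so they are excluded from the updates and from the per-individual copy
count.

**Fitting.**  `fit_admixture` uses multiple restarts
(Q ~ Dirichlet(1,…,1), F ~ Uniform(0.05, 0.95), restart seeds derived
deterministically from the top-level seed).  By default each restart
runs a 100-sweep burn-in and only the best by log-likelihood continues
to convergence (|Δℓ| < 1e−6 or 2000 sweeps); `search_iters=None` runs
every restart to convergence.  With four strongly diverged source
lineages all restarts reach the same basin, so the burn-in search is a
runtime optimization, not an approximation of the optimum; on tiny
instances the EM optimum matches direct constrained numerical
maximization of ℓ to 1e−3.  The absolute tolerance 1e−6 is strict for
study-scale problems (ℓ ~ −3×10⁵); fits capped at 2000 sweeps report
`converged=False` while mean-ancestry estimates are already stable to
well under one percentage point.

F is clamped to [1e−6, 1−1e−6] to avoid boundary log singularities.
Cluster labels are exchangeable, so clusters are matched to lineages
afterwards by Hungarian assignment on mean reference-panel ancestry;
matching fails loudly if any lineage's best cluster carries < 0.5 mean
reference ancestry.  Population summaries report mean ancestry
percentages with SE = sample SD/√n over individuals (the obvious reading
of a per-population "mean (SE)"; n = 15 in the presets).

## Per-site frequencies, SNP test, filters

The minor-allele frequency at a site maximizes
Π_i Σ_g GL_i(g)·Binom(g; 2, p) by EM (update: mean posterior dose / 2
over individuals with reads; |Δp| < 1e−8 or 200 iterations).  The SNP
statistic is the likelihood ratio 2[ℓ(p̂) − ℓ(0)] against χ²(1); the
boundary-at-zero halving is deliberately not applied, matching common
usage of the corresponding ANGSD test.  Sites are repolarized so
MAF ≤ 0.5 (ties keep input polarization).  Count-based frequencies pool
reads across individuals (minor reads / total reads), the dialect used
for the SNP-π route.

Site filters apply in a fixed order — coverage, SNP LRT, tri-allelic,
MAF — and the report records removals per rule so counts always conserve.
The "63% of individuals with ≥3× depth" rule is read jointly (an
individual counts as covered only at ≥ min_depth; a two-rule alternative
is selectable).  LD thinning keeps every 100th SNP by ordinal within
each chromosome block, starting at the first.  The admixture-stage
filter (presence ≥ 94%, MAF ≥ 5%) is applied to the thinned SNP set.

## PCA from genotype likelihoods

Each genotype is replaced by its posterior mean
E_ij = Σ_g g·GL(g)·Binom(g; 2, p_j) / Σ_g GL(g)·Binom(g; 2, p_j)
(no-data entries fall back to 2p_j), and the individual covariance is
the frequency-standardized form C = (1/M) Σ_j (E_•j − 2p_j)(E_•j −
2p_j)ᵀ / (2p_j(1−p_j)), with sites below the MAF cutoff or fixed skipped
with a warning.  Coordinates are leading eigenvectors scaled by
√eigenvalue, the sign fixed so each PC's largest-magnitude loading is
positive.  An optional iterative refinement re-estimates
individual-specific allele frequencies from the leading PCs (two rounds
when enabled), off by default since no published settings constrain it.

## Diversity

**Folded-SFS route.**  The likelihood of each total minor-allele count
c ∈ 0..2N at a site is computed by the exact dynamic program
T_i(c) = Σ_g T_{i−1}(c−g)·GL_i(g)·C(2,g), L(c) = T_N(c)/C(2N,c) — the
SAF construction.  Folding averages the two orientations
(L(c) + L(2N−c))/2, and an EM over folded spectrum weights φ (monotone
in likelihood, |Δℓ| < 1e−8) estimates the SFS from sites where at least
50% of the population's individuals have reads.  With η_c = φ_c ·
n_sites_used,

    θ̂π = Σ_c η_c · c(2N−c)/C(2N,2) / total_sites,
    θ̂W = Σ_{c≥1} η_c / (a_{2N−1} · total_sites),   a_m = Σ_{i≤m} 1/i,

where total_sites includes invariant sites.  With noise-free genotype
likelihoods both reduce exactly (to 1e−12) to the textbook
genotype-count estimators.

**SNP-density-weighted route.**  A SNP list is fixed on the *total*
sample (pooled-count MAF > 5%, ≤ 50% of individuals missing).  Within a
population, per-SNP diversity is 2p̂(1−p̂)·n/(n−1) from pooled base
counts, with n the number of chromosomes with coverage (2 × covered
individuals); the mean over SNPs is rescaled by SNP density
S_total/genome_length to account for invariant sites.  The small-sample
factor n/(n−1) is the standard unbiased correction for estimating
heterozygosity from n sampled chromosomes; it is isolated in one
function should a different correction be preferred.

**Block jackknife.**  SEs come from delete-one blocks (chromosomes):
se = √[(B−1)/B · Σ_b (θ_(b) − θ̄)²], unweighted, matching sequential
exclusion of whole chromosomes.  In calibration runs (20 replicate
simulations, 16 blocks) the jackknife SE averages ~1.2× the empirical
SD.

## Mitotype classification

Pairwise distances use the Kimura 2-parameter closed form
d = −½ln(1−2P−Q) − ¼ln(1−2Q) with P/Q the transition/transversion
mismatch proportions over columns retained after *alignment-wide*
complete deletion (any gap or ambiguity removes the column for all
pairs, the MEGA convention).  Saturation (non-positive log arguments)
raises rather than returning a distance.  Trees are built with
Saitou–Nei neighbor joining (Q-criterion, ties broken at the smallest
index pair, negative branch lengths clamped to zero with a warning);
NJ is exact on additive matrices, verified by property test up to 12
leaves and cross-checked against an independent implementation.
Bootstrap supports follow Felsenstein: columns resampled with
replacement, each replicate tree voting for the internal bipartitions of
the full-data tree (no majority-rule consensus); saturated replicates
are dropped and the denominator adjusted.  Rooting is at the midpoint of
the longest leaf-to-leaf path.

A query's clade is read from the smallest clade of the midpoint-rooted
tree containing the query and at least one reference, provided those
references are single-clade; otherwise the query falls back to the
minimum mean K2P distance to a reference clade, and the method used is
recorded per query.  Under the default generator divergences the two
rules agree for every query.

## The synthetic-data generator

The generator emulates the statistical structure the estimators assume,
with the study's own quantities as defaults:

* **Source lineages** (A, M, C, O): per site an ancestral frequency
  p ~ Uniform(0.05, 0.95) drifts into each lineage via the
  Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F).  The
  default drift F = 0.15 per lineage gives pairwise Hudson FST ≈ 0.15,
  enough to separate the four lineages as clearly as the published PCA;
  no inter-lineage divergence is published, so this is a package choice.
* **Admixed individuals**: each of the two allele copies independently
  picks lineage k with probability q_ik and is minor with probability
  f_kj — the exact generative counterpart of the fitted model.  Preset Q
  vectors are the published population means (renormalized to sum 1);
  per-copy lineage labels are retained for future local-ancestry work.
* **Genotype likelihoods**: depth ~ Poisson(29) (the study's mean
  coverage), optional missingness, minor-read counts
  ~ Binomial(d, g/2·(1−ε) + (1−g/2)·ε) with a single symmetric error
  ε = 0.01, GLs the binomial likelihoods normalized to max 1.  No
  quality strings and no four-allele error split: downstream stages are
  strictly biallelic.
* **Mitochondria**: a root sequence evolves along a four-clade
  star-of-stars under the K2P process (κ = 4 by default), between-clade
  divergence 0.05 and within-clade 0.005 substitutions/site, no indels —
  sequences are aligned by construction, which is why multiple alignment
  is out of scope.  The O clade is simulated as its own mitochondrial
  clade; the known carriage of C-type mtDNA by some O-clade subspecies
  is not emulated by default (`merge_co=True` enables it).
* **Genome-like data for diversity**: most sites monomorphic;
  ancestrally segregating sites follow the neutral 1/p frequency shape;
  each lineage additionally carries private rare variants (rate
  0.03/site, frequencies log-uniform on [0.005, 0.05]).  Drift is
  rank-ordered (A 0.05 < O 0.10 < M 0.16 < C 0.22) so the A lineage is
  the most internally diverse, as observed.  Private rare variation is
  the feature that makes a total-sample MAF > 5% SNP list systematically
  under-count diversity, reproducing the published ordering of the
  SNP-based π below the genome-wide π.
* An independent neutral-SFS generator (P(count c) = θ/c) provides
  ground truth for SFS recovery and estimator calibration.

What the generator does **not** emulate: linkage disequilibrium (sites
are independent, so LD thinning is exercised only mechanically),
platform differences between sequencing projects, mapping artifacts,
indels, tri-allelic sites and base-quality variation.  Passing tests
therefore demonstrate correctness of the estimators under their own
model assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Benchmark runs use 5000 SNPs × (80 reference + 15 admixed) individuals
at depth 29 for ancestry recovery (10 EM restarts), 15 kb alignments
with 3 references/clade and 200 bootstrap replicates (scaled from 2000;
support estimates at deep clades are already pinned at 100%) for
mitotype recovery, and 20 000-site genomes with 16 chromosome blocks
for diversity — sizes chosen so a complete verification runs on a
single CPU in minutes while leaving recovery tolerances comfortably
testable.  Degenerate inputs fail loudly: no informative individuals at
a site, zero pooled reads, K > N, fewer than 2 jackknife blocks,
saturated distances, unsupported cluster labelings.

## Known limitations

* The admixture fit is unsupervised by default (references fitted
  jointly, as in the published combined run); `fixed_q` provides the
  supervised variant.
* No model-selection criterion for K is provided (the study reports
  K = 2–6 descriptively and focuses on K = 4).
* Absolute diversity values depend on the real data and are not
  reproduced — only the table structure, estimator definitions and
  qualitative orderings are.
* The tree-walk clade-assignment rule is a documented convention; how
  clade membership was read off the published phylogeny is not stated.
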