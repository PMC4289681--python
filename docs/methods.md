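# Methods

This note documents the statistical models implemented in `admixpop`,
the assumptions behind them, the synthetic-data generators used to test
them, and the numerical and design choices that were genuinely open.

## Setting and notation

A cohort of n diploid individuals is genotyped at biallelic SNPs
(genotypes g ∈ {0, 1, 2} count the alternate allele). Each individual i
carries known admixture proportions α_i = (α_i1, …, α_iK) over K
ancestral populations (K = 2 in the motivating setting: an indigenous
and a recent European component). Admixture proportions are treated as
known inputs — estimating them is the job of dedicated software and out
of scope here.

## Distribution of admixture proportions and corrected allele frequencies

Individual admixture proportions in a recently admixed cohort pile up at
the boundaries: many individuals are entirely unadmixed and a few are
entirely of donor ancestry, with a continuous spread between. The
fitted model is therefore a three-part mixture: a point mass p0 at 0, a
Beta(a, b) density on the interior, and a point mass p1 at 1. Values
within eps = 1e-3 of a boundary are assigned to the point masses,
because ancestry-estimation software reports near-boundary rather than
exact-boundary values; the beta shapes are maximum-likelihood fitted to
the interior values (scipy's beta MLE with the support fixed to [0, 1],
started from moment estimates). The fitted-model mean is reported next
to the empirical mean as a goodness-of-fit check.

The fitted distribution is discretized into B = 10 equal-width bins.
Each bin's probability is its beta mass plus any point mass on its
boundary (0 into the first bin, 1 into the last); its representative
α_b is the probability-weighted mean of its content, computed in closed
form through the Beta(a+1, b) distribution. The number of bins trades
resolution against noise amplification by the 1/(1 − α_b) factor below;
ten is comfortable. Whether bins should be equal-width or equal-mass,
and what value represents a bin, were open choices: equal width with
weighted means is used, and both choices are isolated in
`discretize_distribution`.

Writing f_G for the cohort allele frequency and f_D for the donor
(European reference) frequency, the identity
f_G = (1 − α) f_I + α f_D holds for a subcohort with admixture α, so
each bin yields an inversion (f_G − α_b f_D)/(1 − α_b) for the
ancestral frequency f_I. The implemented corrector averages these over
the bins:

    f′_G = Σ_b Pr(α_b) (f_G − α_b f_D)/(1 − α_b),

with bins at α_b = 1 excluded (fully-donor individuals carry no
information about f_I) and the remaining weights renormalized, and the
result clamped to [0, 1] with a per-site flag since noisy inputs can
push the raw value outside the unit interval.

**Bias of the bin-averaged corrector.** Because the cohort-level f_G —
not a bin-specific frequency — enters every bin's inversion, the
corrector's expectation is

    f_I (1 − ᾱ) A + f_D (ᾱ A − (A − 1)),   A = Σ_b Pr(α_b)/(1 − α_b),

and A ≥ 1/(1 − ᾱ) by Jensen's inequality, with equality only for a
degenerate distribution. The corrector is therefore unbiased when the
admixture distribution is concentrated (which the test suite verifies)
and overshoots the ancestral frequency when it is wide; with half the
cohort unadmixed and the rest spread as Beta(2, 2), A ≈ 2 and the
overshoot is large. For wide distributions the package also provides
the moment-based inversion

    f′_G = (f_G − E[α] f_D)/(1 − E[α]),

which inverts the expectation of the mixing identity directly and is
unbiased for any admixture distribution with E[α] < 1. The bin-averaged
form is the primary interface; the moment form is the recommended check
whenever the fitted distribution has appreciable mass above ~0.5.

## Ancestry-specific haplotype frequencies and LD

For a pair of nearby SNPs, let p_jk be the frequency of two-locus
haplotype j ∈ {AB, Ab, aB, ab} in ancestry k. Each of an individual's
two haplotypes is modeled as an independent draw: ancestry k ~ α_i,
then haplotype j ~ p_{·k}. Two assumptions matter: a haplotype keeps a
single ancestry across both sites (reasonable for tightly linked SNPs,
since local-ancestry tracts are megabases long), and the two haplotype
ancestries are conditionally independent given α_i. The likelihood sums
over the ordered haplotype pairs h(G_i) consistent with the unphased
genotypes (1, 2 or 4 pairs for 0, 1 or 2 heterozygous sites) and over
the latent ancestries:

    L(p) = Π_i Σ_{h∈h(G_i)} Σ_{k1} Σ_{k2} p_{h1 k1} p_{h2 k2} α_{i k1} α_{i k2}.

EM maximizes L(p). The E-step computes each individual's posterior over
(haplotype, ancestry) assignments; the M-step is the standard ratio of
expected counts,

    p*_{jk} = E[# haplotypes of type j and ancestry k] /
              E[# haplotypes of ancestry k],

which keeps every ancestry's four frequencies on the simplex (verified
to 1e-12 per iteration) and never decreases the log-likelihood
(property-tested on random inputs). A per-individual-normalized update
with a global 1/(2n) factor would instead make each column sum to 1/2
summed over j and cannot be a valid M-step for this likelihood; the
ratio-of-sums form is used. Iteration stops when no parameter moves by
more than 1e-6 (tolerance configurable); 5 uniform-random restarts are
run and the best final likelihood kept, ties resolved toward the
earlier start so results are reproducible for a fixed seed.

Identifiability requires variation in α across individuals: if every
individual had identical proportions the likelihood would depend only on
the mixed haplotype frequencies Σ_k α_k p_{jk}. Relatedly, an ancestry
whose summed proportion over the analyzed individuals is ≤ 0.5 is
flagged unresolved rather than reported as noise.

Per-ancestry LD follows from the fitted columns exactly as in a phased
sample: D = p_AB − p_A p_B and r² = D²/(p_A(1−p_A) p_B(1−p_B)), with a
NaN flag when a locus is monomorphic within an ancestry. LD-decay
curves average the naive composite (genotype-dosage) r² and the
per-ancestry EM r² over SNP pairs sampled uniformly (without
replacement, capped per bin) within chromosome and distance bin, after
a 5% MAF filter.

## Inbreeding

For one individual, the chance of carrying the alternate allele at site
s is the ancestry-weighted frequency f*_s = Σ_k α_k f_sk, and with
inbreeding coefficient F (probability of identity by descent) the
genotype distribution is the mixture

    Pr(g=0) = (1−f*)²(1−F) + (1−f*)F
    Pr(g=1) = 2 f*(1−f*)(1−F)
    Pr(g=2) = f*²(1−F) + f* F.

F is estimated by maximizing the composite log-likelihood over sites;
independence between sites is assumed (LD is ignored), which leaves the
point estimate consistent but makes no claim about its standard error.
F is constrained to [0, 1]: negative values would require a different
model (the mixture reading of F breaks down), and the estimators this
package corrects report excess homozygosity, not heterozygosity.
Numerically the likelihood is linear in F per site, so it is scanned on
a 101-point grid and refined by bounded scalar minimization between the
neighbours of the best grid point; this lands within 1e-3 of a
10,001-point exhaustive scan on random inputs (tested). Sites with f*
within f_eps = 0.005 of a boundary are dropped to keep logs finite, and
at least 50 usable sites are required by default.

Using pooled cohort frequencies instead of f* mistakes admixture for
inbreeding — homozygote excess from population structure (the Wahlund
effect) — and the test suite reproduces that inflation on cohorts
simulated with true F = 0.

## D statistics, the block jackknife, and F_ST

For populations arranged as (((H1, H2), H3), H4) with per-site allele
frequencies f_iH, the D statistic is the ratio of sums

    D = Σ_i (f_iH3 − f_iH4)(f_iH1 − f_iH2) /
        Σ_i (f_iH3 + f_iH4 − 2 f_iH3 f_iH4)(f_iH1 + f_iH2 − 2 f_iH1 f_iH2).

Only sites with a frequency present in all four populations enter, and
sites whose denominator term is zero (monomorphic in both pairs) are
excluded from both sums — they would contribute 0/0 and no information.
The frequency form is polarization-free (relabeling alleles at a site
leaves D unchanged; swapping H1/H2 or H3/H4 flips its sign), so no
outgroup polarization step is applied.

Standard errors use a delete-m jackknife for unequal m over contiguous
5 Mb blocks anchored at each chromosome's first site (the anchoring was
an open choice; empty windows are skipped). With block sizes m_j,
n = Σ m_j, g blocks and leave-one-block-out estimates θ̂_{−j}, weights
h_j = n/m_j give pseudo-values τ_j = h_j θ̂ − (h_j − 1) θ̂_{−j}, the
jackknife estimate θ̂_J = g θ̂ − Σ_j (1 − m_j/n) θ̂_{−j}, and

    Var = (1/g) Σ_j (τ_j − θ̂_J)² / (h_j − 1),

with Z = θ̂/SE. Equal block sizes reduce this exactly to the ordinary
delete-m jackknife and one-SNP blocks to the classic delete-1 (both
pinned by tests to 1e-12). A statistic constant across blocks yields
SE = 0 and an infinite/undefined Z rather than an error.

F_ST between two populations uses the Weir–Cockerham (1984)
ratio-of-sums estimator: per-site variance components a (between
populations), b (between individuals within populations) and c (within
individuals) from sample sizes, frequencies and observed
heterozygosity, with F_ST = Σa / Σ(a+b+c); monomorphic panels return an
undefined (NaN) value.

## Ancestry-tract lengths

Along a haplotype of an admixed individual, ancestry is approximated as
a two-state Markov chain over base pairs. A single admixture pulse of
proportion m, t generations ago, with uniform recombination rate r
(Morgans/bp) gives transition rates λ1 = (1−m) r (t−1) from admixed to
unadmixed and λ2 = m r (t−1) back, with stationary probability
π₂ = 1 − m of the unadmixed state. A site initiates an admixed run of
at least k sites with probability R = π₂ λ₂ (1 − λ1)^(k−1); for small R
and genome size S the number of such runs is approximately Poisson(RS),
so the probability of seeing none is exp(−RS). Lengths in cM convert to
sites as k = round((L/100)/r) — one bp is one Markov step — which at
r = 1.3e-8 maps 39 cM to 3×10⁷ sites; (1 − λ1)^(k−1) is evaluated in
log space to avoid underflow at genome scale. The model assumes a
single pulse, a uniform recombination map (the rate is constant, unlike
an empirical genetic map) and independence between runs; m = 1 is a
degenerate edge (the whole genome is one admixed tract, yet R = 0).

The no-long-tract probability is *not* monotone in t everywhere:
R(t) ∝ (t−1)(1−λ1)^(k−1) rises while k·λ1 < 1 (very recent admixture,
where more generations mean more tracts still mostly longer than the
threshold) and falls beyond it (older admixture chops tracts below the
threshold). Property tests assert the increasing-in-t behaviour on the
t ≥ 5 regime for the worked-example parameters, monotone decrease in m
(for m ≤ 0.5) and S, and monotone increase in the length threshold.

Tract-length distributions are summarized in 5 cM bins (counts and
within-population frequencies). To compare tract-length distributions
between two cohorts with different admixture levels, individuals are
matched on ancestry proportion by optimal one-to-one assignment
(minimizing the total absolute difference via the Hungarian algorithm)
after excluding individuals below a 5% threshold; optimal assignment is
deterministic and strictly dominates greedy pairing, whose worst-case
excess is unbounded in ratio terms.

## Synthetic cohorts: what they emulate and what they do not

Each generator is the exact generative counterpart of one estimator, so
parameter-recovery tests probe the estimators under their own
assumptions:

* admixture proportions from the point-mass/beta/point-mass mixture —
  defaults (p0 = 0.2, Beta(2, 5), p1 = 0) emulate a cohort where ~80%
  of individuals carry some donor ancestry and the cohort mean is ~25%;
* genotypes with per-site independent inbreeding (matching the
  composite likelihood; real inbreeding produces runs of homozygosity,
  which this deliberately does not);
* two-locus genotype pairs from ancestry-specific haplotype
  frequencies, phase discarded;
* ancestry tracts from the two-state Markov chain with geometric
  segment lengths, cM = bp·r·100 under the uniform rate;
* four-population allele frequencies drifted along the fixed tree
  (((H1,H2),H3),H4) under Balding–Nichols (each branch draws
  child ~ Beta(f(1−c)/c, (1−f)(1−c)/c)), chosen over a coalescent
  simulator because its closed-form moments (E[f_child] = f_parent,
  Var = c f(1−f)) make drift-calibration and D-statistic nulls exactly
  checkable; root frequencies are uniform on (0.05, 0.95) and drifted
  frequencies are clipped to (1e-9, 1−1e-9) so later beta draws remain
  proper.

Passing recovery tests therefore demonstrates correctness of the
estimators under their stated models, not robustness to features real
data add: genotyping error, SNP ascertainment, non-uniform recombination
and mutation, linked sites, phasing or local-ancestry inference error,
and uncertainty in the α_i themselves (treated as known throughout).

Problem sizes in the test suite (cohorts of 1,000–2,000 individuals,
10⁴ sites or SNP pairs, 100–1,000 replicates, a 2.7×10⁸ bp genome for
tract Monte Carlo) were chosen so each recovery check has comfortable
statistical resolution — Monte-Carlo tolerances are stated as 3
standard errors at those sizes — while the whole suite runs in minutes.

## Numerical conventions and degenerate inputs

* Missing genotypes are excluded pairwise everywhere (frequencies,
  missingness, r², EM input pairs).
* Site positions are 1-based (VCF convention); tract intervals are
  half-open 0-based [start, end) (BED convention).
* LD pruning slides 50-SNP windows by 5 within each chromosome and
  removes the later SNP of any pair with dosage r² > 0.3 at evaluation
  time; the scan is deterministic. Pruning r² is the squared Pearson
  correlation of 0/1/2 dosages (composite LD), the natural choice when
  phase is unavailable.
* Likelihood evaluations floor probabilities at 1e-300 before logs;
  EM per-individual likelihoods are floored the same way so that a
  start vector with a zero in the wrong place cannot produce −∞/NaN.
* Filters that remove everything warn and return an empty container
  rather than raising; estimators that would have to return noise
  (too few usable sites, no complete genotype pairs, an ancestry with
  negligible total α) raise or flag instead.
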