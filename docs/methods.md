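# Methods

## The analysis in one paragraph

`ltrpopgen` treats each LTR-retrotransposon (LTR-RT) insertion as an
individual and each evolutionary lineage as a population sample.  The
lineage's aligned reverse-transcriptase (RT) amino-acid sequences are
recoded as multilocus genotypes; a Bayesian admixture model clusters the
elements into K source populations; the Evanno delta-K statistic over
replicate runs chooses K; replicate membership matrices are label-aligned
and averaged; elements holding at least 1% membership in two or more
clusters are called admixed.  Orthogonally, each element's insertion is
dated from the divergence of its two LTRs (identical at insertion time)
by the molecular clock T = k / 2r, elements are grouped into families by
the 80-80-80 rule on their RT nucleotide sequences, and insertion-time
distributions are compared across clusters and the admixed group with
nonparametric statistics.

## Genotype encoding

Only variable alignment columns are retained; each column is one locus.
The 20 amino acids and the stop codon are alleles, coded by a fixed
alphabetical bijection (A=1 … Y=20, `*`=21); gaps become the missing code
-9.  Variability is judged on non-missing states only, so a column whose
residues are constant apart from gaps is dropped: this is the
conservative reading of "variable position" in the presence of missing
data.  Columns where a single sequence differs (singletons) are retained
— they carry two distinct states.  Because plant genome assemblies are
effectively homozygous, every element is written as a homozygous diploid
(two identical rows) in the classic STRUCTURE input dialect
(MISSING=-9, PLOIDY=2, LABEL=1); the reader rejects heterozygous records.

## The admixture model and its sampler

The model is the standard model-based clustering of multilocus genotypes:
individual i has membership simplex q_i; population k has an
allele-frequency simplex p_kl per locus; each allele copy at a
non-missing site originates from population k with probability q_ik and
is then drawn from p_kl.  The Gibbs sweep is

1. Z_{i,l,a} | Q, P  ∝  q_ik · p_{k,l,x_il}  (two independent copies per
   site, matching the homozygous-diploid coding; a haploid likelihood
   would halve all counts),
2. p_kl | Z  ~  Dirichlet(λ + m_kl)  (independent-frequency model), or
   Dirichlet(p_Al (1−F_k)/F_k + m_kl) under the correlated-frequency
   F-model, with Metropolis updates of each drift parameter F_k
   (gamma prior with mean 0.01, sd 0.05) and of the ancestral
   frequencies p_Al (mass-shift proposal between a random allele pair),
3. q_i | Z  ~  Dirichlet(α + n_i),
4. Metropolis update of α (normal proposal, sd 0.025, uniform prior on
   (0, 10)); a flag can hold α fixed instead.

Per-locus allele spaces are the observed allele sets.  Missing sites
contribute nothing and carry no Z.  Initial state is drawn from the
priors.  Defaults (λ = 1, the F-model hyperpriors above) mirror the
documented defaults of the classic clustering program; the desk-scale
default run is 5,000 burn-in + 10,000 recorded sweeps, and any larger
protocol is reachable through the configuration.

ln Pr(X|K) is estimated from the post-burn-in complete-data
log-likelihood trace D as mean(D) − var(D)/2 (sample variance, n−1).

### Numerical and performance choices

The sweep kernel is compiled with numba and specialized on K so the
per-population loops unroll.  It uses an inline xorshift128+ generator
(seeded via splitmix64 from the run seed), so every run is a pure
function of its configuration.  The two allele-copy draws at a site
share one 64-bit random word (26 bits of resolution each — far below
any categorical probability the model can resolve over ≤ 21 states).
The log-likelihood is accumulated as Σ m·log p over occupied
(population, locus, allele) cells, which equals the per-copy sum
exactly.  Gamma draws are Marsaglia–Tsang with an exponential fast path
at shape 1, clamped at 1e-300 before simplex normalization to keep
frequencies strictly positive when drift parameters make shapes tiny.
With one population the origins are fixed and the chain reduces to iid
P | X draws; the kernel takes that exact shortcut.  The posterior mean
of P is accumulated every 10th recorded sweep (it is the largest state
array and its Monte-Carlo error is dominated by chain autocorrelation,
not the thinning); Q is accumulated every sweep.

### Known property: bias of the mean − var/2 estimator

The estimator assumes the log-likelihood is approximately Gaussian under
the posterior.  At K=1 its expectation has a digamma/trigamma closed
form, which the test suite uses as an exact check of the sampler's
trace.  Against the true Dirichlet-multinomial marginal likelihood the
estimator carries a positive small-sample bias — about one log unit for
a 4-individual, 3-locus matrix, shrinking as counts grow.  Model
selection is unaffected in practice because delta-K differences at
informative K ranges are orders of magnitude larger, but the bias is
real and the corresponding strict accuracy check in the acceptance
suite documents it.

### Choice of frequency model for K scans

The correlated-frequency F-model is the appropriate prior when
populations are weakly differentiated (it shares information through an
ancestral pool), and it is the package default.  For delta-K scans over
simulated lineages with well-separated populations the independent-
frequency model is statistically adequate and avoids the F-model's
extra Metropolis machinery, so the K-recovery experiments
(`ltrpopgen.experiments.delta_k_recovery`) default to it; both models
are available everywhere via `frequency_model`.

## Model selection and consensus

Evanno's delta-K is computed from the per-K means of ln Pr(X|K) over
replicate runs: L'(K) = L(K) − L(K−1), L''(K) = |L'(K+1) − L'(K)|,
delta-K = L''(K) / sd(K), defined at interior K with positive replicate
standard deviation; the selected K is the argmax, ties breaking toward
smaller K with a warning.  Replicate Q matrices at the selected K are
aligned to the first run by minimum summed L1 distance over column
permutations (optimal assignment via the Hungarian algorithm; verified
against exhaustive permutation search for K ≤ 5), then averaged and
row-renormalized.  An element is admixed when its averaged membership
reaches the cutoff (default 1%, inclusive) in two or more clusters.
Classification operates on the run average, consistent with averaging
runs for display; the choice of reference run is immaterial after
averaging.

## Insertion dating and families

LTR-pair identity comes from a global pairwise alignment with affine gap
costs (match +1, mismatch −1, open −2, extend −0.5) and free end gaps;
identity = matches / aligned columns excluding end gaps.  This replaces
the local-alignment identity of BLAST2seq-style tools: paired LTRs are
near-full-length homologs, where a free-end-gap global alignment is the
cleaner estimator and has no arbitrary seeding heuristics.  Divergence
k = 1 − identity and T = k / (2r) with r = 1.3e-8 substitutions per
site per year (the grass intergenic-region rate) as default.  Elements
without an LTR pair (e.g. nested insertions whose pair cannot be
resolved) are flagged `dating_unavailable` and excluded from dating and
group statistics rather than imputed.

Families follow the 80-80-80 rule (≥80% identity, ≥80% coverage, ≥80 bp
overlap) by greedy centroid clustering: sequences sorted longest-first
(ties by identifier) join the first family whose representative they
match, else found a new family — the algorithm of CD-HIT-EST-style
clustering, deterministic and input-order independent.  Coverage is
measured against the longer sequence, the stricter of the two possible
denominators.  Mean pairwise p-distances within a lineage use pairwise
deletion of gapped positions; pairs with no comparable columns are
excluded with a warning.

## Group statistics

Insertion times of full-membership elements (grouped by cluster) and of
admixed elements are compared with the Kruskal-Wallis rank ANOVA
(tie-corrected, chi-square approximation), followed by Dunn's pairwise
z tests on the joint ranks (tie-corrected rank variance; unadjusted p
by default, Bonferroni optional — the ranking tool used for the original
tables does not document its post-hoc).  The compact letter display is
built by insert-and-absorb: starting from one letter spanning all
groups, each significant pair splits the sets containing it and
contained sets are absorbed, which guarantees exactly that two groups
share a letter iff they do not differ at the chosen α.  Normality
pre-testing is omitted: the nonparametric route is taken by design.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with ground truth retained:

* **Structured lineages.**  Population allele frequencies at each locus
  are s·onehot(modal_k) + (1−s)·b_l, with distinct modal residues per
  population and a shared baseline simplex b_l supported on 4 random
  residues (alignment columns of a conserved domain rarely show more
  than a handful of states).  s ∈ [0,1] is the separation: 1 gives
  disjoint modal supports, 0 identical populations.  Memberships are
  one-hot balanced (round-robin) in the no-admixture limit — exact
  rather than tiny-α sampling, avoiding numerical degeneracies — or
  Dirichlet(α_true), with an option to inject a fixed admixed profile
  into a subset of individuals.  Gaps are independent dropout.  Default
  L = 200 columns, within the 176–251 range of real per-lineage RT
  alignments.
* **LTR pairs.**  A random 5' LTR and a copy substituted per site with
  probability d (no indels: the dating formula consumes divergence, and
  the alignment kernel is exercised separately).
* **Family sets.**  One root per family, mutually diverged to a
  between-family identity target (default 0.5), members mutated to a
  within-family target (default 0.95); both straddle the 0.80 threshold.

What the generators deliberately do not model: phylogenetic
autocorrelation within populations (sites are independent given the
population), insertions/deletions in LTRs, rate variation across sites,
and selection.  Passing recovery tests therefore demonstrate that the
inference machinery is correct under its own model assumptions, not
that real LTR-RT lineages satisfy those assumptions.

## Problem sizes used in the recovery experiments

The seeded K-recovery experiments use N = 60 (3 populations) and N = 80
(2 populations, 5% admixed at 0.7/0.3), L = 200, separation 0.9, 2% gaps,
K scanned 1–6 with 5 replicate runs of 2,000 + 8,000 sweeps, and 10
replicate datasets — sizes chosen to match real per-lineage element
counts and alignment widths at desk scale.  Genome-scale figures (about
2,000 elements across nine lineages, K up to 13) require the source
assembly and upstream annotation tools and are outside this package's
scope; the property-based suite covers the corresponding logic.

## Pipeline conventions

Lineages are processed fully independently; per-lineage seeds derive
from the master seed and the lineage name, so input order cannot change
any output.  Genomic coordinates are 1-based; density windows (default
5 Mb) are inclusive of their upper bound and the final partial window
is kept.  All randomness flows from one master seed; rerunning a
configuration reproduces every output byte-for-byte.  INFO logging
echoes every parameter used (rate, cutoff, sweep counts, seeds).

## Limitations

* The sampler has no linkage model and no use of prior population
  information; markers are treated as unlinked, matching the intended
  use on RT amino-acid columns.
* Delta-K cannot select K at the boundary of the scanned range and is
  undefined when replicate runs are numerically identical; the pipeline
  reports these conditions explicitly.
* CLUMPP-style alignment here handles label switching only; multimodal
  run clustering (major/minor modes) is not implemented.
* The mean − var/2 marginal-likelihood estimator is biased at very
  small sample sizes (see above).
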