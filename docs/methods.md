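# Methods

This note documents the models, estimators and numerical conventions behind
`mothroutes`, the parameters that matter and their defaults, what the
synthetic-data generators do and do not emulate, and the design choices made
where several defensible options existed.

## Data model

Genotypes are unordered pairs of microsatellite allele sizes (bp) per locus
per diploid individual, grouped into named populations.  Any allele code of
0 marks the whole genotype as missing (the GenePop convention); partially
missing genotypes do not exist.  GenePop I/O accepts 2- and 3-digit allele
encodings and writes 3 digits whenever an allele exceeds 99 bp.  GenePop has
no population-name field; on read the label is derived from the first
individual's label with a trailing `_<number>` stripped, which makes the
write→read round trip the identity for datasets labeled that way.

## Diversity statistics and F-statistics

* **He** is Nei's unbiased gene diversity `(2n/(2n−1))(1 − Σp²)` with `n`
  the typed individuals at the locus.
* **RA** is hypergeometric rarefaction: the expected allele count in a
  random draw of `g` gene copies, `Σ_a [1 − C(N−N_a, g)/C(N, g)]`.  The
  default `g` per locus is the smallest typed gene count across populations,
  so all populations are compared at a common depth; `g` is configurable.
* **FIS** is the Weir–Cockerham small-sample within-population estimator
  `f = 1 − Σc/Σ(b+c)` summed over loci and alleles, not the plug-in
  `1 − Ho/He`; its significance is assessed by permuting allele copies
  among individuals within the population (default 10,000 permutations),
  reporting one-tailed deficit and excess p-values.
* **FST** is multilocus Weir–Cockerham θ, the ratio of summed among-
  population variance components to total; negative estimates are retained
  everywhere because downstream linearization and matrix summaries expect
  the raw estimator.

Undefined cells (no data, or monomorphic for FIS) are reported as NaN and
excluded from means rather than silently zeroed.

## Locus screening

The Hardy–Weinberg exact test is probability-based: the p-value is the total
conditional probability (given allele counts) of genotype tables no more
probable than the observed one.  Tables are fully enumerated when the locus
has ≤3 alleles and ≤20 typed individuals; otherwise the null is sampled by
randomly re-pairing the observed gene copies (Monte Carlo, default 10,000
tables, p estimated with the (b+1)/(m+1) correction).  The switch point
keeps enumeration where it is cheap and exact, and the MC sampler is
validated against enumeration in the tests.

Null-allele frequencies use the Dempster EM scheme: a non-amplifying allele
of frequency `r` makes null homozygotes appear as blanks and null
heterozygotes as visible homozygotes.  The E-step splits each observed
homozygote class between true homozygotes (`p²/(p²+2pr)`) and null
carriers; blanks count as null homozygotes (an option disables this for
datasets whose missingness is mostly technical).  Convergence is `|Δr| <
tol` (default 1e-6, max 5,000 iterations, non-convergence flagged).

The linkage screen computes a genotypic log-likelihood-ratio (G) statistic
of the locus×locus genotype table pooled over populations and permutes one
locus's genotype column within populations; pairs with fewer than five
jointly typed individuals are skipped and flagged.

The QC filter mirrors the two-condition rule used for microsatellite panel
cleanup: a locus is dropped only when its mean null-allele frequency exceeds
0.20 **and** it is out of HW equilibrium in at least half of the populations
with data.  No multiple-testing correction is applied at this stage — the
screen is a conjunction of two independent red flags, not a formal test.

## Isolation by distance and by resistance

Genetic distances are `FST/(1−FST)`; geographic distances default to planar
Euclidean distance on decimal degrees (the spreadsheet-toolkit convention,
kept as the default so results line up with that lineage of analyses), with
great-circle (haversine, R = 6371 km) available for sensitivity analysis.
Distances are natural-log transformed; Mantel r is invariant to the log
base.  Zero distances are rejected rather than patched.

The hurricane-conductance stage maps an incidence-category raster (1–5) to
per-cell conductances through a configurable table (default: identity —
the study gives no numeric mapping, so the identity keeps the monotone
"more hurricanes, more flow" assumption and nothing else).  Cells connect
to 8 neighbors by default (4 available); edge conductance is the mean of
the two cell conductances, diagonal edges scaled by 1/√2.  Pairwise
effective resistance comes from the weighted graph Laplacian with one node
grounded: solve `L x = e_s − e_t` and read the potential drop.  Disconnected
anchors raise an error naming the components.

Mantel tests correlate the n(n−1)/2 off-diagonal entries; the permutation
null shuffles rows/columns of one matrix simultaneously, one-tailed upper,
p = (b+1)/(m+1), default 10,000 permutations.  The partial Mantel follows
the residual-permutation method (regress both matrices on the conditioning
matrix, correlate residuals, permute the first residual matrix); this
variant is stated explicitly because the literature contains several.  If
the conditioning matrix explains one input exactly, the partial correlation
is defined as 0 (the residual is numerical noise).

## Admixture clustering

The sampler implements the admixture model: cluster allele frequencies with
independent Dirichlet(λ=1) priors, per-individual admixture proportions with
a symmetric Dirichlet(α) prior, latent cluster-of-origin per allele copy,
and a single α shared across individuals updated by random-walk Metropolis
(step 0.025, uniform(0,10) prior).  This is deliberately simpler than the
correlated-allele-frequencies and LOCPRIOR variants: independent priors are
sufficient to resolve the strong native/invaded split that is the testable
claim here, at a fraction of the parameterization.  Chain defaults are
burn-in 10⁴ and 5×10⁴ total iterations (thin 10) — sized for desk-scale
datasets; longer chains are plain arguments.  The model log-evidence per K
is estimated as `mean(lnL) − var(lnL)/2` over post-burn-in samples, and the
number of clusters is chosen by the Evanno second difference
`ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K))` across replicate runs, ties
toward smaller K, with a smallest-K fallback (and warning) when ΔK is
undefined everywhere.  Cluster label switching is handled by best-permutation
matching (Hungarian assignment on the Q overlap matrix).

## Coalescent simulator

Genealogies are simulated backward in time per locus with exponential
waiting times at rate `k(k−1)/2 / (2N)` per generation within each deme
(diploid size N), a continuous-time approximation of the discrete
coalescent that is adequate down to founder sizes of a few individuals and
makes piecewise-constant epochs straightforward.  Demes interact only
through events: a founding moves all of a deme's lineages to its source at
time T, preceded (backward) by a bottleneck epoch of size `n_b` for the
last `db` generations before T; an admixture founding sends each lineage
independently to the first source with probability `r5` (defined as the
proportion of Highlands ancestry from La Romana), else to the second.  The
native deme switches to an ancestral size `N_anc ~ U[10, 3000]` at `T1` —
the standard treatment of a native population's deeper history when the
data cannot resolve it.

Mutations are Poisson on branches under the generalized stepwise model:
±1 repeat with probability 1−P, otherwise a geometric number of steps
(parameter P), reflected at the locus's allele-size bounds.  The bounds and
2-bp motif come from the ten retained loci's published size ranges.  Per
dataset, the mean rate is drawn log-uniform on [10⁻⁴, 10⁻³], per-locus
rates are Gamma(shape 2) around that mean, and P ~ U[0.1, 0.3] — the
conventional microsatellite ABC defaults, stated here as assumptions since
the tools this emulates do not expose what any given study used.  The
simulator is validated against the strict-SMM equilibrium heterozygosity
`He = 1 − 1/√(1+8Nμ)`, against an independent coalescent implementation
(msprime) in the tests, and against limiting FST behavior.

## ABC scenario choice and estimation

Each simulated or observed dataset is reduced to a fixed 40-statistic
vector over the five sampled demes: per deme the mean (over loci) allele
count, unbiased He, allele-size variance and Garza–Williamson M-ratio; per
deme pair the multilocus Weir–Cockerham θ and mean (δμ)² distance.
Monomorphic conventions: He = 0, variance 0, M-ratio 1, undefined pairwise
θ = 0 (flagged).  Statistics are z-scored by the reference table's moments;
the 1% of rows nearest the observed vector (Euclidean; ties broken by row
index) are retained.  Scenario probabilities are reported two ways: the
retained scenario frequencies ("direct") and a multinomial logistic
regression of scenario on the stat differences evaluated at the observed
point (weak L2 regularization standing in for the classical ridge).
Parameter posteriors use local-linear regression adjustment with
Epanechnikov weights; bounded-uniform parameters are logit-transformed and
log-uniform ones log-transformed before regression, which keeps adjusted
draws inside their priors.

Error rates for a focal scenario come from pseudo-observed datasets drawn
from the priors: type I is the fraction of focal-scenario pods for which
the focal scenario is not ranked first; type II, per alternative scenario,
is the fraction of that alternative's pods in which the focal scenario wins,
averaged over alternatives; binomial standard errors accompany both.  Note
that with the admixture rate uniform on [0.1, 0.9], the admixture scenario
approaches each one-source scenario at its prior boundaries, so prior-based
error rates for it have a substantial intrinsic floor on this statistic
set — the package reports what the experiment yields rather than a
localized (posterior-conditioned) error that would require a real observed
dataset.

Problem sizes: the package defaults to reference tables of 30,000
simulations per scenario and 500 pods per scenario — the scale at which the
full error-rate experiment runs in minutes on one CPU while leaving the
Monte-Carlo error of the reported rates near the percent level.  Larger
tables are a single argument.

## Synthetic data

`generate_study_like_dataset` extends the admixture scenario with the seven
populations outside the three-scenario core (including the second native
deme), each attached as a serial founding from its geographically nearest
scenario deme at a time drawn safely below the source's own founding time.
This is a fixture convention to produce a 12-deme, 229-individual,
10-locus dataset shaped like the study design; it makes no historical claim
about those populations.  What passing tests on these data show is that the
pipeline's estimators and classifiers behave correctly on data whose truth
is known — not that any particular route reconstruction for the real moth
is correct.  Real-data features deliberately not emulated: genotyping
error and allele dropout beyond the null-allele model, linkage between
loci, population growth between events, and geographically realistic
hurricane surfaces (the raster generator produces a monotone gradient with
noise and optional land masks, which is enough to test the circuit solver's
corridor behavior).

`generate_hw_population` draws one population at given allele frequencies
with a planted inbreeding coefficient (P(aa) = p² + f·p(1−p)), an optional
null allele (added to the gene pool, then expressed as blank homozygotes /
visible false homozygotes), and random missingness — the ground-truth
fixtures for the estimator-recovery tests.

## Numerical conventions and edge cases

* Permutation p-values always use (b+1)/(m+1); they can never be 0.
* All generators and samplers are pure functions of their seed; reference
  tables derive one RNG stream per row from (master seed, scenario, row),
  so worker count cannot change results.
* Genealogies that fail to coalesce (mis-wired scenarios) raise rather than
  return partial data; zero or negative deme sizes are rejected.
* Reflection at allele bounds is applied per mutation step until the state
  is in range.
* Zero-variance summary-statistic columns are dropped (with a warning)
  before distance computation.

## Known limitations

* The admixture-model sampler averages Q over the chain without
  re-labelling within a run; for weakly separated clusters label switching
  can blur posterior means (between-run comparisons do use best-permutation
  matching).
* The HW enumeration path is limited to 3 alleles; beyond that the MC
  sampler is used even for small n.
* The LD screen's G statistic pools populations without weighting; very
  unbalanced samples are dominated by the largest population.
* Effective resistance uses a dense solve per anchor pair after one sparse
  factorization; rasters far beyond ~10⁶ cells would need an iterative
  solver.
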