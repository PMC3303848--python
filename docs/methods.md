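# Methods

## The model

`bnbmla` treats relevance in a genetic association study as a structural
property of a Bayesian network over the observed variables: SNP genotypes
coded as 0/1/2 minor-allele counts and treated as 3-category multinomial
variables, binary phenotypes, and discretized clinical measurements.  A
network structure `G` is a DAG; given complete multinomial data `D` with a
Dirichlet parameter prior, the marginal likelihood `P(D|G)` has the
closed decomposable form

    P(D|G) = prod_i prod_j  Γ(a_ij) / Γ(a_ij + N_ij)
             * prod_k Γ(a_ijk + N_ijk) / Γ(a_ijk)

with `N_ijk` the count of rows where child `i` takes state `k` under
parent configuration `j`.  The default hyperparameters are the classical
uniform choice `a_ijk = 1` ("CH"); a BDeu parameterization
(`a_ijk = ess / (r_i q_i)`) is available when likelihood score-equivalence
across Markov-equivalent DAGs is wanted.  The structure prior is uniform
over DAGs respecting a parent limit (default 8), so it cancels in all
posterior ratios; the limit itself implicitly reshapes the prior, which we
accept and document rather than renormalize.

A structural feature `f(G)` (edge presence, blanket membership, dependency
type, ...) has posterior `P(f|D) = Σ_G f(G) P(G|D)`.  Exact summation is
intractable beyond a handful of variables, so posteriors are estimated by
Metropolis-coupled MCMC (MC³) over DAG space and, on domains of at most
six variables, computed exactly by enumeration as an internal oracle.

## Relevance features

For a predictor X and target Y on a single structure:

* **DCR** — edge between X and Y (either direction);
* **TCR** — directed path of length ≥ 1 between them (a direct edge counts;
  the `mediated_only` flag isolates paths of length ≥ 2 without an edge);
* **ConfR** — a proper common ancestor;
* **Association** — DCR ∨ TCR ∨ ConfR;
* **PIR** — common child *and no direct edge*;
* **SR** — DCR ∨ PIR, equivalently membership in Y's Markov blanket.

PIR is defined disjointly from DCR so that averaged posteriors satisfy
P(SR) = P(DCR) + P(PIR) exactly; the additivity of reported
direct/interaction/strong columns in the literature this package follows
motivates that reading of "common child".  Markov blanket sets (MBS) are
parents ∪ children ∪ children's other parents; the blanket of a target
*set* is the union of member blankets minus the set.  k-MBS (partial
multivariate relevance) sums the observed MBS posterior over supersets of
each k-subset; because only visited structures contribute, k-MBS values
are exact with respect to the empirical MBS table and lower bounds with
respect to the full posterior.  Multi-target decompositions report, per
target, Exist (SR to it), Only (SR to it alone), OtherThan (SR to some
other target), the joint MT posterior, and the independence approximation
AP = 1 − Π_y (1 − Exist_y), displayed at two decimals.

A variable is *called* relevant when its posterior reaches 0.5
(inclusive).

## The sampler

Proposals use three operators — add, reverse, delete an edge — with the
operator drawn uniformly; an operator with no valid instantiation is
resampled, which is implemented equivalently as a uniform draw over the
operators that have one.  The instantiation is uniform over the
operator's valid instantiations, and the acceptance ratio carries the
exact Hastings correction from neighborhood sizes on both sides of the
move.  Validity is tracked incrementally: a reflexive reachability matrix
makes cycle checks for additions O(1) per candidate, and the boolean
product `adj @ closure` counts exactly the edges whose reversal would
leave an alternative directed path.  Reversals are checked against both
acyclicity and the parent limit.

The published protocol this package implements states the burn-in (10⁶
steps), sample count (5×10⁶, which we read as post-burn-in steps) and
parent limit (8) but not the coupling scheme; the defaults here are 4
chains at inverse temperatures 1.0/0.8/0.6/0.4, a swap attempt between a
uniformly chosen adjacent pair every 10 sweeps, all chains started from
the empty graph (deterministic and unbiased under the uniform prior), and
cold-chain feature evaluation every 10th sweep (interval 1 is the
per-visited-DAG variant).  A single seeded generator drives every random
draw in a fixed order, so runs are bit-reproducible.  Convergence is
monitored with the classic Gelman-Rubin statistic on feature indicator
series across independent runs; note that for identical chains the
statistic is √((n−1)/n), i.e. 1 only up to O(1/n).

## Frequentist baselines and QC

Hardy-Weinberg equilibrium uses a 1-df chi-square goodness of fit against
expected counts from the estimated allele frequency.  QC removes
monomorphic SNPs, SNPs with HWE p < 0.005 *in controls only*, and SNPs
with call rate ≤ 90% (computed before complete-case filtering).  Allele
and genotype association tests use chi-square without continuity
correction (the simplest documented choice; sources vary), cross-product
odds ratios with 95% Woolf intervals, and the Haldane 0.5 correction
(flagged) for zero cells.  Bonferroni thresholds are α/m, displayed at
one significant figure.  Haplotype odds ratios are reconstructed from
carrier frequencies and chromosome counts by rounding to integer counts;
this count-based OR can differ in the last printed digit from a
conditional-logistic haplotype OR (e.g. 1.42 vs 1.41 on the same
frequencies), which we document rather than force.  Logistic interaction
fits delegate to statsmodels' Newton IRLS with genotypes entered
numerically (0/1/2) and raise explicitly on separation or
non-convergence.  Covariate adjustment (age, sex) is supported as extra
columns but not required by any test.

## Missing data and discretization

The closed-form score assumes complete data.  Loaders keep missing cells
flagged; `complete_case_filter` either drops incomplete rows (default,
preserving the score's assumptions and reporting the count) or
mode-imputes (reported per cell).  Continuous clinical measurements are
discretized by median split by default (tertiles and fixed cutpoints are
available); ties go to the lower bin and cutpoints are returned for
reproducibility.  The upstream analysis this design follows did not state
its discretization or missingness policy, so both are explicit,
conservative defaults here.

## The synthetic generator

The generator emulates a candidate-region case-control design: founder
SNPs drawn under Hardy-Weinberg equilibrium from stated MAFs; LD proxies
produced by copying each source allele with a fidelity `f` (else
redrawing from the population frequency), giving allelic correlation `f`
and r² = f² — sufficient to create transitive-but-not-direct structure
while staying analytically checkable; direct effects as additive
per-allele log-odds in a logistic model; epistatic pairs acting only
through an XOR of heterozygosity indicators (or a centered genotype
product), both of which have exactly zero marginal effect at MAF 0.5; and
acyclic phenotype wiring (e.g. an IgE → eosinophil/rhinitis → asthma
chain) with continuous phenotypes drawn log-normally and discretized.
Every (SNP, target) pair carries a mutually exclusive ground-truth label
(direct / pure_interaction / transitive_only / null).

What the generator does **not** emulate: haplotype-block LD, population
stratification or admixture, genotyping error, and missingness patterns.
Passing recovery tests therefore demonstrate that the method identifies
planted structure under clean HWE sampling, not robustness to those
real-data complications.

Scenario defaults: the recovery scenario uses n = 1500 individuals and 20
SNPs with one direct SNP (per-allele log-OR 0.6, MAF 0.3), one fidelity-
0.9 proxy of it, one XOR pair (log-OR 1.0, MAF 0.5) and 16 nulls —
moderate-to-strong candidate-gene effect sizes chosen once so the planted
architecture is identifiable at that sample size.  The two-target and
clinical scenarios mirror smaller embedded designs (two wired binary
targets at n = 1500; four targets at n = 200).

## Problem sizes used in the test suite

Sampler correctness is established against exact enumeration on ≤5
variable, 200-row datasets with 2×10⁵ recorded sweeps (agreement within
0.02 on every edge, SR, association, PIR and MBS posterior), and the
no-data analytic limit P(edge) = 2/3 on two variables.  Recovery runs use
10⁵ burn-in plus 5×10⁵ sweeps of 4 chains with evaluation interval 10 —
a deliberately scaled-down schedule relative to the full protocol,
sufficient for the 21-variable scenario because the tempered chains mix
across the planted modes within a few thousand sweeps.  The package's own
defaults remain the full protocol.

## Known limitations

* The CH prior is not score-equivalent; Markov-equivalent DAGs can score
  differently, which slightly informs edge orientation posteriors.  Use
  BDeu when that matters.
* k-MBS aggregation is exact only over visited structures; deep subset
  queries (large k) on flat posteriors inherit Monte Carlo truncation.
* Exhaustive enumeration is limited to six variables.
* Binomial Monte Carlo standard errors ignore autocorrelation; treat them
  as lower bounds and use the R-hat diagnostic across independent seeds
  for convergence assessment.
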