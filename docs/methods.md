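# Methods

`pocos` discovers **population-covering locus sets** — groups of genotyped
loci whose binarized genotypes jointly "cover" (take value 1 for) every case
sample of a case-control cohort while covering as few controls as possible —
and evaluates them as features of sparse logistic risk models. This note
documents the model, the numerical choices, and what the synthetic study
conditions do and do not establish.

## Dataset model and preprocessing

A cohort is `D = (C, S, g, f)`: loci `C`, samples `S`, genotypes
`g(c, s) ∈ {hom-allele1, het, hom-allele2, missing}`, and a dichotomous
phenotype `f(s) ∈ {0, 1}` partitioning `S` into cases `S₁` and controls
`S₀`. Genotypes are stored as allele2 copy counts; the minor allele is
derived per dataset over non-missing genotypes, with frequency-0.5 ties
broken toward the lexicographically smaller allele symbol so that results
do not depend on input order. Missing genotypes shrink the denominators of
allele frequencies and association tables.

Two filters run before discovery, by default on the whole cohort (the
original pipeline order; per-training-fold filtering is available through
the same functions for leakage-free variants):

* MAF filter: loci with minor allele frequency ≤ 0.05 are removed.
* Marginal exclusion: loci whose allelic-association p-value (1-df Pearson
  chi-square on the 2×2 allele-count table, two alleles per individual, no
  continuity correction) is below 1e-7 are removed, so that discovered sets
  reflect joint rather than single-locus effects. These p-values are not
  Bonferroni-adjusted; Bonferroni correction applies only where individual
  loci are ranked as model features.

## Five genotype models and adaptive binarization

Each locus admits five binary encodings, defined by the genotype states
mapped to 1 (a = minor allele): {aa}, {Aa}, {AA}, {Aa, aa}, {Aa, AA}. For
encoding *i* the discrimination score is

    D⁽ⁱ⁾(c) = ⟨f, m⁽ⁱ⁾(c)⟩/|S₁| − ⟨1−f, m⁽ⁱ⁾(c)⟩/|S₀|,

and the selected model maximizes |D⁽ⁱ⁾(c)|. Because encodings 4 and 5 are
complements of 3 and 1, the argmax is structurally non-unique on
missing-free data (|D⁽⁴⁾| = |D⁽³⁾|, |D⁽⁵⁾| = |D⁽¹⁾|). The tie rule — among
maximizers prefer D > 0, then the lowest model index — makes the selection
deterministic and hands coverage a case-enriched 1-profile, which is the
asymmetry the covering step relies on. Float ties are detected with an
absolute tolerance of 1e-12 because complement scores are computed from
different integer numerators. Missing genotypes contribute 0 to every
encoding while the |S₁|, |S₀| denominators stay at full class sizes.

Within cross-validation the selection is fitted on training samples only;
the selected genotype-of-interest states are stored as a lookup over
allele2 copy counts and applied verbatim to held-out samples.

## Greedy covering search

Starting from an empty set `P`, the search repeatedly adds the candidate
maximizing the conditional gain

    δ(c) = |E({c}) ∩ S′|/|S₁| − |T({c}) ∩ S′|/|S₀|,

where `E`/`T` are covered cases/controls and `S′` the still-uncovered
samples, until the covered cases reach `ceil(coverage_fraction · |S₁|)`
(default 1.0 — every case). Only candidates covering at least one uncovered
case are eligible, which guarantees termination. Ties are broken by more
newly covered cases, then larger |D| of the locus's selected encoding, then
the lexicographically smallest locus id — deterministic and independent of
input order. Completed sets leave the candidate pool (sets are disjoint in
loci) and the search restarts; the first incomplete attempt ends discovery
and its loci are discarded (an `emit_partial` flag keeps them for
diagnostics). The algorithm is a heuristic: tests compare its control
coverage against the exhaustive optimum on small instances and assert only
that it is never better, not that it matches.

## Heterogeneous network and the constrained search

The network `G = (V ∪ U, E ∪ F ∪ Q)` has locus nodes `U` and gene nodes
`V`, with RoI edges `F` (locus within 50 kb up/downstream of a gene's
coding region), eQTL edges `Q`, and PPI edges `E`. `U` contains exactly the
genotyped loci with at least one locus–gene edge. Since loci never neighbor
loci, all locus–locus paths of length ≤ 3 run through genes: shared-gene
pairs are 2 hops apart and PPI-bridged pairs 3 hops. Hops are counted
uniformly over edge types, so eQTL–gene–eQTL pairs at 2 hops are admitted
alongside the RoI-based patterns; the 3-hop reachability matrix is computed
sparsely as `B Bᵀ + B A Bᵀ` (B = locus–gene incidence, A = PPI adjacency).
The constrained search differs from the free search only in that the first
locus of each set is unrestricted within `U` while every later addition
must lie within 3 hops of a current member. Consumed loci remain in the
graph (irrelevant to paths, stated for determinism).

A gene-frequency report counts, per gene, the selected sets containing at
least one adjacent locus (top 10 by default, ties by gene id).

## Features, filters, risk models

Each set contributes one feature per sample, the representative genotype
`h(P, s) = Σ_{c∈P} M(c, s)/|P| ∈ [0, 1]`. Before model fitting, features
are filtered at threshold α either by a two-sample two-sided KS test of the
case vs control feature distributions (exact p below 25 samples per class,
asymptotic above) or by Wald p-values from one joint logistic regression on
all features. The joint regression is ill-posed when features outnumber
samples, so an L2 stabilizer of 1e-4 (intercept unpenalized) is always
added and the run is flagged when q > n/2; with the stabilizer sent to zero
the fit matches an ordinary maximum-likelihood logistic regression.
Set-level p-values are compared to α raw; individual-locus baselines use
Bonferroni-corrected p-values by default (a `raw` switch exists, used in
the penalty sweep where the comparison fixes one common threshold of 0.05
for both feature types).

The risk model minimizes the *total* negative log-likelihood plus
`λ‖β‖₁` with an unpenalized intercept (default λ = 0.001). The solver
recasts each penalized coefficient as a difference of two non-negative
parts and runs L-BFGS-B on the resulting smooth bound-constrained problem,
giving exact zeros at the bound; it is cross-checked in the tests against
statsmodels (λ = 0) and scikit-learn's saga path (λ > 0). On cohorts of a
few thousand samples this λ range penalizes weakly — model size then comes
mainly from the filtering step — whereas λ of the order of the sample size
zeroes everything; both regimes are exercised in tests. AUC is computed by
the Mann–Whitney identity with ties counted 1/2.

Evaluation is nested stratified K-fold cross-validation (K = 5, 5 fold
randomizations with recorded seeds). Inner folds select (α, λ) by mean AUC
over the grid α ∈ {5e-8, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3} and
λ ∈ {1e-4, 1e-3, 1e-2, 1e-1}, ties resolved toward the sparser model
(larger λ, then smaller α). Every discovery/selection stage sees training
samples only; out-of-fold predictions are pooled into one AUC per repeat.
An inner-CV configuration with an empty feature set scores 0.5 with size 0
for the set-based and individual-locus methods and is invalid for the
polygenic score (which cannot score without loci).

Baselines: (1) individual loci — additive minor-allele coding of loci
passing the Bonferroni-corrected association threshold, then the same L1
classifier; (2) polygenic score `PS_α(s) = Σ_{c∈L} γ(c) g(c, s)` with `L`
the loci at training p < α and `γ` the slope of a univariate logistic
regression on the additive coding (vectorized Newton solver, slopes capped
at |30| under separation, degenerate designs get 0; statsmodels is the
test oracle).

## Synthetic study conditions

The generator draws biallelic genotypes independently per locus under
Hardy–Weinberg proportions (background MAF uniform on [0.05, 0.5], so the
default MAF filter passes essentially all loci) and assigns phenotypes from
a logistic model whose linear predictor adds `log(OR)` per active planted
module. Module rules are `union` (≥ 1 member locus carries the module's
genotype state — a genetic-heterogeneity model) and `xor` (exactly one of
two loci carries the state; with state frequency near 0.5 the marginals
vanish while the joint association remains). Cohorts are ascertained
case-control by rejection sampling to exact quotas; the analytic population
prevalence (enumeration over module-indicator patterns) must lie in
[0.005, 0.995] or the specification is rejected. The companion network
generator wires each module's loci within 3 hops through module genes,
cycling the four association patterns (shared RoI; RoI–eQTL; RoI–PPI–RoI;
RoI–PPI–eQTL), tiles background genes so background loci acquire RoI edges,
and adds random PPI (mean degree 3) and eQTL (rate 0.05) edges. All tables
round-trip through the package's own readers.

The frozen signal preset plants five purely-combinatorial modules in a
2,000-sample, 500-locus cohort: four 2-locus heterozygous-state union
modules at MAF 0.5 with covered odds ratio 4, and one 2-locus
homozygous-minor union module at MAF 0.35 with odds ratio 2.2 (base odds
0.015). The heterozygous modules exploit an exact symmetry: at allele
frequency 0.5, enriching heterozygotes among cases leaves case and control
allele frequencies identical, so allelic tests and additive codings are
null in expectation *regardless of effect size* — the planted signal is
purely a genotype-combination effect, visible to the five-model
binarization and coverage but not to single-locus baselines. The
homozygous-minor module leaks a small additive signal (marginal p around
1e-3 to 1e-5) so that individual-locus baselines are weak but not empty.
An XOR pair was considered for this role and rejected: with state
frequency exactly 0.5 its representative-genotype feature is distributed
mirror-symmetrically in cases and controls, so no monotone (logistic)
model can rank by it; XOR remains a supported rule exercised in unit tests
(near-null marginals, strongly significant joint 4-cell association).

What passing these conditions shows — and does not. The generator omits
linkage disequilibrium, population structure, genotyping error and missing
data, and its planted effects are stronger than typical common-variant
effects so that orderings are resolvable at desk scale (a 500-locus cohort
stands in for a filtered genome-wide panel). Results on it demonstrate
correctness of the machinery and the qualitative superiority of
combinatorial features under combinatorial truth, not expected performance
on real GWAS data. One scale effect deserves note: with only hundreds of
candidate loci, full-case coverage forces sets to absorb long tails of
weakly informative loci (set sizes of ~5–40 versus ~3 in genome-scale
data), which dilutes the representative genotypes; the planted effect
sizes were chosen with this dilution in mind.

## Known limitations

* The covering objective is greedy and non-optimal by design; no
  approximation guarantee is claimed.
* Joint-regression filter p-values are Wald statistics from a ridge-
  stabilized fit; with q approaching n they are screening scores, not
  calibrated tail probabilities.
* The whole-cohort preprocessing filters (MAF, marginal exclusion) reuse
  the full sample set including eventual test folds, mirroring the original
  pipeline; the leakage-free variant must be requested explicitly.
* Phenotypes are strictly dichotomous; quantitative traits are out of
  scope.
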