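# Methods

## Data model

A dataset is a samples × SNPs matrix of minor-allele counts {0, 1, 2}
with a binary phenotype (0 = control, 1 = case). Missing genotypes are
rejected rather than imputed: the simulator never produces them, and
imputation is out of scope. SNP indices are 0-based internally; the
continuous search space uses the 1-based grid [1, M] so that the
opposition mirror ub + lb − v is symmetric about the middle SNP.

## Objectives

For a SNP combination S of order k, the 3^k × 2 contingency table
counts samples per (genotype combination, phenotype class); empty
combinations keep their all-zero row, which contributes nothing to
either score.

* Mutual information uses plug-in entropies with natural logarithms.
  The plug-in estimate can be a few ulp negative on independent tables
  and is clipped to 0.
* The K2 score is the Dirichlet(1,…,1) marginal likelihood of the
  phenotype given the combination; we report its negative natural log
  via `gammaln`, so it is exact up to floating-point rounding with no
  factorial overflow at any count. Lower = stronger association.
* Fitness is the ratio fit = MI / max(K2log, 1e-12). The ε-guard covers
  degenerate single-sample tables where K2log = 0; both numerator and
  denominator are in nats, so the ratio's units cancel consistently.
  With a different log base both scores scale by the same constant and
  the ranking is unchanged.
* The Pearson chi-square p-value (over rows with nonzero margin,
  df = (I_occupied − 1)(J − 1)) is reporting-only; tables with fewer
  than two occupied rows or an absent phenotype class return p = 1 by
  convention.

## Simulator

Functional genotypes at the k = 2 embedded loci are drawn from the
joint Hardy–Weinberg distribution of the configured MAFs; disease
status is Bernoulli with the drawn combination's penetrance; draws
continue until both the case and control quotas fill (prospective
rejection sampling). This matches penetrance semantics exactly: the
over-representation of high-penetrance genotypes among cases *is* the
disease signal. Sampling aborts with a clear error after a bounded
number of draws when quotas are unreachable (e.g. an all-zero
penetrance table with cases requested).

Noise SNPs are independent HWE draws with MAFs uniform on (0.05, 0.5).
The functional MAFs default to (0.25, 0.25). Neither value is dictated
by the benchmark definitions of the 12 built-in models, which specify
only the penetrance tables; (0.25, 0.25) is a typical GWAS benchmark
setting and both are configurable. Consequence: the "no marginal
effect" property of models 9–12 holds only under the original
generator's (unpublished) MAFs and is not enforced here.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, covariates, genotyping error or missingness, population
stratification. A green detection test therefore establishes that the
search finds a planted signal among independent noise, not that it is
robust to real-data structure.

## Network

The Barabási–Albert graph starts from a complete clique of m₀ nodes and
adds nodes one at a time, each attaching `n_links` distinct edges drawn
with probability proportional to current degree (duplicate targets
resampled, so the graph stays simple). Edge count is therefore exactly
m₀(m₀−1)/2 + n_links·(N−m₀). Hub ids 1..m₀ are assigned to the clique
in random order; later nodes take ids by join order. The network is
built once per run and never mutated (guarded by a structural hash).

`n_links = 2` is the package default: the protocol fixes m₀ = 3 and the
construction needs n_links < m₀; 2 gives the denser of the two legal
choices. The fitted power-law exponent γ̂ (least squares of ln P_k on
ln k for k ≥ n_links) is diagnostic only; the plain log-log fit on BA
graphs lands near 2, below the theoretical tail exponent 3, because the
sparse large-k classes flatten the slope.

## Search

Defaults follow the small-scale protocol: N = 100 bees, T = 50
iterations, limit = 10, m₀ = 3, n_links = 2. Design choices where the
procedure was genuinely open:

* **Decoding.** Positions are continuous; decoding rounds half-up,
  clamps to [1, M], and redraws later coordinates uniformly on
  collision, then overwrites the position with the decoded integers.
  Combos are unordered (both objectives are invariant to locus order),
  so scores are cached per sorted pair.
* **All k dimensions** are perturbed per move (k = 2). The classic
  single-random-dimension ABC variant mixes more slowly at such low
  dimensionality.
* **Onlooker trigger is rand > Pᵢ** — the *unselected* sources are
  re-updated, which inverts classic ABC but is implemented as designed;
  exactly N update events run per onlooker phase, giving a fixed
  candidate budget.
* **Opposition ties favor the opposed point** (v wins only strictly);
  the greedy against the incumbent is strict, so the trail counter
  counts genuine stagnation.
* **Scout** examines only the single max-trail source per iteration
  (ties to the smallest index) and replaces it unconditionally — even
  by a worse random source — to restore diversity. The global best is
  never lost because the ranked output comes from the score cache, not
  the live population; this also makes the best-so-far trace
  non-decreasing by construction.
* **RNG.** One `numpy` Generator seeded from the config; draw order is
  initialization positions → network seed → per-iteration phases. The
  entire run is bitwise reproducible.

### Evaluation accounting

Candidate evaluations per iteration are exactly 4N + scout for the
network search (employed and onlooker each produce N candidate/opposed
pairs) and 2N + scout for the single-objective baselines (no opposition
point). Distinct objective computations (`n_evaluations`) are what the
memo cache actually computed and are the fair cost measure against the
C(M, 2)-pair exhaustive scan: a converging run on 100 SNPs typically
computes 1.5–3.5 thousand distinct pair scores versus 4950.

## Evaluation protocol

Detection is the strictest defensible criterion: the embedded pair must
be the top-1 ranked solution (configurable `top_k`). Because each
simulated dataset embeds exactly one functional pair, Power = #T/#S and
recall coincide identically. A dataset counts as a false positive when
the top-1 report is wrong *and* its Bonferroni-corrected chi-square
p-value (over C(M, 2) tests) clears α = 0.05 — a confidently wrong
report; this makes precision < 1 reachable and testable. The F-measure
is the harmonic mean of recall and precision, 0 by convention when
either is 0. Wall-times in the benchmark table are informational only.

## Known limitations

* Order k = 2 only; higher-order interactions must be inferred from
  pairwise output.
* No Pareto front: the two objectives are scalarized by the MI/K2log
  ratio.
* Absolute fitness values depend on sample size and the log base and
  are not comparable across datasets; only rankings matter.
* The exhaustive oracle is guarded at 10⁶ combinations; beyond that the
  stochastic search runs unvalidated.
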