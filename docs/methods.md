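# Methods

## Correlated, irreversible gene loss

### Model

Presence/absence of a gene pair on a rooted species tree is modeled as
a continuous-time Markov chain over the joint states
(1,1), (1,0), (0,1), (0,0) — "1" present, "0" absent — with all gain
rates identically zero.  The dependent model's four free rates are

| rate | transition | meaning |
|------|------------|---------|
| q₄₂  | (1,1) → (0,1) | loss of gene 1 while gene 2 present |
| q₄₃  | (1,1) → (1,0) | loss of gene 2 while gene 1 present |
| q₃₁  | (1,0) → (0,0) | loss of gene 1 after gene 2 is gone |
| q₂₁  | (0,1) → (0,0) | loss of gene 2 after gene 1 is gone |

The independent model constrains q₄₂ = q₃₁ = β₁ and q₄₃ = q₂₁ = β₂, in
which case the joint chain factorizes into two single-trait loss chains
(state 0 absorbing).  This factorization is an exact identity and is
asserted to 1e-8 in the test suite.  The likelihood-ratio statistic
Λ = 2(lnL_dep − lnL_indep) is referred to χ² with 4 − 2 = 2 degrees of
freedom; the constrained optimum is an interior point of the dependent
rate space, so standard asymptotics apply.

Assumptions worth keeping in mind:

* **Irreversibility** — the genes are defined as strict orthologs, so a
  gain is impossible.  Consequently the root state must be both-present
  whenever either gene is observed anywhere (any other root state gives
  zero likelihood), and the root is fixed there rather than estimated
  or integrated.
* **Branch lengths are absolute time** (TimeTree-style, e.g. millions
  of years).  Only the product rate × length enters the likelihood, so
  this is a unit convention; loss rates are "per unit branch length".
* A stem (root) edge present in the Newick input is preserved by I/O
  and pruning but ignored by the likelihood, which conditions on the
  crown root state.
* **Missing tip states** contribute all-ones partial likelihoods
  (unobserved, not absent).  The missing token in trait tables defaults
  to `?`.

### Numerics

* Transition probabilities are matrix exponentials computed by Padé-13
  scaling-and-squaring, re-implemented vectorized over the whole branch
  batch (`cooccurrence.expm_batched`) and validated against
  `scipy.linalg.expm` to <1e-12, including at the coincident-eigenvalue
  degeneracy q₄₂ + q₄₃ = q₃₁ where closed forms are numerically
  fragile.
* The pruning recursion runs on a flattened postorder representation of
  the tree; no per-node rescaling is applied (log-likelihoods down to
  ≈ −700 per partial product are representable, far beyond the sizes
  used here).
* Optimization is bounded L-BFGS-B on log rates, internally rescaled by
  the tree's mean branch length for conditioning, with box
  [1e-6, 1e3] per unit mean branch length.  The default is 25 starts:
  one deterministic start (a moment-based guess for the single-trait
  fits; the independent-fit factorization point for the dependent fit,
  which guarantees lnL_dep ≥ lnL_indep up to tolerance) plus seeded
  uniform draws.  Empirically the extra random starts change lnL by
  <0.02 on 40-tip data, so bulk simulations in the test suite use 5.
* A gene never observed absent has its MLE at the boundary β = 0 with
  likelihood exactly 1; this case is short-circuited rather than
  optimized.
* Λ < 0 can only arise from optimizer noise; values below −1e-6 emit a
  warning (optimization failure), and Λ is clipped at 0.
* Multiple gene pairs are tested without multiple-testing correction by
  default (raw p-values are the primary output); a Bonferroni-adjusted
  p-value is available via `n_tests=`.

### Calibration

With 40-tip trees and β₁ = β₂ = 0.3 (tree depth ≈ 3 time units at
birth rate 1), the LRT's type-I error at nominal 0.05 measured over 500
simulated null datasets is ≈ 0.04 — mildly conservative, as expected
from the asymptotic χ² reference on data of this size.  The acceptance
suite asserts the rate lies inside the exact central 95% binomial
interval around 0.05 and re-measures it on every run.

## Evolutionary rate covariation

* **Rate transformation.**  Branch-specific relative rates are the
  gene's branch length divided by the reference (genome-wide average)
  length of that branch, then mean-centered and unit-scaled per gene
  over its non-missing branches.  Standardization makes ERC invariant
  to per-gene positive rescaling (a gene-wide rate multiplier does not
  change its correlations).  Pearson correlation is the default; a
  Spearman option exists because the exact statistic used by upstream
  ERC tools varies.
* Profiles with fewer than `min_branches` (default 10) usable branches
  are dropped with a warning; pairs sharing fewer than 3 branches, or
  with zero variance on the shared branches, give an undefined (NaN)
  ERC rather than a number.
* **Permutation null.**  The pathway statistic is the mean ERC between
  the focal gene and the set.  Null draws replace the focal gene with a
  random gene from the background pool — all profiled genes excluding
  the focal gene *and* the set, so the tested entities cannot inflate
  their own null — with replacement (the pool is typically far smaller
  than the 10,000 default draws).  Ties count toward the numerator
  ("observed or greater").  The primary p-value is k/N; the
  bias-corrected (k+1)/(N+1) is always reported alongside, since k/N
  can be exactly 0.

## Interactome filtering

* Fold thresholds are inclusive ("at least 3-fold" means ≥ 3.0).
* A protein with zero control counts and positive bait counts passes
  the fold test with infinite enrichment and is flagged; a pseudocount
  mode (+0.5 to both statistics) is available instead.
* The peptide floor applies to bait replicates either in *any* replicate
  (single-experiment BioID style) or in *each* replicate (paired
  technical replicates); count statistics are totals or replicate
  averages correspondingly.
* The default carboxylase exclusion list is PC, PCCA, PCCB, MCCC1,
  MCCC2, ACACA, ACACB — the class (endogenously biotinylated,
  streptavidin-binding) is the rule; the membership is editable.
* Isoforms collapse by gene symbol: a gene is a hit if any isoform
  passes, and the best-supported isoform's evidence is reported.
  Accession-level grouping can be emulated by supplying gene symbols
  derived from accession prefixes.

## Synthetic data: what it emulates, and what it does not

* **Trees** are Yule (pure birth): after the crown reaches n lineages
  the process runs one further exponential waiting time, so
  E[depth] = Σ_{k=2..n} 1/(λk).  Real species trees have extinction,
  sampling bias and rate variation; the co-occurrence test conditions
  on the tree, so tree shape realism is not load-bearing.
* **Traits** evolve by exact Gillespie simulation of the loss chain —
  the forward counterpart of the likelihood — and agree with the
  transition matrices within binomial noise (asserted on star trees).
* **Branch rates** use a per-branch latent factor with loading √ρ for
  block genes and log-normal multiplicative noise (sd 0.3 by default),
  keeping rates positive; for this noise level the Pearson correlation
  of the multipliers is within ~0.02 of the latent ρ, and the
  within-block mean ERC tracks ρ (asserted at ρ = 0, 0.5, 0.9, 1).
* **Spectral counts** are negative binomial around log-normal
  per-protein baselines (dispersion α = 0.5 by default,
  var = μ + αμ²); true interactors scale the bait mean by the fold
  change; unique peptides grow with counts and never exceed them.
  With the default overdispersion, ≈10% of null proteins exceed 3-fold
  by chance in a single bait/control pair — a realistic reminder that
  the fold filter controls signal-to-noise, not an error rate.
* Green simulation tests establish internal consistency (estimators
  recover planted parameters; nulls are calibrated), not that the
  generators reproduce any particular real dataset: real
  presence/absence calls carry genome-quality artifacts, real branch
  lengths share the tree's sampling error across genes, and real
  spectral counts have correlated contaminants, none of which are
  modeled.
* Defaults for the stated simulation worlds (used by tests): 40-tip
  trees at birth rate 1.0 with β = 0.3 for null calibration; 30
  branches, 120 profiled genes, 10-gene pathway for ERC calibration;
  deviations are stated where each test scales a world down for
  runtime.

## Known limitations

* Exactly two traits jointly; no gain rates, hidden rates, or Bayesian
  (MCMC) machinery.
* Published p-values for the MCM8/MCM9/MCM8IP pairs depend on the
  specific retrieved species tree and on root/branch-length conventions
  not fully determined by their description, so real-data checks are
  directional (dependent model preferred) rather than bit-exact.
* ERC consumes precomputed branch-length tables; no alignments or
  branch-length estimation from sequences.
* The filters operate on identified-protein tables; peptide-spectrum
  matching and FDR control are upstream of this package.
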