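# Methods

## Scope and model

`forageblup` implements pedigree-based genetic evaluation for a
clonally replicated perennial-forage trial: 21 unrelated founder
parents, 42 full-sib families (120 progenies) from their crosses, two
replicates (clones) per genotype, four years, three seasonal cuts.
Every analysis is an animal model solved through Henderson's
mixed-model equations (MME); variance components come from restricted
maximum likelihood.

Three model layouts are provided per trait:

* **single-cut**: `y = μ + year + a + e`, `a ~ N(0, A σ²_A)`,
  `e ~ N(0, I σ²_e)`;
* **multi-cut repeatability** (default for pooled analyses):
  `y = μ + cut + year + a + p + e`, with one additive variance shared
  across cuts, a permanent-environment effect `p ~ N(0, I σ²_pe)`
  attached to the *physical plant* (genotype × replicate), and a
  separate residual variance per cut.  An `unstructured` option
  replaces the shared additive variance with a full cut × cut genetic
  covariance `G ⊗ A`;
* **bivariate**: two traits stacked, additive covariance `G ⊗ A`
  (unstructured 2×2), an unstructured 2×2 plant permanent-environment
  term whenever plants carry repeated records, and an unstructured 2×2
  residual block per plot record.  Only complete-case records (both
  traits observed) enter, which keeps the residual blocks uniform.

The permanent environment is attached to the plant rather than the
genotype because clones of a genotype are physically distinct plants:
under that reading clones share breeding value but not `p`, which is
what makes `σ²_pe` separable from `σ²_A` at all.  With a single
observed cut the multi-cut fit deliberately collapses to the single-cut
layout (no `p`): the two models then agree exactly in likelihood.  The
consequence, documented here, is that for once-per-year traits
(NS, FL) the pooled univariate analysis absorbs plant permanent
environment into `σ²_A`; the bivariate fit does include `p` for such
traits since it detects repeated records per plant.

## Pedigree algebra

Inbreeding coefficients use the Meuwissen–Luo tabular-kinship
recursion (path coefficients against the mendelian-sampling variances
`d_i = 1 − 0.25(1+F_s) − 0.25(1+F_d)`, with missing parents treated as
unrelated non-inbred founders).  A is built by the tabular method; A⁻¹
is constructed directly from pedigree structure by Henderson's rules
with the inbreeding correction, stored sparse, and log|A| falls out as
`Σ log d_i`.  Topological ordering uses a stable Kahn traversal so a
permuted input yields identical matrices by label — evaluations are
bit-reproducible.

## REML

The restricted log-likelihood is computed through the MME
factorization, `−2 logL = log|C| + log|R| + Σ log|G_k| + y'Py` with C
the full coefficient matrix; this equals the dense
`log|V| + log|X'V⁻¹X| + y'Py` identity, which the tests assert to
1e−8.  Updates are average-information (AI) steps,
`AI_ij = ½ y'P V̇_i P V̇_j P y`, assembled from working vectors
(`Z û/σ²` for genetic terms, scaled residuals for R-side parameters);
first derivatives use the standard trace identities on the inverse
coefficient matrix.  A step is halved (up to 10 times) if it leaves
the parameter space or decreases the likelihood; otherwise an EM step
is taken, which is always uphill and always valid.  Convergence:
maximum relative parameter change < 1e−8 or |ΔlogL| < 1e−9, capped at
200 iterations.  Variances are floored at 1e−8 × var(y); an estimate
stuck within 2× the floor is flagged as a boundary solution.  Standard
errors come from the inverse AI matrix at the optimum, and derived
quantities (h², r_g) get delta-method SEs.

Systems are assembled sparse and factorized by dense LAPACK Cholesky:
at this package's scale (≤ ~900 equations) that is faster than any
sparse pipeline available here and exactly deterministic.  Fixed
effects use reference-level (drop-first) coding; BLUEs therefore
depend on that parameterization, while BLUPs, likelihoods and variance
components do not (tested).  Records missing the response are dropped
from that trait's fit.

One statistical subtlety the tests encode: when the true genetic
variance is zero, the REML estimate lies on the boundary with
asymptotic probability one half (half-normal mass at zero), not with
near certainty; the pure-noise test asserts a boundary fraction in
[0.25, 0.75] together with negligible interior estimates.

## Selection arithmetic

`h²n = σ²_A/σ²_P`, where `σ²_P` sums the fitted components; with
cut-specific residuals the residual contribution is their mean across
cuts (one pooled phenotypic variance per trait is the convention the
published tables use).  Response `R = i h² σ_P`, correlated response
`CR_y = i r_g h_x h_y σ_P(y)`, `RSE = CR_y/R_y = r_g h_x/h_y`;
selection intensity defaults to 1.75 (top 10%), configurable.  The
`as_reported` flag rounds intermediate h² and r_g to two decimals
before the response formulas — published response tables are
reproduced exactly only under that convention; full precision is the
default for new analyses.

## Stability and PCA

Eberhart–Russell stability regresses each entry's yearly mean yield on
the environmental index (yearly grand mean of the entity set, each set
— parents, families, progenies — analyzed separately).  The slope is
tested against 1 by a two-sided t-test with n_years − 2 df; the
deviation-from-regression variance S²d is reported as the method's
second parameter even though only b is customarily printed.  Entries
missing a year are fitted on their available years and flagged; fewer
than 3 usable years omits the entry with a warning.  PCA standardizes
traits (correlation-matrix PCA) and fixes component signs by making
each component's largest-magnitude loading positive, so results are
invariant to entity order.

## Synthetic data

The generator is the package's evidence base, since the trial's raw
field records were never deposited.  It reproduces the crossing design
exactly (or randomized analogues for batteries), draws multi-trait
breeding values by the mendelian-sampling recursion — founders from
`N(0, Σ_G)`, descendants as mid-parent plus a deviation with
covariance `d_i Σ_G` — so `Cov(vec a) = Σ_G ⊗ A` holds by
construction, then adds year and cut fixed effects, one
permanent-environment draw per plant (shared across all its repeated
measures, independent across traits), and per-record residuals with
cut-specific variances and cross-trait correlation 0.2 within a
record.  Default truths sit at the published component scale (e.g.
yield `σ²_A = 4350.66`, `σ²_pe = 3000`, mean residual 11750 g²/plant²,
genetic correlations 0.36–0.86) with seasonal means showing the usual
summer depression; NS and FL are generated spring-only.  Identical
seed and configuration give bit-identical output.

What passing tests show — and do not show: the simulator realizes the
fitted models' own assumptions (normality, additivity, no
genotype × year interaction, clone-faithful replication), so parameter
recovery demonstrates the estimator is correct and calibrated, not
that real fescue data meet those assumptions.  Real trials add
non-additive genetic variance, spatial trend and G×E, none of which
are generated here.

## Problem sizes used for the stochastic batteries

Chosen as the package's own balance of precision and turnaround:
single-cut recovery and coverage at the full study design (141
individuals × 2 reps × 4 years, 200 replicates); multi-cut recovery at
a randomized 21-family design (200 replicates); bivariate r_g at
r_g ∈ {0, 0.5, 0.85} on a 15-family single-cut design with unit-scale
traits of h² 0.2/0.3 (200 replicates each).  Acceptance bands:
mean σ̂²_A within 10 % of truth, ±2 SE coverage within [0.90, 0.99],
median r̂_g within 0.05.

## Known limitations

* Multi-trait fits stop at bivariate; no maternal, dominance or
  genotype × year terms.
* Heterogeneous residuals are cut-specific only (no year × cut cells).
* The bivariate fit discards records observed for just one of the two
  traits.
* BLUEs are reported under drop-first coding; compare contrasts, not
  raw coefficients, across software.
* Published-table regression checks exclude cells whose printed digit
  grouping is ambiguous in the source and the one pooled-analysis
  heritability that is inconsistent with its own printed components.
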