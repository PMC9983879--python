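# Methods

## Model and assumptions

`magreml` quantifies genetic mediation: the share of an outcome's
additive-SNP genetic variance that runs through a mediator trait. The
generative model is a structural equation model with two latent genetic
factors — *G*, which may affect the outcome both directly and through the
mediator, and *G\**, which reaches the outcome only through the mediator —
and two idiosyncratic environmental factors:

```
M = a·G + g·G* + f·E*        Y = c·G + b·M + e·E
```

All latents have zero mean and unit variance; the genetic factors covary
across individuals according to the genomic relatedness matrix (GRM), the
environmental factors do not. The implied variance components are

| VC | value |
|----|-------|
| σ^G_MM | a² + g² |
| σ^G_MY | (a² + g²) b + a c |
| σ^G_YY | (a² + g²) b² + c² + 2abc |
| σ^E_MM | f² |
| σ^E_MY | f² b |
| σ^E_YY | f² b² + e² |

Not every path coefficient is identified (under full mediation a² and g²
are only identified in sum), but the targets — b, the indirect effect
(a²+g²)b², and the direct effect c² — always are, provided:

1. the heritability model behind the GRM is correct;
2. the mediator precedes the outcome with a homogeneous effect;
3. the mediator's environmental component affects the outcome only through
   the mediator;
4. environmental confounders of the mediator–outcome association are
   included as fixed-effect covariates (and colliders are not);
5. the mediator has non-zero environmental variance.

Assumptions 1–4 are substantive and cannot be verified from the data; the
CLI prints them as a checklist. Assumption 5 is checked numerically: the
estimated σ^E_MM must exceed a floor of 1e-6 times the mediator's total
variance, otherwise b = σ^E_MY/σ^E_MM would be returned as an exploding
ratio and the analysis is refused instead.

The genetic variance of Y decomposes exactly as
direct + indirect + 2abc; the cross term 2abc is genetic covariance between
the direct and mediated channels and is deliberately reported on its own,
never folded into either effect. The "proportion mediated" is reported two
ways — indirect/σ^G_YY (the headline, matching the heritability-share
interpretation) and indirect/(indirect+direct) — because the two differ
exactly when the cross term is non-zero.

## REML computation

The stacked model is y ~ N(Xβ, Σ_G ⊗ A + Σ_E ⊗ I). With the
eigendecomposition A = U D U′, rotating each trait's phenotype and design by
U′ reduces the covariance to per-individual 2×2 blocks
V_i = d_i Σ_G + Σ_E, so one restricted-likelihood evaluation is O(n)
after a single O(n³) eigendecomposition per dataset. The restricted
log-likelihood uses the standard form
−½[(N−p)·log 2π + log|V| + log|X′V⁻¹X| + y′Py]. Fixed effects (intercept,
user covariates, optionally the top GRM principal components) get a separate
coefficient vector per trait and are concentrated out by GLS.

Σ_G and Σ_E are parameterized by lower-triangular factors (Σ = LL′), which
enforces positive semi-definiteness — hence h² ∈ [0,1] per trait and genetic
correlation in [−1,1] — and makes the two null subspaces of the mediation
test linear restrictions: zeroing the mediator row of the genetic factor
gives σ^G_MM = σ^G_MY = 0 (`Pa`), zeroing the off-diagonal environmental
loading gives σ^E_MY = 0 (`Pb`).

Optimization is L-BFGS-B on the factor parameters with fully analytic
gradients (the standard REML identity dl/dθ = −½[tr(P V̇) − y′P V̇ P y],
evaluated blockwise and chained to the factors), tolerances ftol 1e-13 /
gradient ∞-norm 1e-6, and three starts: a method-of-moments split of the
OLS-residual phenotypic covariance at h² = 0.5, the same at h² = 0.25, and a
seed-controlled random split. Constrained fits additionally warm-start from
the unconstrained optimum projected onto the constraint, which in practice
guarantees the nesting inequality that the LRT relies on. Non-convergence
is flagged on the estimate, never silently ignored; flagged Monte-Carlo
replicates are excluded from summaries with the count reported.

The sampling covariance of the six VCs is the inverse observed information,
with the information matrix obtained by central finite differences of the
analytic VC-space gradient (relative step 1e-5). Differentiating in VC space
directly (rather than factor space) is valid at an interior optimum because
the likelihood is a smooth function of Σ_G, Σ_E wherever the blocks
V_i stay positive definite — which admits slightly indefinite Σ_G, so the
finite-difference stencil is well-defined even when an estimate sits near
the PSD boundary (a one-sided fallback handles the exact boundary).

### Missing data

Per-trait missingness breaks the Kronecker structure that the canonical
transform needs. Two exact options exist and one approximation:

* complete two-trait data: canonical transform (the fast path);
* some individuals missing one trait, total observations ≤ `dense_max`
  (default 1000): the likelihood is evaluated on the explicit stacked
  covariance matrix over all observed entries — exact, O(N³) per evaluation;
* larger problems: complete-case analysis with a warning.

A hybrid ("dense for the missing subset only") would not be exact, because
the GRM couples missing-trait and complete individuals; we prefer an exact
answer at small scale and an honest complete-case fallback at large scale.
The dense likelihood doubles as the independent oracle that the
canonical-transform implementation is tested against (agreement to 1e-8 on
random instances).

## The likelihood-ratio test

The indirect effect (a²+g²)b² is zero iff a²+g² = 0 or b = 0, so the null
parameter space is the union Pa ∪ Pb. The test fits the model three times
(unconstrained, Pa, Pb), takes the null log-likelihood as the larger of the
two constrained optima, and sets the degrees of freedom adaptively: 2 if the
null optimum lies in Pa, 1 if in Pb. Numerical ties (within 1e-8) resolve
to Pb — deterministic, and anti-conservative by at most the tie tolerance;
ties occur only in degenerate fixtures. No chi-bar-square boundary mixture
is applied beyond this two-space construction. The statistic is clipped at
zero; a statistic below −1e-5 raises, since a nested model can only beat the
full one through optimizer failure.

Calibration, verified by simulation in the test suite: when the mediator is
heritable but has no effect (b = 0), p-values are uniform; when the mediator
has no genetic variance, the test is conservative (the null optimum then
sits on the Pa boundary and the chi-square(2) reference overshoots). The
Wald statistic (estimate/SE)² is reported only as a diagnostic.

## Power bound

The power to detect the indirect effect is bounded by the power to detect
the mediator's heritability. The implemented bound uses the standard GREML
sampling-variance approximation var(ĥ²) ≈ 2/(n²·var_π) with var_π the
variance of off-diagonal GRM entries (default 2e-5, typical for common-SNP
GRMs in conventionally unrelated samples), noncentrality h⁴/var(ĥ²), and a
central chi-square(1) critical value at two-sided α = 0.05. These defaults
reproduce the reference values for N = 10,000 (97.7% at h² = 12.5%, ~100% at
25%, 49.0% at 6.125%), which is itself a test.

## Synthetic data

`simulate_dataset` draws SNP-wise binomial(2, p) genotypes with
p ~ Uniform(0.05, 0.95) (independent SNPs, Hardy–Weinberg proportions), and
builds G and G* as independent polygenic scores with effects ~ N(0, 1/m) on
sample-standardized genotypes, so the cross-individual covariance of each
genetic factor equals the realized GRM — the fitted model is correctly
specified at the effect-distribution level. E and E* are iid standard
normal. The named verification scenarios fix f = e = 1, split a²+g² evenly
between a and g (only the cross term depends on the split; the convention is
exposed as an option), and set (a²+g², b, c²) to: Baseline (2, 1, 1),
(i) (0, 1, 1), (ii) (2, 0, 1), (iii) (0, 0, 1), (iv) (2, 1, 0).

What the generator does **not** emulate: linkage disequilibrium, MAF- or
annotation-dependent genetic architecture, population structure, assortative
mating, genetic nurture, and shared (correlated) environments. Passing
Monte-Carlo checks therefore demonstrate correctness of the estimator under
its own assumptions, not robustness to their violation; on real data the
burden of assumptions 1–4 above remains with the analyst.

Scenario fits use no relatedness pruning: at m = 2500 simulated SNPs the
off-diagonal GRM standard deviation is 1/√m = 0.02, so the 0.025 real-data
cutoff would discard ~10% of pairs of genuinely unrelated individuals.
Pruning (greedy maximum-degree removal until no pair exceeds the cutoff,
ties broken towards individuals with more missing phenotypes) is a QC step
of the real-data CLI pipeline.

## Problem sizes and numerical choices

* Acceptance runs (`scripts/acceptance.py`): 100 replicates per scenario at
  n = 2000, m = 2500 — the package's desk-scale verification design. At this
  size the full-mediation scenario shows a small positive finite-sample bias
  of the direct-effect estimate (~0.03), driven by GRM sampling noise at
  finite m; it shrinks as m grows.
* Test-suite Monte-Carlo studies run smaller (n = 500–1000, 30–100
  replicates) with tolerances of three Monte-Carlo standard errors of their
  own design.
* GRM: allele frequencies from the analysis sample unless supplied
  (missing dosages mean-imputed for the frequency only, excluded from pair
  sums); per-pair SNP counts as denominator by default, global m optional.
  Note per-pair division can make a GRM slightly non-PSD under missingness;
  with complete dosages the GRM is PSD by construction.
* GRM principal components: deterministic sign (largest-magnitude entry
  positive) for cross-platform reproducibility.
* All stochastic steps (simulation, multi-start) take explicit seeds;
  per-replicate seeds derive from the scenario seed via a seed sequence, so
  scenario tables are bit-reproducible.

## Known limitations

* Two traits, one GRM: no partitioned or multi-GRM heritability models, no
  LD-aware GRM weighting.
* Complete-case fallback for missing data beyond `dense_max` observations.
* The step-wise univariate-GREML comparison procedure is out of scope; a
  univariate fit is provided for heritability only.
* Delta-method SEs and the chi-square reference are asymptotic; at a few
  hundred individuals, interval coverage for the indirect effect is close to
  but slightly below nominal (verified ~92–95% in the suite).
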