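# Methods

## The model

`antscale` searches for a fixed-length short form of a Likert questionnaire
whose items follow a simple confirmatory factor structure: item *i* of factor
*f* has standardized loading λ_i on *f* and on no other factor, factors are
correlated (Φ), and residual variances are 1 − λ_i². Responses are ordered
categories 1..C generated, under the model, by discretizing a latent normal
variable at item-specific thresholds.

### Polychoric correlations

Ordinal items are correlated through the latent scale, so all model fitting
operates on the polychoric correlation matrix. Estimation is two-step:
thresholds are the inverse-normal transform of marginal cumulative
proportions; each pairwise ρ then maximizes the bivariate-normal contingency
likelihood with thresholds fixed (bounded scalar optimization, tolerance
1e-6, estimates clipped to ±0.999). Rectangle probabilities use a
single-integral identity for the bivariate normal CDF, evaluated by 48-node
Gauss–Legendre quadrature after the substitution r = sin t; against a
reference implementation the CDF is accurate to ~1e-15, far below the
optimizer tolerance. Infinite threshold sentinels (empty boundary
categories) are capped at ±8 before quadrature, where the normal tail mass
is below 1e-15. If the assembled matrix has an eigenvalue under 1e-8 it is
clipped there and rescaled to unit diagonal, and the smoothing is flagged.

### CFA, fit indices, reliability

The CFA minimizes the maximum-likelihood discrepancy
F = log|Σ| − log|S| + tr(SΣ⁻¹) − p with Σ = ΛΦΛ′ + diag(1 − λ²), by L-BFGS-B
with an analytic gradient, starts λ = 0.7 and Φ off-diagonals 0.5, and up to
three deterministically jittered restarts. Residual variances are floored at
1e-4 so Σ stays positive definite near the |λ| = 1 boundary. The test
statistic is T = (N−1)F; the baseline (independence) statistic is
(N−1)(−log|S|); df = p(p−1)/2 − p − q with q free factor correlations
(298/34/43 at p = 26/10/11, q = 1). CFI and RMSEA follow their standard
truncated definitions; a baseline that outfits the model yields CFI = 0.
McDonald's ω = (Σλ)²/((Σλ)² + Σ(1−λ²)) per factor.

This is deliberately ML-on-polychoric rather than a mean-and-variance
adjusted weighted-least-squares statistic: the adjustment needs the
asymptotic covariance of the polychoric estimates, and the package's
benchmarks (worked reliability arithmetic, df conventions, synthetic
parameter recovery, search optimality) do not depend on the scaling of T.
Reported fit indices on real ordinal data will therefore differ from WLSMV
software in the test statistic's scale, though loadings, Φ, and ω agree.

**Heywood cases.** Under this parameterization the ML minimizer is attracted
onto the admissibility boundary rather than past it, so a solution is flagged
inadmissible when any residual variance reaches its floor (equivalently
|λ| ≥ √(1 − 1e-4)). Flagged or non-converged candidates receive objective 0
— conservative, deterministic, and it removes any incentive for the search
to exploit degenerate fits.

## The objective

Four criteria become (0,1)-valued rewards through logistic transforms with
midpoints at CFI = 0.95, RMSEA = 0.05, ω = 0.90, sum-score correlation
= 0.85, and factor-correlation deviation = 0.03; the objective is
φ = (φ_CFI + φ_RMSEA)/2 + φ_Rel + φ_Corr + φ_Fc ∈ (0, 4). The decreasing
transforms are computed in their direct sigmoid form so they underflow to
tiny positive numbers, never to exactly 0. Aggregation across factors, where
a rule had to be chosen: reliability averages the per-factor sigmoids
(symmetric with the fit term's equal weighting); the full-scale agreement
criterion applies the sigmoid to the *minimum* per-factor correlation, so "at
least 0.85" binds for every subscale rather than on average; the
factor-correlation term uses the maximum absolute deviation over factor
pairs. A single-factor scale has no factor correlation; its deviation is
defined as 0. `total_pheromone` accepts one optional extra (0,1)-valued term
as a hook for study-specific criteria.

## The search

Per iteration, each of `n_ants` ants draws, within every factor
independently, the quota of items sequentially without replacement with
probability τ_i/Στ over the remaining pool. Identical subsets are evaluated
once (cache keyed by the sorted item tuple; the cache is shared across the
runs of one invocation, which is pure memoization because evaluations are
deterministic given the data). After each iteration τ decays
multiplicatively by the evaporation rate, the iteration-best candidate
deposits its φ onto its members, and τ is floored at 1e-6. The run stops when
the best-so-far has not strictly improved for `patience` consecutive
iterations (patience 0 therefore stops after the first iteration) or at
`max_iterations`. Ties everywhere break toward the lexicographically
smallest sorted item tuple, and run r of a multi-run invocation uses seed
`base_seed + r`, so every result is reproducible.

**Initial pheromone.** Levels start equal — the first iteration samples
uniformly — at the steady-state deposit ceiling 4/(1 − evaporation) (the
bound of φ divided by the net retention), the max–min initialization of the
ACO literature. Starting far lower lets the very first deposit dominate the
sampling distribution and collapses exploration after one or two iterations,
which measurably degrades how often the search finds the true optimum on
enumerable pools.

**Defaults.** 60 ants, up to 50 iterations, evaporation 0.5, patience 15,
5 runs. These sit where, on two-factor pools of the motivating size, more
ants or iterations no longer change the best solution found but only shrink
run-to-run variance; evaporation near 0.5 keeps selections homogeneous
across runs without the longer convergence of slower evaporation.

**Aggregation.** ACO-P is the best subset across runs; ACO-C keeps every
item selected in ≥ 60 % of the per-run best subsets (per-run bests only, not
all ants). ACO-C may violate the per-factor quotas — it is a union rule and
is reported with its selection frequencies, not re-balanced.

## Synthetic data

The generator draws factor scores from N(0, Φ), builds latent item scores
λf + √(1−λ²)ε, and discretizes at per-item thresholds; draws happen factor
scores first, then item noise in item-id order, so a seed pins the dataset.
Default thresholds are equal-probability quintile cuts (balanced categories),
chosen for clean parameter-recovery tests; a right-shifted preset emulates
the skew typical of real importance ratings. `paper_like_spec` reproduces
the published ADBS validation structure (26 items, 13 pros/13 cons, loadings
0.25–0.94, Φ₁₂ = 0.56); `planted_optimum_spec` builds enumerable pools whose
best subset is known by construction.

What the synthetic benchmarks show: the estimator recovers generating
loadings (RMSE ≤ 0.05 at N = 2000) and the factor correlation (±0.05), and
the colony almost always (≥ 90 % of seeded runs on 400-candidate pools)
finds the same optimum as brute-force enumeration under the identical
evaluation pipeline. What they do not show: behavior under response styles,
skewed thresholds matching any particular population, missingness, or
violations of the bivariate-normality assumption behind polychoric
correlations. The respondent-level data of the motivating study are not
public, so its fit indices are not reproduction targets; the published
loading tables, reliability arithmetic, and df conventions are.

## Problem sizes and numerical choices

The enumerable oracle benchmark uses a 6+6 pool choosing 3+3 (400
candidates) at N = 500; recovery benchmarks use N = 2000 with 10 seeds —
sizes at which the Monte-Carlo error of each check is comfortably below its
acceptance band. Polychoric pair tolerance 1e-6; CFA convergence by L-BFGS-B
success with ftol 1e-12; listwise deletion for incomplete rows (mirroring
complete-case analysis; no imputation); categories must be consecutive
integers from 1. Item ids are opaque strings ordered lexicographically for
every tie-break.

## Known limitations

- The test statistic is unscaled ML-on-polychoric; absolute CFI/RMSEA values
  on real ordinal data are not comparable to WLSMV output.
- The deposit rule (iteration-best, decay-then-deposit) is one member of the
  ACO family; the method's originators do not pin this choice and other
  deposit schedules may explore differently.
- The asymptotic covariance of polychoric estimates is not computed, so no
  standard errors or robust corrections are available.
- Consensus selection frequencies are computed over per-run bests; with few
  runs the 60 % threshold is coarse (3 of 5).
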