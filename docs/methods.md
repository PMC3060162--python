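# Methods

## The cycle map

The package's central object is the expectation update of a
grow-and-disperse patch model.  One cycle consists of Poisson seeding of
infinitely many identical patches from a common pool (per-patch means
`α n_k`), deterministic within-patch competitive growth until the shared
resource `R` is exhausted, and complete pooling.  Because the patch
number is taken to infinity, the update is the exact expectation

    n_k(t+1) = Σ_m P(m) f_k(m),   P(m) = Π_k Pois(m_k; α n_k),

with no demographic stochasticity: the only randomness in a noisy run is
the per-cycle dilution draw.  The growth time of a seeding solves
`Σ_k m_k (e^{μ_k T} − 1)/Y_k = R`; its left side is strictly increasing
and convex in `T`, so the root is unique and a vectorized Newton
iteration started from the bracket `min_k ln(1 + R Y_k/m_k)/μ_k` (the
first species that could exhaust the patch alone) converges monotonically
from above.  Absolute residual tolerance: 1e−12.  Two exact identities
serve as permanent self-checks: resource conservation
`Σ_k (f_k − m_k)/Y_k = R` for every solved seeding, and the equivalence
of rescaling `R` with rescaling all `Y_k`.

## Truncating the seeding sum

The infinite sum over seedings is truncated by total seed count: the
total of independent Poissons is Poisson with rate `λ = α Σ_k n_k`, so
the smallest `M` with upper-tail mass below `tail_epsilon` (default 1e−7)
certifies the neglected probability.  By default `M` is re-derived from
the current state every cycle, because noisy trajectories wander over
orders of magnitude in total abundance and a truncation anchored at the
fixpoint would silently shed mass during excursions; a static,
fixpoint-anchored mode is provided for comparison and *raises* when its
bound is violated rather than losing mass.  Enumeration is lexicographic
over compositions of each total (`C(N+M, M)` configurations in all);
per-configuration weights are computed in log space.  Growth outcomes
`f(m)` depend only on `m` and the community — never on `n` or `α` — so
they are tabulated once per total and reused across an entire trajectory;
this memoization is what makes 1e5-cycle runs routine.

When a large excursion would push the enumeration past a configurable
ceiling (default 2e5 configurations), the step falls back to plain
Monte-Carlo estimation of the expectation: `mc_samples` (default 8192)
seedings drawn from the exact Poisson product, growth solved in one
vectorized batch, outcomes averaged.  Fallback cycles are counted in the
trace metadata.  The ceiling trades bias-free enumeration against memory
and per-cycle cost: at 15 species the cached tables for `M = 8` already
hold ~5×10⁵ configurations.

## Building coexisting communities

Communities are constructed backwards: prescribe growth rates `μ`
(geometric grids on [0.1, 0.3] — uniform in the phenotype coordinate
`z = log μ` — for the canonical 6-, 10- and 15-species systems), a
dilution `α₀`, and a target equal-abundance fixpoint `n* = n₀·1`
(totalling 100 per patch), then solve for the efficiency vector `Y`.
The solver is a damped Newton iteration on `G(Y) = step(n*; Y) − n*`
whose Jacobian in `Y` is computed analytically by implicit
differentiation of the growth-time equation
(`∂T/∂Y_j = (f_j − m_j)/Y_j² / Σ_i μ_i f_i / Y_i` per seeding), and whose
initial iterate inverts the complete-dominance hierarchy — the
large-resource limit in which only the fastest species present on a patch
reaps it, making the fixpoint equations triangular.  Convergence demands
`max_k |G_k| / n*_k < 1e−9`; non-convergence raises rather than returning
a partial result.  The solve runs first under a coarse truncation
(1e−7) and is then polished under a deep one (default 1e−13).  The deep
polish matters: the slowest eigenvalue gaps probed downstream are
~3×10⁻⁸, smaller than the coarse tail itself, and the eigenstructure is
only trustworthy when the fixpoint and the Jacobian are computed under
the same, sufficiently deep truncation (the computed slowest relaxation
time is stable to <0.5% across tails 1e−9 … 1e−15).

The complete-dominance fixpoint itself is exposed as an operation: solved
top-down, each level is a scalar root `n_k = sY_k(1 − e^{−αn_k})·e^{−αΣ_{j>k}n_j}`
(bracketed `brentq`), with a positive root existing iff the effective
seeding gain exceeds 1; levels without one are flagged as excluded.  Its
agreement with the full model improves as the resource scale `s` grows
with `α·s` held fixed, the regime in which the non-dominant growth
corrections decay like `s^{μ/μ′−1}`.

## Linear theory

`J` and `r` are computed analytically from the Poisson-product
derivatives (`∂P/∂n_l = P(m_l/n_l − α)`, `∂P/∂α = P(Σ m_j/α − Σ n_j)`)
over the certified enumeration, and cross-checked against central finite
differences of the full update (agreement < 1e−5 relative).  Eigenmodes
are sorted by descending eigenvalue, unit-normalized, and sign-fixed
(largest-magnitude component positive).  Derived per-mode quantities:
relaxation time `τ = −1/ln λ`, stationary amplitude
`⟨q²⟩ = p²σ_α²/(1 − λ²)`, and noise coupling `γ = ⟨q²⟩/τ`.  Because all
modes are driven by the one shared dilution draw, their amplitudes are
cross-correlated, `⟨q_k q_l⟩ = p_k p_l σ_α²/(1 − λ_k λ_l)`; the
stationary abundance covariance is therefore `S C_q Sᵀ` with the full
`C_q`, not its diagonal — simulations at cv = 0.01 confirm the
per-species variances to ~1%.

Two dilution sensitivities must not be confused.  The *one-step* response
`r_k = ∂n_k(t+1)/∂α` is large and nearly uniform across species (~6×10³
for the 15-species system, max/min ≈ 1.08) — the shared drive behind
Moran synchrony.  The *steady-state press* response `(I − J)⁻¹ r` is
dominated by the near-marginal jagged modes (gaps `1 − λ` down to
~3×10⁻⁸) and is orders of magnitude larger with alternating signs; both
are exposed (`dilution_response`, `alpha_sensitivity`), and the latter is
validated against re-solved fixpoints at `α₀ ± δ`.

Mode profiles are reported raw and interaction-weighted: component `j`
multiplied by `mean_{l≠j} |ΔJ_jl|` (`ΔJ = J − I`), which undoes the
systematic attenuation of strong competitors' components.  The exact
weight is a modelling choice — "the average interaction strength of the
species" admits several readings — and only qualitative conclusions rest
on it.  Roughness is scored as the number of sign alternations of the
weighted profile along the μ-sorted axis, tie-broken by total variation;
the score is invariant to overall sign flips.  For the canonical
communities the roughness order exactly reverses the eigenvalue order
(smoothest = fastest); `τ` rises monotonically along it, `γ` falls by
six orders of magnitude apart from one inversion at the smooth end (in
the 15-species system the shared-noise input projects slightly more
strongly onto the second-smoothest mode than onto the smoothest, under
any eigenvector normalization), and the amplitude `γτ` peaks at interior
roughness — the clustering signature.

## Noise and simulation

Dilution noise is white log-normal with `θ = log α₀` held fixed as the
width `ω = sqrt(log(1 + cv²))` varies, so the long-term dilution rate
(set by E[log α]) is noise-level independent; `α₀` is the distribution's
median, and `σ_α = α₀ cv √(1+cv²)`.  Trajectories iterate the expectation
update with per-cycle draws from a seeded generator; the Monte-Carlo
fallback, if engaged, uses a separate stream (seed + 1) so the α series
is bit-identical across clamp configurations.  Clamped counterfactuals
overwrite the chosen species with `n*` *after* each update: clamped
species keep exerting competitive pressure at fixed density while only
free species fluctuate.  (Re-imposing the clamp before growth instead
would be a different, also defensible convention; it is a one-line
switch.)  Deterministic pulse/press experiments perturb `α`
multiplicatively or a single species' abundance by a fraction of `n*_k`.

## Statistics

Pairwise correlations versus phenotypic distance `|z_k − z_l|` are
computed per clamp regime: within-trace pairs (full model), across
single-free-species traces (pure Moran), within two-free-species traces
(pairwise compensation), always under one shared α series.  Correlations
are Pearson on log abundances by default — trajectories span orders of
magnitude and raw-scale correlations are dominated by rare excursions —
with the raw scale available.  On the geometric μ grids pair distances
are integer multiples of the grid step, so the binned curve is an exact
per-distance mean, not a smoothing.  The first 1e3 cycles (500 in the
shorter pair runs) are discarded as burn-in.  Empirical mode amplitudes
project deviations onto the eigenbasis, `q(t) = S⁻¹(n(t) − n*)`, and
time-average `q_k²`; a validity flag marks modes whose `τ` does not fit
several times into the averaged window (relative deviations `(n−n*)/n*`
are an alternative normalization, also offered).

## Problem sizes and numerical defaults

The validation suite runs the canonical 15-species community end to end,
with the correlation-regime comparison at 6000 cycles (full and
single-species runs) and 4000 cycles for all 105 pair runs, burn-in
1000/500 — enough for the qualitative sign structure (alternating ≥ 2
times / uniformly > 0.9 / one crossing) while keeping the whole suite in
minutes.  The 6-species spectrum comparison uses the full 1e5 cycles at
cv = 0.045; with its longest `τ ≈ 3×10³` every mode equilibrates, and
empirical amplitudes match predictions within a few standard errors of a
mean-square over correlated samples (`SE_rel ≈ sqrt(2(2τ+1)/T)`).

## What the generator does and does not emulate

Synthetic inputs are the model's own study conditions: parameter-defined
communities, log-normal white dilution noise, expectation dynamics.  They
do not include demographic noise (finite patch numbers or individuals),
colored environmental noise, per-patch resource variation, or spatial
structure beyond patchiness — so passing tests validate the model's
internal consistency and its linear theory, not the fidelity of any real
ecosystem's time series.

## Known limitations

- The near-marginal 15-species eigenvalues (`1 − λ ~ 3×10⁻⁸`) sit far
  below any practical truncation certificate; their relaxation *times*
  are reproducible under self-consistent deep truncation but should be
  read as order-of-magnitude quantities.
- The Monte-Carlo fallback injects O(1/√K) estimator noise into cycles
  past the enumeration ceiling; long high-noise runs where excursions are
  frequent therefore carry a small pseudo-demographic component.
- Correlation curves at scaled-down cycle counts retain the sign
  structure but not converged magnitudes; slow modes make all such
  statistics run-length dependent (the comparison across regimes at fixed
  run length is the meaningful contrast).
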