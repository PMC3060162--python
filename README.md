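# patchcomm

Community dynamics of many species competing for a single resource in a
patchy, periodically disturbed environment — and the counter-intuitive
ordering effect of environmental noise on such communities.

## The model

An ecosystem of `N` species lives on many identical patches, each holding
an amount `R` of one resource (think soil pockets repeatedly washed and
re-seeded by rain).  Dynamics proceed in cycles:

1. **Seeding.** A fraction `α` of the pooled population lands on fresh
   patches.  With per-patch abundances `n = (n_1 … n_N)`, a patch receives
   `m_k` individuals of species `k` with independent Poisson probabilities,
   `P(m) = Π_k Pois(m_k; α n_k)`.
2. **Growth.** Each individual of species `k` reproduces exponentially at
   rate `μ_k` while consuming `1/Y_k` resource per offspring.  Growth stops
   when the patch is exhausted, at the time `T(m)` solving
   `Σ_k m_k (e^{μ_k T} − 1)/Y_k = R`, leaving `f_k(m) = m_k e^{μ_k T}`.
3. **Dispersal.** All patches pool again:
   `n_k(t+1) = Σ_m P(m) f_k(m)`.

Each species is thus entirely characterized by a speed/efficiency
phenotype `(μ_k, Y_k)`.  With an appropriate trade-off (fast growers less
efficient), arbitrarily many species coexist at a stable fixpoint `n*`:
crowded cycles select for speed, sparse cycles for yield, a
frequency-dependent balance.

Environmental noise enters as a log-normal dilution factor: each cycle
`α` is drawn with `log α ~ N(θ, ω²)`, `θ = log α₀` so that the long-term
dilution rate is noise-level independent.  Linearizing the cycle map at
the fixpoint,

    Δn(t+1) = J Δn(t) + r Δα(t),

and diagonalizing `J = S Λ S⁻¹` splits the community response into `N`
AR(1) eigenmodes with relaxation times `τ_k = −1/ln λ_k`, noise couplings
`γ_k`, and stationary amplitudes `⟨q_k²⟩ = p_k² σ_α²/(1 − λ_k²) = γ_k τ_k`
(`p = S⁻¹ r`).  Smooth modes (same-sign deformations of the abundance
profile) are strongly noise-driven but relax fast; jagged modes
(alternating-sign) are weakly driven but extraordinarily long-lived.  The
stationary amplitude therefore peaks at *intermediate* roughness, which
shows up in simulations as dynamic clusters of abundant species along the
phenotype axis `z = log μ` and as alternating positive/negative pairwise
correlations versus phenotypic distance.

## Worked example

```python
import numpy as np
from patchcomm import (
    geometric_mu_grid, solve_efficiencies, linear_model, NoiseModel,
)

# 6 species, growth rates geometric on [0.1, 0.3], equal fixpoint
# abundances 100/6 per patch, dilution 0.001
fp = solve_efficiencies(100 / 6, geometric_mu_grid(6), alpha0=0.001)
print(np.round(fp.Y, 1))
# [1088.6 1074.4 1058.3 1041.9 1026.3 1013.1]   <- efficiency falls as rate rises

lm = linear_model(fp, sigma_alpha=NoiseModel(0.001, cv=0.045).sigma_alpha)
print(np.round(lm.tau, 1))
# [2960.1 1221.7  551.4  195.8   91.6   32.1]   <- mode relaxation times (cycles)
```

The solved efficiencies decrease monotonically with growth rate — the
trade-off that lets all six species coexist at equal abundances.  The
slowest eigenmode of the linearized dynamics relaxes over ~3.0×10³
cycles; a 10⁵-cycle noisy simulation (see `patchcomm spectrum paper6`)
reproduces every mode's stationary amplitude within sampling error.

The command line mirrors the library:

```bash
patchcomm fixpoint paper15            # solve the 15-species community
patchcomm linearize paper15           # eigenmode table (lambda, tau, gamma, amp2)
patchcomm simulate paper15 --cycles 10000 --cv 0.15
patchcomm correlate paper15 --regime pair
patchcomm reproduce-fig 4B --out out/
```

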