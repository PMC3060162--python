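"""Within-patch competitive growth.

All individuals seeded on a patch grow exponentially at their own rate
``mu_k`` while drawing on the shared resource at ``1/Y_k`` units per
offspring.  Growth stops everywhere on the patch the moment the resource is
exhausted.  The stopping time ``T`` for a seeding ``m`` therefore solves

    sum_k m_k * (exp(mu_k * T) - 1) / Y_k = R,

whose left side is strictly increasing in ``T``, so the positive root is
unique.  The final per-patch abundances follow directly:

    f_k(m) = m_k * exp(mu_k * T).

A convenient identity: summing ``(f_k - m_k) / Y_k`` over species recovers
``R`` exactly (resource conservation), which is used as the solver's
correctness certificate throughout the test-suite.

The batch solver below is the computational workhorse of the whole package:
the expectation dynamics evaluate ``f`` on tens of thousands of seeding
configurations per update, so roots are found with a vectorized Newton
iteration started from a guaranteed upper bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community

__all__ = [
    "SeedingConfig",
    "GrowthOutcome",
    "solve_growth_time",
    "final_abundances",
    "growth_times_batch",
    "final_abundances_batch",
]

# exp() argument cap; exp(700) is near the float64 ceiling
_EXP_CAP = 700.0


@dataclass(frozen=True)
class SeedingConfig:
    """An integer seeding vector m (individuals of each species on a patch)."""

    m: np.ndarray
    prob: float | None = None  # set by the expectation layer

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.m))
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            if not np.all(np.equal(np.mod(m, 1), 0)) or np.any(m < 0):
                raise ValueError("seed counts must be non-negative integers")
            m = m.astype(np.int64)
        object.__setattr__(self, "m", m)

    @property
    def total(self) -> int:
        return int(self.m.sum())


@dataclass(frozen=True)
class GrowthOutcome:
    """Growth time and final abundances for one seeding configuration."""

    T: float
    f: np.ndarray


def _as_m_array(m) -> np.ndarray:
    if isinstance(m, SeedingConfig):
        return np.asarray(m.m, dtype=float)
    return np.atleast_1d(np.asarray(m, dtype=float))


def growth_times_batch(
    m: np.ndarray,
    community: Community,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Growth times for a (C, N) batch of seeding vectors.

    Rows with no individuals get ``T = 0``.  The residual

        g(T) = sum_k m_k (exp(mu_k T) - 1)/Y_k - R

    is increasing and convex, so Newton started from an upper bracket
    converges monotonically from above.  At the root every species'
    consumption term is at most R, so ``T_hi = min_k log(1 + R Y_k/m_k)/mu_k``
    over the species present (the first species that could exhaust the
    resource alone) brackets the root tightly and keeps every exponent
    moderate.  ``tol`` is the absolute residual tolerance.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    mu, Y, R = community.mu, community.Y, community.R
    C = m.shape[0]
    T = np.zeros(C)
    active = m.sum(axis=1) > 0
    if not np.any(active):
        return T

    ma = m[active]
    # tight upper bracket: fastest lone consumer of the full resource
    with np.errstate(divide="ignore"):
        solo = np.log1p(R * Y / np.where(ma > 0, ma, np.inf)) / mu
    Thi = np.where(ma > 0, solo, np.inf).min(axis=1)

    t = Thi.copy()
    for _ in range(max_iter):
        E = np.exp(np.minimum(mu * t[:, None], _EXP_CAP))
        g = (ma * (E - 1.0) / Y).sum(axis=1) - R
        if np.all(np.abs(g) <= tol):
            break
        gp = (ma * mu * E / Y).sum(axis=1)
        step = g / gp
        t = np.maximum(t - step, 0.0)
    T[active] = t
    return T


def final_abundances_batch(m: np.ndarray, community: Community, tol: float = 1e-12) -> np.ndarray:
    """Final abundances ``f_k = m_k exp(mu_k T)`` for a (C, N) batch."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    T = growth_times_batch(m, community, tol=tol)
    return m * np.exp(np.minimum(community.mu * T[:, None], _EXP_CAP))


def solve_growth_time(m, community: Community, tol: float = 1e-12) -> float:
    """Growth time for a single seeding configuration.

    Raises for an all-zero seeding: with nobody on the patch the resource is
    never consumed and no growth time is defined (the expectation layer
    handles empty seedings separately, with ``f = 0``).
    """
    ma = _as_m_array(m)
    if ma.shape[0] != community.N:
        raise ValueError("seeding length does not match community size")
    if ma.sum() <= 0:
        raise ValueError("growth time is undefined for an empty seeding")
    return float(growth_times_batch(ma[None, :], community, tol=tol)[0])


def final_abundances(m, community: Community, tol: float = 1e-12) -> GrowthOutcome:
    """Final per-patch abundances for one seeding (empty seeding allowed)."""
    ma = _as_m_array(m)
    if ma.shape[0] != community.N:
        raise ValueError("seeding length does not match community size")
    if ma.sum() <= 0:
        return GrowthOutcome(T=0.0, f=np.zeros(community.N))
    T = float(growth_times_batch(ma[None, :], community, tol=tol)[0])
    f = ma * np.exp(np.minimum(community.mu * T, _EXP_CAP))
    return GrowthOutcome(T=T, f=f)
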