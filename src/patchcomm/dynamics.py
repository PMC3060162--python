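"""Exact expectation dynamics of the dispersal-growth cycle.

Each cycle a fraction ``alpha`` of the pooled population seeds fresh
patches.  In the many-patch limit the seeding of one patch is a product of
independent Poissons,

    P(m) = prod_k Poisson(m_k; alpha * n_k),

and the next per-patch abundance vector is the expectation of the final
abundances over all seedings:

    n_k(t+1) = sum_m P(m) * f_k(m).

The infinite sum is truncated at a total seed count ``M`` chosen so that the
neglected probability mass — the upper tail of a Poisson with rate
``alpha * sum(n)`` (the total of independent Poissons is Poisson) — is below
``tail_epsilon``.  By default ``M`` is re-derived from the current state
every cycle ("adaptive"); a static mode with a fixed ``M`` is available for
comparison but raises if its tail bound is violated mid-run.

When the enumeration would exceed ``config_ceiling`` configurations
(stars-and-bars: C(N+M, M) of them), the update falls back to plain
Monte-Carlo estimation of the expectation with ``mc_samples`` seedings drawn
from the exact Poisson product; the fallback is flagged in the step info so
long noisy runs record which cycles are stochastic estimates.

Growth outcomes ``f(m)`` depend only on ``m`` and the community — never on
``n`` or ``alpha`` — so they are tabulated once per total seed count and
reused across every cycle (the memoization that makes 1e5-cycle runs cheap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .community import Community
from .growth import final_abundances_batch

__all__ = [
    "TruncationPolicy",
    "StaleTruncationError",
    "StepInfo",
    "StepKernel",
    "compositions",
    "n_configurations",
    "required_total",
    "seeding_probability",
    "derive_truncation",
    "step_map",
]


class StaleTruncationError(RuntimeError):
    """A static truncation no longer satisfies its tail bound."""


@dataclass(frozen=True)
class TruncationPolicy:
    """How to certify and bound the finite seeding sum.

    tail_epsilon
        Maximum total probability mass the truncation may neglect.
    max_total
        Static cap ``M`` on the total seed count; ``None`` derives ``M``
        from the current state (adaptive mode).
    adaptive
        Re-derive ``M`` each step.  When False, ``max_total`` must be set
        and a violated tail bound is an error, not a silent loss of mass.
    config_ceiling
        Enumerated-configuration budget per step before the Monte-Carlo
        fallback engages.
    mc_samples
        Seedings drawn per step in the fallback.
    """

    tail_epsilon: float = 1e-7
    max_total: int | None = None
    adaptive: bool = True
    config_ceiling: int = 200_000
    mc_samples: int = 8192

    def __post_init__(self) -> None:
        if not (0.0 < self.tail_epsilon < 1.0):
            raise ValueError("tail_epsilon must be in (0, 1)")
        if not self.adaptive and self.max_total is None:
            raise ValueError("static mode requires max_total")


@dataclass(frozen=True)
class StepInfo:
    """Diagnostics for one expectation update."""

    M: int
    n_configs: int
    mass: float  # enumerated probability mass (1.0 reported for MC steps)
    monte_carlo: bool
    samples: int = 0


@lru_cache(maxsize=4096)
def compositions(n_parts: int, total: int) -> np.ndarray:
    """All length-``n_parts`` non-negative integer vectors summing to ``total``.

    Lexicographically ordered (ascending in the first coordinate, then
    recursively), C(n_parts + total - 1, total) rows.  Cached and returned
    read-only.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    if n_parts == 1:
        out = np.array([[total]], dtype=np.int64)
    else:
        blocks = []
        for first in range(total + 1):
            rest = compositions(n_parts - 1, total - first)
            blk = np.empty((rest.shape[0], n_parts), dtype=np.int64)
            blk[:, 0] = first
            blk[:, 1:] = rest
            blocks.append(blk)
        out = np.vstack(blocks)
    out.flags.writeable = False
    return out


def n_configurations(n_species: int, max_total: int) -> int:
    """Number of seedings of ``n_species`` with total <= ``max_total``.

    Stars and bars summed over totals: sum_t C(N-1+t, t) = C(N+M, M).
    """
    return math.comb(n_species + max_total, max_total)


def required_total(lam: float, tail_epsilon: float) -> int:
    """Smallest M with P(Poisson(lam) > M) < tail_epsilon."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return 0
    M = max(int(lam), 0)
    while stats.poisson.sf(M, lam) >= tail_epsilon:
        M += 1
    # sf is monotone; walk back in case the start overshot
    while M > 0 and stats.poisson.sf(M - 1, lam) < tail_epsilon:
        M -= 1
    return M


def seeding_probability(m, n: np.ndarray, alpha: float) -> float:
    """Probability of the seeding ``m`` given pool abundances ``n``.

    The product of per-species Poisson pmfs with means ``alpha * n_k``.
    """
    m = np.atleast_1d(np.asarray(getattr(m, "m", m)))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(n < 0) or not np.all(np.isfinite(n)):
        raise ValueError("abundances must be finite and non-negative")
    return float(np.prod(stats.poisson.pmf(m, alpha * n)))


def derive_truncation(
    n: np.ndarray, alpha: float, tail_epsilon: float = 1e-7, **kwargs
) -> TruncationPolicy:
    """Static truncation policy certified for the given state."""
    lam = float(alpha * np.sum(n))
    M = required_total(lam, tail_epsilon)
    return TruncationPolicy(
        tail_epsilon=tail_epsilon, max_total=M, adaptive=False, **kwargs
    )


class StepKernel:
    """Expectation-update engine for one community.

    Holds the growth-outcome tables f(m), built lazily per total seed
    count, plus the analytic derivatives of the update used by the
    linearization and the efficiency solver.  The tables depend only on the
    community, so one kernel serves an entire trajectory.
    """

    def __init__(self, community: Community, policy: TruncationPolicy | None = None):
        self.community = community
        self.policy = policy if policy is not None else TruncationPolicy()
        self._tables: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._stacked: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # ---------------------------------------------------------------- tables
    def table(self, total: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(m-configs, log m!, f) arrays for one total seed count."""
        tab = self._tables.get(total)
        if tab is None:
            A = compositions(self.community.N, total)
            logfact = gammaln(A + 1.0).sum(axis=1)
            F = final_abundances_batch(A.astype(float), self.community)
            tab = (A, logfact, F)
            self._tables[total] = tab
        return tab

    def _stacked_table(self, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All totals 0..M concatenated — one matmul per step in hot loops."""
        tab = self._stacked.get(M)
        if tab is None:
            parts = [self.table(t) for t in range(M + 1)]
            A = np.vstack([p[0] for p in parts]).astype(float)
            logfact = np.concatenate([p[1] for p in parts])
            F = np.vstack([p[2] for p in parts])
            tab = (A, logfact, F)
            self._stacked[M] = tab
        return tab

    def _derive_M(self, lam_tot: float) -> int:
        pol = self.policy
        if pol.adaptive:
            return required_total(lam_tot, pol.tail_epsilon)
        M = int(pol.max_total)
        if stats.poisson.sf(M, lam_tot) >= pol.tail_epsilon:
            raise StaleTruncationError(
                f"static truncation M={M} neglects >= {pol.tail_epsilon} "
                f"probability at total seeding rate {lam_tot:.4g}"
            )
        return M

    def _weights(self, total: int, lam: np.ndarray, lam_tot: float) -> np.ndarray:
        """Poisson-product probabilities for every config of one total."""
        A, logfact, _ = self.table(total)
        zero = lam <= 0.0
        loglam = np.where(zero, 0.0, np.log(np.where(zero, 1.0, lam)))
        logw = A @ loglam - lam_tot - logfact
        if np.any(zero):
            impossible = (A[:, zero] > 0).any(axis=1)
            logw = np.where(impossible, -np.inf, logw)
        return np.exp(logw)

    # ----------------------------------------------------------------- step
    def step(
        self,
        n: np.ndarray,
        alpha: float,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, StepInfo]:
        """One expectation update n -> n'.

        Enumerates all seedings up to the certified total, or falls back to
        Monte Carlo past the configuration ceiling (requires ``rng``).
        """
        n = np.atleast_1d(np.asarray(n, dtype=float))
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if np.any(n < 0) or not np.all(np.isfinite(n)):
            raise ValueError("abundances must be finite and non-negative")
        lam = alpha * n
        lam_tot = float(lam.sum())
        if lam_tot == 0.0:
            return np.zeros_like(n), StepInfo(0, 1, 1.0, False)
        M = self._derive_M(lam_tot)
        n_cfg = n_configurations(self.community.N, M)
        if n_cfg > self.policy.config_ceiling:
            if rng is None:
                raise RuntimeError(
                    f"{n_cfg} configurations exceed the ceiling "
                    f"{self.policy.config_ceiling}; pass an rng to enable "
                    "the Monte-Carlo fallback"
                )
            K = self.policy.mc_samples
            samples = rng.poisson(lam, size=(K, n.size)).astype(float)
            F = final_abundances_batch(samples, self.community)
            return F.mean(axis=0), StepInfo(M, n_cfg, 1.0, True, samples=K)

        A, logfact, F = self._stacked_table(M)
        zero = lam <= 0.0
        loglam = np.where(zero, 0.0, np.log(np.where(zero, 1.0, lam)))
        logw = A @ loglam - lam_tot - logfact
        if np.any(zero):
            logw = np.where((A[:, zero] > 0).any(axis=1), -np.inf, logw)
        w = np.exp(logw)
        return w @ F, StepInfo(M, n_cfg, float(w.sum()), False)

    # ------------------------------------------------------- derivatives
    def jacobian(self, n: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Analytic (J, r): derivatives of the update wrt n and wrt alpha.

        Differentiating the Poisson product (f(m) carries no n- or
        alpha-dependence):

            dP/dn_l    = P * (m_l / n_l - alpha)
            dP/dalpha  = P * (sum_j m_j / alpha - sum_j n_j)

        so J_kl = sum_m P (m_l/n_l - alpha) f_k and
        r_k = sum_m P (total/alpha - sum n) f_k, summed over the certified
        enumeration.  Species with n_l = 0 use the one-sided limit
        d/dn_l at 0+ (only m_l = 0 configs contribute, factor -alpha).
        """
        n = np.atleast_1d(np.asarray(n, dtype=float))
        lam = alpha * n
        lam_tot = float(lam.sum())
        n_tot = float(n.sum())
        N = self.community.N
        M = self._derive_M(lam_tot) if lam_tot > 0 else 0
        if n_configurations(N, M) > self.policy.config_ceiling:
            raise RuntimeError(
                "jacobian requires full enumeration; raise config_ceiling "
                "or loosen tail_epsilon"
            )
        J = np.zeros((N, N))
        r = np.zeros(N)
        safe_n = np.where(n > 0, n, 1.0)
        for total in range(M + 1):
            A, _, F = self.table(total)
            w = self._weights(total, lam, lam_tot)
            G = A / safe_n - alpha  # (C, N) d log P / d n_l
            J += F.T @ (w[:, None] * G)
            r += F.T @ (w * (total / alpha - n_tot))
        return J, r

    def efficiency_jacobian(self, n: np.ndarray, alpha: float) -> np.ndarray:
        """Analytic derivative of the update wrt the efficiency vector Y.

        Implicit differentiation of the growth-time equation gives, per
        seeding m,

            dT/dY_j   = (f_j - m_j) / Y_j^2 / sum_i mu_i f_i / Y_i
            df_k/dY_j = mu_k f_k * dT/dY_j,

        accumulated with the Poisson weights.  Used as the Newton Jacobian
        when solving efficiencies for a prescribed fixpoint.
        """
        n = np.atleast_1d(np.asarray(n, dtype=float))
        mu, Y = self.community.mu, self.community.Y
        lam = alpha * n
        lam_tot = float(lam.sum())
        N = self.community.N
        M = self._derive_M(lam_tot) if lam_tot > 0 else 0
        JY = np.zeros((N, N))
        for total in range(1, M + 1):
            A, _, F = self.table(total)
            w = self._weights(total, lam, lam_tot)
            denom = (mu * F / Y).sum(axis=1)  # > 0 for total >= 1
            D = (F - A) / Y**2 / denom[:, None]  # (C, N) dT/dY_j
            JY += (w[:, None] * (mu * F)).T @ D
        return JY

    # ------------------------------------------------------------- export
    def table_frame(self, n: np.ndarray, alpha: float) -> pd.DataFrame:
        """Enumerated step table (m, probability, f) as a DataFrame."""
        n = np.atleast_1d(np.asarray(n, dtype=float))
        lam = alpha * n
        lam_tot = float(lam.sum())
        M = self._derive_M(lam_tot) if lam_tot > 0 else 0
        rows = []
        for total in range(M + 1):
            A, _, F = self.table(total)
            w = self._weights(total, lam, lam_tot)
            block = pd.DataFrame(
                {
                    **{f"m{k+1}": A[:, k] for k in range(self.community.N)},
                    "prob": w,
                    **{f"f{k+1}": F[:, k] for k in range(self.community.N)},
                }
            )
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


def step_map(
    n: np.ndarray,
    alpha: float,
    community: Community,
    policy: TruncationPolicy | None = None,
    kernel: StepKernel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Functional one-shot expectation update (see ``StepKernel.step``)."""
    if kernel is None:
        kernel = StepKernel(community, policy)
    out, _ = kernel.step(n, alpha, rng=rng)
    return out
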