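"""Constructing coexisting communities.

Competition for a single resource ordinarily ends in exclusion, but the
division into patches rescues coexistence when growth rate trades off
against efficiency: crowded cycles favour fast growers, sparse cycles
favour efficient ones, producing frequency-dependent selection that can
balance many species.  This module solves the inverse problem — given
growth rates, a dilution factor and a prescribed equal-abundance steady
state, find the efficiency vector ``Y`` that makes that state a fixpoint
of the expectation dynamics — and implements the large-resource
"complete dominance" hierarchy that seeds the solve and proves that
arbitrarily many species can coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .community import Community
from .dynamics import StepKernel, TruncationPolicy

__all__ = [
    "FixpointResult",
    "FixpointError",
    "solve_efficiencies",
    "solve_abundance_fixpoint",
    "dominance_fixpoint",
    "dominance_efficiencies",
    "stability_check",
]


class FixpointError(RuntimeError):
    """Fixpoint solve failed to converge within its iteration budget."""


@dataclass
class FixpointResult:
    """A solved community steady state."""

    community: Community
    n_star: np.ndarray
    alpha0: float
    residual: float
    converged: bool
    iterations: int
    kernel: StepKernel = field(repr=False, default=None)

    @property
    def Y(self) -> np.ndarray:
        return self.community.Y

    @property
    def mu(self) -> np.ndarray:
        return self.community.mu


def dominance_efficiencies(
    n_star: np.ndarray, mu: np.ndarray, alpha: float, R: float = 1.0, s: float = 1.0
) -> np.ndarray:
    """Efficiencies implied by the complete-dominance hierarchy at ``n_star``.

    In the large-resource limit only the fastest species present on a patch
    reaps its resource, so the fixpoint equations decouple hierarchically
    (species sorted by increasing mu; "stronger" = faster):

        n_k = s Y_k (1 - exp(-alpha n_k)) * exp(-alpha sum_{j>k} n_j).

    Inverting each level for Y_k gives a cheap, well-placed initial guess
    for the exact solve.
    """
    n_star = np.asarray(n_star, dtype=float)
    stronger = np.concatenate([np.cumsum(n_star[::-1])[::-1][1:], [0.0]])
    return n_star / (R * s * (1.0 - np.exp(-alpha * n_star)) * np.exp(-alpha * stronger))


def solve_efficiencies(
    n0,
    mu: np.ndarray,
    alpha0: float,
    R: float = 1.0,
    tail_epsilon: float = 1e-13,
    coarse_tail: float = 1e-7,
    tol: float = 1e-9,
    max_iter: int = 200,
    config_ceiling: int = 2_000_000,
) -> FixpointResult:
    """Solve the efficiency vector Y so that ``n*`` is a fixpoint.

    Damped Newton on ``G(Y) = step(n*; Y) - n*`` with the analytic
    dY-Jacobian of the update, initialized from the dominance hierarchy.
    The solve runs first under a coarse truncation (``coarse_tail``) and is
    then polished under ``tail_epsilon``; the tight final truncation
    matters because the slowest relaxation times probed downstream are set
    by eigenvalue gaps as small as 1e-7.

    ``tol`` is relative: convergence requires max_k |G_k| / n*_k < tol.

    Raises ``FixpointError`` on non-convergence (no silent partial result).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    n_star = np.broadcast_to(np.asarray(n0, dtype=float), mu.shape).astype(float)
    if np.any(n_star <= 0):
        raise ValueError("target abundances must be positive")
    if np.unique(mu).size != mu.size:
        raise ValueError("growth rates must be distinct")
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")

    # solve in mu-sorted order (the dominance initialization is
    # hierarchical); relabel back at the end
    order = np.argsort(mu)
    if not np.array_equal(order, np.arange(mu.size)):
        inner = solve_efficiencies(
            n_star[order], mu[order], alpha0, R=R, tail_epsilon=tail_epsilon,
            coarse_tail=coarse_tail, tol=tol, max_iter=max_iter,
            config_ceiling=config_ceiling,
        )
        inv = np.argsort(order)
        kernel = StepKernel(
            Community(mu=mu, Y=inner.community.Y[inv], R=R), inner.kernel.policy
        )
        return FixpointResult(
            community=kernel.community,
            n_star=n_star.copy(),
            alpha0=alpha0,
            residual=inner.residual,
            converged=inner.converged,
            iterations=inner.iterations,
            kernel=kernel,
        )

    Y = dominance_efficiencies(n_star, mu, alpha0, R=R)
    total_iters = 0
    kernel = None
    stages = [coarse_tail, tail_epsilon] if coarse_tail > tail_epsilon else [tail_epsilon]
    for stage_tail in stages:
        policy = TruncationPolicy(tail_epsilon=stage_tail, config_ceiling=config_ceiling)
        Y, kernel, iters = _newton_Y(
            Y, n_star, mu, alpha0, R, policy, tol=tol, max_iter=max_iter
        )
        total_iters += iters

    n_next, _ = kernel.step(n_star, alpha0)
    residual = float(np.max(np.abs(n_next - n_star)))
    return FixpointResult(
        community=kernel.community,
        n_star=n_star.copy(),
        alpha0=alpha0,
        residual=residual,
        converged=True,
        iterations=total_iters,
        kernel=kernel,
    )


def _newton_Y(Y, n_star, mu, alpha, R, policy, tol, max_iter):
    def G_of(Yvec):
        kern = StepKernel(Community(mu=mu, Y=Yvec, R=R), policy)
        n_next, _ = kern.step(n_star, alpha)
        return n_next - n_star, kern

    G, kernel = G_of(Y)
    err = np.max(np.abs(G) / n_star)
    for it in range(1, max_iter + 1):
        if err < tol:
            return Y, kernel, it - 1
        JY = kernel.efficiency_jacobian(n_star, alpha)
        try:
            delta = np.linalg.solve(JY, G)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FixpointError(f"singular efficiency Jacobian: {exc}") from exc
        step_scale = 1.0
        for _ in range(30):
            Y_new = Y - step_scale * delta
            if np.all(Y_new > 0):
                G_new, kern_new = G_of(Y_new)
                err_new = np.max(np.abs(G_new) / n_star)
                if err_new < err:
                    Y, G, kernel, err = Y_new, G_new, kern_new, err_new
                    break
            step_scale *= 0.5
        else:
            raise FixpointError(
                f"efficiency solve stalled at residual {err:.3g} "
                f"(iteration {it})"
            )
    if err < tol:
        return Y, kernel, max_iter
    raise FixpointError(
        f"efficiency solve did not converge in {max_iter} iterations; "
        f"final relative residual {err:.3g}"
    )


def solve_abundance_fixpoint(
    community: Community,
    alpha: float,
    n_init: np.ndarray,
    tail_epsilon: float = 1e-13,
    tol: float = 1e-11,
    max_iter: int = 200,
    kernel: StepKernel | None = None,
) -> FixpointResult:
    """Solve the forward fixpoint n = step(n) for a *given* community.

    Newton on ``step(n) - n`` using the analytic abundance Jacobian.  Used
    for dilution-sensitivity cross-checks (re-solving the steady state at
    perturbed alpha) and for validating the dominance approximation.
    """
    if kernel is None:
        kernel = StepKernel(community, TruncationPolicy(tail_epsilon=tail_epsilon))
    n = np.asarray(n_init, dtype=float).copy()
    scale = float(np.max(n))
    for it in range(1, max_iter + 1):
        n_next, _ = kernel.step(n, alpha)
        G = n_next - n
        err = float(np.max(np.abs(G)))
        if err < tol * scale:
            return FixpointResult(
                community=community,
                n_star=n,
                alpha0=alpha,
                residual=err,
                converged=True,
                iterations=it,
                kernel=kernel,
            )
        J, _ = kernel.jacobian(n, alpha)
        delta = np.linalg.solve(J - np.eye(community.N), -G)
        step_scale = 1.0
        while np.any(n + step_scale * delta < -0.1 * n) and step_scale > 1e-6:
            step_scale *= 0.5
        # abundances live on the non-negative orthant; an overshooting
        # Newton step is projected back (competitive exclusion lands here)
        n = np.maximum(n + step_scale * delta, 0.0)
    raise FixpointError(f"abundance fixpoint did not converge; residual {err:.3g}")


def dominance_fixpoint(
    community: Community, alpha: float, s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical fixpoint of the complete-dominance approximation.

    Species must be sorted by increasing mu.  Working from the strongest
    competitor down, each abundance solves the scalar equation

        n_k = s Y_k R (1 - exp(-alpha n_k)) * exp(-alpha sum_{j>k} n_j),

    which has a positive root iff the effective seeding gain
    ``alpha * s Y_k R * exp(-alpha sum_{j>k} n_j)`` exceeds 1; otherwise the
    species is excluded (abundance 0, flagged).

    Returns ``(n, excluded)``.
    """
    if np.any(np.diff(community.mu) <= 0) and community.N > 1:
        raise ValueError("species must be sorted by strictly increasing mu")
    Y = community.Y * s * community.R
    N = community.N
    n = np.zeros(N)
    excluded = np.zeros(N, dtype=bool)
    stronger_sum = 0.0
    for k in range(N - 1, -1, -1):
        c = Y[k] * np.exp(-alpha * stronger_sum)
        if alpha * c <= 1.0:
            excluded[k] = True
            continue
        # root of g(x) = c(1 - e^{-alpha x}) - x on (0, c]
        g = lambda x: c * (1.0 - np.exp(-alpha * x)) - x
        n[k] = brentq(g, 1e-12 * c, c, xtol=1e-14 * max(c, 1.0), rtol=1e-14)
        stronger_sum += n[k]
    return n, excluded


def stability_check(fp: FixpointResult) -> tuple[float, bool]:
    """Spectral radius of the one-step response at the fixpoint.

    The fixpoint is stable iff every eigenvalue of J has modulus < 1.
    """
    J, _ = fp.kernel.jacobian(fp.n_star, fp.alpha0)
    lam = np.linalg.eigvals(J)
    rho = float(np.max(np.abs(lam)))
    return rho, rho < 1.0
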