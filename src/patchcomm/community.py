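"""Species communities for the grow-and-disperse patch model.

A community is a set of ``N`` species competing for a single resource on
identical patches.  Each species is characterized by exactly two traits:

``mu``
    exponential growth rate while resource remains on a patch
    (per unit time),
``Y``
    efficiency — the number of offspring one individual produces if it
    consumes the entire resource of a patch by itself.

The per-patch resource amount ``R`` is a free scale: multiplying ``R`` by a
constant is equivalent to multiplying every efficiency by the same constant,
so ``R = 1`` is the conventional choice.  The phenotype coordinate used for
distances and abundance profiles is ``z = log(mu)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Community", "geometric_mu_grid"]


def geometric_mu_grid(n_species: int, mu_min: float = 0.1, mu_max: float = 0.3) -> np.ndarray:
    """Growth rates geometrically (log-uniformly) spaced on [mu_min, mu_max].

    Both endpoints are included, so the phenotype coordinates z = log(mu)
    form a uniform grid.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_species == 1:
        return np.asarray([mu_min], dtype=float)
    return np.geomspace(mu_min, mu_max, n_species)


@dataclass(frozen=True)
class Community:
    """An N-species community defined by growth rates and efficiencies.

    Parameters
    ----------
    mu : array of float
        Growth rates, strictly positive.  Species are conventionally sorted
        by increasing ``mu``.
    Y : array of float
        Efficiencies (offspring per full patch resource), strictly positive.
    R : float
        Resource per patch.  Default 1 (pure convention, see module docs).
    """

    mu: np.ndarray
    Y: np.ndarray
    R: float = 1.0

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        Y = np.atleast_1d(np.asarray(self.Y, dtype=float))
        if mu.shape != Y.shape or mu.ndim != 1:
            raise ValueError("mu and Y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(Y)) and np.isfinite(self.R)):
            raise ValueError("community parameters must be finite")
        if np.any(mu <= 0) or np.any(Y <= 0) or self.R <= 0:
            raise ValueError("mu, Y and R must be strictly positive")
        mu.flags.writeable = False
        Y.flags.writeable = False
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Y", Y)

    @property
    def N(self) -> int:
        return self.mu.size

    @property
    def z(self) -> np.ndarray:
        """Phenotype coordinates z_k = log(mu_k)."""
        return np.log(self.mu)

    def rescaled(self, s: float) -> "Community":
        """Return a copy with all efficiencies multiplied by ``s``.

        ``s >> 1`` is the large-resource limit in which the fastest grower
        present on a patch reaps essentially the whole resource
        ("complete dominance").
        """
        if s <= 0:
            raise ValueError("s must be positive")
        return replace(self, Y=self.Y * s)

    def with_resource(self, R: float) -> "Community":
        return replace(self, R=R)

    def sorted_by_mu(self) -> "Community":
        order = np.argsort(self.mu)
        return replace(self, mu=self.mu[order], Y=self.Y[order])
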