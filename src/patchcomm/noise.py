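"""Log-normal environmental noise in the dispersal dilution factor.

Each cycle's dilution alpha is drawn i.i.d. (white noise) from a
log-normal with density parameters theta and omega — the mean and standard
deviation of log(alpha).  Anchoring theta = log(alpha0) keeps the long-term
dilution rate (set by the expectation of log alpha over many consecutive
cycles) independent of the noise level, so raising omega widens the
fluctuations without biasing the competition toward fast or efficient
species.  The familiar log-normal identities connect omega to the
coefficient of variation:

    cv = sigma_alpha / <alpha>,   omega = sqrt(log(1 + cv^2)),
    <alpha> = alpha0 * sqrt(1 + cv^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "draw_alphas"]


@dataclass(frozen=True)
class NoiseModel:
    """White log-normal noise on the dilution factor.

    alpha0 : reference (fixpoint) dilution; the distribution's median.
    cv     : coefficient of variation sigma_alpha / <alpha>.
    seed   : RNG seed; the same seed reproduces the same alpha series
             bit-for-bit, which is what lets clamped counterfactual runs
             share one noise realization.
    """

    alpha0: float
    cv: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def theta(self) -> float:
        return float(np.log(self.alpha0))

    @property
    def omega(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    @property
    def mean_alpha(self) -> float:
        return self.alpha0 * float(np.sqrt(1.0 + self.cv**2))

    @property
    def sigma_alpha(self) -> float:
        return self.mean_alpha * self.cv

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def draw(self, cycles: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """i.i.d. log-normal alpha series of the given length."""
        if cycles < 0:
            raise ValueError("cycles must be >= 0")
        if rng is None:
            rng = self.rng()
        if self.cv == 0:
            return np.full(cycles, self.alpha0)
        return rng.lognormal(self.theta, self.omega, size=cycles)


def draw_alphas(nm: NoiseModel, cycles: int) -> np.ndarray:
    """Functional form of ``NoiseModel.draw`` (fresh RNG from the seed)."""
    return nm.draw(cycles)
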