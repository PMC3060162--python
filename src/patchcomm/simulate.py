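"""Stochastic trajectories and perturbation experiments.

A run iterates the exact expectation update with a freshly drawn dilution
factor each cycle.  Counterfactual "clamped" runs hold a chosen subset of
species at their fixpoint abundances: the clamp is re-imposed after each
growth/dispersal update, so clamped species keep exerting competitive
pressure at fixed density while only the free species fluctuate.  Because
the alpha series is produced by a separate, seeded stream, every clamp
configuration can be driven by bit-identical noise — the comparison that
separates the Moran (synchronizing) effect of shared noise from the
compensatory (anti-synchronizing) effect of competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import StepKernel, TruncationPolicy
from .fixpoint import FixpointResult
from .noise import NoiseModel

__all__ = ["SimulationTrace", "run", "perturbation_experiment"]


@dataclass
class SimulationTrace:
    """Recorded trajectory of per-patch abundances.

    ``abundances[t]`` is n(t) with row 0 the initial state; ``alphas[t]``
    is the dilution applied between rows t and t+1, so there are
    ``cycles + 1`` abundance rows and ``cycles`` alpha entries.
    """

    alphas: np.ndarray
    abundances: np.ndarray
    clamp_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def cycles(self) -> int:
        return self.alphas.size

    def free_species(self) -> np.ndarray:
        return np.flatnonzero(~self.clamp_mask)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cycle, alpha, species, abundance)."""
        T1, N = self.abundances.shape
        alphas = np.concatenate([[np.nan], self.alphas])  # alpha leading into row t
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(T1), N),
                "alpha_in": np.repeat(alphas, N),
                "species": np.tile(np.arange(1, N + 1), T1),
                "abundance": self.abundances.ravel(),
            }
        )

    def save_npz(self, path) -> None:
        """Compact array container with the metadata header."""
        meta = {f"meta_{k}": np.asarray(v) for k, v in self.metadata.items()}
        np.savez_compressed(
            path,
            alphas=self.alphas,
            abundances=self.abundances,
            clamp_mask=self.clamp_mask,
            **meta,
        )

    @classmethod
    def load_npz(cls, path) -> "SimulationTrace":
        with np.load(path, allow_pickle=False) as z:
            meta = {
                k[5:]: (v.item() if v.ndim == 0 else v)
                for k, v in z.items()
                if k.startswith("meta_")
            }
            return cls(
                alphas=z["alphas"],
                abundances=z["abundances"],
                clamp_mask=z["clamp_mask"],
                metadata=meta,
            )


def run(
    fp: FixpointResult,
    nm: NoiseModel,
    cycles: int,
    clamp_mask: np.ndarray | None = None,
    n_init: np.ndarray | None = None,
    policy: TruncationPolicy | None = None,
    kernel: StepKernel | None = None,
    alphas: np.ndarray | None = None,
) -> SimulationTrace:
    """Simulate ``cycles`` noisy dispersal-growth cycles from a fixpoint.

    Parameters of note
    ------------------
    clamp_mask : boolean (N,)
        Species held at their fixpoint abundance (see module docs).
    alphas : optional precomputed dilution series
        Overrides drawing from ``nm`` — used to push one noise realization
        through many clamp configurations.
    n_init : optional starting state (defaults to n*).

    Monte-Carlo fallback draws (engaged only when an excursion makes full
    enumeration too large) come from an RNG seeded by ``nm.seed + 1`` so
    they never consume the alpha stream.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    N = fp.community.N
    clamp = (
        np.zeros(N, dtype=bool)
        if clamp_mask is None
        else np.asarray(clamp_mask, dtype=bool).copy()
    )
    if clamp.shape != (N,):
        raise ValueError("clamp_mask must have one entry per species")
    if kernel is None:
        kernel = StepKernel(fp.community, policy) if policy is not None else fp.kernel
    if alphas is None:
        alphas = nm.draw(cycles)
    else:
        alphas = np.asarray(alphas, dtype=float)
        if alphas.size != cycles:
            raise ValueError("alpha series length must equal cycles")
    mc_rng = np.random.default_rng(np.uint32(nm.seed) + 1)

    n = fp.n_star.copy() if n_init is None else np.asarray(n_init, dtype=float).copy()
    n[clamp] = fp.n_star[clamp]
    traj = np.empty((cycles + 1, N))
    traj[0] = n
    mc_cycles = 0
    for t in range(cycles):
        n, info = kernel.step(n, float(alphas[t]), rng=mc_rng)
        if not np.all(np.isfinite(n)):
            raise FloatingPointError(
                f"abundances left the model's range at cycle {t} "
                "(excursion beyond validity)"
            )
        n[clamp] = fp.n_star[clamp]
        traj[t + 1] = n
        mc_cycles += int(info.monte_carlo)
    return SimulationTrace(
        alphas=alphas,
        abundances=traj,
        clamp_mask=clamp,
        metadata={
            "seed": nm.seed,
            "alpha0": nm.alpha0,
            "cv": nm.cv,
            "tail_epsilon": kernel.policy.tail_epsilon,
            "adaptive_truncation": kernel.policy.adaptive,
            "mc_cycles": mc_cycles,
        },
    )


def perturbation_experiment(
    fp: FixpointResult,
    kind: str,
    magnitude: float,
    at_cycle: int,
    cycles: int,
    species: int | None = None,
    kernel: StepKernel | None = None,
) -> SimulationTrace:
    """Deterministic pulse/press experiments around the fixpoint.

    kind
        ``"pulse-in-alpha"``  — alpha multiplied by (1 + magnitude) for the
        single cycle ``at_cycle``;
        ``"press-in-alpha"``  — same shift applied from ``at_cycle`` on;
        ``"pulse-in-species"`` — abundance of ``species`` (0-based) jumps
        by ``magnitude * n*_k`` once, at ``at_cycle``.

    No noise is drawn: the response isolates the community's intrinsic
    relaxation (or its displaced steady state for a press).
    """
    kinds = {"pulse-in-alpha", "press-in-alpha", "pulse-in-species"}
    if kind not in kinds:
        raise ValueError(f"kind must be one of {sorted(kinds)}")
    if not (0 <= at_cycle < cycles):
        raise ValueError("at_cycle must lie within the run")
    if kind == "pulse-in-species":
        if species is None:
            raise ValueError("species index required for a species pulse")
    if kernel is None:
        kernel = fp.kernel
    N = fp.community.N
    alpha0 = fp.alpha0
    alphas = np.full(cycles, alpha0)
    if kind == "pulse-in-alpha":
        alphas[at_cycle] *= 1.0 + magnitude
    elif kind == "press-in-alpha":
        alphas[at_cycle:] *= 1.0 + magnitude

    n = fp.n_star.copy()
    traj = np.empty((cycles + 1, N))
    traj[0] = n
    for t in range(cycles):
        if kind == "pulse-in-species" and t == at_cycle:
            n = n.copy()
            n[species] += magnitude * fp.n_star[species]
        n, _ = kernel.step(n, float(alphas[t]))
        traj[t + 1] = n
    return SimulationTrace(
        alphas=alphas,
        abundances=traj,
        clamp_mask=np.zeros(N, dtype=bool),
        metadata={"kind": kind, "magnitude": magnitude, "at_cycle": at_cycle},
    )
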