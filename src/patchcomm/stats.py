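"""Summary statistics of simulated community trajectories.

Three views connect the stochastic simulations back to theory:

* pairwise abundance correlations as a function of phenotypic distance
  |z_k - z_l| (z = log mu) — the signature separating Moran synchrony
  (uniformly positive), pairwise compensation (one negative crossover) and
  the collective clustering of the full model (alternating sign);
* abundance profiles over the phenotype axis at chosen times and averaged
  over a window — where the peak-and-valley clusters are visible directly;
* empirical eigenmode amplitudes: projecting deviations from the fixpoint
  onto the eigenbasis, q(t) = S^-1 (n(t) - n*), and time-averaging q_k^2
  for comparison with the stationary linear prediction.

Correlations are computed on log abundances by default: trajectories span
orders of magnitude, and Pearson on logs is far less dominated by rare
excursions.  The raw scale remains available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linear import LinearModel
from .simulate import SimulationTrace

__all__ = [
    "CorrelationCurve",
    "correlation_vs_distance",
    "profile_snapshots",
    "empirical_mode_amplitudes",
    "sign_changes",
]

_TINY = 1e-300


def sign_changes(values: np.ndarray) -> int:
    """Number of sign alternations in a sequence (zeros ignored)."""
    v = np.asarray(values, dtype=float)
    nz = v[v != 0]
    return int(np.sum(np.sign(nz[1:]) * np.sign(nz[:-1]) < 0))


@dataclass
class CorrelationCurve:
    """Pairwise correlations against phenotypic distance."""

    pairs: pd.DataFrame  # columns: k, l, distance, corr
    binned: pd.DataFrame  # columns: distance, corr_mean, n_pairs
    provenance: str

    def binned_signs(self) -> int:
        """Sign alternations of the distance-binned mean curve."""
        return sign_changes(self.binned["corr_mean"].to_numpy())


def _series(trace: SimulationTrace, k: int, burn_in: int, use_log: bool) -> np.ndarray:
    x = trace.abundances[burn_in:, k]
    return np.log(np.maximum(x, _TINY)) if use_log else x


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _check_shared_noise(traces) -> None:
    ref = traces[0].alphas
    for tr in traces[1:]:
        if tr.alphas.shape != ref.shape or not np.array_equal(tr.alphas, ref):
            raise ValueError(
                "traces in a shared-noise regime must carry identical alpha series"
            )


def correlation_vs_distance(
    traces,
    z: np.ndarray,
    regime: str = "full",
    use_log: bool = True,
    burn_in: int = 1000,
) -> CorrelationCurve:
    """Pairwise correlation vs phenotypic distance under a clamp regime.

    regime
        ``"full"``   — one unclamped trace; all within-trace species pairs.
        ``"single"`` — N traces, each with exactly one free species, driven
        by one shared noise series; correlations are taken across traces
        (pure Moran limit: no two free species ever interact).
        ``"pair"``   — traces each with exactly two free species; the
        correlation of each trace's own pair (noise + pairwise
        interaction only).
        ``"subset"`` — traces with any clamp pattern; within-trace pairs
        over the free species of each trace (interpolates between the pair
        and full regimes as fewer species are clamped).
    """
    if isinstance(traces, SimulationTrace):
        traces = [traces]
    z = np.asarray(z, dtype=float)
    rows = []
    if regime == "full":
        tr = traces[0]
        free = tr.free_species()
        series = {k: _series(tr, k, burn_in, use_log) for k in free}
        for k, l in itertools.combinations(free, 2):
            rows.append((k, l, abs(z[k] - z[l]), _pearson(series[k], series[l])))
    elif regime == "single":
        _check_shared_noise(traces)
        series = {}
        for tr in traces:
            free = tr.free_species()
            if free.size != 1:
                raise ValueError("single regime requires one free species per trace")
            series[int(free[0])] = _series(tr, int(free[0]), burn_in, use_log)
        for k, l in itertools.combinations(sorted(series), 2):
            rows.append((k, l, abs(z[k] - z[l]), _pearson(series[k], series[l])))
    elif regime in ("pair", "subset"):
        _check_shared_noise(traces)
        for tr in traces:
            free = tr.free_species()
            if regime == "pair" and free.size != 2:
                raise ValueError("pair regime requires two free species per trace")
            for k, l in itertools.combinations(free, 2):
                rows.append(
                    (
                        int(k),
                        int(l),
                        abs(z[k] - z[l]),
                        _pearson(
                            _series(tr, int(k), burn_in, use_log),
                            _series(tr, int(l), burn_in, use_log),
                        ),
                    )
                )
    else:
        raise ValueError(f"unknown regime {regime!r}")

    pairs = pd.DataFrame(rows, columns=["k", "l", "distance", "corr"])
    pairs["distance_bin"] = pairs["distance"].round(9)
    binned = (
        pairs.groupby("distance_bin")["corr"]
        .agg(corr_mean="mean", n_pairs="size")
        .reset_index()
        .rename(columns={"distance_bin": "distance"})
        .sort_values("distance", ignore_index=True)
    )
    return CorrelationCurve(
        pairs=pairs.drop(columns="distance_bin"), binned=binned, provenance=regime
    )


def profile_snapshots(
    trace: SimulationTrace,
    times,
    z: np.ndarray,
    average_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Abundance profiles over the phenotype axis at chosen cycles.

    Returns one row per species (indexed by z), one column per requested
    time plus a ``time_average`` column over ``average_window``
    (default: the whole trace).
    """
    T1 = trace.abundances.shape[0]
    data = {"z": np.asarray(z, dtype=float)}
    for t in times:
        if not (0 <= t < T1):
            raise ValueError(f"cycle {t} outside trace range")
        data[f"t{t}"] = trace.abundances[t]
    lo, hi = (0, T1) if average_window is None else average_window
    data["time_average"] = trace.abundances[lo:hi].mean(axis=0)
    return pd.DataFrame(data)


def empirical_mode_amplitudes(
    trace: SimulationTrace,
    lm: LinearModel,
    burn_in: int = 1000,
    normalization: str = "absolute",
) -> pd.DataFrame:
    """Time-averaged squared mode amplitudes of a simulated trajectory.

    Deviations from the fixpoint are rotated into the eigenbasis,
    q(t) = S^-1 Dn(t), and <q_k^2> is averaged over the post-burn-in
    cycles.  ``normalization="relative"`` divides deviations by n* first
    (an alternative reading of "normalizing to the fixpoint"; the absolute
    convention matches the linearized equations and is the default).

    The ``valid`` flag marks modes whose relaxation time fits well inside
    the averaged window — slower modes cannot equilibrate in the trace and
    their empirical amplitude is an underestimate.
    """
    if lm.S is None:
        raise ValueError("linear model needs eigen_analysis")
    dn = trace.abundances[burn_in:] - lm.fp.n_star
    if normalization == "relative":
        dn = dn / lm.fp.n_star
    elif normalization != "absolute":
        raise ValueError("normalization must be 'absolute' or 'relative'")
    q = np.linalg.solve(lm.S, dn.T)  # (N, T)
    amp2_emp = (q**2).mean(axis=1)
    window = dn.shape[0]
    out = pd.DataFrame(
        {
            "mode": np.arange(1, lm.S.shape[1] + 1),
            "lam": lm.lambdas,
            "tau": lm.tau,
            "amp2_empirical": amp2_emp,
            "valid": lm.tau < window / 5.0,
        }
    )
    if lm.amp2 is not None:
        out["amp2_predicted"] = lm.amp2
    if lm.roughness_rank is not None:
        out["roughness_rank"] = lm.roughness_rank
    return out
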