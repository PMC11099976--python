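"""Pauli master equations with time-dependent pairwise rate coefficients.

Populations evolve incoherently by gain-loss kinetics,

    dP_j/dt = sum_{k != j} [ k_{k->j}(t) P_k - k_{j->k}(t) P_j ],

with every k_{j->k}(t) supplied on a common time grid (typically the
IMT rate series).  Rates are linearly interpolated inside the grid and
extended beyond its end by holding each transition's plateau value,
since the rate coefficients relax to their equilibrium constants well
before population transfer completes.  The generator has exact zero
column sums, so total population is conserved up to integrator
truncation error; integration uses an adaptive stiff-capable solver
because the rates of different transitions can span many orders of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .core import PS_PER_S, TimeGrid
from .rates import RateSeries

__all__ = [
    "RateMatrixSeries",
    "PopulationTrajectory",
    "integrate_populations",
    "survival_two_state",
    "default_output_times",
]

_SUM_TOL = 1e-10
_RANGE_TOL = 1e-8


@dataclass
class RateMatrixSeries:
    """All pairwise rate series k_{j->k}(t) on one grid, in s^-1.

    ``rates[(j, k)]`` has shape ``(n_points,)``; 1-based indices.
    ``plateaus[(j, k)]`` supplies the hold value used beyond the grid
    end (defaults to the final grid value).
    """

    n_states: int
    grid: TimeGrid
    rates: Dict[Tuple[int, int], np.ndarray]
    plateaus: Dict[Tuple[int, int], float] = field(default_factory=dict)
    extension_policy: str = "hold_plateau"

    def __post_init__(self) -> None:
        for pair, arr in self.rates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.n_points,):
                raise ValueError(
                    f"rate series for {pair} has shape {arr.shape}, "
                    f"grid has {self.grid.n_points} points"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"invalid (negative/non-finite) rates for {pair}")
            self.rates[pair] = arr
            self.plateaus.setdefault(pair, float(arr[-1]))
        if self.extension_policy != "hold_plateau":
            raise ValueError(
                f"unknown extension policy {self.extension_policy!r}"
            )

    @classmethod
    def from_rate_series(
        cls, n_states: int, series: Sequence[RateSeries]
    ) -> "RateMatrixSeries":
        grid = series[0].grid
        rates = {s.transition: s.k for s in series}
        plateaus = {s.transition: s.plateau for s in series}
        return cls(n_states=n_states, grid=grid, rates=rates, plateaus=plateaus)

    def generator(self, t_ps: float) -> np.ndarray:
        """Kinetic generator G(t) in ps^-1: dP/dt = G P, columns sum to 0."""
        f = self.n_states
        g = np.zeros((f, f))
        tmax = self.grid.span
        times = self.grid.times
        for (j, k), arr in self.rates.items():
            if t_ps >= tmax:
                val = self.plateaus[(j, k)]
            else:
                val = np.interp(t_ps, times, arr)
            val /= PS_PER_S  # s^-1 -> ps^-1
            g[k - 1, j - 1] += val
            g[j - 1, j - 1] -= val
        return g


@dataclass
class PopulationTrajectory:
    """State populations P_j(t) on an output time grid (ps).

    ``populations`` has shape ``(n_states, n_times)``.  Construction
    enforces conservation of total population to 1e-10 and containment
    in [0, 1] within integrator tolerance.
    """

    times: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        total = self.populations.sum(axis=0)
        err = np.max(np.abs(total - 1.0))
        if err > _SUM_TOL:
            raise ValueError(
                f"total population deviates from 1 by {err:.3e} (> {_SUM_TOL})"
            )
        if np.any(self.populations < -_RANGE_TOL) or np.any(
            self.populations > 1.0 + _RANGE_TOL
        ):
            raise ValueError("populations leave [0, 1] beyond tolerance")

    def state(self, j: int) -> np.ndarray:
        return self.populations[j - 1]


def default_output_times(t_end: float, dense_until: float = 5.0,
                         dense_dt: float = 0.01, coarse_dt: float = 0.1) -> np.ndarray:
    """Output grid: dense early times, coarser afterwards, ends at t_end."""
    if t_end <= dense_until:
        return np.arange(0.0, t_end + 0.5 * dense_dt, dense_dt)
    early = np.arange(0.0, dense_until, dense_dt)
    late = np.arange(dense_until, t_end + 0.5 * coarse_dt, coarse_dt)
    return np.concatenate([early, late])


def integrate_populations(
    rates: RateMatrixSeries,
    p0: Sequence[float],
    t_end: float,
    output_times: np.ndarray | None = None,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> PopulationTrajectory:
    """Integrate the master equations from ``p0`` (on the simplex) to t_end ps.

    The same rate set serves any initial electronic population, because
    the rate coefficients are precomputed from the nonequilibrium gap
    statistics and do not feed back on the populations.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (rates.n_states,):
        raise ValueError(
            f"p0 must have {rates.n_states} entries, got shape {p0.shape}"
        )
    if np.any(p0 < -1e-8) or abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must lie on the probability simplex")
    if output_times is None:
        output_times = default_output_times(t_end)
    output_times = np.asarray(output_times, dtype=float)
    if output_times[-1] > t_end:
        raise ValueError("output times extend past t_end")

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        return rates.generator(t) @ p

    def jac(t: float, p: np.ndarray) -> np.ndarray:
        return rates.generator(t)

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        p0,
        method="LSODA",
        jac=jac,
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"population integration failed: {sol.message}")
    return PopulationTrajectory(times=sol.t, populations=sol.y)


def survival_two_state(grid: TimeGrid, k: np.ndarray) -> np.ndarray:
    """Donor survival P_D(t) = exp(-int_0^t k(t') dt') for one rate series.

    ``k`` is in s^-1 on ``grid``; the cumulative integral uses
    trapezoidal quadrature on the rate grid.  This is the two-state
    master equation with the backward rate set to zero.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("rate coefficient must be nonnegative")
    k_ps = k / PS_PER_S
    integral = cumulative_trapezoid(k_ps, grid.times, initial=0.0)
    return np.exp(-integral)
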