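"""Time-dependent IMT rate coefficients and Marcus-theory quantities.

The instantaneous Marcus theory (IMT) rate for transition j -> k is a
Marcus-like golden-rule expression evaluated with the *time-dependent*
mean and variance of the energy gap U_jk = V_j - V_k:

    k_{j->k}(t) = (Gamma_jk^2 / hbar) * sqrt(2 pi / sigma^2(t))
                  * exp(-Ubar(t)^2 / (2 sigma^2(t)))

where Ubar(t) and sigma^2(t) are the nonequilibrium average and
variance of the gap after vertical excitation from the equilibrated
ground state.  In the long-time limit Ubar -> <U>_j and
sigma^2 -> sigma_eq^2, and the expression reduces *exactly* to the
classical Marcus rate constant with

    E_r    = sigma_eq^2 / (2 k_B T)
    DeltaE = -<U>_j - E_r

(the sign convention is fixed by the shifted-harmonic model, for which
<U_jk>_j = -(DeltaE + E_r) holds identically).

All rates are returned in s^-1; the single ps -> s conversion of the
package lives in this module (through hbar expressed in eV*s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import norm

from .core import HBAR, K_B, TimeGrid

__all__ = [
    "MomentSeries",
    "RateSeries",
    "FreeEnergySeries",
    "moments_from_tcf",
    "imt_rate_series",
    "imt_rate",
    "marcus_rate",
    "free_energy_decomposition",
    "gap_distribution",
    "plateau_rate",
    "reorganization_from_variance",
]


@dataclass
class MomentSeries:
    """Nonequilibrium mean and variance of one gap channel versus time.

    ``mean`` is Ubar_jk(t) in eV, ``variance`` sigma^2_jk(t) in eV^2,
    both on ``grid``.  Standard errors are optional (zero for analytic
    series).  A nonpositive variance anywhere is rejected at
    construction: it indicates an estimator failure (noisy exponential
    reweighting), not physics, and must never be clamped.
    """

    grid: TimeGrid
    mean: np.ndarray
    variance: np.ndarray
    se_mean: np.ndarray | None = None
    se_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        n = self.grid.n_points
        if self.mean.shape != (n,) or self.variance.shape != (n,):
            raise ValueError(
                f"moment arrays must have shape ({n},); got "
                f"{self.mean.shape} and {self.variance.shape}"
            )
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.variance))):
            raise ValueError("non-finite moment values")
        bad = np.flatnonzero(self.variance <= 0.0)
        if bad.size:
            t_bad = self.grid.times[bad[0]]
            raise ValueError(
                f"nonpositive gap variance {self.variance[bad[0]]:.3e} eV^2 "
                f"at t = {t_bad:.4g} ps: the reweighted estimator is too "
                "noisy at this lag (check the effective sample size); "
                "refusing to clamp"
            )


@dataclass
class RateSeries:
    """IMT rate coefficient k_{j->k}(t) in s^-1 plus its two constants.

    ``plateau`` is the trailing-window average of k(t); ``marcus`` the
    equilibrium Marcus rate constant for the same transition.
    """

    grid: TimeGrid
    k: np.ndarray
    plateau: float
    marcus: float
    transition: Tuple[int, int]

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if np.any(self.k < 0):
            raise ValueError("negative rate coefficient")
        if self.plateau < 0:
            raise ValueError("negative plateau rate")


@dataclass
class FreeEnergySeries:
    """Time-dependent driving force, reorganization and activation energy.

    ``delta_e`` = DeltaE(t), ``e_r`` = E_r(t), ``e_a`` = E_a(t), all eV.
    """

    grid: TimeGrid
    delta_e: np.ndarray
    e_r: np.ndarray
    e_a: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.e_r <= 0):
            raise ValueError("reorganization energy must be positive")
        if np.any(self.e_a < 0):
            raise ValueError("activation energy must be nonnegative")


def moments_from_tcf(stats, tcf) -> MomentSeries:
    """Nonequilibrium moments from equilibrium stats and the two TCFs.

        Ubar(t)    = <U_jk>   + C1(t)
        sigma^2(t) = <U_jk^2> + C2(t) - Ubar(t)^2

    Parameters
    ----------
    stats : EquilibriumStats
        Pooled equilibrium mean and second moment of U_jk on state j.
    tcf : TcfSeries
        First- and second-kind nonlinear-response TCFs for the same
        transition and ensemble.

    Raises
    ------
    ValueError
        If the implied variance is nonpositive at any lag (reported
        with the offending time), which signals reweighting noise.
    """
    mean = stats.mean_gap + tcf.c1
    variance = stats.second_moment + tcf.c2 - mean**2
    se_mean = None
    se_variance = None
    if tcf.jk_mean is not None:
        # jackknife over trajectory batches on the complete moment
        # estimators, so the correlated errors of the equilibrium means
        # and the TCFs propagate together
        nb = tcf.jk_mean.shape[0]
        fac = np.sqrt((nb - 1) / nb)
        se_mean = fac * np.sqrt(
            np.sum((tcf.jk_mean - tcf.jk_mean.mean(axis=0)) ** 2, axis=0)
        )
        se_variance = fac * np.sqrt(
            np.sum((tcf.jk_variance - tcf.jk_variance.mean(axis=0)) ** 2, axis=0)
        )
    elif tcf.se_c1 is not None and tcf.se_c2 is not None:
        # fall back to quadrature propagation (ignores correlations)
        se_mean = np.asarray(tcf.se_c1, dtype=float)
        se_variance = np.sqrt(
            np.asarray(tcf.se_c2, dtype=float) ** 2
            + (2.0 * mean * np.asarray(tcf.se_c1, dtype=float)) ** 2
        )
    return MomentSeries(
        grid=tcf.grid,
        mean=mean,
        variance=variance,
        se_mean=se_mean,
        se_variance=se_variance,
    )


def imt_rate(gamma: float, mean, variance):
    """Pointwise IMT rate in s^-1 for coupling ``gamma`` (eV).

    Accepts scalars or arrays for ``mean`` (eV) and ``variance`` (eV^2).
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("gap variance must be positive")
    pref = (gamma**2 / HBAR) * np.sqrt(2.0 * np.pi / variance)
    out = pref * np.exp(-(mean**2) / (2.0 * variance))
    return out if out.ndim else float(out)


def imt_rate_series(
    gamma: float,
    moments: MomentSeries,
    transition: Tuple[int, int] = (0, 0),
    temperature: float | None = None,
    plateau_window: float | None = None,
) -> RateSeries:
    """IMT rate coefficient series k(t) for one transition.

    ``plateau`` is the average over the trailing ``plateau_window`` ps
    (default: the final quarter of the grid).  If ``temperature`` is
    given, the Marcus constant built from the *final-time* moments is
    attached as ``marcus`` (at long times the final moments approach
    the equilibrium ones and this is the equilibrium Marcus rate).
    """
    k = imt_rate(gamma, moments.mean, moments.variance)
    k = np.atleast_1d(k)
    if plateau_window is None:
        plateau_window = 0.25 * moments.grid.span
    series = RateSeries(
        grid=moments.grid,
        k=k,
        plateau=0.0,
        marcus=0.0,
        transition=transition,
    )
    series.plateau = plateau_rate(series, plateau_window)
    if temperature is not None:
        e_r = reorganization_from_variance(moments.variance[-1], temperature)
        delta_e = -moments.mean[-1] - e_r
        series.marcus = marcus_rate(gamma, delta_e, e_r, temperature)
    return series


def marcus_rate(gamma: float, delta_e: float, e_r: float, temperature: float) -> float:
    """Classical Marcus rate constant in s^-1.

        k = (Gamma^2/hbar) sqrt(pi/(E_r k_B T))
            exp(-(DeltaE + E_r)^2 / (4 E_r k_B T))

    with ``gamma`` = Gamma in eV, ``delta_e`` = DeltaE in eV (reaction
    free energy, negative downhill), ``e_r`` = E_r in eV.
    """
    if e_r <= 0:
        raise ValueError(f"reorganization energy must be positive, got {e_r}")
    kbt = K_B * temperature
    pref = (gamma**2 / HBAR) * np.sqrt(np.pi / (e_r * kbt))
    return float(pref * np.exp(-((delta_e + e_r) ** 2) / (4.0 * e_r * kbt)))


def reorganization_from_variance(variance: float, temperature: float):
    """Linear-response reorganization energy E_r = sigma^2/(2 k_B T), eV."""
    return np.asarray(variance, dtype=float) / (2.0 * K_B * temperature)


def free_energy_decomposition(
    moments: MomentSeries, temperature: float
) -> FreeEnergySeries:
    """Map gap moments onto DeltaE(t), E_r(t), E_a(t).

        E_r(t)    = sigma^2(t) / (2 k_B T)
        DeltaE(t) = -Ubar(t) - E_r(t)
        E_a(t)    = k_B T * Ubar(t)^2 / (2 sigma^2(t))

    so that the IMT exponential equals exp(-E_a(t)/(k_B T)).  The sign
    of DeltaE follows from the shifted-harmonic identity
    <U_jk>_j = -(DeltaE + E_r) under the gap convention U_jk = V_j - V_k.
    """
    kbt = K_B * temperature
    e_r = moments.variance / (2.0 * kbt)
    delta_e = -moments.mean - e_r
    e_a = kbt * moments.mean**2 / (2.0 * moments.variance)
    return FreeEnergySeries(grid=moments.grid, delta_e=delta_e, e_r=e_r, e_a=e_a)


def gap_distribution(
    moments: MomentSeries, t: float, u_grid: np.ndarray
) -> np.ndarray:
    """Gaussian gap density p(U; t) on ``u_grid`` (eV), in eV^-1.

    ``t`` must lie on the moment grid (no interpolation is performed;
    an off-grid time raises ``ValueError``).
    """
    times = moments.grid.times
    idx = np.flatnonzero(np.isclose(times, t, rtol=0.0, atol=1e-12 + 1e-9 * moments.grid.dt))
    if idx.size == 0:
        raise ValueError(
            f"t = {t} ps is not on the moment grid (dt = {moments.grid.dt} ps); "
            "interpolation is not enabled"
        )
    i = int(idx[0])
    return norm.pdf(
        np.asarray(u_grid, dtype=float),
        loc=moments.mean[i],
        scale=np.sqrt(moments.variance[i]),
    )


def plateau_rate(rates: RateSeries, window: float) -> float:
    """Average of k(t) over the trailing ``window`` ps of the series."""
    span = rates.grid.span
    if window > span:
        raise ValueError(
            f"plateau window {window} ps exceeds the series span {span} ps"
        )
    t = rates.grid.times
    sel = t >= span - window
    return float(np.mean(rates.k[sel]))
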