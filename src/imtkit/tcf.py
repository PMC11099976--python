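"""Nonlinear-response time correlation functions from equilibrium ensembles.

The nonequilibrium gap moments after vertical excitation from the
ground state can be recovered from *equilibrium* dynamics on the
initial excited state j by exponential reweighting.  Writing
``dA = A - <A>`` for fluctuations about the pooled equilibrium average,
the first- and second-kind nonlinear-response TCFs are

    C1(t) = < dU_jk(t)   exp(beta dU_jg(0)) > / < exp(beta dU_jg(0)) >
    C2(t) = < dU_jk^2(t) exp(beta dU_jg(0)) > / < exp(beta dU_jg(0)) >

estimated over time origins taken across trajectories and along each
trajectory (time-translation invariance of the equilibrium ensemble).
The nonequilibrium mean and variance then follow as
Ubar(t) = <U> + C1(t) and sigma^2(t) = <U^2> + C2(t) - Ubar(t)^2.

Both TCFs share one set of weights w = exp(beta dU_jg) per origin,
computed with log-sum-exp stabilization (beta is ~38.7 eV^-1 at 300 K,
so raw exponentials overflow easily).  Statistical errors come from
splitting the trajectories into batches and jackknifing the pooled
estimator over them: because the estimator is a weighted ratio, the
delete-one-batch jackknife tracks its sampling variability (including
the random-denominator contribution) better than the plain spread of
per-batch estimates does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .core import EquilibriumStats, GapEnsemble, TimeGrid, beta as _beta

__all__ = [
    "TcfSeries",
    "ReweightingDiagnostics",
    "equilibrium_stats",
    "reweighting_diagnostics",
    "compute_tcfs",
    "compute_c1",
    "compute_c2",
    "batch_errors",
]

logger = logging.getLogger("imtkit")

#: Default effective-sample-size fraction below which a warning is logged.
DEFAULT_ESS_FLOOR = 0.05


@dataclass
class TcfSeries:
    """First- and second-kind nonlinear-response TCFs with batch errors.

    ``c1`` in eV, ``c2`` in eV^2, on ``grid`` (lag times).
    ``numerator_c1``, ``numerator_c2`` and ``denominator`` expose the
    estimator's numerator TCFs and its (positive) denominator for sign
    diagnostics.  ``jk_mean`` and ``jk_variance`` hold the
    leave-one-batch-out replicates of the downstream nonequilibrium
    mean and variance, so moment standard errors can be jackknifed
    with all correlations intact.
    """

    grid: TimeGrid
    c1: np.ndarray
    c2: np.ndarray
    se_c1: np.ndarray | None = None
    se_c2: np.ndarray | None = None
    n_batches: int = 0
    ess_fraction: float = 1.0
    numerator_c1: np.ndarray | None = None
    numerator_c2: np.ndarray | None = None
    denominator: float | None = None
    jk_mean: np.ndarray | None = None
    jk_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c1 = np.asarray(self.c1, dtype=float)
        self.c2 = np.asarray(self.c2, dtype=float)
        if not (np.all(np.isfinite(self.c1)) and np.all(np.isfinite(self.c2))):
            raise ValueError("non-finite TCF values")
        if self.se_c1 is not None and np.any(np.asarray(self.se_c1) < 0):
            raise ValueError("negative standard errors")
        if not (0.0 < self.ess_fraction <= 1.0):
            raise ValueError(f"ess_fraction {self.ess_fraction} outside (0, 1]")


@dataclass
class ReweightingDiagnostics:
    """Normalized origin weights and their effective sample size."""

    weights: np.ndarray  # normalized, sums to 1
    ess: float
    n_origins: int

    @property
    def ess_fraction(self) -> float:
        return self.ess / self.n_origins


def _require_equilibrium(ens: GapEnsemble) -> None:
    if not ens.is_equilibrium:
        raise ValueError(
            "TCF estimation needs an equilibrium ensemble (sampled and "
            f"propagated on the same state); got sampling_state="
            f"{ens.sampling_state}, propagation_state={ens.propagation_state}"
        )


def _batch_slices(n_traj: int, n_batches: int) -> List[slice]:
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    if n_batches > n_traj:
        raise ValueError(
            f"cannot split {n_traj} trajectories into {n_batches} batches"
        )
    edges = np.linspace(0, n_traj, n_batches + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _jackknife_se(loo: np.ndarray) -> np.ndarray:
    """Jackknife SE from leave-one-out replicates along axis 0."""
    b = loo.shape[0]
    dev = loo - loo.mean(axis=0)
    return np.sqrt((b - 1) / b * np.sum(dev**2, axis=0))


def equilibrium_stats(
    ens: GapEnsemble, j: int, k: int, n_batches: int = 4
) -> EquilibriumStats:
    """Pooled equilibrium mean and second moment of U_jk, with batch SEs.

    Averages run over every trajectory and every time point of an
    equilibrium ensemble on state j.
    """
    _require_equilibrium(ens)
    u = ens.channel(j, k)
    mean = float(np.mean(u))
    second = float(np.mean(u**2))
    se_mean = 0.0
    se_second = 0.0
    if 2 <= n_batches <= u.shape[0]:
        slices = _batch_slices(u.shape[0], n_batches)
        bm = np.array([np.mean(u[s]) for s in slices])
        bs = np.array([np.mean(u[s] ** 2) for s in slices])
        se_mean = float(np.std(bm, ddof=1) / np.sqrt(n_batches))
        se_second = float(np.std(bs, ddof=1) / np.sqrt(n_batches))
    return EquilibriumStats(
        mean_gap=mean,
        second_moment=second,
        variance=max(second - mean**2, 0.0),
        se_mean=se_mean,
        se_second_moment=se_second,
    )


def _origin_indices(n_points: int, n_lags: int, stride: int) -> np.ndarray:
    last = n_points - n_lags
    if last < 0:
        raise ValueError("lag window exceeds the trajectory span")
    return np.arange(0, last + 1, stride)


def reweighting_diagnostics(
    ens: GapEnsemble,
    j: int,
    temperature: float,
    ground_index: int,
    origin_stride: int = 1,
    n_lags: int | None = None,
    ess_floor: float = DEFAULT_ESS_FLOOR,
) -> ReweightingDiagnostics:
    """Normalized reweighting weights over all time origins and their ESS.

    ESS = (sum w)^2 / sum w^2 lies in [1, n_origins]; a small
    ESS/n_origins means the exponential reweighting is dominated by a
    few origins and the TCF estimates will be noisy.  The weights are
    exp(beta dU_jg) at each origin, stabilized by subtracting the
    maximum exponent before exponentiation.
    """
    _require_equilibrium(ens)
    ujg = ens.channel(j, ground_index)
    if n_lags is None:
        n_lags = ens.grid.n_points
    origins = _origin_indices(ens.grid.n_points, n_lags, origin_stride)
    logw = _beta(temperature) * (ujg[:, origins] - np.mean(ujg))
    w = np.exp(logw - logw.max()).ravel()
    total = w.sum()
    ess = float(total**2 / np.sum(w**2))
    n_origins = w.size
    if ess / n_origins < ess_floor:
        logger.warning(
            "effective sample size fraction %.3g below floor %.3g for "
            "reweighting on state %d (%d origins): TCF estimates may be noisy",
            ess / n_origins,
            ess_floor,
            j,
            n_origins,
        )
    return ReweightingDiagnostics(weights=w / total, ess=ess, n_origins=n_origins)


def _weighted_sums(
    u: np.ndarray,
    u2: np.ndarray,
    logw: np.ndarray,
    origins: np.ndarray,
    n_lags: int,
    per_trajectory: bool,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Raw weighted sums A(t) = sum w U(t0+t), B(t) = sum w U^2(t0+t), D = sum w.

    ``logw`` must already carry the global stabilization shift so sums
    from different trajectory batches are commensurable.
    """
    w = np.exp(logw)
    if per_trajectory:
        w = w / w.sum(axis=1, keepdims=True)
    a = np.zeros(n_lags)
    b = np.zeros(n_lags)
    for oi, t0 in enumerate(origins):
        wi = w[:, oi]
        a += wi @ u[:, t0 : t0 + n_lags]
        b += wi @ u2[:, t0 : t0 + n_lags]
    return a, b, float(w.sum())


def compute_tcfs(
    ens: GapEnsemble,
    j: int,
    k: int,
    temperature: float,
    ground_index: int,
    n_lags: int | None = None,
    origin_stride: int = 1,
    n_batches: int = 4,
    ess_floor: float = DEFAULT_ESS_FLOOR,
    per_trajectory_weights: bool = False,
) -> TcfSeries:
    """Estimate C1(t) and C2(t) for transition j -> k with batch errors.

    Parameters
    ----------
    ens
        Equilibrium ensemble sampled and propagated on state ``j`` with
        channels U_jk and U_jg.
    n_lags
        Number of lag points; defaults to the full grid (single origin
        per trajectory).  If larger than the grid it is truncated with
        a logged warning.
    origin_stride
        Spacing, in grid steps, between successive time origins along
        each trajectory.  Dense origins are statistically correlated;
        the stride trades variance against cost.
    n_batches
        Trajectory batches for the jackknife standard errors.
    per_trajectory_weights
        Normalize the reweighting within each trajectory before pooling
        instead of across the whole ensemble (pooled is the default).

    Notes
    -----
    Because the pooled equilibrium mean cancels between the fluctuation
    and the weights, Ubar(t) = <U> + C1(t) is algebraically identical to
    the plain weighted ratio sum[w U(t0+t)]/sum[w]; the implementation
    exploits this to jackknife the downstream moments directly.
    """
    _require_equilibrium(ens)
    if j != ens.propagation_state:
        raise ValueError(
            f"ensemble was propagated on state {ens.propagation_state}, "
            f"not {j}"
        )
    u = ens.channel(j, k)
    ujg = ens.channel(j, ground_index)
    n_points = ens.grid.n_points
    if n_lags is None:
        n_lags = n_points
    if n_lags > n_points:
        logger.warning(
            "requested %d lag points but trajectories hold %d; truncating",
            n_lags,
            n_points,
        )
        n_lags = n_points
    origins = _origin_indices(n_points, n_lags, origin_stride)
    beta_val = _beta(temperature)

    u2 = u**2
    logw_all = beta_val * ujg[:, origins]
    logw_all = logw_all - logw_all.max()  # global stabilization shift

    slices = _batch_slices(u.shape[0], n_batches)
    sums_a = np.empty((n_batches, n_lags))
    sums_b = np.empty((n_batches, n_lags))
    sums_d = np.empty(n_batches)
    sums_u = np.empty(n_batches)
    sums_u2 = np.empty(n_batches)
    counts = np.empty(n_batches)
    for bi, s in enumerate(slices):
        a, b, d = _weighted_sums(
            u[s], u2[s], logw_all[s], origins, n_lags, per_trajectory_weights
        )
        sums_a[bi] = a
        sums_b[bi] = b
        sums_d[bi] = d
        sums_u[bi] = u[s].sum()
        sums_u2[bi] = u2[s].sum()
        counts[bi] = u[s].size

    tot_a = sums_a.sum(axis=0)
    tot_b = sums_b.sum(axis=0)
    tot_d = sums_d.sum()
    mean_u = sums_u.sum() / counts.sum()
    mean_u2 = sums_u2.sum() / counts.sum()

    ubar = tot_a / tot_d
    usq = tot_b / tot_d
    c1 = ubar - mean_u
    c2 = usq - mean_u2

    # leave-one-batch-out replicates of everything downstream
    loo_d = tot_d - sums_d
    loo_n = counts.sum() - counts
    loo_ubar = (tot_a - sums_a) / loo_d[:, None]
    loo_usq = (tot_b - sums_b) / loo_d[:, None]
    loo_mean_u = (sums_u.sum() - sums_u) / loo_n
    loo_mean_u2 = (sums_u2.sum() - sums_u2) / loo_n
    loo_c1 = loo_ubar - loo_mean_u[:, None]
    loo_c2 = loo_usq - loo_mean_u2[:, None]
    loo_var = loo_usq - loo_ubar**2

    diag = reweighting_diagnostics(
        ens,
        j,
        temperature,
        ground_index,
        origin_stride=origin_stride,
        n_lags=n_lags,
        ess_floor=ess_floor,
    )

    # denominator diagnostic: <exp(beta dU_jg)> with fluctuations about
    # the pooled mean of U_jg; logw_all was shifted by its max, so the
    # centred value is restored in log space (capped to stay finite)
    shift = beta_val * ujg[:, origins].max() if origins.size else 0.0
    log_den = np.log(tot_d / logw_all.size) + shift - beta_val * np.mean(ujg)
    den_mean = float(np.exp(min(log_den, 700.0)))

    return TcfSeries(
        grid=TimeGrid(n_lags, ens.grid.dt),
        c1=c1,
        c2=c2,
        se_c1=_jackknife_se(loo_c1),
        se_c2=_jackknife_se(loo_c2),
        n_batches=n_batches,
        ess_fraction=diag.ess_fraction,
        numerator_c1=c1 * den_mean,
        numerator_c2=c2 * den_mean,
        denominator=den_mean,
        jk_mean=loo_ubar,
        jk_variance=loo_var,
    )


def compute_c1(ens: GapEnsemble, j: int, k: int, temperature: float,
               ground_index: int, **kwargs) -> TcfSeries:
    """First-kind TCF C1(t); see :func:`compute_tcfs` for parameters."""
    return compute_tcfs(ens, j, k, temperature, ground_index, **kwargs)


def compute_c2(ens: GapEnsemble, j: int, k: int, temperature: float,
               ground_index: int, **kwargs) -> TcfSeries:
    """Second-kind TCF C2(t); see :func:`compute_tcfs` for parameters."""
    return compute_tcfs(ens, j, k, temperature, ground_index, **kwargs)


def batch_errors(
    ens: GapEnsemble,
    j: int,
    k: int,
    temperature: float,
    ground_index: int,
    n_batches: int = 4,
    **kwargs,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-lag standard errors (se_c1, se_c2) from trajectory batches."""
    series = compute_tcfs(
        ens, j, k, temperature, ground_index, n_batches=n_batches, **kwargs
    )
    return series.se_c1, series.se_c2
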