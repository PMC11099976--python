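"""Exactly solvable multistate bath models for generating gap ensembles.

The surrogate replaces all-atom molecular dynamics with a set of
independent mass-weighted modes whose state-dependent potentials are
shifted harmonic wells,

    V_j(x, p) = sum_i [ p_i^2/2 + omega_i^2 x_i^2 / 2 - c_i^j x_i ] + eps_j,

so every energy gap U_jk = V_j - V_k = sum_i (c_i^k - c_i^j) x_i
+ eps_j - eps_k is *linear* in the coordinates and all gap statistics
are exactly Gaussian with closed-form time dependence.  Two dynamics
are supported:

* ``underdamped`` — Newtonian motion, propagated by the exact
  harmonic rotation (no integrator, no step-size error).  The gap
  mean oscillates at the mode frequencies and the gap variance is
  constant in time.
* ``overdamped`` — high-friction Langevin dynamics, propagated by the
  exact Ornstein-Uhlenbeck update.  Each mode's mean relaxes
  exponentially at rate omega_i^2/gamma_i toward the propagation
  state's minimum, emulating the monotone few-picosecond energy-gap
  relaxation of condensed-phase systems.

Units are mass-weighted: x in sqrt(eV)*ps, p in sqrt(eV),
c in sqrt(eV)/ps, omega and gamma in 1/ps, energies in eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .core import GapEnsemble, K_B, SystemSpec, TimeGrid
from .rates import MomentSeries

__all__ = [
    "HarmonicModelSpec",
    "PhasePointSet",
    "sample_equilibrium",
    "propagate_on_state",
    "generate_gap_ensemble",
    "analytic_moments",
    "analytic_equilibrium_stats",
    "model_reorganization",
    "default_triad_model",
    "displaced_overdamped_model",
]


@dataclass(frozen=True)
class HarmonicModelSpec:
    """Multistate shifted-harmonic bath.

    Parameters
    ----------
    frequencies
        Mode frequencies omega_i in ps^-1, shape ``(n_modes,)``.
    couplings
        Linear state-mode couplings c_i^j in sqrt(eV)/ps, shape
        ``(n_states, n_modes)`` with 1-based state j stored in row
        ``j - 1``.  State j's minimum along mode i is c_i^j/omega_i^2.
    offsets
        Vertical energy offsets eps_j in eV, shape ``(n_states,)``.
    temperature
        Bath temperature in K.
    dynamics
        ``"underdamped"`` (Newtonian) or ``"overdamped"`` (Langevin).
    frictions
        Friction gamma_i in ps^-1 per mode; required for overdamped
        dynamics, ignored otherwise.
    """

    frequencies: np.ndarray
    couplings: np.ndarray
    offsets: np.ndarray
    temperature: float
    dynamics: str = "underdamped"
    frictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        object.__setattr__(
            self, "couplings", np.asarray(self.couplings, dtype=float)
        )
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.frictions is not None:
            object.__setattr__(
                self, "frictions", np.asarray(self.frictions, dtype=float)
            )
        if self.frequencies.ndim != 1 or np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be a 1-d array of positive ps^-1")
        f, m = self.couplings.shape
        if m != self.n_modes:
            raise ValueError(
                f"couplings have {m} modes, frequencies {self.n_modes}"
            )
        if self.offsets.shape != (f,):
            raise ValueError("one offset per state is required")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dynamics not in ("underdamped", "overdamped"):
            raise ValueError(f"unknown dynamics mode {self.dynamics!r}")
        if self.dynamics == "overdamped":
            if self.frictions is None or np.any(self.frictions <= 0):
                raise ValueError(
                    "overdamped dynamics requires positive frictions"
                )

    @property
    def n_modes(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_states(self) -> int:
        return self.couplings.shape[0]

    @property
    def kbt(self) -> float:
        return K_B * self.temperature

    def minima(self, state: int) -> np.ndarray:
        """Equilibrium positions c_i^state/omega_i^2 (1-based state)."""
        self._check_state(state)
        return self.couplings[state - 1] / self.frequencies**2

    def relaxation_rates(self) -> np.ndarray:
        """Exponential mean-relaxation rates omega_i^2/gamma_i (overdamped)."""
        if self.frictions is None:
            raise ValueError("model has no frictions")
        return self.frequencies**2 / self.frictions

    def _check_state(self, state: int) -> None:
        if not (1 <= state <= self.n_states):
            raise ValueError(
                f"state {state} outside 1..{self.n_states}"
            )

    def gap_map(self, j: int, k: int) -> Tuple[np.ndarray, float]:
        """Slope and intercept of U_jk(x) = slope . x + const."""
        self._check_state(j)
        self._check_state(k)
        slope = self.couplings[k - 1] - self.couplings[j - 1]
        const = float(self.offsets[j - 1] - self.offsets[k - 1])
        return slope, const

    def potential(self, state: int, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Total energy on ``state`` for phase points along the last axis."""
        self._check_state(state)
        c = self.couplings[state - 1]
        w2 = self.frequencies**2
        return (
            0.5 * np.sum(p**2, axis=-1)
            + 0.5 * np.sum(w2 * x**2, axis=-1)
            - np.sum(c * x, axis=-1)
            + self.offsets[state - 1]
        )


@dataclass
class PhasePointSet:
    """Sampled phase points; ``x`` and ``p`` have shape (n, n_modes)."""

    x: np.ndarray
    p: np.ndarray
    state: int
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.x.shape[0]


def sample_equilibrium(
    model: HarmonicModelSpec, state: int, n: int, seed: int | np.random.Generator
) -> PhasePointSet:
    """Draw ``n`` phase points from the classical Boltzmann law of ``state``.

    Positions are Gaussian about the state minimum with variance
    k_B T / omega_i^2; momenta are Gaussian with variance k_B T
    (equipartition).
    """
    model._check_state(state)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xmin = model.minima(state)
    sx = np.sqrt(model.kbt) / model.frequencies
    x = xmin + sx * rng.standard_normal((n, model.n_modes))
    p = np.sqrt(model.kbt) * rng.standard_normal((n, model.n_modes))
    return PhasePointSet(
        x=x, p=p, state=state, seed=seed if isinstance(seed, int) else None
    )


def propagate_on_state(
    model: HarmonicModelSpec,
    state: int,
    points: PhasePointSet,
    grid: TimeGrid,
    rng: np.random.Generator | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Propagate phase points on ``state``; returns (x_t, p_t).

    Output arrays have shape ``(n, n_modes, n_points)``.  Underdamped
    dynamics uses the exact harmonic rotation about the state minimum;
    overdamped dynamics uses the exact Ornstein-Uhlenbeck transition
    law per grid step (both are step-size exact, so a coarse grid only
    undersamples the trajectory, it does not bias it).
    """
    model._check_state(state)
    xmin = model.minima(state)
    t = grid.times
    if model.dynamics == "underdamped":
        w = model.frequencies
        wt = w[None, :, None] * t[None, None, :]
        dx0 = (points.x - xmin)[:, :, None]
        p0 = points.p[:, :, None]
        coswt, sinwt = np.cos(wt), np.sin(wt)
        x_t = xmin[None, :, None] + dx0 * coswt + (p0 / w[None, :, None]) * sinwt
        p_t = p0 * coswt - w[None, :, None] * dx0 * sinwt
        return x_t, p_t
    if rng is None:
        raise ValueError("overdamped propagation requires an rng for the noise")
    lam = model.relaxation_rates()
    a = np.exp(-lam * grid.dt)
    svar = model.kbt / model.frequencies**2  # stationary variance per mode
    noise_sd = np.sqrt(svar * (1.0 - a**2))
    n, m = points.x.shape
    x_t = np.empty((n, m, grid.n_points))
    x = points.x.copy()
    x_t[:, :, 0] = x
    for it in range(1, grid.n_points):
        x = xmin + (x - xmin) * a + noise_sd * rng.standard_normal((n, m))
        x_t[:, :, it] = x
    p_t = np.broadcast_to(points.p[:, :, None], x_t.shape).copy()
    return x_t, p_t


def generate_gap_ensemble(
    model: HarmonicModelSpec,
    propagation_state: int,
    sampling_state: int,
    n: int,
    grid: TimeGrid,
    seed: int,
    chunk: int = 4096,
) -> GapEnsemble:
    """Sample, propagate, and record all gap channels U_jk(t), k != j.

    Initial conditions come from ``sampling_state``'s equilibrium law;
    the dynamics runs on ``propagation_state``'s surface.  Equal states
    give an equilibrium (stationary) ensemble; ``sampling_state`` equal
    to the ground state gives the nonequilibrium ensemble of a vertical
    excitation.  Channels are evaluated through the exact linear gap
    map, chunked over trajectories to bound peak memory.
    """
    model._check_state(propagation_state)
    model._check_state(sampling_state)
    j = propagation_state
    others = [k for k in range(1, model.n_states + 1) if k != j]
    maps = {k: model.gap_map(j, k) for k in others}
    channels: Dict[Tuple[int, int], np.ndarray] = {
        (j, k): np.empty((n, grid.n_points)) for k in others
    }
    rng = np.random.default_rng(seed)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        pts = sample_equilibrium(model, sampling_state, m, rng)
        x_t, _ = propagate_on_state(model, j, pts, grid, rng=rng)
        for k, (slope, const) in maps.items():
            channels[(j, k)][done : done + m] = (
                np.einsum("i,nit->nt", slope, x_t) + const
            )
        done += m
    return GapEnsemble(
        propagation_state=j,
        sampling_state=sampling_state,
        grid=grid,
        channels=channels,
        seed=seed,
    ).validate()


def analytic_moments(
    model: HarmonicModelSpec,
    j: int,
    k: int,
    grid: TimeGrid,
    sampling_state: int,
) -> MomentSeries:
    """Closed-form nonequilibrium gap moments for sampling on ``sampling_state``,
    propagation on ``j``.

    Underdamped:

        Ubar_jk(t) = sum_i (c_i^k - c_i^j) [ c_i^j/omega_i^2
                     + (c_i^g - c_i^j)/omega_i^2 * cos(omega_i t) ]
                     + eps_j - eps_k
        sigma^2(t) = sum_i (c_i^k - c_i^j)^2 k_B T / omega_i^2   (constant)

    Overdamped replaces cos(omega_i t) by exp(-(omega_i^2/gamma_i) t);
    the variance is again the constant stationary value because the
    sampling and propagation states share every mode's force constant.
    """
    slope, const = model.gap_map(j, k)
    w2 = model.frequencies**2
    cj = model.couplings[j - 1]
    cg = model.couplings[sampling_state - 1]
    t = grid.times
    if model.dynamics == "underdamped":
        relax = np.cos(model.frequencies[:, None] * t[None, :])
    else:
        relax = np.exp(-model.relaxation_rates()[:, None] * t[None, :])
    mean_x = cj[:, None] / w2[:, None] + ((cg - cj) / w2)[:, None] * relax
    mean = np.einsum("i,it->t", slope, mean_x) + const
    var = float(np.sum(slope**2 * model.kbt / w2))
    return MomentSeries(
        grid=grid,
        mean=mean,
        variance=np.full(grid.n_points, var),
        se_mean=np.zeros(grid.n_points),
        se_variance=np.zeros(grid.n_points),
    )


def analytic_equilibrium_stats(model: HarmonicModelSpec, j: int, k: int):
    """Exact equilibrium mean/variance of U_jk on state j's surface."""
    from .core import EquilibriumStats

    slope, const = model.gap_map(j, k)
    w2 = model.frequencies**2
    mean = float(np.sum(slope * model.couplings[j - 1] / w2) + const)
    var = float(np.sum(slope**2 * model.kbt / w2))
    return EquilibriumStats(
        mean_gap=mean, second_moment=var + mean**2, variance=var
    )


def model_reorganization(model: HarmonicModelSpec, j: int, k: int) -> float:
    """Reorganization energy E_r = sum_i (c_i^j - c_i^k)^2/(2 omega_i^2), eV.

    For this bath E_r satisfies sigma^2_jk = 2 k_B T E_r exactly.
    """
    dc = model.couplings[j - 1] - model.couplings[k - 1]
    return float(np.sum(dc**2 / (2.0 * model.frequencies**2)))


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def _triad_spec(couplings: np.ndarray, temperature: float) -> SystemSpec:
    return SystemSpec(
        n_states=4,
        labels=("pipi*", "CT1", "CT2", "g"),
        ground_index=4,
        couplings=couplings,
        temperature=temperature,
    )


def default_triad_model(
    dynamics: str = "underdamped", temperature: float = 300.0
) -> Tuple[SystemSpec, HarmonicModelSpec]:
    """Four-state surrogate mirroring a donor/acceptor triad topology.

    Three mutually coupled excited states (a bright local excitation
    and two charge-transfer states) plus an uncoupled ground state that
    only supplies the nonequilibrium initial nuclear distribution.
    Five modes spanning sub-ps to few-ps periods; displacements are
    kept moderate so exponential reweighting from any excited state's
    equilibrium ensemble is well conditioned, and offsets place the
    pairwise driving forces within a few reorganization energies so
    the interstate rates fall in the 1e9-1e12 s^-1 window.
    """
    w = np.array([2.0, 3.0, 4.5, 6.0, 8.0])  # ps^-1
    # dimensionless displacements d_i^j = c_i^j/omega_i (E_r = sum dd^2/2)
    d = np.array(
        [
            [0.10, 0.08, -0.06, 0.05, 0.09],
            [-0.08, 0.10, 0.07, -0.06, 0.04],
            [0.05, -0.09, 0.10, 0.08, -0.07],
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    c = d * w[None, :]
    eps = np.array([0.0, -0.04, -0.07, 0.0])
    gam = np.zeros((4, 4))
    gam[0, 1] = gam[1, 0] = -1.5e-3
    gam[0, 2] = gam[2, 0] = 7.2e-4
    gam[1, 2] = gam[2, 1] = -2.9e-3
    frictions = None
    if dynamics == "overdamped":
        # mean-relaxation rates w^2/gamma of 0.17-0.30 ps^-1 (3-6 ps decay)
        frictions = w**2 / np.array([0.30, 0.25, 0.22, 0.19, 0.17])
    model = HarmonicModelSpec(
        frequencies=w,
        couplings=c,
        offsets=eps,
        temperature=temperature,
        dynamics=dynamics,
        frictions=frictions,
    )
    return _triad_spec(gam, temperature), model


def displaced_overdamped_model(
    e_r_target: float = 0.5,
    temperature: float = 300.0,
) -> Tuple[SystemSpec, HarmonicModelSpec]:
    """Strongly displaced two-state-plus-ground diffusive surrogate.

    Tuned to condensed-phase charge-transfer scales: donor-acceptor
    reorganization energy ``e_r_target`` (eV, default 0.5), monotone
    gap relaxation over 3-6 ps, and a ground-state minimum displaced
    from the donor's so a vertical excitation starts the gap mean well
    away from its donor-equilibrium value.  Intended for direct
    (nonequilibrium-ensemble or closed-form) moment evaluation; the
    donor-ground displacement is too large for useful exponential
    reweighting, as it typically is in real condensed-phase systems.
    """
    w = np.array([2.0, 3.0, 4.5, 6.0, 8.0])
    base = np.array([0.45, -0.45, 0.45, -0.45, 0.44])
    scale = np.sqrt(2.0 * e_r_target / np.sum(base**2))
    d_acc = base * scale
    d = np.array(
        [
            np.zeros(5),  # donor at the coordinate origin
            d_acc,  # acceptor displaced to give E_r = e_r_target
            d_acc / 3.0,  # ground between the two, nearer the donor
        ]
    )
    c = d * w[None, :]
    eps = np.array([0.3, 0.0, 0.0])
    gam = np.zeros((3, 3))
    gam[0, 1] = gam[1, 0] = 1.0e-2
    frictions = w**2 / np.array([0.30, 0.25, 0.22, 0.19, 0.17])
    model = HarmonicModelSpec(
        frequencies=w,
        couplings=c,
        offsets=eps,
        temperature=temperature,
        dynamics="overdamped",
        frictions=frictions,
    )
    spec = SystemSpec(
        n_states=3,
        labels=("D", "A", "g"),
        ground_index=3,
        couplings=gam,
        temperature=temperature,
    )
    return spec, model
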