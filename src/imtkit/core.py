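"""Shared domain types, physical constants, and validation.

Conventions used across the package:

* Energies are in eV, time in ps, rate coefficients in s^-1 (the
  ps^-1 -> s^-1 conversion happens exactly once, in :mod:`imtkit.rates`).
* Electronic state indices are 1-based everywhere the user sees them,
  matching the convention of labelling states j = 1..F with the ground
  state as one of them.
* The energy gap for transition j -> k is U_jk = V_j - V_k (initial
  minus final), so a *positive* equilibrium gap on the initial state
  means the transition is downhill in free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "K_B",
    "HBAR",
    "PS_PER_S",
    "beta",
    "SystemSpec",
    "TimeGrid",
    "GapEnsemble",
    "EquilibriumStats",
    "validate_spec",
    "list_transitions",
]

#: Boltzmann constant in eV/K.
K_B: float = 8.617333262e-5

#: Reduced Planck constant in eV*s.
HBAR: float = 6.582119569e-16

#: Number of picoseconds per second (rate conversion factor).
PS_PER_S: float = 1.0e12


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in eV^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature} K")
    return 1.0 / (K_B * temperature)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid starting at t = 0.

    Parameters
    ----------
    n_points
        Number of grid points, at least 2.
    dt
        Spacing in ps, strictly positive.
    """

    n_points: int
    dt: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        """Grid times in ps, shape ``(n_points,)``."""
        return np.arange(self.n_points) * self.dt

    @property
    def span(self) -> float:
        """Total span of the grid in ps."""
        return (self.n_points - 1) * self.dt

    def truncated(self, n_points: int) -> "TimeGrid":
        return TimeGrid(n_points=n_points, dt=self.dt)


@dataclass(frozen=True)
class SystemSpec:
    """Multistate electronic system: states, couplings, temperature.

    ``couplings[j-1, k-1]`` is the Condon (configuration-independent)
    electronic coupling Gamma_jk in eV; the matrix must be symmetric
    with a zero diagonal.  ``ground_index`` is the 1-based index of the
    electronic ground state used for nonequilibrium initial sampling.
    """

    n_states: int
    labels: Tuple[str, ...]
    ground_index: int
    couplings: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(
            self, "couplings", np.asarray(self.couplings, dtype=float)
        )

    @property
    def beta(self) -> float:
        """1/(k_B T) in eV^-1."""
        return beta(self.temperature)

    def coupling(self, j: int, k: int) -> float:
        """Gamma_jk in eV for 1-based state indices."""
        return float(self.couplings[j - 1, k - 1])

    def label(self, j: int) -> str:
        return self.labels[j - 1]


def validate_spec(spec: SystemSpec) -> SystemSpec:
    """Check all :class:`SystemSpec` invariants; return the spec unchanged.

    Raises
    ------
    ValueError
        Naming the violated invariant: state count/label mismatch,
        asymmetric couplings, nonzero coupling diagonal, nonpositive
        temperature, or an out-of-range ground index.
    """
    f = spec.n_states
    if f < 2:
        raise ValueError(f"n_states must be >= 2, got {f}")
    if len(spec.labels) != f:
        raise ValueError(
            f"expected {f} state labels, got {len(spec.labels)}"
        )
    if len(set(spec.labels)) != f:
        raise ValueError("state labels must be distinct")
    if not (1 <= spec.ground_index <= f):
        raise ValueError(
            f"ground_index {spec.ground_index} outside 1..{f}"
        )
    g = spec.couplings
    if g.shape != (f, f):
        raise ValueError(
            f"couplings must be {f}x{f}, got shape {g.shape}"
        )
    if not np.all(np.isfinite(g)):
        raise ValueError("couplings contain non-finite entries")
    if not np.allclose(g, g.T, rtol=0.0, atol=0.0):
        bad = np.argwhere(g != g.T)[0] + 1
        raise ValueError(
            f"asymmetric couplings: Gamma_{bad[0]}{bad[1]} != "
            f"Gamma_{bad[1]}{bad[0]}"
        )
    if np.any(np.diag(g) != 0.0):
        raise ValueError("coupling diagonal must be zero")
    if spec.temperature <= 0:
        raise ValueError(
            f"temperature must be positive, got {spec.temperature} K"
        )
    return spec


def list_transitions(spec: SystemSpec) -> List[Tuple[int, int]]:
    """Ordered (j, k) pairs with j != k and Gamma_jk != 0, 1-based.

    Both directions of every coupled pair appear exactly once; pairs
    with zero coupling carry no transition pathway and are excluded.
    """
    validate_spec(spec)
    out: List[Tuple[int, int]] = []
    for j in range(1, spec.n_states + 1):
        for k in range(1, spec.n_states + 1):
            if j != k and spec.couplings[j - 1, k - 1] != 0.0:
                out.append((j, k))
    return out


@dataclass
class GapEnsemble:
    """Ensemble of energy-gap trajectories on a common time grid.

    ``channels[(j, k)]`` holds U_jk(t) in eV with shape
    ``(n_traj, n_points)``.  ``propagation_state`` is the electronic
    state whose surface generated the nuclear dynamics;
    ``sampling_state`` is the state whose equilibrium distribution
    supplied the initial conditions (equal to ``propagation_state``
    for equilibrium ensembles, to the ground state for nonequilibrium
    ones).
    """

    propagation_state: int
    sampling_state: int
    grid: TimeGrid
    channels: Dict[Tuple[int, int], np.ndarray]
    seed: int | None = None

    @property
    def n_traj(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def is_equilibrium(self) -> bool:
        return self.sampling_state == self.propagation_state

    def channel(self, j: int, k: int) -> np.ndarray:
        try:
            return self.channels[(j, k)]
        except KeyError:
            raise KeyError(
                f"ensemble has no gap channel U_{j}{k}; available: "
                f"{sorted(self.channels)}"
            ) from None

    def validate(self) -> "GapEnsemble":
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent channel shapes: {shapes}")
        (shape,) = shapes
        if shape[1] != self.grid.n_points:
            raise ValueError(
                f"channels have {shape[1]} time points, grid has "
                f"{self.grid.n_points}"
            )
        for key, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel U_{key[0]}{key[1]} has non-finite values")
        return self

    def consistency_residual(self, g: int) -> float:
        """Max |U_jk - (U_jg - U_kg)| over channels where all three exist.

        The gap channels derive from per-state potentials, so wherever
        U_jk, U_jg and U_kg are all recorded the identity
        U_jk = U_jg - U_kg must hold up to floating-point error.
        """
        worst = 0.0
        for (j, k) in self.channels:
            if k == g or j == g:
                continue
            if (j, g) in self.channels and (k, g) in self.channels:
                r = np.max(
                    np.abs(
                        self.channels[(j, k)]
                        - (self.channels[(j, g)] - self.channels[(k, g)])
                    )
                )
                worst = max(worst, float(r))
        return worst


@dataclass(frozen=True)
class EquilibriumStats:
    """Equilibrium moments of one gap channel U_jk on the initial state.

    ``variance`` is the centred second moment
    ``second_moment - mean_gap**2``; estimator round-off can make the
    stored fields disagree at machine precision, so the invariant is
    enforced up to a small tolerance at construction.
    """

    mean_gap: float
    second_moment: float
    variance: float
    se_mean: float = 0.0
    se_second_moment: float = 0.0

    def __post_init__(self) -> None:
        if self.variance < -1e-12:
            raise ValueError(f"negative variance {self.variance}")
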