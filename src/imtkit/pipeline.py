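"""End-to-end orchestration: ensembles -> TCFs -> rates -> populations.

For every coupled ordered transition j -> k the pipeline takes the
equilibrium ensemble on state j, estimates the equilibrium gap
statistics and the two nonlinear-response TCFs, converts them to
nonequilibrium moments and IMT rate coefficients, and finally
integrates the Pauli master equations with all pairwise rates.  All
stage outputs are written as TSV tables with provenance headers plus
one machine-readable YAML summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GapEnsemble, SystemSpec, list_transitions, validate_spec
from .io import RunConfig, read_gap_ensemble, write_gap_ensemble, write_table
from .kinetics import RateMatrixSeries, integrate_populations
from .rates import (
    FreeEnergySeries,
    MomentSeries,
    RateSeries,
    free_energy_decomposition,
    imt_rate_series,
    marcus_rate,
    moments_from_tcf,
    reorganization_from_variance,
)
from .surrogate import generate_gap_ensemble
from .tcf import TcfSeries, compute_tcfs, equilibrium_stats

__all__ = ["TransitionResult", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("imtkit")


@dataclass
class TransitionResult:
    transition: Tuple[int, int]
    stats: object
    tcf: TcfSeries
    moments: MomentSeries
    free_energy: FreeEnergySeries
    rates: RateSeries


@dataclass
class PipelineResult:
    config: RunConfig
    transitions: Dict[Tuple[int, int], TransitionResult]
    populations: object
    summary: dict
    outdir: Path | None = None


def _state_seeds(seed: int, n_states: int) -> List[int]:
    """Independent per-state integer seeds derived from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n_states)
    return [int(s % 2**31) for s in state]


def build_ensembles(config: RunConfig) -> Dict[int, GapEnsemble]:
    """Equilibrium ensemble per propagation state, generated or loaded."""
    spec = validate_spec(config.system)
    states = sorted({j for j, _ in list_transitions(spec)})
    seeds = _state_seeds(config.seed, spec.n_states)
    out: Dict[int, GapEnsemble] = {}
    for j in states:
        if config.model is not None:
            out[j] = generate_gap_ensemble(
                config.model,
                propagation_state=j,
                sampling_state=j,
                n=config.n_traj,
                grid=config.grid,
                seed=seeds[j - 1],
            )
        else:
            paths = (config.ensemble_paths or {}).get(j)
            if not paths:
                raise ValueError(
                    f"no ensemble files configured for propagation state {j}"
                )
            ens = read_gap_ensemble(paths, propagation_state=j, sampling_state=j)
            if (j, spec.ground_index) not in ens.channels:
                raise ValueError(
                    f"ensemble for state {j} lacks the reweighting channel "
                    f"U_{j}_{spec.ground_index}"
                )
            out[j] = ens
    return out


def analyze_transition(
    config: RunConfig, ens: GapEnsemble, j: int, k: int
) -> TransitionResult:
    """Full estimator chain for one transition on one EMD ensemble."""
    spec = config.system
    stats = equilibrium_stats(ens, j, k, n_batches=config.n_batches)
    tcf = compute_tcfs(
        ens,
        j,
        k,
        temperature=spec.temperature,
        ground_index=spec.ground_index,
        n_lags=config.n_lags,
        origin_stride=config.origin_stride,
        n_batches=config.n_batches,
        ess_floor=config.ess_floor,
        per_trajectory_weights=config.per_trajectory_weights,
    )
    moments = moments_from_tcf(stats, tcf)
    fes = free_energy_decomposition(moments, spec.temperature)
    rates = imt_rate_series(
        spec.coupling(j, k),
        moments,
        transition=(j, k),
        temperature=spec.temperature,
        plateau_window=config.plateau_window,
    )
    return TransitionResult(
        transition=(j, k),
        stats=stats,
        tcf=tcf,
        moments=moments,
        free_energy=fes,
        rates=rates,
    )


def _tcf_frame(res: TransitionResult) -> pd.DataFrame:
    t = res.tcf.grid.times
    return pd.DataFrame(
        {
            "time_ps": t,
            "c1_eV": res.tcf.c1,
            "se_c1": res.tcf.se_c1 if res.tcf.se_c1 is not None else np.zeros_like(t),
            "c2_eV2": res.tcf.c2,
            "se_c2": res.tcf.se_c2 if res.tcf.se_c2 is not None else np.zeros_like(t),
        }
    )


def _rate_frame(res: TransitionResult) -> pd.DataFrame:
    t = res.moments.grid.times
    return pd.DataFrame(
        {
            "time_ps": t,
            "mean_eV": res.moments.mean,
            "var_eV2": res.moments.variance,
            "k_per_s": res.rates.k,
            "Ea_eV": res.free_energy.e_a,
            "dE_eV": res.free_energy.delta_e,
            "Er_eV": res.free_energy.e_r,
        }
    )


def run_pipeline(config: RunConfig, outdir: Path | str | None = None) -> PipelineResult:
    """Run the complete analysis; write all artifacts when ``outdir`` given.

    Artifacts: ``tcf_<j>_<k>.tsv`` and ``rates_<j>_<k>.tsv`` per coupled
    ordered transition, ``populations.tsv``, and ``summary.yaml``.
    Failures name the transition being processed.
    """
    spec = validate_spec(config.system)
    transitions = list_transitions(spec)
    ensembles = build_ensembles(config)

    results: Dict[Tuple[int, int], TransitionResult] = {}
    for (j, k) in transitions:
        try:
            results[(j, k)] = analyze_transition(config, ensembles[j], j, k)
        except Exception as exc:
            raise RuntimeError(
                f"transition {spec.label(j)} -> {spec.label(k)} "
                f"({j} -> {k}) failed: {exc}"
            ) from exc
        logger.info(
            "transition %d->%d: plateau %.4g s^-1, Marcus %.4g s^-1, "
            "ESS fraction %.3g",
            j,
            k,
            results[(j, k)].rates.plateau,
            results[(j, k)].rates.marcus,
            results[(j, k)].tcf.ess_fraction,
        )

    populations = None
    if transitions:
        matrix = RateMatrixSeries.from_rate_series(
            spec.n_states, [r.rates for r in results.values()]
        )
        populations = integrate_populations(matrix, config.p0, config.t_end)
    else:
        from .kinetics import PopulationTrajectory, default_output_times

        t = default_output_times(config.t_end)
        populations = PopulationTrajectory(
            times=t,
            populations=np.tile(
                np.asarray(config.p0, dtype=float)[:, None], (1, len(t))
            ),
        )

    summary = {
        "imtkit_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash,
        "temperature_K": spec.temperature,
        "transitions": {
            f"{j}->{k}": {
                "labels": f"{spec.label(j)}->{spec.label(k)}",
                "gamma_eV": spec.coupling(j, k),
                "mean_gap_eV": res.stats.mean_gap,
                "variance_eV2": res.stats.variance,
                "e_r_eV": float(
                    reorganization_from_variance(res.stats.variance, spec.temperature)
                ),
                "plateau_per_s": res.rates.plateau,
                "marcus_per_s": res.rates.marcus,
                "ess_fraction": res.tcf.ess_fraction,
            }
            for (j, k), res in results.items()
        },
    }

    out = PipelineResult(
        config=config,
        transitions=results,
        populations=populations,
        summary=summary,
        outdir=Path(outdir) if outdir is not None else None,
    )
    if outdir is not None:
        _write_artifacts(out)
    return out


def _write_artifacts(result: PipelineResult) -> None:
    outdir = result.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    config = result.config
    meta = {"config_hash": config.hash, "seed": config.seed}
    for (j, k), res in result.transitions.items():
        write_table(_tcf_frame(res), outdir / f"tcf_{j}_{k}.tsv", meta)
        write_table(_rate_frame(res), outdir / f"rates_{j}_{k}.tsv", meta)
    pops = result.populations
    cols = {"time_ps": pops.times}
    for j in range(1, config.system.n_states + 1):
        cols[f"P_{j}"] = pops.populations[j - 1]
    write_table(pd.DataFrame(cols), outdir / "populations.tsv", meta)
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(result.summary, fh, sort_keys=False)
    logger.info("artifacts written to %s", outdir)
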