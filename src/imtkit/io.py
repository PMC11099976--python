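"""Delimited-text interchange formats and run configuration.

Gap ensembles, TCFs, rate series and populations are exchanged as
tab-separated text with a header row; energy-gap columns are named
``U_<j>_<k>_eV`` and times ``time_ps``.  Every table written by the
package carries provenance comment lines (``# key: value``) recording
the config hash, seed and code version, so a run can be re-identified
from any of its outputs.

The run configuration is a YAML document with four blocks — system,
data, estimator, kinetics — validated into a :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GapEnsemble, SystemSpec, TimeGrid, validate_spec
from .surrogate import (
    HarmonicModelSpec,
    default_triad_model,
    displaced_overdamped_model,
)

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_gap_ensemble",
    "read_gap_ensemble",
    "write_table",
    "read_table",
]

_CHANNEL_RE = re.compile(r"^U_(\d+)_(\d+)_eV$")


def config_hash(raw: dict) -> str:
    """Short stable hash of a config dict (canonical JSON, sha256)."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(meta: Dict[str, object]) -> str:
    lines = [f"# {k}: {str(v).replace(chr(10), ' ')}" for k, v in meta.items()]
    lines.insert(0, f"# imtkit_version: {__version__}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: Path | str, meta: Dict[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with provenance comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta or {}))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path: Path | str) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a TSV table, returning (frame, provenance metadata)."""
    path = Path(path)
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_gap_ensemble(
    ens: GapEnsemble, path: Path | str, meta: Dict[str, object] | None = None
) -> None:
    """Write an ensemble as one concatenated TSV with a ``traj`` column."""
    frames = []
    times = ens.grid.times
    for i in range(ens.n_traj):
        cols = {"traj": np.full(ens.grid.n_points, i), "time_ps": times}
        for (j, k), arr in sorted(ens.channels.items()):
            cols[f"U_{j}_{k}_eV"] = arr[i]
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    all_meta = {
        "propagation_state": ens.propagation_state,
        "sampling_state": ens.sampling_state,
    }
    if ens.seed is not None:
        all_meta["seed"] = ens.seed
    all_meta.update(meta or {})
    write_table(df, path, all_meta)


def _parse_one_file(path: Path) -> Tuple[pd.DataFrame, Dict[str, str]]:
    try:
        df, meta = read_table(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse gap table: {exc}") from exc
    if "time_ps" not in df.columns:
        raise ValueError(f"{path}: missing required column time_ps")
    channel_cols = [c for c in df.columns if _CHANNEL_RE.match(c)]
    if not channel_cols:
        raise ValueError(f"{path}: no gap channel columns (U_<j>_<k>_eV)")
    for col in ["time_ps", *channel_cols]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            # +2: one for the header row, one for 1-based line numbers
            n_meta = len(meta) + 1
            raise ValueError(
                f"{path}: non-numeric or non-finite value in column {col} "
                f"at data row {bad[0] + 1} (file line ~{bad[0] + n_meta + 2})"
            )
        df[col] = vals
    return df, meta


def read_gap_ensemble(
    paths: Sequence[Path | str],
    propagation_state: int | None = None,
    sampling_state: int | None = None,
) -> GapEnsemble:
    """Load a gap ensemble from one or more TSV files.

    Each file holds either one trajectory or several stacked under a
    ``traj`` column.  All trajectories must share the same time grid.
    Propagation/sampling states default to the provenance headers of
    the first file.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no ensemble files given")
    traj_frames: List[pd.DataFrame] = []
    meta0: Dict[str, str] = {}
    for path in paths:
        df, meta = _parse_one_file(path)
        if not meta0:
            meta0 = meta
        if "traj" in df.columns:
            for _, sub in df.groupby("traj", sort=True):
                traj_frames.append(sub.drop(columns="traj").reset_index(drop=True))
        else:
            traj_frames.append(df)

    times0 = traj_frames[0]["time_ps"].to_numpy()
    if len(times0) < 2:
        raise ValueError("trajectories need at least two time points")
    dts = np.diff(times0)
    if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
        raise ValueError("time grid is not uniform")
    grid = TimeGrid(n_points=len(times0), dt=float(dts[0]))

    channel_cols = [c for c in traj_frames[0].columns if _CHANNEL_RE.match(c)]
    channels: Dict[Tuple[int, int], np.ndarray] = {}
    for col in channel_cols:
        m = _CHANNEL_RE.match(col)
        key = (int(m.group(1)), int(m.group(2)))
        rows = []
        for i, tf in enumerate(traj_frames):
            if not np.allclose(tf["time_ps"].to_numpy(), times0, rtol=1e-8, atol=1e-12):
                raise ValueError(
                    f"trajectory {i} has a different (ragged) time grid"
                )
            if col not in tf.columns:
                raise ValueError(f"trajectory {i} is missing channel {col}")
            rows.append(tf[col].to_numpy())
        channels[key] = np.array(rows)

    if propagation_state is None:
        propagation_state = int(meta0.get("propagation_state", 0)) or None
    if propagation_state is None:
        raise ValueError(
            "propagation_state not given and not recorded in file headers"
        )
    if sampling_state is None:
        sampling_state = int(meta0.get("sampling_state", propagation_state))
    return GapEnsemble(
        propagation_state=propagation_state,
        sampling_state=sampling_state,
        grid=grid,
        channels=channels,
    ).validate()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated run configuration.

    Either ``model`` (surrogate generation) or ``ensemble_paths``
    (pre-computed gap tables, keyed by propagation state) supplies the
    equilibrium data.
    """

    system: SystemSpec
    seed: int
    grid: TimeGrid
    n_traj: int
    model: HarmonicModelSpec | None = None
    ensemble_paths: Dict[int, List[str]] | None = None
    # estimator block
    origin_stride: int = 1
    n_lags: int | None = None
    n_batches: int = 4
    ess_floor: float = 0.05
    per_trajectory_weights: bool = False
    # kinetics block
    p0: Tuple[float, ...] = ()
    t_end: float = 50.0
    extension_policy: str = "hold_plateau"
    plateau_window: float | None = None
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def _build_system(block: dict) -> SystemSpec:
    labels = tuple(block["labels"])
    spec = SystemSpec(
        n_states=len(labels),
        labels=labels,
        ground_index=int(block["ground_index"]),
        couplings=np.asarray(block["couplings_eV"], dtype=float),
        temperature=float(block["temperature_K"]),
    )
    return validate_spec(spec)


def _build_model(block: dict, temperature: float) -> HarmonicModelSpec:
    kind = block.get("kind", "custom")
    dynamics = block.get("dynamics", "underdamped")
    if kind == "default_triad":
        _, model = default_triad_model(dynamics=dynamics, temperature=temperature)
        return model
    if kind == "displaced_overdamped":
        _, model = displaced_overdamped_model(temperature=temperature)
        return model
    if kind != "custom":
        raise ValueError(f"unknown surrogate kind {kind!r}")
    frictions = block.get("frictions_per_ps")
    return HarmonicModelSpec(
        frequencies=np.asarray(block["frequencies_per_ps"], dtype=float),
        couplings=np.asarray(block["couplings_sqrt_eV_per_ps"], dtype=float),
        offsets=np.asarray(block["offsets_eV"], dtype=float),
        temperature=temperature,
        dynamics=dynamics,
        frictions=None if frictions is None else np.asarray(frictions, dtype=float),
    )


def load_config(path: Path | str) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("system", "data"):
        if key not in raw:
            raise ValueError(f"{path}: missing required block {key!r}")
    system = _build_system(raw["system"])
    data = raw["data"]
    seed = int(data.get("seed", 0))
    gridblock = data.get("grid", {})
    grid = TimeGrid(
        n_points=int(gridblock.get("n_points", 201)),
        dt=float(gridblock.get("dt_ps", 0.02)),
    )
    n_traj = int(data.get("n_traj", 1000))
    model = None
    ensemble_paths = None
    if "surrogate" in data:
        model = _build_model(data["surrogate"], system.temperature)
        if model.n_states != system.n_states:
            raise ValueError(
                f"surrogate model has {model.n_states} states, system "
                f"block has {system.n_states}"
            )
    elif "ensembles" in data:
        ensemble_paths = {
            int(j): [str(Path(path).parent / p) for p in plist]
            for j, plist in data["ensembles"].items()
        }
    else:
        raise ValueError(
            f"{path}: data block needs either 'surrogate' or 'ensembles'"
        )
    est = raw.get("estimator", {})
    kin = raw.get("kinetics", {})
    p0 = tuple(float(x) for x in kin.get("p0", ()))
    if not p0:
        p0 = tuple(
            1.0 if i == 0 else 0.0 for i in range(system.n_states)
        )
    return RunConfig(
        system=system,
        seed=seed,
        grid=grid,
        n_traj=n_traj,
        model=model,
        ensemble_paths=ensemble_paths,
        origin_stride=int(est.get("origin_stride", 1)),
        n_lags=(int(est["n_lags"]) if "n_lags" in est else None),
        n_batches=int(est.get("n_batches", 4)),
        ess_floor=float(est.get("ess_floor", 0.05)),
        per_trajectory_weights=bool(est.get("per_trajectory_weights", False)),
        p0=p0,
        t_end=float(kin.get("t_end_ps", 50.0)),
        extension_policy=str(kin.get("extension", "hold_plateau")),
        plateau_window=(
            float(kin["plateau_window_ps"]) if "plateau_window_ps" in kin else None
        ),
        raw=raw,
    )
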