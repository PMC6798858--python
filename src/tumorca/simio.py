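"""Configuration, run drivers, metrics/snapshot writers and parameter sweeps.

Formats: JSON config in; CSV metrics and CSV/PGM lattice snapshots out.
A metrics CSV has one row per step with the fixed header
``step,live_cells,processed,cumulative_processed,region_counts,seam_rows,
moves_started,moves_active,moves_completed`` (the two list-valued columns
are ``;``-joined; sequential runs leave them empty).  A snapshot CSV is
the raw 0/1 occupancy grid, one lattice row per line; the optional PGM
variant is plain ``P2`` with maxval 1 for quick visual inspection.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fast import run_fast
from .metrics import StepMetrics
from .model import Lattice, ModelParams
from .parallel import init_parallel, parallel_step
from .partition import region_counts as _region_counts
from .sequential import init_state, step_oracle, step_sequential

__all__ = [
    "SimConfig",
    "StepMetrics",
    "load_config",
    "save_config",
    "run_config",
    "write_metrics",
    "write_snapshot",
    "write_snapshot_pgm",
    "read_snapshot",
    "sweep_rho",
    "sweep_threads",
]

ENGINES = ("sequential", "oracle", "parallel", "fast")

SeedsSpec = Union[str, list[tuple[int, int]]]


@dataclass
class SimConfig:
    """One simulation's full configuration; defaults give the reference
    parameterization on a 200x200 lattice seeded at the center."""

    n_rows: int = 200
    n_cols: int = 200
    seeds: SeedsSpec = "center"
    params: ModelParams = field(default_factory=ModelParams)
    engine: str = "sequential"
    t: int = 1
    rho: float = 10.0
    n_steps: int = 200
    seed: int = 0
    out_dir: Optional[str] = None
    snapshot_interval: int = 0  # 0 disables snapshots

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}, got {self.engine!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.t < 1:
            raise ValueError("worker count t must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0 (percent threshold)")
        if self.snapshot_interval < 0:
            raise ValueError("snapshot_interval must be >= 0")
        if self.engine == "parallel" and self.n_rows < 3 * self.params.delta * self.t:
            raise ValueError(
                "lattice height too small for the requested worker count: "
                f"needs >= 3 * delta * t = {3 * self.params.delta * self.t} rows"
            )
        self.seed_positions()  # validates the seeds spec

    def seed_positions(self) -> list[tuple[int, int]]:
        if self.seeds == "center":
            return [(self.n_rows // 2, self.n_cols // 2)]
        if isinstance(self.seeds, str):
            raise ValueError(f"seeds must be 'center' or a position list, got {self.seeds!r}")
        positions = [(int(r), int(c)) for r, c in self.seeds]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate seed positions")
        for r, c in positions:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"seed ({r}, {c}) outside the lattice")
        return positions

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        if not isinstance(self.seeds, str):
            d["seeds"] = [list(p) for p in self.seeds]
        return d


def load_config(path: Union[str, Path]) -> SimConfig:
    """Parse a JSON config file; missing fields fall back to the defaults
    (an empty file is an all-defaults config)."""
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ValueError("config must be a JSON object")
    params = ModelParams(**data.pop("params", {}))
    seeds = data.pop("seeds", "center")
    if not isinstance(seeds, str):
        seeds = [tuple(p) for p in seeds]
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(params=params, seeds=seeds, **data)


def save_config(config: SimConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def write_metrics(series: Sequence[StepMetrics], path: Union[str, Path]) -> None:
    df = pd.DataFrame([m.as_row() for m in series], columns=list(StepMetrics.COLUMNS))
    df.to_csv(path, index=False)


def write_snapshot(lattice: Lattice, path: Union[str, Path]) -> None:
    np.savetxt(path, lattice.occupancy, fmt="%d", delimiter=",")


def write_snapshot_pgm(lattice: Lattice, path: Union[str, Path]) -> None:
    occ = lattice.occupancy
    lines = [f"P2", f"{occ.shape[1]} {occ.shape[0]}", "1"]
    lines += [" ".join(map(str, row)) for row in occ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path: Union[str, Path]) -> np.ndarray:
    return np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)


def run_config(config: SimConfig) -> tuple[int, list[StepMetrics]]:
    """Run one simulation as configured; returns the final live-cell count
    and the per-step metrics.  Writes ``metrics.csv`` (and snapshots, if
    an interval is set) into ``out_dir`` when given."""
    seeds = config.seed_positions()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    metrics: list[StepMetrics] = []

    def snapshot(step: int, lattice: Lattice) -> None:
        if out_dir and config.snapshot_interval and step % config.snapshot_interval == 0:
            write_snapshot(lattice, out_dir / f"snapshot_{step:06d}.csv")
            write_snapshot_pgm(lattice, out_dir / f"snapshot_{step:06d}.pgm")

    if config.engine == "fast":
        result = run_fast(
            config.n_rows, config.n_cols, seeds, config.params, config.n_steps,
            config.seed,
        )
        cumulative = 0
        for i in range(config.n_steps):
            cumulative += int(result.processed[i])
            metrics.append(
                StepMetrics(i + 1, int(result.live[i]), int(result.processed[i]), cumulative)
            )
        final_lattice = Lattice(config.n_rows, config.n_cols)
        final_lattice.occupancy = result.occupancy
        final = result.final_size
    elif config.engine == "parallel":
        sim = init_parallel(
            config.n_rows, config.n_cols, seeds, config.params, config.t,
            config.rho, config.seed,
        )
        for step in range(config.n_steps):
            metrics.append(parallel_step(sim))
            snapshot(step + 1, sim.lattice)
        final_lattice = sim.lattice
        final = sim.lattice.census()
    else:
        step_fn = step_oracle if config.engine == "oracle" else step_sequential
        state = init_state(
            config.n_rows, config.n_cols, seeds, config.params, config.seed
        )
        cumulative = 0
        for step in range(config.n_steps):
            processed = len(state.current_list)
            cumulative += processed
            state = step_fn(state)
            metrics.append(
                StepMetrics(state.step_index, len(state.current_list), processed, cumulative)
            )
            snapshot(step + 1, state.lattice)
        final_lattice = state.lattice
        final = state.lattice.census()

    if out_dir:
        write_metrics(metrics, out_dir / "metrics.csv")
        write_snapshot(final_lattice, out_dir / "final_snapshot.csv")
    return final, metrics


def _derived_seeds(master_seed: int, n: int, stream: int = 0) -> list[int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _balance(m: StepMetrics) -> float:
    counts = m.region_counts
    if not counts:
        return 1.0
    return max(counts) / max(min(counts), 1)


def _sweep(base: SimConfig, key: str, values: Sequence, repeats: int) -> pd.DataFrame:
    rows = []
    for grid_index, value in enumerate(values):
        seeds = _derived_seeds(base.seed, repeats, stream=grid_index)
        finals, processed, rates, balances = [], [], [], []
        for s in seeds:
            cfg = dataclasses.replace(base, seed=s, out_dir=None, **{key: value})
            t0 = time.perf_counter()
            final, metrics = run_config(cfg)
            elapsed = max(time.perf_counter() - t0, 1e-9)
            total = metrics[-1].cumulative_processed if metrics else 0
            finals.append(final)
            processed.append(total)
            rates.append(total / elapsed)
            balances.append(_balance(metrics[-1]) if metrics else 1.0)
        rows.append(
            {
                key: value,
                "repeats": repeats,
                "final_size_mean": float(np.mean(finals)),
                "final_size_sd": float(np.std(finals, ddof=1)) if repeats > 1 else 0.0,
                "processed_mean": float(np.mean(processed)),
                "processed_sd": float(np.std(processed, ddof=1)) if repeats > 1 else 0.0,
                "cells_per_sec_mean": float(np.mean(rates)),
                "balance_mean": float(np.mean(balances)),
            }
        )
    return pd.DataFrame(rows)


def sweep_rho(base: SimConfig, rho_values: Sequence[float], repeats: int) -> pd.DataFrame:
    """Average outcome of ``repeats`` seeded parallel runs per imbalance
    threshold.  ``balance_mean`` is the final-step max/min region-count
    ratio; the processed-per-second column is informational only (it
    measures this host, not the model)."""
    base = dataclasses.replace(base, engine="parallel")
    return _sweep(base, "rho", list(rho_values), repeats)


def sweep_threads(base: SimConfig, t_values: Sequence[int], repeats: int) -> pd.DataFrame:
    """Average outcome of ``repeats`` seeded parallel runs per worker count."""
    base = dataclasses.replace(base, engine="parallel")
    return _sweep(base, "t", [int(v) for v in t_values], repeats)
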