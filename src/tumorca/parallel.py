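"""Phase-ordered parallel engine over the seam partition.

One worker owns each region.  A step runs three phases in strict order —
bottom seam parts, then centers, then top seam parts — with a full
barrier between phases: within a phase every worker consumes its
region's current list for that part type, and each surviving record
(and any daughter) is appended to the next list of the subregion that
contains its possibly-new position under the *current* geometry.  The
part-height and spacing invariants of :mod:`tumorca.partition` guarantee
that no two workers ever append to the same next list within a phase,
so no locking is needed; a debug mode tags every append with its writer
and raises on a conflict.

After the third phase the coordinator records metrics, starts and
advances seam moves, and swaps the current/next lists.  Seam moves do
not relabel cells — a cell is processed from whatever list it is on and
its output re-routed by the geometry of the moment (lazy
reconciliation).

The engine is realized serially (workers executed in index order inside
each phase), which satisfies the same post-conditions as a truly
threaded realization — the phase barriers make worker interleaving
within a phase unobservable — while keeping runs exactly reproducible:
each worker draws from its own stream derived from
``(master seed, region index, step)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .metrics import StepMetrics
from .model import CellRecord, Lattice, ModelParams, apply_fate, evaluate_cell
from .partition import (
    PART_NAMES,
    Partition,
    advance_seam_moves,
    initial_partition,
    region_counts,
    start_moves,
)
from .sequential import init_state, run as run_sequential

__all__ = [
    "ParallelSimulation",
    "OwnershipViolation",
    "init_parallel",
    "parallel_step",
    "run_parallel",
    "equivalence_check",
    "EquivalenceResult",
]

PHASE_ORDER = ("bottom", "center", "top")


class OwnershipViolation(AssertionError):
    """Two workers appended to the same next list within one phase."""


def _worker_rng(master_seed: int, region_index: int, step: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(region_index, step))
    )


@dataclass
class ParallelSimulation:
    """State of a partitioned run between steps."""

    lattice: Lattice
    params: ModelParams
    partition: Partition
    master_seed: int
    step_index: int = 0
    cumulative_processed: int = 0
    debug: bool = False

    def live_cells(self) -> list[CellRecord]:
        cells: list[CellRecord] = []
        for region in self.partition.regions:
            for part in PART_NAMES:
                cells.extend(region.current[part])
                cells.extend(region.next[part])
        return cells

    def census_consistent(self) -> bool:
        cells = self.live_cells()
        positions = {(c.row, c.col) for c in cells}
        return (
            len(positions) == len(cells)
            and self.lattice.census() == len(cells)
            and all(self.lattice.occupancy[c.row, c.col] for c in cells)
        )


def init_parallel(
    n_rows: int,
    n_cols: int,
    seeds: Sequence[tuple[int, int]],
    params: ModelParams,
    t: int,
    rho: float,
    seed: int,
    debug: bool = False,
) -> ParallelSimulation:
    """Build the lattice, the initial partition around the seed mass, and
    the per-subregion cell lists."""
    if not seeds:
        raise ValueError("parallel runs need at least one seed cell")
    state = init_state(n_rows, n_cols, seeds, params, seed)
    seed_rows = [r for r, _ in seeds]
    partition = initial_partition(
        min(seed_rows), max(seed_rows), t, params.delta, n_rows, rho
    )
    partition.distribute(state.current_list)
    return ParallelSimulation(state.lattice, params, partition, int(seed), debug=debug)


def parallel_step(sim: ParallelSimulation) -> StepMetrics:
    """Advance one step: three part-type phases, then the coordinator."""
    partition = sim.partition
    regions = partition.regions
    rngs = [
        _worker_rng(sim.master_seed, i, sim.step_index) for i in range(len(regions))
    ]
    processed = 0

    for phase in PHASE_ORDER:
        owners: dict[tuple[int, str], int] = {}
        for worker, region in enumerate(regions):  # barrier between phases
            batch = region.current[phase]
            if not batch:
                continue
            region.current[phase] = []
            rng = rngs[worker]
            for cell in batch:
                processed += 1
                fate = evaluate_cell(cell, sim.lattice, sim.params, rng)
                for rec in apply_fate(cell, fate, sim.lattice, sim.params):
                    idx, part = partition.locate(rec.row)
                    if sim.debug:
                        key = (idx, part)
                        prev = owners.setdefault(key, worker)
                        if prev != worker:
                            raise OwnershipViolation(
                                f"phase {phase}: workers {prev} and {worker} both "
                                f"wrote next list of region {idx} part {part}"
                            )
                    regions[idx].next[part].append(rec)

    counts = region_counts(partition, sim.lattice)
    started = start_moves(partition, counts)
    active_before = len(partition.moves)
    advance_seam_moves(partition)
    completed = active_before - len(partition.moves)

    for region in regions:
        region.current, region.next = region.next, {p: [] for p in PART_NAMES}

    sim.step_index += 1
    sim.cumulative_processed += processed
    return StepMetrics(
        step=sim.step_index,
        live_cells=sim.lattice.census(),
        processed=processed,
        cumulative_processed=sim.cumulative_processed,
        region_counts=counts,
        seam_rows=[r.row_stop for r in regions[:-1]],
        moves_started=len(started),
        moves_active=len(partition.moves),
        moves_completed=completed,
    )


def run_parallel(
    n_rows: int,
    n_cols: int,
    seeds: Sequence[tuple[int, int]],
    params: ModelParams,
    n_steps: int,
    t: int,
    rho: float,
    seed: int,
    debug: bool = False,
) -> tuple[ParallelSimulation, list[StepMetrics]]:
    """Build a partitioned simulation and run it for ``n_steps`` steps."""
    sim = init_parallel(n_rows, n_cols, seeds, params, t, rho, seed, debug=debug)
    metrics = [parallel_step(sim) for _ in range(n_steps)]
    return sim, metrics


def _disk_seeds(n_rows: int, n_cols: int, radius: int) -> list[tuple[int, int]]:
    cr, cc = n_rows // 2, n_cols // 2
    return [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if (r - cr) ** 2 + (c - cc) ** 2 <= radius**2
    ]


@dataclass
class EquivalenceResult:
    """Final-size samples from the two engines and their KS comparison."""

    sizes_a: np.ndarray
    sizes_b: np.ndarray
    statistic: float
    pvalue: float


def equivalence_check(
    params: ModelParams,
    n_runs: int,
    n_steps: int,
    grid: tuple[int, int],
    t: int,
    seed: int = 0,
    rho: float = 10.0,
    seed_radius: int = 20,
    sizes_sequential: Optional[np.ndarray] = None,
) -> EquivalenceResult:
    """Compare final-tumor-size distributions of the sequential and
    parallel engines with a two-sample Kolmogorov–Smirnov test.

    Worker scheduling makes individual parallel trajectories
    irreproducible in principle, so engines are compared
    distributionally: ``n_runs`` independently seeded runs per engine,
    identical in every other respect.  Runs start from a filled disk of
    ``seed_radius`` around the lattice center so that every region holds
    cells and the comparison exercises all workers.

    ``sizes_sequential`` lets a caller reuse one sequential sample across
    several parallel configurations.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs per engine")
    n_rows, n_cols = grid
    seeds_spec = _disk_seeds(n_rows, n_cols, seed_radius)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_runs)]

    if sizes_sequential is None:
        sizes_a = np.array(
            [
                sequential_final_size(n_rows, n_cols, seeds_spec, params, n_steps, s)
                for s in child_seeds[:n_runs]
            ]
        )
    else:
        sizes_a = np.asarray(sizes_sequential)

    sizes_b = np.empty(n_runs)
    for i, s in enumerate(child_seeds[n_runs:]):
        sim, _ = run_parallel(
            n_rows, n_cols, seeds_spec, params, n_steps, t, rho, s
        )
        sizes_b[i] = sim.lattice.census()

    ks = stats.ks_2samp(sizes_a, sizes_b)
    return EquivalenceResult(sizes_a, sizes_b, float(ks.statistic), float(ks.pvalue))


def sequential_final_size(
    n_rows: int,
    n_cols: int,
    seeds_spec: Sequence[tuple[int, int]],
    params: ModelParams,
    n_steps: int,
    seed: int,
) -> int:
    state = init_state(n_rows, n_cols, seeds_spec, params, seed)
    state, _ = run_sequential(state, n_steps)
    return state.lattice.census()


def null_calibration(
    sizes: np.ndarray,
    n_splits: int,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Rejection rate of the KS test under the null: random half-splits of
    one engine's final-size pool compared against each other.  With
    continuous data this is ~``alpha``; ties make the KS test
    conservative, so the observed rate is at most that."""
    sizes = np.asarray(sizes)
    rng = np.random.default_rng(seed)
    half = sizes.size // 2
    rejections = 0
    for _ in range(n_splits):
        perm = rng.permutation(sizes.size)
        p = stats.ks_2samp(sizes[perm[:half]], sizes[perm[half:2 * half]]).pvalue
        rejections += p < alpha
    return rejections / n_splits
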