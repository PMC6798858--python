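"""Sequential simulation engines.

Two engines share the per-cell rule from :mod:`tumorca.model`:

* :func:`step_sequential` — the two-list scheme: the current step's live
  cells sit in a list that is consumed in order, survivors and newborn
  daughters are appended to the next step's list, and the lattice only
  records state changes.  Work per step is proportional to the number of
  live cells, not the lattice area.
* :func:`step_oracle` — the naive scheme that scans every lattice site in
  row-major order, evaluating live sites only.  It exists as a test
  oracle: started from the same RNG state with the current list sorted
  row-major, both engines produce identical next states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .model import CellRecord, Lattice, ModelParams, apply_fate, evaluate_cell

__all__ = ["SimulationState", "init_state", "step_sequential", "step_oracle", "run"]


@dataclass
class SimulationState:
    """Full state of a simulation between steps.

    At a step boundary ``next_list`` is empty and ``current_list``
    enumerates exactly the occupied lattice sites.
    """

    lattice: Lattice
    params: ModelParams
    current_list: list[CellRecord]
    next_list: list[CellRecord]
    step_index: int
    rng: np.random.Generator

    def census_consistent(self) -> bool:
        """Occupied-site count equals the live-cell list length and every
        listed cell sits on an occupied site at a distinct position."""
        cells = self.current_list + self.next_list
        positions = {(c.row, c.col) for c in cells}
        if len(positions) != len(cells):
            return False
        if self.lattice.census() != len(cells):
            return False
        return all(self.lattice.occupancy[c.row, c.col] for c in cells)


def init_state(
    n_rows: int,
    n_cols: int,
    seeds: Sequence[tuple[int, int]],
    params: ModelParams,
    seed: int,
) -> SimulationState:
    """Build the initial state: one live cell (with ``ph = ph_init``) per
    seed position, deterministic RNG from ``seed``."""
    lattice = Lattice(n_rows, n_cols)
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seed positions")
    cells: list[CellRecord] = []
    for row, col in seeds:
        if not lattice.in_bounds(row, col):
            raise ValueError(f"seed ({row}, {col}) outside the {n_rows}x{n_cols} lattice")
        lattice.occupancy[row, col] = 1
        cells.append(CellRecord(row, col, params.ph_init))
    rng = np.random.default_rng(seed)
    return SimulationState(lattice, params, cells, [], 0, rng)


def _process_cell(cell: CellRecord, state: SimulationState) -> None:
    fate = evaluate_cell(cell, state.lattice, state.params, state.rng)
    state.next_list.extend(apply_fate(cell, fate, state.lattice, state.params))


def step_sequential(state: SimulationState) -> SimulationState:
    """Advance one step: consume ``current_list`` in order, then swap lists."""
    for cell in state.current_list:
        _process_cell(cell, state)
    state.current_list, state.next_list = state.next_list, []
    state.step_index += 1
    return state


def step_oracle(state: SimulationState) -> SimulationState:
    """Advance one step by scanning all lattice sites in row-major order.

    RNG draws are consumed for live cells only, so the result is
    identical to :func:`step_sequential` run from the same RNG state on a
    row-major-sorted current list.
    """
    by_pos = {(c.row, c.col): c for c in state.current_list}
    occ = state.lattice.occupancy
    for row in range(state.lattice.n_rows):
        for col in range(state.lattice.n_cols):
            if not occ[row, col]:
                continue
            cell = by_pos.pop((row, col), None)
            if cell is None:
                continue  # placed this step (daughter or migrant); not evaluated
            _process_cell(cell, state)
    state.current_list, state.next_list = state.next_list, []
    state.step_index += 1
    return state


@dataclass
class StepRecord:
    """Per-step bookkeeping emitted by :func:`run`."""

    step: int
    live_cells: int
    processed: int
    cumulative_processed: int


def run(
    state: SimulationState,
    n_steps: int,
    hooks: Optional[Iterable[Callable[[SimulationState], None]]] = None,
    step_fn: Callable[[SimulationState], SimulationState] = step_sequential,
) -> tuple[SimulationState, list[StepRecord]]:
    """Apply ``step_fn`` ``n_steps`` times, recording per-step metrics.

    ``processed`` counts the cells evaluated in a step, i.e. the length
    of the list consumed at its start.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    metrics: list[StepRecord] = []
    cumulative = 0
    for _ in range(n_steps):
        processed = len(state.current_list)
        cumulative += processed
        state = step_fn(state)
        metrics.append(
            StepRecord(state.step_index, len(state.current_list), processed, cumulative)
        )
        if hooks:
            for hook in hooks:
                hook(state)
    return state, metrics
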