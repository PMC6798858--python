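"""Core domain types and the per-cell stochastic transition rule.

The model is a two-state stochastic cellular automaton on a 2-D lattice:
each site is either empty (0) or holds one tumor cell (1).  Once per
simulation step every live cell draws its fate:

* **death** with probability ``1 - p_survive``;
* otherwise a **proliferation signal** with probability ``p_signal`` —
  the cell's signal counter ``ph`` is incremented and, once it reaches
  ``np_threshold``, the cell attempts mitosis into an empty neighboring
  site;
* otherwise, with probability ``p_migrate``, the cell attempts to
  **migrate** to an empty neighboring site;
* failing all of the above the cell stays **quiescent** (the G0 phase).

A single uniform draw ``rr`` partitions the first three outcomes:
``rr >= p_survive`` is death, ``rr < p_signal`` is the signal branch and
the remainder is the migration branch (which consumes a second draw).
With the default parameters the three intervals are disjoint, so the
one-draw rule is a genuine categorical distribution with
``P(die) = 1 - p_survive`` and ``P(signal) = p_signal``.

Candidate target sites are scanned in a uniformly random order and the
first empty one wins; a cell with no empty candidate stays quiescent.
Out-of-bounds sites count as permanently occupied (fixed, non-periodic
borders).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "CellRecord",
    "Lattice",
    "FateKind",
    "CellFate",
    "evaluate_cell",
    "apply_fate",
    "NEIGHBORHOODS",
]

# Candidate-target offsets, (drow, dcol).  "von_neumann" is the default
# 4-site axial set used by the growth rule; "moore" adds the diagonals.
NEIGHBORHOODS: dict[str, tuple[tuple[int, int], ...]] = {
    "von_neumann": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "moore": (
        (-1, -1), (-1, 0), (-1, 1),
        (0, -1), (0, 1),
        (1, -1), (1, 0), (1, 1),
    ),
}

# All orderings of each candidate set, so a single integer draw selects a
# uniformly random scan order (much cheaper than a per-cell shuffle).
_PERMS: dict[str, tuple[tuple[tuple[int, int], ...], ...]] = {
    name: tuple(itertools.permutations(dirs))
    for name, dirs in NEIGHBORHOODS.items()
    if name == "von_neumann"
}


def _scan_orders(neighborhood: str) -> tuple[tuple[tuple[int, int], ...], ...]:
    try:
        return _PERMS[neighborhood]
    except KeyError:
        # 8! orders for Moore; built once on first use.
        _PERMS[neighborhood] = tuple(
            itertools.permutations(NEIGHBORHOODS[neighborhood])
        )
        return _PERMS[neighborhood]


@dataclass(frozen=True)
class ModelParams:
    """Transition probabilities and counters of the stochastic growth rule.

    Parameters
    ----------
    p_survive:
        Per-step survival probability W; a cell dies with ``1 - p_survive``.
    p_signal:
        Probability W' of receiving a proliferation signal this step.
    p_migrate:
        Probability W'' that a surviving, non-signaled cell attempts to
        migrate.
    np_threshold:
        NP — number of accumulated signals required before a
        proliferation attempt.
    ph_init:
        Initial value of the per-cell signal counter PH, used for seed
        cells and for newborn daughters.
    delta:
        Maximum per-step displacement (Chebyshev distance) of any cell;
        1 for the nearest-neighbor rule.  Also the minimum subregion
        height used by the parallel decomposition.
    neighborhood:
        Candidate-target set for proliferation/migration: ``"von_neumann"``
        (4 axial sites, default) or ``"moore"`` (8 sites).
    """

    p_survive: float = 0.8
    p_signal: float = 0.2
    p_migrate: float = 0.25
    np_threshold: int = 1
    ph_init: int = 1
    delta: int = 1
    neighborhood: str = "von_neumann"

    def __post_init__(self) -> None:
        for name in ("p_survive", "p_signal", "p_migrate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p!r}")
        if self.np_threshold < 1:
            raise ValueError(f"np_threshold must be >= 1, got {self.np_threshold!r}")
        if self.ph_init < 0:
            raise ValueError(f"ph_init must be >= 0, got {self.ph_init!r}")
        if self.delta < 1:
            raise ValueError(f"delta must be >= 1, got {self.delta!r}")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(
                f"neighborhood must be one of {sorted(NEIGHBORHOODS)}, "
                f"got {self.neighborhood!r}"
            )


@dataclass(eq=False)
class CellRecord:
    """One live tumor cell: lattice position plus its PH signal counter."""

    __slots__ = ("row", "col", "ph")

    row: int
    col: int
    ph: int

    def copy(self) -> "CellRecord":
        return CellRecord(self.row, self.col, self.ph)


class Lattice:
    """Boolean occupancy grid: 1 where a tumor cell sits, 0 elsewhere.

    The grid records state only; cell identity (the PH counter) lives in
    the cell lists.  Row 0 is the topmost row.
    """

    __slots__ = ("occupancy",)

    def __init__(self, n_rows: int, n_cols: int) -> None:
        if n_rows < 1 or n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        self.occupancy = np.zeros((n_rows, n_cols), dtype=np.uint8)

    @property
    def n_rows(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_cols(self) -> int:
        return self.occupancy.shape[1]

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def is_occupied(self, row: int, col: int) -> bool:
        """True for occupied sites *and* for out-of-bounds sites (blocked
        borders)."""
        if not self.in_bounds(row, col):
            return True
        return bool(self.occupancy[row, col])

    def census(self) -> int:
        """Number of occupied sites."""
        return int(self.occupancy.sum())

    def row_counts(self) -> np.ndarray:
        """Occupied-site count per lattice row."""
        return self.occupancy.sum(axis=1, dtype=np.int64)


class FateKind(Enum):
    DIE = "die"
    QUIESCENT = "quiescent"
    PROLIFERATE = "proliferate"
    MIGRATE = "migrate"


@dataclass(frozen=True)
class CellFate:
    """Outcome of one cell evaluation; ``target`` is set only for
    proliferation and migration."""

    kind: FateKind
    target: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        needs_target = self.kind in (FateKind.PROLIFERATE, FateKind.MIGRATE)
        if needs_target != (self.target is not None):
            raise ValueError(f"fate {self.kind} target mismatch: {self.target!r}")


def _find_empty_target(
    cell: CellRecord, lattice: Lattice, params: ModelParams, rng: np.random.Generator
) -> Optional[tuple[int, int]]:
    """First empty candidate site in a uniformly random scan order."""
    orders = _scan_orders(params.neighborhood)
    order = orders[int(rng.integers(len(orders)))]
    for drow, dcol in order:
        r, c = cell.row + drow, cell.col + dcol
        if not lattice.is_occupied(r, c):
            return (r, c)
    return None


def evaluate_cell(
    cell: CellRecord,
    lattice: Lattice,
    params: ModelParams,
    rng: np.random.Generator,
) -> CellFate:
    """Draw one cell's fate for this step.

    A single uniform ``rr`` partitions [0, 1) into the signal branch
    ``[0, p_signal)``, the migration branch ``[p_signal, p_survive)`` and
    death ``[p_survive, 1)``.  In the signal branch PH is incremented
    and, when it reaches ``np_threshold``, a proliferation attempt scans
    for an empty candidate site; in the migration branch a second draw
    against ``p_migrate`` gates a migration attempt.  Attempts with no
    empty candidate fall back to quiescence.

    Mutates only ``cell.ph`` (incremented on a signal; reset to 0 when a
    PROLIFERATE fate is returned).  Never mutates the lattice.
    """
    if not lattice.in_bounds(cell.row, cell.col):
        raise ValueError(f"cell at ({cell.row}, {cell.col}) outside lattice bounds")
    if not lattice.occupancy[cell.row, cell.col]:
        raise ValueError(f"cell site ({cell.row}, {cell.col}) is not occupied")

    rr = rng.random()
    if rr >= params.p_survive:
        return CellFate(FateKind.DIE)

    if rr < params.p_signal:
        cell.ph += 1
        if cell.ph >= params.np_threshold:
            target = _find_empty_target(cell, lattice, params, rng)
            if target is not None:
                cell.ph = 0
                return CellFate(FateKind.PROLIFERATE, target)
        return CellFate(FateKind.QUIESCENT)

    rrm = rng.random()
    if rrm < params.p_migrate:
        target = _find_empty_target(cell, lattice, params, rng)
        if target is not None:
            return CellFate(FateKind.MIGRATE, target)
    return CellFate(FateKind.QUIESCENT)


def apply_fate(
    cell: CellRecord,
    fate: CellFate,
    lattice: Lattice,
    params: ModelParams,
) -> list[CellRecord]:
    """Write one cell's fate into the lattice and return the surviving
    records (parent and, on mitosis, the newborn daughter).

    Updates are in place and list-ordered, so a target chosen as empty
    during evaluation may have been taken meanwhile; the cell then simply
    stays quiescent this step.
    """
    r, c = cell.row, cell.col
    if not lattice.in_bounds(r, c) or not lattice.occupancy[r, c]:
        raise ValueError(f"fate/cell mismatch: site ({r}, {c}) not occupied")

    if fate.kind is FateKind.DIE:
        lattice.occupancy[r, c] = 0
        return []

    if fate.kind is FateKind.QUIESCENT:
        return [cell]

    tr, tc = fate.target  # type: ignore[misc]
    if lattice.is_occupied(tr, tc):
        # Conflict: the target was taken after evaluation.
        return [cell]

    if fate.kind is FateKind.MIGRATE:
        lattice.occupancy[r, c] = 0
        lattice.occupancy[tr, tc] = 1
        cell.row, cell.col = tr, tc
        return [cell]

    # PROLIFERATE: the daughter starts in quiescence with a fresh counter.
    lattice.occupancy[tr, tc] = 1
    daughter = CellRecord(tr, tc, params.ph_init)
    return [cell, daughter]
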