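"""Row-band domain decomposition with seam-based load balancing.

The lattice is split into horizontal *regions*, one per worker.  Each
region has up to three parts: a top seam part, a center part and a
bottom seam part; the two seam parts meeting at a region boundary form a
*seam*.  Every part is at least ``delta`` rows tall, where ``delta`` is
the longest per-step cell displacement, so same-type parts of different
regions are always separated by at least two other parts — that spacing
is what lets workers process all parts of one type concurrently without
locks.

Load balancing moves a region boundary by ``delta`` rows via a
three-phase protocol spread over three simulation steps (one phase per
step), which preserves the spacing guarantee throughout:

1. the seam part on the shrinking side absorbs ``delta`` rows from its
   region's center (that part is now ``2*delta`` thick);
2. those rows are handed across the boundary to the opposite seam part
   (the boundary itself moves; total seam thickness is unchanged);
3. the enlarged seam part releases ``delta`` rows into the growing
   region's center, returning every part to ``delta`` thickness.

Adjacent seams are never adjusted simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import CellRecord, Lattice

__all__ = [
    "Span",
    "Region",
    "SeamMove",
    "Partition",
    "initial_partition",
    "region_counts",
    "needs_adjustment",
    "advance_seam_moves",
]

Span = tuple[int, int]  # half-open [start, stop) row range

PART_NAMES = ("top", "center", "bottom")


def _height(span: Optional[Span]) -> int:
    return 0 if span is None else span[1] - span[0]


@dataclass
class Region:
    """One worker's row band: top-seam / center / bottom-seam parts plus
    the per-part current/next cell lists.

    The first region has no top part and the last region has no bottom
    part (there is no neighbor to synchronize with).
    """

    index: int
    top: Optional[Span]
    center: Span
    bottom: Optional[Span]
    current: dict[str, list[CellRecord]] = field(
        default_factory=lambda: {p: [] for p in PART_NAMES}
    )
    next: dict[str, list[CellRecord]] = field(
        default_factory=lambda: {p: [] for p in PART_NAMES}
    )

    @property
    def row_start(self) -> int:
        return self.top[0] if self.top is not None else self.center[0]

    @property
    def row_stop(self) -> int:
        return self.bottom[1] if self.bottom is not None else self.center[1]

    def part_span(self, part: str) -> Optional[Span]:
        return {"top": self.top, "center": self.center, "bottom": self.bottom}[part]

    def parts(self) -> Iterable[tuple[str, Span]]:
        for name in PART_NAMES:
            span = self.part_span(name)
            if span is not None:
                yield name, span


@dataclass
class SeamMove:
    """In-flight boundary adjustment at seam ``seam`` (between regions
    ``seam`` and ``seam + 1``).  ``shrink`` names the region losing
    ``delta`` rows; ``phase`` counts completed phases (0..3)."""

    seam: int
    shrink: int
    delta: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.shrink not in (self.seam, self.seam + 1):
            raise ValueError("shrink must name one of the seam's two regions")


@dataclass
class Partition:
    """Ordered regions tiling all lattice rows, plus active seam moves."""

    regions: list[Region]
    n_rows: int
    delta: int
    rho: float
    moves: dict[int, SeamMove] = field(default_factory=dict)

    @property
    def n_seams(self) -> int:
        return len(self.regions) - 1

    def locate(self, row: int) -> tuple[int, str]:
        """(region index, part name) of the subregion containing ``row``
        under the current geometry."""
        for region in self.regions:
            if region.row_start <= row < region.row_stop:
                for name, (start, stop) in region.parts():
                    if start <= row < stop:
                        return region.index, name
        raise ValueError(f"row {row} outside lattice rows [0, {self.n_rows})")

    def distribute(self, cells: Iterable[CellRecord]) -> None:
        """Append each cell to the current list of the subregion holding it."""
        for cell in cells:
            idx, part = self.locate(cell.row)
            self.regions[idx].current[part].append(cell)

    def check_invariants(self) -> None:
        """Raise AssertionError if the geometry invariants are violated:
        exact tiling, minimum part heights, seam-part thickness in
        {delta, 2*delta} (2*delta only mid-move), no adjacent active seams.
        """
        d = self.delta
        cursor = 0
        for region in self.regions:
            assert region.row_start == cursor, "regions must tile rows in order"
            prev = None
            for name, (start, stop) in region.parts():
                assert stop > start, f"empty part {name} in region {region.index}"
                if prev is not None:
                    assert start == prev, "parts must be contiguous"
                prev = stop
            cursor = region.row_stop
            assert _height(region.center) >= d, "center thinner than delta"
            for name in ("top", "bottom"):
                span = region.part_span(name)
                if span is not None:
                    assert _height(span) in (d, 2 * d), "bad seam-part thickness"
        assert cursor == self.n_rows, "regions must cover all rows"
        assert (self.regions[0].top is None
                and self.regions[-1].bottom is None), "outer seam parts must be absent"
        active = sorted(self.moves)
        for a, b in zip(active, active[1:]):
            assert b - a >= 2, "adjacent seams active simultaneously"
        wide = {
            (r.index, name)
            for r in self.regions
            for name, span in r.parts()
            if name != "center" and _height(span) == 2 * d
        }
        for key in wide:
            idx, name = key
            seam = idx if name == "bottom" else idx - 1
            assert seam in self.moves, "2*delta-thick seam part outside a move"


def initial_partition(
    tumor_row_min: int,
    tumor_row_max: int,
    t: int,
    delta: int,
    n_rows: int,
    rho: float = 10.0,
) -> Partition:
    """Place the initial region boundaries around the seed tumor mass.

    The band holding the ``t - 1`` internal boundaries has height
    ``H0 = max(tumor_row_max - tumor_row_min, 3 * delta * t)`` — the
    minimum that accommodates ``t`` regions of three ``delta``-tall parts
    each — and is centered on the tumor mass so equal numbers of regions
    lie above and below it.  The first region is then extended up to row
    0 and the last down to the final row.
    """
    if t < 1:
        raise ValueError("worker count t must be >= 1")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if n_rows < 3 * delta * t:
        raise ValueError(
            f"lattice height {n_rows} cannot hold {t} regions of minimum "
            f"height {3 * delta} (needs >= {3 * delta * t} rows)"
        )
    if not (0 <= tumor_row_min <= tumor_row_max < n_rows):
        raise ValueError("tumor row extent outside the lattice")
    if rho < 0:
        raise ValueError("rho must be >= 0")

    h0 = max(tumor_row_max - tumor_row_min, 3 * delta * t)
    h0 = min(h0, n_rows)
    center_row = (tumor_row_min + tumor_row_max) // 2
    band_start = center_row - h0 // 2
    band_start = max(0, min(band_start, n_rows - h0))

    # Internal boundaries, evenly spaced: each band segment is at least
    # floor(h0 / t) >= 3 * delta rows tall.
    bounds = [0]
    bounds += [band_start + (j * h0) // t for j in range(1, t)]
    bounds.append(n_rows)

    regions: list[Region] = []
    for i in range(t):
        start, stop = bounds[i], bounds[i + 1]
        top: Optional[Span] = (start, start + delta) if i > 0 else None
        bottom: Optional[Span] = (stop - delta, stop) if i < t - 1 else None
        c0 = top[1] if top else start
        c1 = bottom[0] if bottom else stop
        regions.append(Region(i, top, (c0, c1), bottom))

    part = Partition(regions, n_rows, delta, float(rho))
    part.check_invariants()
    return part


def region_counts(partition: Partition, lattice: Lattice) -> list[int]:
    """Live cells per region, from the lattice census (never from the
    possibly-stale cell lists)."""
    rows = lattice.row_counts()
    return [int(rows[r.row_start:r.row_stop].sum()) for r in partition.regions]


def needs_adjustment(
    counts: Sequence[int],
    rho: float,
    active: Iterable[int],
    center_heights: Optional[Sequence[int]] = None,
    delta: int = 1,
) -> list[SeamMove]:
    """Seam moves to start, given per-region cell counts.

    A seam qualifies when the relative difference between its two
    regions' counts, ``100 * |a - b| / max(a, b, 1)``, exceeds ``rho``
    percent; the move shrinks the larger region.  Moves whose shrinking
    center could not spare ``delta`` rows are dropped, and the
    no-adjacent-active-seams rule filters candidates in decreasing order
    of imbalance (ties broken toward the lower seam index).
    """
    candidates: list[tuple[float, int, int]] = []
    for s in range(len(counts) - 1):
        a, b = counts[s], counts[s + 1]
        imbalance = 100.0 * abs(a - b) / max(a, b, 1)
        if imbalance > rho:
            shrink = s if a > b else s + 1
            if center_heights is not None and center_heights[shrink] < 2 * delta:
                continue
            candidates.append((imbalance, s, shrink))

    blocked: set[int] = set()
    for s in active:
        blocked.update((s - 1, s, s + 1))
    selected: list[SeamMove] = []
    for imbalance, s, shrink in sorted(candidates, key=lambda x: (-x[0], x[1])):
        if s in blocked:
            continue
        selected.append(SeamMove(s, shrink, delta))
        blocked.update((s - 1, s, s + 1))
    return selected


def start_moves(partition: Partition, counts: Sequence[int]) -> list[SeamMove]:
    """Run :func:`needs_adjustment` against the partition's own geometry
    and register the returned moves."""
    heights = [_height(r.center) for r in partition.regions]
    moves = needs_adjustment(
        counts, partition.rho, partition.moves.keys(), heights, partition.delta
    )
    for move in moves:
        partition.moves[move.seam] = move
    return moves


def _advance_one(partition: Partition, move: SeamMove) -> bool:
    """Advance one move by one phase; returns False if the move had to be
    aborted (shrinking center could no longer spare ``delta`` rows)."""
    d = move.delta
    upper = partition.regions[move.seam]
    lower = partition.regions[move.seam + 1]
    assert upper.bottom is not None and lower.top is not None

    if move.shrink == move.seam:  # boundary moves up, into the upper region
        if move.phase == 0:
            if _height(upper.center) < 2 * d:
                return False
            upper.bottom = (upper.bottom[0] - d, upper.bottom[1])
            upper.center = (upper.center[0], upper.center[1] - d)
        elif move.phase == 1:
            upper.bottom = (upper.bottom[0], upper.bottom[1] - d)
            lower.top = (lower.top[0] - d, lower.top[1])
        else:
            lower.top = (lower.top[0], lower.top[1] - d)
            lower.center = (lower.center[0] - d, lower.center[1])
    else:  # boundary moves down, into the lower region
        if move.phase == 0:
            if _height(lower.center) < 2 * d:
                return False
            lower.top = (lower.top[0], lower.top[1] + d)
            lower.center = (lower.center[0] + d, lower.center[1])
        elif move.phase == 1:
            lower.top = (lower.top[0] + d, lower.top[1])
            upper.bottom = (upper.bottom[0], upper.bottom[1] + d)
        else:
            upper.bottom = (upper.bottom[0] + d, upper.bottom[1])
            upper.center = (upper.center[0], upper.center[1] + d)

    move.phase += 1
    return True


def advance_seam_moves(partition: Partition) -> Partition:
    """Advance every active move by exactly one phase; drop completed and
    aborted moves.  Called once per simulation step by the coordinator.

    Cell-list membership is *not* updated here: cells keep whatever list
    they are on and are re-routed lazily the next time they are
    processed.
    """
    finished: list[int] = []
    for seam in sorted(partition.moves):
        move = partition.moves[seam]
        ok = _advance_one(partition, move)
        if not ok or move.phase >= 3:
            finished.append(seam)
    for seam in finished:
        del partition.moves[seam]
    partition.check_invariants()
    return partition
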