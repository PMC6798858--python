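"""Tests for region/seam geometry, imbalance detection and seam moves."""

import numpy as np
import pytest

from tumorca import Lattice, ModelParams, init_state
from tumorca.partition import (
    Partition,
    SeamMove,
    advance_seam_moves,
    initial_partition,
    needs_adjustment,
    region_counts,
    start_moves,
)


def random_partition(rng, max_t=6, max_delta=3):
    t = int(rng.integers(1, max_t + 1))
    delta = int(rng.integers(1, max_delta + 1))
    n_rows = int(rng.integers(3 * delta * t, 6 * delta * t + 40))
    lo = int(rng.integers(0, n_rows))
    hi = int(rng.integers(lo, n_rows))
    return initial_partition(lo, hi, t, delta, n_rows, rho=float(rng.uniform(0, 40)))


def same_type_parts(partition, name):
    return [r.part_span(name) for r in partition.regions if r.part_span(name)]


def assert_spacing(partition):
    """Same-type parts separated by >= 2*delta rows (the write-disjointness
    guarantee under the delta displacement bound)."""
    d = partition.delta
    for name in ("top", "center", "bottom"):
        spans = sorted(same_type_parts(partition, name))
        for (_, stop), (start, _) in zip(spans, spans[1:]):
            assert start - stop >= 2 * d, f"{name} parts too close"


class TestInitialPartition:
    def test_single_worker_owns_everything(self):
        part = initial_partition(10, 20, 1, 1, 50)
        region = part.regions[0]
        assert (region.top, region.center, region.bottom) == (None, (0, 50), None)
        assert part.n_seams == 0

    def test_minimum_band_height_forced(self):
        """Tumor height 5 < 3*delta*t = 12: the band takes the minimum
        height, so internal regions are exactly 3 rows tall."""
        part = initial_partition(48, 53, 4, 1, 100)
        heights = [r.row_stop - r.row_start for r in part.regions[1:-1]]
        assert heights == [3, 3]
        assert part.regions[0].row_start == 0
        assert part.regions[-1].row_stop == 100

    def test_boundary_centered_on_tumor(self):
        part = initial_partition(50, 50, 2, 1, 100, rho=10.0)
        assert part.regions[0].row_stop == 50
        assert part.regions[0].bottom == (49, 50)
        assert part.regions[1].top == (50, 51)
        assert part.regions[1].center == (51, 100)

    def test_band_follows_large_tumor(self):
        part = initial_partition(10, 90, 4, 1, 100)
        bounds = [r.row_stop for r in part.regions[:-1]]
        assert bounds == [30, 50, 70]  # 80-row band centered at 50

    def test_too_small_lattice_rejected(self):
        with pytest.raises(ValueError):
            initial_partition(0, 5, 4, 1, 11)  # needs >= 12 rows

    @pytest.mark.parametrize("case", range(50))
    def test_randomized_construction_invariants(self, case):
        rng = np.random.default_rng(case)
        part = random_partition(rng)
        part.check_invariants()
        assert_spacing(part)


class TestRegionCounts:
    def test_empty_and_concentrated(self):
        part = initial_partition(50, 50, 2, 1, 100)
        lat = Lattice(100, 100)
        assert region_counts(part, lat) == [0, 0]
        lat.occupancy[60:70, :5] = 1
        assert region_counts(part, lat) == [0, 50]

    def test_counts_sum_to_census(self):
        rng = np.random.default_rng(8)
        part = initial_partition(30, 70, 3, 2, 100)
        lat = Lattice(100, 40)
        lat.occupancy[:] = rng.random((100, 40)) < 0.2
        assert sum(region_counts(part, lat)) == lat.census()


class TestNeedsAdjustment:
    def test_balanced_counts_no_move(self):
        assert needs_adjustment([100, 100], 10.0, []) == []

    def test_single_imbalanced_pair(self):
        """|100-125|/125 = 20% > 10%: shrink the larger (lower) region."""
        moves = needs_adjustment([100, 125], 10.0, [])
        assert len(moves) == 1
        assert (moves[0].seam, moves[0].shrink) == (0, 1)

    def test_adjacent_seam_exclusion_with_tie_break(self):
        """Both pairs qualify at 33.3%; only the lower-index seam starts."""
        moves = needs_adjustment([100, 150, 100], 10.0, [])
        assert len(moves) == 1
        assert (moves[0].seam, moves[0].shrink) == (0, 1)

    def test_active_seams_block_neighbors(self):
        moves = needs_adjustment([100, 150, 100], 10.0, active=[1])
        assert moves == []
        moves = needs_adjustment([100, 150, 100, 300, 100], 10.0, active=[1])
        assert [m.seam for m in moves] == [3]

    def test_largest_imbalance_wins(self):
        """Seam 2 (80%) is picked first, blocking adjacent seam 1 (76%);
        seam 0 (16.7%) is far enough away to start as well."""
        moves = needs_adjustment([100, 120, 500, 100], 10.0, [])
        assert [(m.seam, m.shrink) for m in moves] == [(2, 2), (0, 1)]

    def test_thin_center_candidate_dropped(self):
        moves = needs_adjustment(
            [100, 200], 10.0, [], center_heights=[5, 1], delta=1
        )
        assert moves == []

    def test_zero_counts_denominator_clamped(self):
        moves = needs_adjustment([0, 0], 10.0, [])
        assert moves == []
        moves = needs_adjustment([0, 5], 10.0, [])
        assert (moves[0].seam, moves[0].shrink) == (0, 1)


class TestSeamMoves:
    def test_shrink_upper_three_phase_trace(self):
        """delta=1 move on the seam between [0,50)/[50,100): after phases
        1-3 the spans are [0,49)/[49,100) with all parts 1 row thick."""
        part = initial_partition(50, 50, 2, 1, 100)
        part.moves[0] = SeamMove(0, 0, 1)
        advance_seam_moves(part)  # phase 1: upper bottom part 2 rows thick
        assert part.regions[0].bottom == (48, 50)
        advance_seam_moves(part)  # phase 2: boundary crosses
        assert part.regions[0].bottom == (48, 49)
        assert part.regions[1].top == (49, 51)
        advance_seam_moves(part)  # phase 3: released into the lower center
        assert not part.moves
        assert part.regions[0].row_stop == 49
        assert part.regions[0].bottom == (48, 49)
        assert part.regions[1].top == (49, 50)
        assert part.regions[1].center == (50, 100)

    def test_shrink_lower_is_mirror(self):
        part = initial_partition(50, 50, 2, 1, 100)
        part.moves[0] = SeamMove(0, 1, 1)
        for _ in range(3):
            advance_seam_moves(part)
        assert part.regions[0].row_stop == 51
        assert part.regions[0].bottom == (50, 51)
        assert part.regions[1].top == (51, 52)

    def test_net_transfer_changes_only_adjoining_centers(self):
        part = initial_partition(10, 90, 4, 1, 100)
        before = [r.center[1] - r.center[0] for r in part.regions]
        part.moves[1] = SeamMove(1, 2, 1)  # shrink region 2, grow region 1
        for _ in range(3):
            advance_seam_moves(part)
        after = [r.center[1] - r.center[0] for r in part.regions]
        deltas = [a - b for a, b in zip(after, before)]
        assert deltas == [0, 1, -1, 0]

    def test_independent_non_adjacent_moves(self):
        part = initial_partition(10, 90, 4, 1, 100)
        part.moves[0] = SeamMove(0, 0, 1)
        part.moves[2] = SeamMove(2, 3, 1)
        stops_before = [r.row_stop for r in part.regions]
        for _ in range(3):
            advance_seam_moves(part)
        assert not part.moves
        stops_after = [r.row_stop for r in part.regions]
        assert stops_after[0] == stops_before[0] - 1
        assert stops_after[2] == stops_before[2] + 1
        assert stops_after[1] == stops_before[1]

    def test_no_moves_no_change(self):
        part = initial_partition(10, 90, 4, 1, 100)
        spans = [(r.top, r.center, r.bottom) for r in part.regions]
        advance_seam_moves(part)
        assert spans == [(r.top, r.center, r.bottom) for r in part.regions]

    def test_abort_when_center_cannot_spare_rows(self):
        """A move that would squeeze a center below delta is dropped at
        phase 1 with the geometry untouched."""
        part = initial_partition(0, 5, 2, 1, 6)  # minimal 3-row regions
        part.moves[0] = SeamMove(0, 0, 1)
        for _ in range(3):
            advance_seam_moves(part)  # first move succeeds: center had 2 rows
        assert part.regions[0].center == (0, 1)
        part.moves[0] = SeamMove(0, 0, 1)
        spans = [(r.top, r.center, r.bottom) for r in part.regions]
        advance_seam_moves(part)
        assert not part.moves  # aborted
        assert spans == [(r.top, r.center, r.bottom) for r in part.regions]

    def test_start_moves_respects_geometry(self):
        part = initial_partition(0, 5, 2, 1, 6)
        part.regions[0].center = (0, 1)
        part.regions[0].bottom = (1, 2)
        part.regions[1].top = (2, 3)
        part.regions[1].center = (3, 6)
        started = start_moves(part, [500, 100])  # would shrink 1-row center
        assert started == []

    @pytest.mark.parametrize("case", range(30))
    def test_randomized_move_sequences_keep_invariants(self, case):
        """Random imbalance-driven move traffic: tiling, thickness and
        spacing invariants hold after every phase."""
        rng = np.random.default_rng(1000 + case)
        part = random_partition(rng)
        for _ in range(20):
            counts = rng.integers(0, 1000, size=len(part.regions)).tolist()
            start_moves(part, counts)
            advance_seam_moves(part)  # asserts check_invariants internally
            assert_spacing(part)


class TestLocateAndDistribute:
    def test_locate_round_trips_every_row(self):
        part = initial_partition(10, 90, 4, 2, 100)
        for row in range(100):
            idx, name = part.locate(row)
            span = part.regions[idx].part_span(name)
            assert span[0] <= row < span[1]
        with pytest.raises(ValueError):
            part.locate(100)

    def test_distribute_places_cells_on_their_subregion(self):
        params = ModelParams()
        state = init_state(100, 20, [(48, 10), (49, 10), (99, 0)], params, 0)
        part = initial_partition(49, 49, 2, 1, 100)  # boundary at row 49
        part.distribute(state.current_list)
        assert len(part.regions[0].current["bottom"]) == 1   # row 48
        assert len(part.regions[1].current["top"]) == 1      # row 49
        assert len(part.regions[1].current["center"]) == 1   # row 99
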