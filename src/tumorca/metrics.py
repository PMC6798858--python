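"""Per-step bookkeeping shared by the engines and the writers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class StepMetrics:
    """Counts and partition state recorded after one simulation step."""

    step: int
    live_cells: int
    processed: int
    cumulative_processed: int
    region_counts: list[int] = field(default_factory=list)
    seam_rows: list[int] = field(default_factory=list)
    moves_started: int = 0
    moves_active: int = 0
    moves_completed: int = 0

    COLUMNS = (
        "step",
        "live_cells",
        "processed",
        "cumulative_processed",
        "region_counts",
        "seam_rows",
        "moves_started",
        "moves_active",
        "moves_completed",
    )

    def as_row(self) -> dict:
        row = {c: getattr(self, c) for c in self.COLUMNS}
        row["region_counts"] = ";".join(map(str, self.region_counts))
        row["seam_rows"] = ";".join(map(str, self.seam_rows))
        return row
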