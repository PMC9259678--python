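"""Per-stage ledger: counts, QC statistics and report rendering.

Every pipeline stage contributes a :class:`StageReport` whose counts
satisfy ``kept_n + removed_n = input_n``; the ledger chains so each
stage's ``kept_n`` equals the next stage's ``input_n`` (per-assembly
expression filters chain into the pooling stage as a sum).  Reports render
both as machine-readable JSON and as a one-column-per-stage text table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .seqio import AssemblyStats


@dataclass
class StageReport:
    stage: str
    input_n: int
    kept_n: int
    removed_n: int
    stats_before: AssemblyStats | None = None
    stats_after: AssemblyStats | None = None
    parameters: dict = field(default_factory=dict)
    notes: str = ""  # free-text slot (e.g. externally computed BUSCO lines)

    def __post_init__(self) -> None:
        if self.kept_n + self.removed_n != self.input_n:
            raise ValidationError(
                f"stage {self.stage!r}: kept_n + removed_n != input_n "
                f"({self.kept_n} + {self.removed_n} != {self.input_n})"
            )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "input_n": self.input_n,
            "kept_n": self.kept_n,
            "removed_n": self.removed_n,
            "stats_before": self.stats_before.to_dict() if self.stats_before else None,
            "stats_after": self.stats_after.to_dict() if self.stats_after else None,
            "parameters": self.parameters,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageReport":
        return cls(
            stage=d["stage"],
            input_n=d["input_n"],
            kept_n=d["kept_n"],
            removed_n=d["removed_n"],
            stats_before=AssemblyStats(**d["stats_before"]) if d.get("stats_before") else None,
            stats_after=AssemblyStats(**d["stats_after"]) if d.get("stats_after") else None,
            parameters=d.get("parameters", {}),
            notes=d.get("notes", ""),
        )


def reports_to_json(reports: Sequence[StageReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)


def reports_from_json(text: str) -> list[StageReport]:
    return [StageReport.from_dict(d) for d in json.loads(text)]


def render_table(reports: Sequence[StageReport]) -> str:
    """Human-readable QC table, one column per stage in ledger order."""
    if not reports:
        raise ValidationError("no stage reports to render")
    rows = [
        ("stage", lambda r: r.stage),
        ("input_n", lambda r: str(r.input_n)),
        ("kept_n", lambda r: str(r.kept_n)),
        ("removed_n", lambda r: str(r.removed_n)),
        ("n_transcripts", lambda r: str(r.stats_after.n_transcripts) if r.stats_after else "."),
        ("gc_percent", lambda r: f"{r.stats_after.gc_percent:.2f}" if r.stats_after else "."),
        ("median_length", lambda r: f"{r.stats_after.median_length:.0f}" if r.stats_after else "."),
        ("n50", lambda r: str(r.stats_after.n50) if r.stats_after else "."),
        ("total_bases", lambda r: str(r.stats_after.total_bases) if r.stats_after else "."),
    ]
    cells = [[label] + [fn(r) for r in reports] for label, fn in rows]
    widths = [max(len(row[col]) for row in cells) for col in range(len(reports) + 1)]
    lines = [
        "  ".join(cell.ljust(width) for cell, width in zip(row, widths)).rstrip()
        for row in cells
    ]
    return "\n".join(lines) + "\n"


def render_report(reports: Sequence[StageReport], json_path: str | Path,
                  table_path: str | Path) -> tuple[Path, Path]:
    """Write the ledger as JSON (machine) and a stage table (human)."""
    json_path, table_path = Path(json_path), Path(table_path)
    json_path.write_text(reports_to_json(reports) + "\n")
    table_path.write_text(render_table(reports))
    return json_path, table_path


# ---- stage-count arithmetic helpers -------------------------------------

def percentage(part: float, whole: float) -> float:
    """100 * part / whole."""
    if whole <= 0:
        raise ValidationError("percentage of a non-positive whole")
    return 100.0 * part / whole


def reduction_summary(input_n: int, kept_n: int) -> dict:
    """Removed count and percentage for one filtering step."""
    if kept_n > input_n:
        raise ValidationError("kept_n exceeds input_n")
    removed = input_n - kept_n
    return {
        "input_n": input_n,
        "kept_n": kept_n,
        "removed_n": removed,
        "removed_pct": percentage(removed, input_n),
    }


def percentage_point_drop(before_pct: float, after_pct: float) -> float:
    """Difference of two percentages, in percentage points."""
    return before_pct - after_pct
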