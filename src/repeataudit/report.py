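"""The missing-sequence ledger and audit report.

Compares read/map-based abundance estimates against what the assembly
actually contains (anchored plus unplaced-contig copies) and renders the
per-class missing-sequence ledger next to the genome-size comparison and
the gap classification summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import pandas as pd

from .abundance import round_sig


@dataclass(frozen=True)
class LedgerEntry:
    repeat_class: str
    estimated_total: float  # bp, read/map-based estimate
    assembled_anchored: float  # bp in pseudomolecules
    assembled_unplaced: float  # bp on unplaced contigs
    missing: float  # bp, max(0, estimated - anchored - unplaced)


def account_missing(repeat_class: str, estimated_total: float,
                    assembled_anchored: float,
                    assembled_unplaced: float = 0.0) -> LedgerEntry:
    """Missing sequence for one repeat class (clamped at zero)."""
    if min(estimated_total, assembled_anchored, assembled_unplaced) < 0:
        raise ValueError("ledger inputs must be >= 0")
    missing = max(0.0, estimated_total - assembled_anchored
                  - assembled_unplaced)
    return LedgerEntry(repeat_class, estimated_total, assembled_anchored,
                       assembled_unplaced, missing)


def ledger_table(entries: Sequence[LedgerEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.repeat_class, e.estimated_total, e.assembled_anchored,
          e.assembled_unplaced, e.missing) for e in entries],
        columns=["repeat_class", "estimated_total", "assembled_anchored",
                 "assembled_unplaced", "missing"])


def audit_report(entries: Sequence[LedgerEntry],
                 gse_table: Optional[pd.DataFrame] = None,
                 gap_summary: Optional[pd.DataFrame] = None,
                 assembly_deficit: Optional[float] = None) -> Dict:
    """Assemble the audit report.

    Returns {"ledger": DataFrame, "total_missing": float, "text": str,
    "deficit_flag": str | None}. The ledger total is printed alongside the
    assembly-size deficit when one is supplied, flagged "<" when the
    per-class ledger cannot account for the whole deficit. Deterministic in
    its inputs; rounding happens only in the rendered text.
    """
    table = ledger_table(entries)
    total = float(table.missing.sum()) if len(table) else 0.0
    lines = ["repeat-class missing-sequence ledger", "-" * 40]
    for e in entries:
        lines.append(f"{e.repeat_class:<24s} est {_fmt(e.estimated_total):>9s}"
                     f"  asm {_fmt(e.assembled_anchored + e.assembled_unplaced):>9s}"
                     f"  missing {_fmt(e.missing):>9s}")
    lines.append(f"{'TOTAL':<24s} missing {_fmt(total):>9s}")
    deficit_flag = None
    if assembly_deficit is not None:
        rel = "<" if total < assembly_deficit else ">="
        deficit_flag = rel
        lines.append(f"assembly-size deficit {_fmt(assembly_deficit)}: "
                     f"ledger total {rel} deficit")
    if gse_table is not None and len(gse_table):
        lines += ["", "genome size estimates", "-" * 40,
                  gse_table.to_string(index=False)]
    if gap_summary is not None and len(gap_summary):
        lines += ["", "gap classification", "-" * 40,
                  gap_summary.to_string(index=False)]
    return {"ledger": table, "total_missing": total,
            "deficit_flag": deficit_flag, "text": "\n".join(lines)}


def _fmt(bp: float) -> str:
    if bp >= 1e9:
        return f"{round_sig(bp / 1e9, 3)} Gb"
    if bp >= 1e6:
        return f"{round_sig(bp / 1e6, 3)} Mb"
    if bp >= 1e3:
        return f"{round_sig(bp / 1e3, 3)} kb"
    return f"{bp:.0f} bp"


def report_to_tsv(report: Dict, path) -> None:
    report["ledger"].to_csv(path, sep="\t", index=False)
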