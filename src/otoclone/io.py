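"""Readers and writers for the pipeline's file formats.

Picks travel as TSV (tab-separated, header row, UTF-8) with columns
``ear_id, pick_id, plap_status, region, cell_type, section_index,
outcome, tag``; clones and summaries as JSON; tags and templates as
FASTA (via Biopython elsewhere); simulation configs as YAML.  All
writers end files with a newline.
"""

from __future__ import annotations

import csv
import json
from typing import Iterable, Sequence

from otoclone.clonecall import NONDISPERSED, Clone, ClonalSummary, PickRecord

PICK_COLUMNS = (
    "ear_id",
    "pick_id",
    "plap_status",
    "region",
    "cell_type",
    "section_index",
    "outcome",
    "tag",
)


class PickParseError(ValueError):
    """A pick table row failed validation; carries the 1-based row number."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


def write_picks(picks: Iterable[PickRecord], path) -> None:
    """Write pick records as TSV; ``write_picks`` then ``read_picks`` is identity."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PICK_COLUMNS)
        for p in picks:
            writer.writerow(
                [
                    p.ear_id,
                    p.pick_id,
                    p.plap_status,
                    p.region,
                    p.cell_type,
                    p.section_index,
                    p.outcome,
                    p.tag or "",
                ]
            )


def read_picks(path) -> list[PickRecord]:
    """Read a pick TSV, validating vocabulary and types per row.

    Raises
    ------
    PickParseError
        Naming the offending row for missing columns, unknown
        region/cell-type/outcome tokens, or a non-integer section index.
    """
    picks: list[PickRecord] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PickParseError(1, "empty file (missing header)") from None
        if tuple(header) != PICK_COLUMNS:
            missing = set(PICK_COLUMNS) - set(header)
            raise PickParseError(
                1, f"bad header {header!r}" + (f"; missing columns {sorted(missing)}" if missing else "")
            )
        for row_number, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(PICK_COLUMNS):
                raise PickParseError(
                    row_number, f"expected {len(PICK_COLUMNS)} columns, got {len(row)}"
                )
            record = dict(zip(PICK_COLUMNS, row))
            try:
                section_index = int(record["section_index"])
            except ValueError:
                raise PickParseError(
                    row_number,
                    f"non-integer section index {record['section_index']!r}",
                ) from None
            try:
                picks.append(
                    PickRecord(
                        ear_id=record["ear_id"],
                        pick_id=record["pick_id"],
                        plap_status=record["plap_status"],
                        region=record["region"],
                        cell_type=record["cell_type"],
                        section_index=section_index,
                        outcome=record["outcome"],
                        tag=record["tag"] or None,
                    )
                )
            except ValueError as exc:
                raise PickParseError(row_number, str(exc)) from None
    return picks


def clones_to_json(clones: Sequence[Clone], path=None, thickness_um: float = 14.0):
    """Serialize called clones as JSON (returns the object; writes if path given)."""
    data = [
        {
            "ear_id": c.ear_id,
            "tag": c.tag,
            "size": c.size,
            "is_multicellular": c.is_multicellular,
            "regions": list(c.regions),
            "cell_types": dict(c.cell_type_counts),
            "member_pick_ids": [m.pick_id for m in c.members],
            "spread_um": (
                None if c.spread_um(thickness_um) is NONDISPERSED else c.spread_um(thickness_um)
            ),
        }
        for c in clones
    ]
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(data, handle, indent=2)
            handle.write("\n")
    return data


def summary_to_json(summary: ClonalSummary, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(summary.to_dict(), handle, indent=2)
        handle.write("\n")
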