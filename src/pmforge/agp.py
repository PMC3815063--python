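"""AGP 2.0 reading, writing and validation.

An AGP file describes how components (scaffolds/segments, type ``W``) and
gaps (type ``U``) tile a larger object such as a chromosome pseudomolecule.
Rows are kept in their native 1-based inclusive convention; the tiling
invariant (consecutive rows cover ``1..L`` without overlap or holes) is
enforced on read and on write.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable

from .records import AGPRecord, Pseudomolecule


class AGPParseError(ValueError):
    pass


class AGPValidationError(ValueError):
    pass


def _parse_row(fields: list, lineno: int) -> AGPRecord:
    if len(fields) < 8:
        raise AGPParseError(f"line {lineno}: expected >= 8 AGP columns, got {len(fields)}")
    try:
        object_id = fields[0]
        object_beg = int(fields[1])
        object_end = int(fields[2])
        part_number = int(fields[3])
        ctype = fields[4]
        if ctype in ("W", "A", "D", "F", "G", "O", "P"):
            if len(fields) < 9:
                raise AGPParseError(f"line {lineno}: component row needs 9 columns")
            return AGPRecord(
                object_id=object_id,
                object_beg=object_beg,
                object_end=object_end,
                part_number=part_number,
                component_type="W",
                component_id=fields[5],
                component_beg=int(fields[6]),
                component_end=int(fields[7]),
                orientation=fields[8],
            )
        if ctype in ("U", "N"):
            return AGPRecord(
                object_id=object_id,
                object_beg=object_beg,
                object_end=object_end,
                part_number=part_number,
                component_type="U",
                gap_length=int(fields[5]),
                gap_type=fields[6],
                linkage=fields[7],
                evidence=fields[8] if len(fields) > 8 else "na",
            )
        raise AGPParseError(f"line {lineno}: unknown component type {ctype!r}")
    except AGPParseError:
        raise
    except ValueError as exc:
        raise AGPParseError(f"line {lineno}: {exc}") from exc


def validate_tiling(records: Iterable[AGPRecord]) -> None:
    """Check that each object's rows tile 1..L contiguously with rising parts."""
    by_object: "OrderedDict[str, list]" = OrderedDict()
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for object_id, rows in by_object.items():
        expected_beg = 1
        last_part = 0
        for rec in rows:
            if rec.part_number <= last_part:
                raise AGPValidationError(
                    f"{object_id}: part_number not strictly increasing at part {rec.part_number}"
                )
            last_part = rec.part_number
            if rec.object_beg != expected_beg:
                raise AGPValidationError(
                    f"{object_id} part {rec.part_number}: starts at {rec.object_beg}, "
                    f"expected {expected_beg} (discontinuity)"
                )
            expected_beg = rec.object_end + 1


def read_agp(path) -> list:
    """Read an AGP 2.0 file into a list of validated :class:`AGPRecord`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                records.append(_parse_row(line.split("\t"), lineno))
            except AGPParseError:
                raise
            except ValueError as exc:
                raise AGPValidationError(f"line {lineno}: {exc}") from exc
    validate_tiling(records)
    return records


def write_agp(records: Iterable[AGPRecord], path, header: str = "") -> None:
    records = list(records)
    validate_tiling(records)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for rec in records:
            if rec.component_type == "W":
                fields = [
                    rec.object_id,
                    rec.object_beg,
                    rec.object_end,
                    rec.part_number,
                    "W",
                    rec.component_id,
                    rec.component_beg,
                    rec.component_end,
                    rec.orientation,
                ]
            else:
                fields = [
                    rec.object_id,
                    rec.object_beg,
                    rec.object_end,
                    rec.part_number,
                    "U",
                    rec.gap_length,
                    rec.gap_type or "contig",
                    rec.linkage or "no",
                    rec.evidence or "na",
                ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def records_to_pseudomolecules(records: Iterable[AGPRecord]) -> list:
    """Group AGP rows per object into :class:`Pseudomolecule` containers."""
    by_object: "OrderedDict[str, list]" = OrderedDict()
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    pms = []
    for object_id, rows in by_object.items():
        total = rows[-1].object_end
        pms.append(Pseudomolecule(chromosome=object_id, records=rows, total_length=total))
    return pms
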