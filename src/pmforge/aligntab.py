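"""Readers for tabular pairwise-alignment files.

Supported dialects
------------------
``blast6``
    The 12-column tab format (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore).  Coordinates are 1-based
    inclusive; a subject start greater than its end encodes the minus strand.
``psl``
    The 21-column PSL layout (matches ... strand qName qSize qStart qEnd
    tName tSize tStart tEnd ...), already 0-based half-open.
``internal``
    The toolkit's own TSV: query, q_beg, q_end, target, t_beg, t_end,
    strand, score, identity_pct (0-based half-open, strand explicit).

All dialects normalize to :class:`~pmforge.records.GenericAlignment` with
0-based half-open coordinates on both sides and an explicit strand.
"""

from __future__ import annotations

from typing import List

from .records import GenericAlignment

DIALECTS = ("blast6", "psl", "internal")


def _from_blast6(fields: List[str], lineno: int) -> GenericAlignment:
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: blast6 needs 12 columns, got {len(fields)}")
    qstart, qend = int(fields[6]), int(fields[7])
    sstart, send = int(fields[8]), int(fields[9])
    if qstart > qend:  # blast never reports reversed query coords, but be safe
        qstart, qend = qend, qstart
    if sstart <= send:
        strand, t_beg, t_end = "+", sstart - 1, send
    else:
        strand, t_beg, t_end = "-", send - 1, sstart
    return GenericAlignment(
        query_id=fields[0],
        q_beg=qstart - 1,
        q_end=qend,
        target_id=fields[1],
        t_beg=t_beg,
        t_end=t_end,
        strand=strand,
        score=float(fields[11]),
        identity_pct=float(fields[2]),
        match_length=int(fields[3]),
    )


def _from_psl(fields: List[str], lineno: int) -> GenericAlignment:
    if len(fields) < 17:
        raise ValueError(f"line {lineno}: psl needs >= 17 columns, got {len(fields)}")
    matches = int(fields[0])
    strand = fields[8][0]
    return GenericAlignment(
        query_id=fields[9],
        q_beg=int(fields[11]),
        q_end=int(fields[12]),
        target_id=fields[13],
        t_beg=int(fields[15]),
        t_end=int(fields[16]),
        strand=strand,
        score=float(matches),
        identity_pct=100.0 * matches / max(1, matches + int(fields[1])),
        match_length=matches,
    )


def _from_internal(fields: List[str], lineno: int) -> GenericAlignment:
    if len(fields) < 8:
        raise ValueError(f"line {lineno}: internal dialect needs >= 8 columns")
    return GenericAlignment(
        query_id=fields[0],
        q_beg=int(fields[1]),
        q_end=int(fields[2]),
        target_id=fields[3],
        t_beg=int(fields[4]),
        t_end=int(fields[5]),
        strand=fields[6],
        score=float(fields[7]),
        identity_pct=float(fields[8]) if len(fields) > 8 else 100.0,
    )


_PARSERS = {"blast6": _from_blast6, "psl": _from_psl, "internal": _from_internal}


def read_alignment_table(path, dialect: str = "blast6") -> List[GenericAlignment]:
    """Read a tabular alignment file, normalizing coordinates and strand."""
    if dialect not in _PARSERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    parse = _PARSERS[dialect]
    out: List[GenericAlignment] = []
    with open(path) as fh:
        width = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"line {lineno}: ragged row ({len(fields)} columns, expected {width})"
                )
            out.append(parse(fields, lineno))
    return out


def write_alignment_table(alignments, path) -> None:
    """Write alignments in the internal 0-based half-open TSV dialect."""
    with open(path, "w") as fh:
        fh.write("#query\tq_beg\tq_end\ttarget\tt_beg\tt_end\tstrand\tscore\tidentity_pct\n")
        for a in alignments:
            fh.write(
                f"{a.query_id}\t{a.q_beg}\t{a.q_end}\t{a.target_id}\t{a.t_beg}\t"
                f"{a.t_end}\t{a.strand}\t{a.score:g}\t{a.identity_pct:g}\n"
            )
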