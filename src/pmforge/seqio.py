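"""FASTA handling and pseudomolecule sequence assembly.

Scaffolds placed with orientation ``-`` are reverse-complemented; gap rows
are rendered as runs of ``N``.  Scaffolds carrying an unknown orientation
(``?``) are written forward and reported, mirroring the practice of
assigning a random orientation to the few scaffolds that cannot be oriented.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Pseudomolecule, ScaffoldSeq

log = logging.getLogger(__name__)


def read_fasta(path) -> Dict[str, ScaffoldSeq]:
    scaffolds: Dict[str, ScaffoldSeq] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise ValueError(f"duplicate scaffold id {rec.id}")
        seq = str(rec.seq).upper()
        scaffolds[rec.id] = ScaffoldSeq(id=rec.id, length=len(seq), sequence=seq)
    return scaffolds


def write_fasta(scaffolds: Iterable[ScaffoldSeq], path, width: int = 80) -> None:
    records = []
    for sc in scaffolds:
        if sc.sequence is None:
            raise ValueError(f"scaffold {sc.id} has no sequence to write")
        records.append(SeqRecord(Seq(sc.sequence), id=sc.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_pm_sequence(
    pm: Pseudomolecule, scaffolds: Dict[str, ScaffoldSeq]
) -> Tuple[ScaffoldSeq, list]:
    """Render a pseudomolecule layout into its nucleotide sequence.

    Returns the assembled sequence plus the list of component ids that were
    written forward despite an unknown (``?``) orientation.
    """
    missing = [
        r.component_id
        for r in pm.records
        if r.component_type == "W" and r.component_id not in scaffolds
    ]
    if missing:
        raise KeyError(f"components absent from scaffold set: {sorted(set(missing))}")

    chunks = []
    unknown_orientation = []
    for rec in pm.records:
        if rec.component_type == "U":
            chunks.append("N" * rec.gap_length)
            continue
        sc = scaffolds[rec.component_id]
        if sc.sequence is None:
            raise ValueError(f"scaffold {sc.id} carries no sequence")
        if rec.component_end > sc.length:
            raise ValueError(
                f"{pm.chromosome}: component_end {rec.component_end} beyond "
                f"scaffold {sc.id} length {sc.length}"
            )
        piece = sc.sequence[rec.component_beg - 1 : rec.component_end]
        orientation = rec.orientation
        if orientation == "?":
            unknown_orientation.append(rec.component_id)
            log.warning(
                "%s: component %s has unknown orientation; written as '+'",
                pm.chromosome,
                rec.component_id,
            )
            orientation = "+"
        if orientation == "-":
            piece = revcomp(piece)
        chunks.append(piece)

    sequence = "".join(chunks)
    if len(sequence) != pm.total_length:
        raise AssertionError(
            f"{pm.chromosome}: assembled {len(sequence)} bp != declared {pm.total_length}"
        )
    return (
        ScaffoldSeq(id=pm.chromosome, length=len(sequence), sequence=sequence),
        unknown_orientation,
    )
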