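"""Marker anchoring: the STS filter cascade producing anchor points.

Stages, applied per marker in order:

1. **depth filter** — alignments largely buried under many competing
   alignments of the same query (or target region) are treated as repeat
   placements and dropped; alignments merely *touching* short repeats are
   kept.
2. **hit grouping** — nearby same-strand alignment blocks on one scaffold
   merge into indel-tolerant "hits".
3. **pair filter** — for markers assayed with a forward/reverse read pair,
   only convergently oriented pairs with a plausible separation survive.
4. **unique placement** — a marker is anchored only when its best hit beats
   the runner-up by a configurable score margin; otherwise it is ambiguous.

Markers designed a priori against the assembly skip the alignment stages:
their unique positions are already known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .records import AnchorPoint, GenericAlignment, MarkerHit

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage 1: repeat-depth filter


def _covered_fraction_at_depth(
    target: GenericAlignment,
    competitors: Sequence[GenericAlignment],
    min_depth: int,
    space: str,
) -> float:
    """Fraction of ``target``'s span covered by >= min_depth competitors."""
    if space == "query":
        lo, hi = target.q_beg, target.q_end
        spans = [(a.q_beg, a.q_end) for a in competitors]
    else:
        lo, hi = target.t_beg, target.t_end
        spans = [(a.t_beg, a.t_end) for a in competitors]
    length = hi - lo
    depth = np.zeros(length + 1, dtype=np.int32)
    for b, e in spans:
        b = max(b, lo)
        e = min(e, hi)
        if e > b:
            depth[b - lo] += 1
            depth[e - lo] -= 1
    depth = np.cumsum(depth[:-1])
    return float(np.mean(depth >= min_depth))


def depth_filter(
    alignments: Sequence[GenericAlignment],
    max_competitors: int = 5,
    frac: float = 0.20,
    space: str = "query",
) -> List[GenericAlignment]:
    """Remove alignments that are largely composed of likely repeats.

    An alignment is removed iff the fraction of its length over which at
    least ``max_competitors`` *other* alignments overlap is >= ``frac``.
    ``space`` selects whether competitors are other alignments of the same
    query over the same query region (default) or alignments crowding the
    same target region.
    """
    if space not in ("query", "target"):
        raise ValueError("space must be 'query' or 'target'")

    groups: Dict[str, List[GenericAlignment]] = {}
    for a in alignments:
        key = a.query_id if space == "query" else a.target_id
        groups.setdefault(key, []).append(a)

    kept: List[GenericAlignment] = []
    for members in groups.values():
        if len(members) <= max_competitors:
            kept.extend(members)
            continue
        for a in members:
            if space == "query":
                competitors = [
                    c for c in members if c is not a and c.q_end > a.q_beg and c.q_beg < a.q_end
                ]
            else:
                competitors = [
                    c for c in members if c is not a and c.t_end > a.t_beg and c.t_beg < a.t_end
                ]
            if len(competitors) < max_competitors:
                kept.append(a)
                continue
            covered = _covered_fraction_at_depth(a, competitors, max_competitors, space)
            if covered < frac:
                kept.append(a)
    # preserve input order
    kept_ids = {id(a) for a in kept}
    return [a for a in alignments if id(a) in kept_ids]


# ---------------------------------------------------------------------------
# stage 2: indel-tolerant hit grouping


def group_into_hits(
    alignments: Sequence[GenericAlignment],
    max_gap_bp: int = 1000,
) -> List[MarkerHit]:
    """Merge same-scaffold, same-strand blocks separated by small target gaps.

    The resulting hit spans the union of its blocks and scores the sum of
    member scores, so a marker interrupted by a small indel still competes
    as a single placement.
    """
    by_key: Dict[Tuple[str, str, str], List[GenericAlignment]] = {}
    for a in alignments:
        by_key.setdefault((a.query_id, a.target_id, a.strand), []).append(a)

    hits: List[MarkerHit] = []
    for (query_id, target_id, strand), blocks in by_key.items():
        blocks = sorted(blocks, key=lambda a: a.t_beg)
        current = [blocks[0]]
        for a in blocks[1:]:
            if a.t_beg - current[-1].t_end <= max_gap_bp:
                current.append(a)
            else:
                hits.append(_blocks_to_hit(query_id, target_id, strand, current))
                current = [a]
        hits.append(_blocks_to_hit(query_id, target_id, strand, current))
    return hits


def _blocks_to_hit(query_id, target_id, strand, blocks) -> MarkerHit:
    return MarkerHit(
        marker_id=query_id,
        scaffold_id=target_id,
        beg=min(a.t_beg for a in blocks),
        end=max(a.t_end for a in blocks),
        strand=strand,
        score=sum(a.score for a in blocks),
        n_blocks=len(blocks),
    )


# ---------------------------------------------------------------------------
# stage 3: forward/reverse pair consistency


def pair_filter(
    forward_hits: Sequence[MarkerHit],
    reverse_hits: Sequence[MarkerHit],
    expected_sep: Tuple[int, int] = (50, 5000),
) -> List[Tuple[MarkerHit, MarkerHit]]:
    """Keep forward/reverse hit pairs that are convergent and plausibly spaced.

    A pair survives when both hits are on one scaffold, oriented toward each
    other (the ``+`` hit upstream of the ``-`` hit), and the outer span lies
    within ``expected_sep``.
    """
    min_sep, max_sep = expected_sep
    pairs: List[Tuple[MarkerHit, MarkerHit]] = []
    for f in forward_hits:
        for r in reverse_hits:
            if f.scaffold_id != r.scaffold_id:
                continue
            if f.strand == r.strand:
                continue  # incorrect orientation
            plus, minus = (f, r) if f.strand == "+" else (r, f)
            if plus.beg > minus.beg:
                continue  # divergent, not convergent
            sep = max(f.end, r.end) - min(f.beg, r.beg)
            if min_sep <= sep <= max_sep:
                pairs.append((f, r))
    return pairs


def merge_pair(f: MarkerHit, r: MarkerHit, marker_id: str) -> MarkerHit:
    """Collapse a consistent read pair into one amplicon-spanning hit."""
    return MarkerHit(
        marker_id=marker_id,
        scaffold_id=f.scaffold_id,
        beg=min(f.beg, r.beg),
        end=max(f.end, r.end),
        strand="+",
        score=f.score + r.score,
        n_blocks=f.n_blocks + r.n_blocks,
    )


# ---------------------------------------------------------------------------
# stage 4: unique placement


def unique_placement(
    hits: Sequence[MarkerHit], min_ratio: float = 1.2
) -> Optional[MarkerHit]:
    """Return the winning hit when it is unique or clearly the best.

    With several placements, the best must out-score the runner-up by
    ``min_ratio``; otherwise the marker is ambiguous and ``None`` is
    returned.
    """
    if not hits:
        raise ValueError("unique_placement requires at least one hit")
    ranked = sorted(hits, key=lambda h: (-h.score, h.scaffold_id, h.beg))
    if len(ranked) == 1:
        return ranked[0]
    if ranked[0].score >= min_ratio * ranked[1].score:
        return ranked[0]
    return None


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class MarkerMeta:
    marker_id: str
    marker_class: str = "SNP"
    apriori_scaffold: Optional[str] = None
    apriori_pos: Optional[int] = None
    expected_sep: Optional[Tuple[int, int]] = None


@dataclass
class AnchorParams:
    max_competitors: int = 5
    depth_frac: float = 0.20
    depth_space: str = "query"
    max_gap_bp: int = 1000
    expected_sep: Tuple[int, int] = (50, 5000)
    min_ratio: float = 1.2


def _marker_of_query(query_id: str) -> Tuple[str, Optional[str]]:
    """Split 'marker/F' style read ids into (marker, read role)."""
    if query_id.endswith("/F") or query_id.endswith("/R"):
        return query_id[:-2], query_id[-1]
    return query_id, None


def anchor_markers(
    alignments: Sequence[GenericAlignment],
    genetic_map: Dict[str, Tuple[str, float]],
    metadata: Optional[Dict[str, MarkerMeta]] = None,
    coseg_groups: Optional[Dict[str, List[str]]] = None,
    params: Optional[AnchorParams] = None,
) -> Tuple[List[AnchorPoint], Dict[str, int], Dict[str, str]]:
    """Run the full cascade and emit one anchor point per placed marker.

    Parameters
    ----------
    alignments
        Depth-unfiltered marker alignments; paired reads use query ids of
        the form ``marker/F`` and ``marker/R``.
    genetic_map
        marker id -> (linkage group, cM).  Markers collapsed during map
        construction inherit the position of their co-segregation-group
        representative via ``coseg_groups`` (representative -> members).
    metadata
        Optional per-marker class / a-priori placement / separation bounds.

    Returns
    -------
    anchors, stage_report, outcomes
        ``stage_report`` counts markers entering/surviving each stage;
        ``outcomes`` records each marker's final classification.
    """
    params = params or AnchorParams()
    metadata = metadata or {}

    # position lookup, extended through co-segregation groups
    lookup: Dict[str, Tuple[str, float]] = dict(genetic_map)
    if coseg_groups:
        for rep, members in coseg_groups.items():
            if rep in lookup:
                for m in members:
                    lookup.setdefault(m, lookup[rep])

    anchors: List[AnchorPoint] = []
    outcomes: Dict[str, str] = {}

    # a-priori designed markers: position known by construction
    for meta in metadata.values():
        if meta.apriori_scaffold is not None and meta.marker_id in lookup:
            lg, cm = lookup[meta.marker_id]
            anchors.append(
                AnchorPoint(
                    marker_id=meta.marker_id,
                    scaffold_id=meta.apriori_scaffold,
                    position_bp=int(meta.apriori_pos),
                    linkage_group=lg,
                    position_cM=cm,
                    source_map="DM",
                    marker_class=meta.marker_class,
                )
            )
            outcomes[meta.marker_id] = "apriori"

    # group alignments per marker
    per_marker: Dict[str, List[GenericAlignment]] = {}
    for a in alignments:
        marker, _role = _marker_of_query(a.query_id)
        if marker in outcomes:
            continue  # already placed a priori
        per_marker.setdefault(marker, []).append(a)

    report = {
        "markers_with_alignments": len(per_marker),
        "apriori": sum(1 for v in outcomes.values() if v == "apriori"),
        "no_map_position": 0,
        "repeat_filtered": 0,
        "pair_filtered": 0,
        "ambiguous": 0,
        "placed": 0,
    }

    for marker, aligns in sorted(per_marker.items()):
        if marker not in lookup:
            outcomes[marker] = "no_map_position"
            report["no_map_position"] += 1
            log.debug("marker %s absent from map and co-segregation groups", marker)
            continue

        surviving = depth_filter(
            aligns, params.max_competitors, params.depth_frac, params.depth_space
        )
        if not surviving:
            outcomes[marker] = "repeat_filtered"
            report["repeat_filtered"] += 1
            continue

        roles = {_marker_of_query(a.query_id)[1] for a in surviving}
        if roles >= {"F", "R"}:
            f_hits = group_into_hits(
                [a for a in surviving if _marker_of_query(a.query_id)[1] == "F"],
                params.max_gap_bp,
            )
            r_hits = group_into_hits(
                [a for a in surviving if _marker_of_query(a.query_id)[1] == "R"],
                params.max_gap_bp,
            )
            meta = metadata.get(marker)
            sep = meta.expected_sep if meta and meta.expected_sep else params.expected_sep
            pairs = pair_filter(f_hits, r_hits, sep)
            if not pairs:
                outcomes[marker] = "pair_filtered"
                report["pair_filtered"] += 1
                continue
            hits = [merge_pair(f, r, marker) for f, r in pairs]
        else:
            hits = group_into_hits(surviving, params.max_gap_bp)

        best = unique_placement(hits, params.min_ratio)
        if best is None:
            outcomes[marker] = "ambiguous"
            report["ambiguous"] += 1
            continue

        lg, cm = lookup[marker]
        meta = metadata.get(marker)
        anchors.append(
            AnchorPoint(
                marker_id=marker,
                scaffold_id=best.scaffold_id,
                position_bp=best.midpoint,
                linkage_group=lg,
                position_cM=cm,
                source_map="DM",
                marker_class=meta.marker_class if meta else "SNP",
            )
        )
        outcomes[marker] = "placed"
        report["placed"] += 1

    return anchors, report, outcomes


# ---------------------------------------------------------------------------
# anchors TSV / GFF3 output


def write_anchors_tsv(anchors: Iterable[AnchorPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#marker\tscaffold\tposition_bp\tlinkage_group\tposition_cM\t"
            "source_map\tmarker_class\tweight\n"
        )
        for a in anchors:
            fh.write(
                f"{a.marker_id}\t{a.scaffold_id}\t{a.position_bp}\t{a.linkage_group}\t"
                f"{a.position_cM:g}\t{a.source_map}\t{a.marker_class}\t{a.weight:g}\n"
            )


def read_anchors_tsv(path) -> List[AnchorPoint]:
    anchors: List[AnchorPoint] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            anchors.append(
                AnchorPoint(
                    marker_id=f[0],
                    scaffold_id=f[1],
                    position_bp=int(f[2]),
                    linkage_group=f[3],
                    position_cM=float(f[4]),
                    source_map=f[5] if len(f) > 5 else "DM",
                    marker_class=f[6] if len(f) > 6 else "SNP",
                    weight=float(f[7]) if len(f) > 7 else 1.0,
                )
            )
    return anchors


def write_anchors_gff3(anchors: Iterable[AnchorPoint], path) -> None:
    """Emit anchors as a GFF3 marker track (1-based point features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in anchors:
            pos = a.position_bp + 1  # internal 0-based -> GFF 1-based
            attrs = (
                f"ID={a.marker_id};linkage_group={a.linkage_group};"
                f"cM={a.position_cM:g};source_map={a.source_map};"
                f"marker_class={a.marker_class}"
            )
            fh.write(
                f"{a.scaffold_id}\tpmforge\tgenetic_marker\t{pos}\t{pos}\t.\t.\t.\t{attrs}\n"
            )
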