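"""Pseudomolecule construction: backbone, chimera handling, AGP, statistics.

Stage I orders scaffolds along each chromosome from their genetic-map
anchors (backbone), then inserts foreign-map-only scaffolds where the
projected positions agree.  Stage II resolves within-bin order and scaffold
orientation from reciprocal link calls (with a map-slope fallback), splits
chimeric scaffolds at detected false joins, and emits the final AGP with
fixed 50-kb gaps plus per-chromosome assembly statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .mapqc import round_half_up
from .records import (
    AGPRecord,
    AnchorPoint,
    BackboneBin,
    ChimeraBreakpoint,
    DEFAULT_GAP_BP,
    DEFAULT_GAP_LINKAGE,
    DEFAULT_GAP_TYPE,
    LinkCall,
    Pseudomolecule,
)

log = logging.getLogger(__name__)

UNANCHORED_OBJECT = "chr00"

#: minimum |Theil-Sen slope| (cM/bp) to orient a scaffold from its own
#: anchors; 0.1 cM/Mb keeps zero-recombination regions unoriented
SLOPE_FLOOR_CM_PER_BP = 0.1 / 1e6


# ---------------------------------------------------------------------------
# Stage I: backbone


@dataclass
class BackboneResult:
    bins: Dict[str, List[BackboneBin]]
    positions: Dict[str, Tuple[str, float]]  # scaffold -> (chromosome, cM)
    ambiguous: List[str] = field(default_factory=list)  # routed to chimera screen


def build_backbone(
    anchors: Sequence[AnchorPoint],
    supermajority: float = 2.0 / 3.0,
) -> BackboneResult:
    """Order scaffolds along chromosomes from their backbone-map anchors.

    Each scaffold is assigned to its weighted-majority anchor chromosome
    (requiring a ``supermajority`` of anchor weight; below it the scaffold
    is routed to chimera screening instead of being placed whole) at the
    median cM of its anchors there.  Scaffolds sharing one cM value share a
    bin; order within a bin is unresolved at this stage.
    """
    by_scaffold: Dict[str, List[AnchorPoint]] = {}
    for a in anchors:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)

    positions: Dict[str, Tuple[str, float]] = {}
    ambiguous: List[str] = []
    for sid, sc_anchors in by_scaffold.items():
        weight_by_chrom: Dict[str, float] = {}
        for a in sc_anchors:
            weight_by_chrom[a.linkage_group] = (
                weight_by_chrom.get(a.linkage_group, 0.0) + a.weight
            )
        total = sum(weight_by_chrom.values())
        chrom, best = max(weight_by_chrom.items(), key=lambda kv: (kv[1], kv[0]))
        if best / total < supermajority:
            ambiguous.append(sid)
            log.info(
                "scaffold %s: anchors split across chromosomes (%s); chimera screen",
                sid,
                weight_by_chrom,
            )
            continue
        cms = [a.position_cM for a in sc_anchors if a.linkage_group == chrom]
        positions[sid] = (chrom, float(np.median(cms)))

    bins: Dict[str, List[BackboneBin]] = {}
    by_chrom: Dict[str, List[Tuple[float, str]]] = {}
    for sid, (chrom, cm) in positions.items():
        by_chrom.setdefault(chrom, []).append((cm, sid))
    for chrom, entries in by_chrom.items():
        entries.sort()
        chrom_bins: List[BackboneBin] = []
        for cm, sid in entries:
            if chrom_bins and chrom_bins[-1].cM == cm:
                chrom_bins[-1].scaffolds.append(sid)
                chrom_bins[-1].ordered = False
            else:
                chrom_bins.append(BackboneBin(chromosome=chrom, cM=cm, scaffolds=[sid]))
        bins[chrom] = chrom_bins
    return BackboneResult(bins=bins, positions=positions, ambiguous=sorted(ambiguous))


# ---------------------------------------------------------------------------
# Stage I: hierarchical insertion of foreign-map-only scaffolds


def hierarchical_insert(
    backbone: BackboneResult,
    rh_positions: Optional[Dict[str, Tuple[str, float]]] = None,
    tom_positions: Optional[Dict[str, Tuple[str, float]]] = None,
) -> Tuple[Dict[str, List[Tuple[str, float]]], Dict[str, object]]:
    """Insert foreign-anchored scaffolds into gaps of the backbone ordering.

    Foreign positions must already be projected onto the backbone map
    (see :func:`pmforge.insilico.project_map`).  Priority is backbone > RH >
    tomato: a scaffold absent from the backbone is inserted between backbone
    neighbours iff its projected cM falls inside their interval; when both
    foreign maps place it, they must agree on that interval, otherwise the
    scaffold stays unplaced and the conflict is reported.

    Returns the extended per-chromosome ordering (scaffold, cM) plus a
    report tallying scaffolds supported by 1, 2 or 3 maps.
    """
    rh_positions = rh_positions or {}
    tom_positions = tom_positions or {}

    ordering: Dict[str, List[Tuple[str, float]]] = {}
    for chrom, chrom_bins in backbone.bins.items():
        ordering[chrom] = [(sid, b.cM) for b in chrom_bins for sid in b.scaffolds]

    report = {"support_1": 0, "support_2": 0, "support_3": 0, "inserted": 0,
              "terminal": 0, "conflicts": [], "unplaceable": []}

    def _interval_of(chrom: str, cm: float) -> Optional[int]:
        """Insertion slot: -1 before the first backbone entry, i for the
        interval [entries[i].cM, entries[i+1].cM], len-1 beyond the last."""
        entries = ordering.get(chrom)
        if not entries:
            return None
        cms = [e[1] for e in entries]
        if cm < cms[0]:
            return -1
        if cm > cms[-1]:
            return len(cms) - 1
        for i in range(len(cms) - 1):
            if cms[i] <= cm <= cms[i + 1]:
                return i
        return len(cms) - 1 if len(cms) == 1 else None

    foreign_only = (set(rh_positions) | set(tom_positions)) - set(backbone.positions)
    for sid in sorted(foreign_only):
        rh = rh_positions.get(sid)
        tom = tom_positions.get(sid)
        if rh and tom:
            i_rh = _interval_of(rh[0], rh[1])
            i_tom = _interval_of(tom[0], tom[1])
            if rh[0] != tom[0] or i_rh != i_tom:
                report["conflicts"].append((sid, rh, tom))
                continue
            chrom, cm = rh
            n_support = 2
        else:
            chrom, cm = rh or tom
            n_support = 1
        idx = _interval_of(chrom, cm)
        if idx is None:
            report["unplaceable"].append(sid)
            continue
        entries = ordering[chrom]
        terminal = idx == -1 or idx == len(entries) - 1
        entries.insert(idx + 1, (sid, cm))
        report["inserted"] += 1
        report["terminal"] += terminal
        report[f"support_{n_support}"] += 1

    # backbone scaffolds corroborated by foreign maps
    for sid, (chrom, cm) in backbone.positions.items():
        n = 1
        for foreign in (rh_positions.get(sid), tom_positions.get(sid)):
            if foreign and foreign[0] == chrom:
                n += 1
        report[f"support_{n}"] += 1
    return ordering, report


# ---------------------------------------------------------------------------
# chimera detection and splitting


@dataclass
class _Run:
    chromosome: str
    cM_lo: float
    cM_hi: float
    bp_first: int
    bp_last: int
    support: int


def _anchor_runs(anchors: List[AnchorPoint], min_cM_gap: float) -> List[_Run]:
    runs: List[_Run] = []
    for a in sorted(anchors, key=lambda x: x.position_bp):
        if (
            runs
            and runs[-1].chromosome == a.linkage_group
            and min(
                abs(a.position_cM - runs[-1].cM_lo), abs(a.position_cM - runs[-1].cM_hi)
            )
            <= min_cM_gap
        ):
            r = runs[-1]
            r.cM_lo = min(r.cM_lo, a.position_cM)
            r.cM_hi = max(r.cM_hi, a.position_cM)
            r.bp_last = a.position_bp
            r.support += 1
        else:
            runs.append(
                _Run(
                    chromosome=a.linkage_group,
                    cM_lo=a.position_cM,
                    cM_hi=a.position_cM,
                    bp_first=a.position_bp,
                    bp_last=a.position_bp,
                    support=1,
                )
            )
    return runs


def detect_chimeras(
    anchors_by_scaffold: Dict[str, List[AnchorPoint]],
    min_support: int = 3,
    min_cM_gap: float = 10.0,
    max_breakpoints: int = 3,
) -> List[ChimeraBreakpoint]:
    """Find false sequence joins from discordant anchor runs along scaffolds.

    Anchors along each scaffold are segmented into maximal runs consistent
    in chromosome and local cM.  Adjacent well-supported runs (support >=
    ``min_support`` each) on different chromosomes, or separated by more
    than ``min_cM_gap`` on one chromosome, yield a breakpoint at the
    midpoint between the flanking anchors.  At most ``max_breakpoints``
    breakpoints are called per scaffold.
    """
    breakpoints: List[ChimeraBreakpoint] = []
    for sid in sorted(anchors_by_scaffold):
        runs = _anchor_runs(anchors_by_scaffold[sid], min_cM_gap)
        strong = [r for r in runs if r.support >= min_support]
        if len(strong) < len(runs):
            log.debug(
                "scaffold %s: %d low-support runs ignored as candidates",
                sid,
                len(runs) - len(strong),
            )
        # merge consecutive strong runs that are actually compatible (can
        # happen when a low-support spurious run separated them)
        merged: List[_Run] = []
        for r in strong:
            if (
                merged
                and merged[-1].chromosome == r.chromosome
                and max(merged[-1].cM_lo - r.cM_hi, r.cM_lo - merged[-1].cM_hi, 0.0)
                <= min_cM_gap
            ):
                m = merged[-1]
                m.cM_lo = min(m.cM_lo, r.cM_lo)
                m.cM_hi = max(m.cM_hi, r.cM_hi)
                m.bp_last = r.bp_last
                m.support += r.support
            else:
                merged.append(r)
        called = 0
        for left, right in zip(merged, merged[1:]):
            if called >= max_breakpoints:
                log.warning("scaffold %s: more than %d breakpoints; extras dropped", sid, max_breakpoints)
                break
            bp = (left.bp_last + right.bp_first) // 2
            breakpoints.append(
                ChimeraBreakpoint(
                    scaffold_id=sid,
                    breakpoint_bp=bp,
                    left_assignment=(left.chromosome, (left.cM_lo, left.cM_hi)),
                    right_assignment=(right.chromosome, (right.cM_lo, right.cM_hi)),
                    support_left=left.support,
                    support_right=right.support,
                )
            )
            called += 1
    return breakpoints


@dataclass
class Segment:
    id: str
    parent: str
    beg: int  # 0-based half-open slice of the parent
    end: int

    @property
    def length(self) -> int:
        return self.end - self.beg


def split_scaffold(
    scaffold_id: str, length: int, breakpoints: Sequence[int]
) -> List[Segment]:
    """Split a scaffold at the given internal breakpoints into ``n+1`` segments.

    Segment ids are ``<parent>_p1 .. _p{n+1}``; their half-open slices cover
    the parent exactly.  A scaffold with no breakpoints yields one segment
    that keeps the parent id.
    """
    bps = sorted(breakpoints)
    if len(set(bps)) != len(bps):
        raise ValueError(f"{scaffold_id}: duplicate breakpoints")
    for bp in bps:
        if not 0 < bp < length:
            raise ValueError(f"{scaffold_id}: breakpoint {bp} outside (0, {length})")
    if not bps:
        return [Segment(id=scaffold_id, parent=scaffold_id, beg=0, end=length)]
    edges = [0] + bps + [length]
    return [
        Segment(id=f"{scaffold_id}_p{i + 1}", parent=scaffold_id, beg=b, end=e)
        for i, (b, e) in enumerate(zip(edges, edges[1:]))
    ]


# ---------------------------------------------------------------------------
# Stage II: within-bin ordering with link evidence


def order_bins_with_links(
    bins: List[BackboneBin], links: Sequence[LinkCall]
) -> Tuple[List[str], List[str]]:
    """Linearize co-positional bins along a chromosome using link calls.

    A multi-scaffold bin whose members form a single simple path in the
    reciprocal-link graph is ordered along that path, directed so that the
    endpoint linked to a neighbouring bin sits adjacent to it.  Bins that
    cannot be resolved keep their input order and are flagged partially
    unordered.

    Returns (ordered scaffold ids, unresolved bin descriptions).
    """
    graph = nx.Graph()
    for link in links:
        if link.reciprocal:
            graph.add_edge(link.scaffold_a, link.scaffold_b)

    ordered: List[str] = []
    unresolved: List[str] = []
    for bi, b in enumerate(bins):
        members = list(b.scaffolds)
        if len(members) == 1:
            ordered.extend(members)
            continue
        sub = graph.subgraph([m for m in members if m in graph])
        path = _as_simple_path(sub, members)
        if path is None:
            ordered.extend(members)
            unresolved.append(f"{b.chromosome}@{b.cM:g}cM ({len(members)} scaffolds)")
            b.ordered = False
            continue
        prev_members = set(bins[bi - 1].scaffolds) if bi > 0 else set()
        next_members = set(bins[bi + 1].scaffolds) if bi + 1 < len(bins) else set()
        if prev_members and _linked_to(graph, path[-1], prev_members) and not _linked_to(
            graph, path[0], prev_members
        ):
            path = path[::-1]
        elif next_members and _linked_to(graph, path[0], next_members) and not _linked_to(
            graph, path[-1], next_members
        ):
            path = path[::-1]
        ordered.extend(path)
        b.ordered = True
    return ordered, unresolved


def _as_simple_path(sub: nx.Graph, members: List[str]) -> Optional[List[str]]:
    if sub.number_of_nodes() != len(members) or not nx.is_connected(sub):
        return None
    degrees = dict(sub.degree())
    tips = [n for n, d in degrees.items() if d == 1]
    if len(tips) != 2 or any(d > 2 for d in degrees.values()):
        return None
    path = [min(tips)]
    seen = {path[0]}
    while len(path) < len(members):
        nxt = [n for n in sub.neighbors(path[-1]) if n not in seen]
        if len(nxt) != 1:
            return None
        path.append(nxt[0])
        seen.add(nxt[0])
    return path


def _linked_to(graph: nx.Graph, node: str, others: Set[str]) -> bool:
    return node in graph and any(n in others for n in graph.neighbors(node))


# ---------------------------------------------------------------------------
# orientation


def theil_sen_slope(anchors: Sequence[AnchorPoint]) -> Optional[float]:
    """Median (Theil-Sen) slope of cM vs bp within one scaffold, or None."""
    if len(anchors) < 2:
        return None
    bp = np.array([a.position_bp for a in anchors], dtype=float)
    cm = np.array([a.position_cM for a in anchors], dtype=float)
    if np.all(bp == bp[0]):
        return None
    return float(sstats.theilslopes(cm, bp).slope)


def orient_segments(
    segment_ids: Iterable[str],
    links: Sequence[LinkCall],
    anchors_by_segment: Dict[str, List[AnchorPoint]],
    slope_floor: float = SLOPE_FLOOR_CM_PER_BP,
) -> Tuple[Dict[str, str], Dict[str, str], int]:
    """Assign '+', '-' or '?' to each segment.

    Link-graph components carry internally consistent relative orientations
    (from reciprocal end pairings); each component is pinned to an absolute
    strand by the majority of its members' anchor cM-vs-bp Theil-Sen slopes
    (slopes below ``slope_floor`` abstain — zero-recombination regions must
    not vote).  Segments outside any component fall back to their own slope.

    Returns (orientation per segment, orientation source per segment,
    number of link-parity conflicts).
    """
    from .linkpeak import propagate_orientations

    signs, components, n_conflicts, conflicted = propagate_orientations(links)

    def _slope_sign(sid: str) -> Optional[int]:
        slope = theil_sen_slope(anchors_by_segment.get(sid, []))
        if slope is None or abs(slope) < slope_floor:
            return None
        return 1 if slope > 0 else -1

    orientation: Dict[str, str] = {}
    source: Dict[str, str] = {}
    in_component: Set[str] = set()
    for component in components:
        in_component.update(component)
        if component & conflicted:
            for sid in component:
                orientation[sid] = "?"
                source[sid] = "conflict"
            continue
        vote = 0
        for sid in component:
            s = _slope_sign(sid)
            if s is not None:
                vote += s * signs[sid]
        if vote == 0:
            for sid in component:
                orientation[sid] = "?"
                source[sid] = "link_unanchored"
            continue
        flip = 1 if vote > 0 else -1
        for sid in component:
            orientation[sid] = "+" if signs[sid] * flip > 0 else "-"
            source[sid] = "link"

    for sid in segment_ids:
        if sid in orientation:
            continue
        s = _slope_sign(sid)
        if s is None:
            orientation[sid] = "?"
            source[sid] = "none"
        else:
            orientation[sid] = "+" if s > 0 else "-"
            source[sid] = "slope"
    return orientation, source, n_conflicts


# ---------------------------------------------------------------------------
# AGP finalization


def finalize_agp(
    orderings: Dict[str, List[str]],
    orientations: Dict[str, str],
    segment_lengths: Dict[str, int],
    unplaced: Optional[Sequence[str]] = None,
    gap_bp: int = DEFAULT_GAP_BP,
    gap_type: str = DEFAULT_GAP_TYPE,
    linkage: str = DEFAULT_GAP_LINKAGE,
) -> Tuple[List[AGPRecord], List[Pseudomolecule]]:
    """Emit the final AGP: W rows alternating with fixed-size U gap rows.

    No gap sizes are estimated; every join uses the same ``gap_bp`` run of
    Ns.  Unplaced segments are collected into the unanchored bin
    (:data:`UNANCHORED_OBJECT`, the "chromosome 0" convention) with unknown
    orientation.
    """
    seen: Set[str] = set()
    records: List[AGPRecord] = []
    all_objects = dict(orderings)
    if unplaced:
        all_objects[UNANCHORED_OBJECT] = list(unplaced)

    for object_id in sorted(all_objects):
        segments = all_objects[object_id]
        pos = 1
        part = 1
        for i, sid in enumerate(segments):
            if sid in seen:
                raise ValueError(f"segment {sid} placed more than once")
            seen.add(sid)
            length = segment_lengths[sid]
            if i > 0:
                records.append(
                    AGPRecord(
                        object_id=object_id,
                        object_beg=pos,
                        object_end=pos + gap_bp - 1,
                        part_number=part,
                        component_type="U",
                        gap_length=gap_bp,
                        gap_type=gap_type,
                        linkage=linkage,
                        evidence="na" if linkage == "no" else "paired-ends",
                    )
                )
                pos += gap_bp
                part += 1
            orientation = orientations.get(sid, "?") if object_id != UNANCHORED_OBJECT else "?"
            records.append(
                AGPRecord(
                    object_id=object_id,
                    object_beg=pos,
                    object_end=pos + length - 1,
                    part_number=part,
                    component_type="W",
                    component_id=sid,
                    component_beg=1,
                    component_end=length,
                    orientation=orientation,
                )
            )
            pos += length
            part += 1

    from .agp import records_to_pseudomolecules, validate_tiling

    validate_tiling(records)
    return records, records_to_pseudomolecules(records)


# ---------------------------------------------------------------------------
# statistics


def n50(lengths: Sequence[int]) -> float:
    """N50 of a length set: the length at which the running (descending)
    cumulative sum first reaches half the total."""
    if not lengths:
        return 0.0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return float(x)
    return float(ordered[-1])


def oriented_percentage(oriented_mb: float, anchored_mb: float) -> float:
    """Size-based oriented percentage, rounded half-up to one decimal."""
    if anchored_mb == 0:
        return 0.0
    return round_half_up(100.0 * oriented_mb / anchored_mb, 1)


def assembly_stats(
    agp_records: Sequence[AGPRecord],
    unanchored_object: str = UNANCHORED_OBJECT,
) -> pd.DataFrame:
    """Per-chromosome anchoring/orientation statistics from an AGP.

    Anchored = components placed on real chromosome objects (count and Mb);
    oriented = anchored components with a known ('+'/'-') orientation;
    oriented percentage is size-based.  The Total row sums counts and sizes
    but *averages* the per-chromosome N50s and oriented percentages, the
    convention of assembly-improvement summary tables.
    """
    rows = []
    by_object: Dict[str, List[AGPRecord]] = {}
    for rec in agp_records:
        if rec.component_type == "W":
            by_object.setdefault(rec.object_id, []).append(rec)

    for object_id in sorted(by_object):
        if object_id == unanchored_object:
            continue
        comps = by_object[object_id]
        lengths = [r.span for r in comps]
        oriented = [r for r in comps if r.orientation in ("+", "-")]
        anchored_mb = sum(lengths) / 1e6
        oriented_mb = sum(r.span for r in oriented) / 1e6
        rows.append(
            {
                "chromosome": object_id,
                "anchored_count": len(comps),
                "anchored_Mb": anchored_mb,
                "oriented_count": len(oriented),
                "oriented_Mb": oriented_mb,
                "oriented_pct": oriented_percentage(oriented_mb, anchored_mb),
                "N50_Mb": n50(lengths) / 1e6,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    total = {
        "chromosome": "Total",
        "anchored_count": int(df["anchored_count"].sum()),
        "anchored_Mb": float(df["anchored_Mb"].sum()),
        "oriented_count": int(df["oriented_count"].sum()),
        "oriented_Mb": float(df["oriented_Mb"].sum()),
        "oriented_pct": round_half_up(float(df["oriented_pct"].mean()), 1),
        "N50_Mb": float(df["N50_Mb"].mean()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# clone-assembly validation graph


def validate_with_clone_assemblies(
    contig_matches: Sequence[Tuple[str, str, str]],
    agp_records: Sequence[AGPRecord],
    unanchored_object: str = UNANCHORED_OBJECT,
) -> Dict[str, list]:
    """Check AGP joins against independent clone (BAC) assemblies.

    ``contig_matches`` are pre-filtered (clone label, clone contig, segment)
    matches.  A graph links segments to clone contigs (matches) and contigs
    to their clone label (membership); a join between two AGP-adjacent
    segments is *validated* when a cycle through a clone label connects
    them — i.e. one clone's sequence reaches both sides of the join.  A
    clone bridging two non-adjacent segments is a contradiction; adjacent
    pairs with no clone evidence are untested.
    """
    graph = nx.Graph()
    for clone, contig, segment in contig_matches:
        graph.add_edge(("label", clone), ("contig", contig))
        graph.add_edge(("contig", contig), ("segment", segment))

    adjacent: List[Tuple[str, str]] = []
    by_object: Dict[str, List[str]] = {}
    for rec in agp_records:
        if rec.component_type == "W" and rec.object_id != unanchored_object:
            by_object.setdefault(rec.object_id, []).append(rec.component_id)
    for comps in by_object.values():
        adjacent.extend(zip(comps, comps[1:]))
    adjacent_set = {frozenset(p) for p in adjacent}

    clone_segments: Dict[str, Set[str]] = {}
    for node in graph.nodes:
        if node[0] != "label":
            continue
        segs: Set[str] = set()
        for contig in graph.neighbors(node):
            for other in graph.neighbors(contig):
                if other[0] == "segment":
                    segs.add(other[1])
        clone_segments[node[1]] = segs

    validated, contradicted = [], []
    for a, b in adjacent:
        supporting = [c for c, segs in clone_segments.items() if a in segs and b in segs]
        if supporting:
            validated.append((a, b, sorted(supporting)))
    for clone, segs in sorted(clone_segments.items()):
        for pair in {frozenset((x, y)) for x in segs for y in segs if x < y}:
            if pair not in adjacent_set:
                x, y = sorted(pair)
                contradicted.append((x, y, clone))
    untested = [
        (a, b) for a, b in adjacent
        if not any(v[0] == a and v[1] == b for v in validated)
    ]
    return {"validated": validated, "contradicted": contradicted, "untested": untested}
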