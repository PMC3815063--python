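"""End-to-end assembly: anchors -> chimera splitting -> backbone -> links -> AGP.

This module wires the individual stages into the full two-stage build and
provides truth-based evaluation helpers for simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .anchoring import AnchorParams, anchor_markers
from .builder import (
    BackboneResult,
    Segment,
    assembly_stats,
    build_backbone,
    detect_chimeras,
    finalize_agp,
    orient_segments,
    order_bins_with_links,
    split_scaffold,
)
from .linkpeak import call_links, classify_mate_pairs, link_score_profile
from .records import AnchorPoint, GenericAlignment, LibrarySpec, LinkCall, MatePairRecord

log = logging.getLogger(__name__)


@dataclass
class AssemblyResult:
    anchors: List[AnchorPoint]
    anchor_report: Dict[str, int]
    breakpoints: list
    segments: Dict[str, Segment]  # segment id -> slice of parent scaffold
    backbone: BackboneResult
    orderings: Dict[str, List[str]]
    unresolved_bins: List[str]
    links: List[LinkCall]
    suggestions: List[LinkCall]
    orientations: Dict[str, str]
    orientation_source: Dict[str, str]
    orientation_conflicts: int
    unplaced: List[str]
    agp_records: list
    pseudomolecules: list
    stats: object
    anchors_by_segment: Dict[str, List[AnchorPoint]] = field(default_factory=dict)


def _remap_anchor(a: AnchorPoint, segments: List[Segment]) -> Optional[AnchorPoint]:
    for seg in segments:
        if seg.beg <= a.position_bp < seg.end:
            return AnchorPoint(
                marker_id=a.marker_id,
                scaffold_id=seg.id,
                position_bp=a.position_bp - seg.beg,
                linkage_group=a.linkage_group,
                position_cM=a.position_cM,
                source_map=a.source_map,
                marker_class=a.marker_class,
                weight=a.weight,
            )
    return None


def _remap_pair_end(
    sid: str, pos: int, segments_by_parent: Dict[str, List[Segment]]
) -> Tuple[str, int]:
    for seg in segments_by_parent[sid]:
        if seg.beg <= pos < seg.end:
            return seg.id, pos - seg.beg
    # position beyond declared length (defensive): clamp into last segment
    seg = segments_by_parent[sid][-1]
    return seg.id, min(pos, seg.end - 1) - seg.beg


def assemble(
    scaffold_lengths: Dict[str, int],
    alignments: Sequence[GenericAlignment],
    genetic_map: Dict[str, Tuple[str, float]],
    pairs: Sequence[MatePairRecord],
    libraries: Dict[str, LibrarySpec],
    anchor_params: Optional[AnchorParams] = None,
    window_bp: int = 10_000,
    step_bp: int = 5_000,
    min_link_score: float = 4.0,
    max_noise_ratio: float = 0.5,
    min_chimera_support: int = 3,
    min_cM_gap: float = 10.0,
    gap_bp: int = 50_000,
) -> AssemblyResult:
    """Run the full two-stage pseudomolecule build.

    Stage I anchors markers, screens scaffolds for false joins (splitting
    them at detected breakpoints), and orders the resulting segments along
    chromosomes by their median anchor cM.  Stage II scores mate-pair link
    evidence over the segments, resolves co-positional bins and scaffold
    orientations from reciprocal links (map-slope fallback), and emits the
    AGP with fixed gaps plus summary statistics.
    """
    anchors, report, _outcomes = anchor_markers(
        alignments, genetic_map, params=anchor_params
    )

    anchors_by_scaffold: Dict[str, List[AnchorPoint]] = {}
    for a in anchors:
        anchors_by_scaffold.setdefault(a.scaffold_id, []).append(a)

    breakpoints = detect_chimeras(
        anchors_by_scaffold, min_support=min_chimera_support, min_cM_gap=min_cM_gap
    )
    bp_by_scaffold: Dict[str, List[int]] = {}
    for b in breakpoints:
        bp_by_scaffold.setdefault(b.scaffold_id, []).append(b.breakpoint_bp)

    segments_by_parent: Dict[str, List[Segment]] = {}
    segments: Dict[str, Segment] = {}
    for sid, length in scaffold_lengths.items():
        segs = split_scaffold(sid, length, bp_by_scaffold.get(sid, []))
        segments_by_parent[sid] = segs
        for seg in segs:
            segments[seg.id] = seg
    seg_lengths = {seg.id: seg.length for seg in segments.values()}

    anchors_by_segment: Dict[str, List[AnchorPoint]] = {}
    for sid, sc_anchors in anchors_by_scaffold.items():
        for a in sc_anchors:
            ra = _remap_anchor(a, segments_by_parent[sid])
            if ra is not None:
                anchors_by_segment.setdefault(ra.scaffold_id, []).append(ra)

    seg_anchors_flat = [a for lst in anchors_by_segment.values() for a in lst]
    backbone = build_backbone(seg_anchors_flat)

    # mate pairs lifted into segment coordinates
    seg_pairs: List[MatePairRecord] = []
    for p in pairs:
        if p.scaffold1 not in segments_by_parent or p.scaffold2 not in segments_by_parent:
            continue
        s1, pos1 = _remap_pair_end(p.scaffold1, p.pos1, segments_by_parent)
        s2, pos2 = _remap_pair_end(p.scaffold2, p.pos2, segments_by_parent)
        seg_pairs.append(
            MatePairRecord(
                pair_id=p.pair_id,
                lib_id=p.lib_id,
                scaffold1=s1,
                pos1=pos1,
                strand1=p.strand1,
                scaffold2=s2,
                pos2=pos2,
                strand2=p.strand2,
                mapq_ok=p.mapq_ok,
            )
        )

    parent_of = {seg.id: seg.parent for seg in segments.values()}
    _satisfied, unsatisfied = classify_mate_pairs(seg_pairs, libraries, parent=parent_of)
    touching: Dict[str, List[MatePairRecord]] = {}
    for p in unsatisfied:
        touching.setdefault(p.scaffold1, []).append(p)
        touching.setdefault(p.scaffold2, []).append(p)
    profiles = [
        link_score_profile(
            seg_id, seg_lengths[seg_id], touching.get(seg_id, []), libraries,
            window_bp=window_bp, step_bp=step_bp,
        )
        for seg_id in sorted(seg_lengths)
    ]
    links, suggestions = call_links(
        profiles, libraries, min_score=min_link_score, max_noise_ratio=max_noise_ratio
    )

    orderings: Dict[str, List[str]] = {}
    unresolved: List[str] = []
    for chrom, bins in sorted(backbone.bins.items()):
        ordered, bad = order_bins_with_links(bins, links)
        orderings[chrom] = ordered
        unresolved.extend(bad)

    placed = {sid for ordered in orderings.values() for sid in ordered}
    orientations, source, n_conflicts = orient_segments(
        sorted(placed), links, anchors_by_segment
    )
    unplaced = sorted(set(seg_lengths) - placed)

    agp_records, pms = finalize_agp(
        orderings, orientations, seg_lengths, unplaced=unplaced, gap_bp=gap_bp
    )
    stats = assembly_stats(agp_records)

    return AssemblyResult(
        anchors=anchors,
        anchor_report=report,
        breakpoints=breakpoints,
        segments=segments,
        backbone=backbone,
        orderings=orderings,
        unresolved_bins=unresolved,
        links=links,
        suggestions=suggestions,
        orientations=orientations,
        orientation_source=source,
        orientation_conflicts=n_conflicts,
        unplaced=unplaced,
        agp_records=agp_records,
        pseudomolecules=pms,
        stats=stats,
        anchors_by_segment=anchors_by_segment,
    )


# ---------------------------------------------------------------------------
# truth-based evaluation (simulated data)


def map_segments_to_truth(result: AssemblyResult, truth) -> Dict[str, str]:
    """Associate each built segment with the truth part it mostly covers."""
    mapping: Dict[str, str] = {}
    for seg in result.segments.values():
        sc = truth.scaffolds.get(seg.parent)
        if sc is None:
            continue
        best_key, best_olap = None, 0
        for idx, part in enumerate(sc.parts):
            p_beg = part.scaffold_offset
            p_end = part.scaffold_offset + part.length
            olap = min(seg.end, p_end) - max(seg.beg, p_beg)
            if olap > best_olap:
                best_olap = olap
                best_key = sc.part_key(idx)
        if best_key is not None:
            mapping[seg.id] = best_key
    return mapping


@dataclass
class RecoveryReport:
    kendall_tau: Dict[str, float]
    mean_kendall_tau: float
    orientation_accuracy: float
    link_orientation_accuracy: float
    n_oriented: int
    n_link_oriented: int
    chimeras_expected: int
    chimeras_detected: int
    false_chimera_calls: int
    breakpoint_errors_bp: List[int]
    adjacency_recall: float
    false_adjacencies: int
    placed_fraction: float


def evaluate_against_truth(result: AssemblyResult, truth) -> RecoveryReport:
    """Score a build against simulator ground truth."""
    seg_to_part = map_segments_to_truth(result, truth)
    part_chrom = {}
    part_rank = {}
    for chrom, keys in truth.order.items():
        for rank, key in enumerate(keys):
            part_chrom[key] = chrom
            part_rank[key] = rank

    taus: Dict[str, float] = {}
    for chrom, ordered in result.orderings.items():
        built_ranks = []
        true_ranks = []
        for i, seg_id in enumerate(ordered):
            key = seg_to_part.get(seg_id)
            if key is None or part_chrom.get(key) != chrom:
                continue
            built_ranks.append(i)
            true_ranks.append(part_rank[key])
        if len(built_ranks) >= 2:
            tau = sstats.kendalltau(built_ranks, true_ranks).statistic
            taus[chrom] = float(tau)

    n_oriented = n_correct = 0
    n_link = n_link_correct = 0
    for seg_id, orientation in result.orientations.items():
        if orientation == "?":
            continue
        key = seg_to_part.get(seg_id)
        if key is None:
            continue
        truth_ori = truth.orientation.get(key)
        if truth_ori is None:
            continue
        n_oriented += 1
        ok = orientation == truth_ori
        n_correct += ok
        if result.orientation_source.get(seg_id) == "link":
            n_link += 1
            n_link_correct += ok

    # chimera recovery
    true_chimeras = {
        sid: sc.breakpoints for sid, sc in truth.scaffolds.items() if sc.is_chimeric
    }
    detected_by_scaffold: Dict[str, List[int]] = {}
    for b in result.breakpoints:
        detected_by_scaffold.setdefault(b.scaffold_id, []).append(b.breakpoint_bp)
    detected = 0
    errors: List[int] = []
    for sid, true_bps in true_chimeras.items():
        got = sorted(detected_by_scaffold.get(sid, []))
        for tb in true_bps:
            if got:
                err = min(abs(g - tb) for g in got)
                detected += 1
                errors.append(int(err))
    false_calls = sum(
        len(v) for sid, v in detected_by_scaffold.items() if sid not in true_chimeras
    )

    # adjacency recovery from reciprocal links
    called_pairs = {
        frozenset((seg_to_part.get(l.scaffold_a), seg_to_part.get(l.scaffold_b)))
        for l in result.links
    }
    called_pairs = {p for p in called_pairs if None not in p and len(p) == 2}
    true_adj = set(truth.adjacencies)
    recalled = len(true_adj & called_pairs)
    false_adj = len(called_pairs - true_adj)

    n_parts = sum(len(sc.parts) for sc in truth.scaffolds.values())
    placed = sum(len(o) for o in result.orderings.values())

    return RecoveryReport(
        kendall_tau=taus,
        mean_kendall_tau=float(np.mean(list(taus.values()))) if taus else float("nan"),
        orientation_accuracy=n_correct / n_oriented if n_oriented else float("nan"),
        link_orientation_accuracy=(
            n_link_correct / n_link if n_link else float("nan")
        ),
        n_oriented=n_oriented,
        n_link_oriented=n_link,
        chimeras_expected=sum(len(v) for v in true_chimeras.values()),
        chimeras_detected=detected,
        false_chimera_calls=false_calls,
        breakpoint_errors_bp=errors,
        adjacency_recall=recalled / len(true_adj) if true_adj else float("nan"),
        false_adjacencies=false_adj,
        placed_fraction=placed / n_parts if n_parts else float("nan"),
    )
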