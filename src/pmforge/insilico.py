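"""In-silico (indirect) anchoring from clone ends, WGP tags and synteny.

Proxy anchors extend the marker backbone: unsequenced clones are placed on
scaffolds by their 25-nt whole-genome-profiling (WGP) sequence tags, clone
ends and synteny matches against a related genome are filtered with strict
published-style thresholds, and foreign-map genetic positions are projected
onto the backbone map through scaffolds anchored in both maps, honouring a
declared inversion catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .records import AnchorPoint, CloneEndHit, SyntenyMatch, WGPTagHit

log = logging.getLogger(__name__)

#: default width of one bin of an ultra-high-density (bin-based) map, in cM
DEFAULT_BIN_WIDTH_CM = 0.8

#: clones whose map position spans this many bins or more are down-weighted
WIDE_BIN_SPAN = 5


def filter_clone_end_hits(
    hits: Iterable[CloneEndHit], min_len: int = 400, min_bits: float = 700.0
) -> List[CloneEndHit]:
    """Keep hits with match length >= ``min_len`` and bit score > ``min_bits``.

    The length bound is a minimum (inclusive); the bit-score bound is strict
    ("exceeding").
    """
    return [h for h in hits if h.match_length >= min_len and h.bit_score > min_bits]


def filter_synteny_matches(
    matches: Iterable[SyntenyMatch], min_len: int = 1000, min_identity: float = 97.0
) -> List[SyntenyMatch]:
    """Keep matches longer than ``min_len`` bp with identity > ``min_identity``.

    Both bounds are strict, following the "longer than / greater than"
    convention for alignment-based validation filters.
    """
    return [
        m for m in matches if m.length_bp > min_len and m.identity_pct > min_identity
    ]


@dataclass
class ClonePlacement:
    clone_id: str
    scaffold_id: str
    beg: int
    end: int
    n_tags: int

    @property
    def midpoint(self) -> int:
        return (self.beg + self.end) // 2


def place_clone_by_wgp_tags(
    tag_hits: Sequence[WGPTagHit],
    min_unique_tags: int = 3,
    majority_frac: float = 0.8,
) -> Optional[ClonePlacement]:
    """Place one clone on the scaffold holding a clear majority of its tags.

    Only unique tag hits count.  The clone is placed when one scaffold holds
    at least ``majority_frac`` of them and that count reaches
    ``min_unique_tags``; the placement span is the min..max tag position.
    """
    unique = [h for h in tag_hits if h.unique]
    if not unique:
        return None
    clone_ids = {h.clone_id for h in unique}
    if len(clone_ids) != 1:
        raise ValueError(f"tag hits for multiple clones passed: {sorted(clone_ids)}")
    by_scaffold: Dict[str, List[WGPTagHit]] = {}
    for h in unique:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    best_scaffold, best_hits = max(
        by_scaffold.items(), key=lambda kv: (len(kv[1]), kv[0])
    )
    if len(best_hits) < min_unique_tags:
        return None
    if len(best_hits) < majority_frac * len(unique):
        return None
    positions = [h.position_bp for h in best_hits]
    return ClonePlacement(
        clone_id=unique[0].clone_id,
        scaffold_id=best_scaffold,
        beg=min(positions),
        end=max(positions),
        n_tags=len(best_hits),
    )


def clones_to_anchors(
    placements: Iterable[ClonePlacement],
    clone_map: Dict[str, Tuple[str, float, float]],
    bin_width_cM: float = DEFAULT_BIN_WIDTH_CM,
    bin_based: bool = True,
) -> List[AnchorPoint]:
    """Convert placed, mapped clones into proxy anchor points (source RH).

    ``clone_map`` maps clone id -> (linkage group, bin_lo, bin_hi) when
    ``bin_based`` (bin interval midpoint converts to pseudo-cM by the
    configured bin width), else (linkage group, cM, cM).  Clones whose map
    interval spans ``WIDE_BIN_SPAN`` or more bins are kept but down-weighted:
    their position is relatively inaccurate.
    """
    anchors: List[AnchorPoint] = []
    for placement in placements:
        entry = clone_map.get(placement.clone_id)
        if entry is None:
            log.debug("clone %s placed but unmapped; skipped", placement.clone_id)
            continue
        lg, lo, hi = entry
        if hi < lo:
            lo, hi = hi, lo
        mid = (lo + hi) / 2.0
        cm = mid * bin_width_cM if bin_based else mid
        weight = 1.0
        if bin_based and (hi - lo + 1) >= WIDE_BIN_SPAN:
            weight = 0.5
        anchors.append(
            AnchorPoint(
                marker_id=placement.clone_id,
                scaffold_id=placement.scaffold_id,
                position_bp=placement.midpoint,
                linkage_group=lg,
                position_cM=cm,
                source_map="RH",
                marker_class="clone_proxy",
                weight=weight,
            )
        )
    return anchors


def synteny_to_anchors(
    matches: Iterable[SyntenyMatch],
    chromosome_to_lg: Dict[str, str],
    cM_of_other_bp,
) -> List[AnchorPoint]:
    """Turn filtered synteny matches into proxy anchors (source TOM).

    ``cM_of_other_bp(chromosome, bp)`` converts a position on the related
    genome into its map position (e.g. by interpolating that genome's own
    Marey curve).
    """
    anchors: List[AnchorPoint] = []
    for i, m in enumerate(matches):
        lg = chromosome_to_lg.get(m.other_chromosome)
        if lg is None:
            continue
        other_mid = (m.other_beg + m.other_end) // 2
        anchors.append(
            AnchorPoint(
                marker_id=f"synteny_{m.other_chromosome}_{i}",
                scaffold_id=m.ref_scaffold,
                position_bp=(m.ref_beg + m.ref_end) // 2,
                linkage_group=lg,
                position_cM=float(cM_of_other_bp(m.other_chromosome, other_mid)),
                source_map="TOM",
                marker_class="synteny_proxy",
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# cross-map projection


@dataclass
class ProjectedAnchor:
    anchor: AnchorPoint
    backbone_cM: float
    extrapolated: bool
    in_inversion: bool


def project_map(
    foreign_anchors: Sequence[AnchorPoint],
    shared_points: Dict[str, List[Tuple[float, float]]],
    inversions_cM: Optional[Dict[str, List[Tuple[float, float]]]] = None,
) -> Tuple[List[ProjectedAnchor], List[str]]:
    """Re-express foreign-map anchor positions in backbone cM.

    Parameters
    ----------
    foreign_anchors
        Anchors whose ``position_cM`` lives on the foreign map.
    shared_points
        Per linkage group, (foreign cM, backbone cM) pairs from scaffolds
        anchored in both maps; these define a monotone piecewise-linear
        transform.  Groups with fewer than two shared points are skipped.
    inversions_cM
        Per linkage group, declared inversion intervals in *foreign* cM.
        Anchor positions inside an interval are reflected about its midpoint
        before transformation, so the local order reverses as the known
        structural difference demands.

    Returns the projected anchors plus the list of skipped linkage groups.
    """
    inversions_cM = inversions_cM or {}
    projected: List[ProjectedAnchor] = []
    skipped: List[str] = []

    by_group: Dict[str, List[AnchorPoint]] = {}
    for a in foreign_anchors:
        by_group.setdefault(a.linkage_group, []).append(a)

    for lg, anchors in sorted(by_group.items()):
        pts = sorted(shared_points.get(lg, []))
        if len(pts) < 2:
            skipped.append(lg)
            log.warning("linkage group %s: <2 shared scaffolds; projection skipped", lg)
            continue
        fx = np.array([p[0] for p in pts], dtype=float)
        fy = np.array([p[1] for p in pts], dtype=float)
        # enforce monotone transform (shared points should already be ordered)
        fy = np.maximum.accumulate(fy)
        intervals = inversions_cM.get(lg, [])
        for a in anchors:
            x = a.position_cM
            in_inv = False
            for lo, hi in intervals:
                if lo <= x <= hi:
                    x = lo + hi - x  # reflect local order inside the inversion
                    in_inv = True
                    break
            if x <= fx[0]:
                slope = (fy[1] - fy[0]) / (fx[1] - fx[0]) if fx[1] > fx[0] else 0.0
                y = fy[0] + slope * (x - fx[0])
                extrapolated = x < fx[0]
            elif x >= fx[-1]:
                slope = (fy[-1] - fy[-2]) / (fx[-1] - fx[-2]) if fx[-1] > fx[-2] else 0.0
                y = fy[-1] + slope * (x - fx[-1])
                extrapolated = x > fx[-1]
            else:
                y = float(np.interp(x, fx, fy))
                extrapolated = False
            projected.append(
                ProjectedAnchor(
                    anchor=a,
                    backbone_cM=float(y),
                    extrapolated=extrapolated,
                    in_inversion=in_inv,
                )
            )
    return projected, skipped
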