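"""The composite directional link-peak score.

Mate pairs whose two ends map reliably to *different, non-adjoining*
scaffolds ("unsatisfied" pairs) carry scaffolding information.  For each
source scaffold a sliding window collects such pairs, groups them by target
scaffold, and sums a per-library weight over each group:

* the **link-peak score** of a window is the largest group score;
* the **noise score** is the summed evidence toward all non-peak targets —
  high noise flags repeat-driven spurious links;
* the **direction** of the evidence follows the read strand: a read on the
  forward strand points off the right end of its scaffold, a reverse-strand
  read off the left end.

A reciprocally high link-peak between the facing ends of two scaffolds is a
probable scaffolding link, and the end pairing implies their relative
orientation (R-L: same strand; R-R or L-L: opposite).
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import yaml

from .records import (
    LibrarySpec,
    LinkCall,
    LinkProfile,
    LinkWindowScores,
    MatePairRecord,
    WiggleTrack,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pair classification


def classify_mate_pairs(
    pairs: Sequence[MatePairRecord],
    libraries: Optional[Dict[str, LibrarySpec]] = None,
    layout: Optional[Dict[str, List[Tuple[str, str]]]] = None,
    scaffold_lengths: Optional[Dict[str, int]] = None,
    gap_bp: int = 50_000,
    parent: Optional[Dict[str, str]] = None,
) -> Tuple[List[MatePairRecord], List[MatePairRecord]]:
    """Split pairs into (satisfied, unsatisfied) against a working layout.

    A pair is satisfied when both ends are on one scaffold, or on scaffolds
    adjacent in ``layout`` with a plausible implied insert (library mean
    +/- 3 sd, counting the fixed inter-scaffold gap).  Satisfied pairs are
    *excluded* from link evidence; with no layout, only same-scaffold pairs
    are satisfied.  Pairs lacking a reliable mapping on either end are
    discarded up front.

    ``parent`` optionally maps split-scaffold segment ids to their parent
    scaffold: a pair bridging two segments of one parent reflects the
    original (possibly false) assembly join, not independent scaffolding
    evidence, and is classified satisfied.
    """
    parent = parent or {}
    rank: Dict[str, Tuple[str, int, str]] = {}
    if layout:
        for chrom, entries in layout.items():
            for idx, entry in enumerate(entries):
                sid, orientation = entry if isinstance(entry, tuple) else (entry, "+")
                rank[sid] = (chrom, idx, orientation)

    satisfied: List[MatePairRecord] = []
    unsatisfied: List[MatePairRecord] = []
    for p in pairs:
        if not p.mapq_ok:
            continue
        if p.scaffold1 == p.scaffold2 or (
            parent.get(p.scaffold1, p.scaffold1) == parent.get(p.scaffold2, p.scaffold2)
        ):
            satisfied.append(p)
            continue
        r1 = rank.get(p.scaffold1)
        r2 = rank.get(p.scaffold2)
        if r1 and r2 and r1[0] == r2[0] and abs(r1[1] - r2[1]) == 1:
            if _adjacent_insert_plausible(p, r1, r2, libraries, scaffold_lengths, gap_bp):
                satisfied.append(p)
                continue
        unsatisfied.append(p)
    return satisfied, unsatisfied


def _adjacent_insert_plausible(
    p: MatePairRecord,
    r1: Tuple[str, int, str],
    r2: Tuple[str, int, str],
    libraries: Optional[Dict[str, LibrarySpec]],
    scaffold_lengths: Optional[Dict[str, int]],
    gap_bp: int,
) -> bool:
    if libraries is None or scaffold_lengths is None:
        return True  # adjacency alone satisfies when no insert model is given
    lib = libraries.get(p.lib_id)
    if lib is None:
        raise KeyError(f"unknown library {p.lib_id!r}")
    # distance from each read to the junction between the two scaffolds,
    # honouring the layout orientation of each scaffold
    (first, pos_first), (second, pos_second) = sorted(
        [((r1, p.scaffold1), p.pos1), ((r2, p.scaffold2), p.pos2)],
        key=lambda item: item[0][0][1],
    )
    (chrom_i, idx_i, ori_i), sid_i = first
    (chrom_j, idx_j, ori_j), sid_j = second
    len_i = scaffold_lengths[sid_i]
    d_i = (len_i - pos_first) if ori_i == "+" else pos_first
    d_j = pos_second if ori_j == "+" else (scaffold_lengths[sid_j] - pos_second)
    implied = d_i + gap_bp + d_j
    return abs(implied - lib.insert_mean) <= 3.0 * lib.insert_sd + gap_bp


# ---------------------------------------------------------------------------
# windowed profile


def link_score_profile(
    source_scaffold: str,
    scaffold_length: int,
    unsatisfied_pairs: Sequence[MatePairRecord],
    libraries: Dict[str, LibrarySpec],
    window_bp: int = 10_000,
    step_bp: int = 5_000,
) -> LinkProfile:
    """Compute the directional link-peak / noise profile of one scaffold."""
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")

    n_windows = max(1, math.ceil(scaffold_length / step_bp))
    # per window: target -> [total, rightward, leftward]
    groups: List[Dict[str, List[float]]] = [dict() for _ in range(n_windows)]

    for p in unsatisfied_pairs:
        for sid, pos, strand, target in (
            (p.scaffold1, p.pos1, p.strand1, p.scaffold2),
            (p.scaffold2, p.pos2, p.strand2, p.scaffold1),
        ):
            if sid != source_scaffold:
                continue
            lib = libraries.get(p.lib_id)
            if lib is None:
                raise KeyError(f"unknown library {p.lib_id!r}")
            w = lib.value_weight
            first = max(0, math.ceil((pos - window_bp + 1) / step_bp))
            last = min(n_windows - 1, pos // step_bp)
            for wi in range(first, last + 1):
                g = groups[wi].setdefault(target, [0.0, 0.0, 0.0])
                g[0] += w
                if strand == "+":
                    g[1] += w
                else:
                    g[2] += w

    windows: List[LinkWindowScores] = []
    for wi in range(n_windows):
        g = groups[wi]
        if not g:
            windows.append(
                LinkWindowScores(
                    start=wi * step_bp,
                    peak_target=None,
                    peak_score=0.0,
                    direction="none",
                    noise_score=0.0,
                )
            )
            continue
        peak_score = max(v[0] for v in g.values())
        at_peak = sorted(t for t, v in g.items() if v[0] == peak_score)
        tie = len(at_peak) > 1
        if tie:
            log.debug(
                "%s window %d: %d targets tie at score %g; lexicographic pick",
                source_scaffold,
                wi,
                len(at_peak),
                peak_score,
            )
        peak_target = at_peak[0]
        right, left = g[peak_target][1], g[peak_target][2]
        direction = "right" if right > left else ("left" if left > right else "none")
        noise = sum(v[0] for t, v in g.items() if t != peak_target)
        windows.append(
            LinkWindowScores(
                start=wi * step_bp,
                peak_target=peak_target,
                peak_score=peak_score,
                direction=direction,
                noise_score=noise,
                tie=tie,
                groups={t: tuple(v) for t, v in g.items()},
            )
        )
    return LinkProfile(
        source_scaffold=source_scaffold,
        scaffold_length=scaffold_length,
        window_bp=window_bp,
        step_bp=step_bp,
        windows=windows,
    )


# ---------------------------------------------------------------------------
# reciprocal link calling


def _terminal_window_count(libraries: Dict[str, LibrarySpec], step_bp: int) -> int:
    """Windows per scaffold end that any library insert can possibly reach."""
    reach = max(lib.insert_mean + 3.0 * lib.insert_sd for lib in libraries.values())
    return max(1, math.ceil(reach / step_bp))


def _end_windows(profile: LinkProfile, end: str, k: int):
    """Terminal windows of one end with the outward direction component."""
    if end == "L":
        return profile.windows[:k], 2  # leftward evidence
    return profile.windows[-k:], 1  # rightward evidence


def _dominant_window(
    profile: LinkProfile, end: str, k: int
) -> Optional[Tuple[str, float, float]]:
    """(target, peak, noise) of the dominant outward peak window of one end.

    Per window, pairs pointing off this end are grouped by target; the
    window peak is the best group score and the window noise the summed
    score of all other groups.  The end's candidate is taken from the
    window with the largest peak, so repeat-driven multi-target windows
    carry their own noise while clean junction windows are not penalized by
    unrelated evidence elsewhere along the scaffold end.
    """
    windows, component = _end_windows(profile, end, k)
    best: Optional[Tuple[str, float, float]] = None
    for w in windows:
        scores = {
            t: vals[component] for t, vals in w.groups.items() if vals[component] > 0
        }
        if not scores:
            continue
        peak = max(scores.values())
        target = sorted(t for t, s in scores.items() if s == peak)[0]
        noise = sum(s for t, s in scores.items() if t != target)
        if best is None or peak > best[1]:
            best = (target, peak, noise)
    return best


def _end_candidates(profile: LinkProfile, end: str, k: int) -> Dict[str, float]:
    """Summed directional per-target evidence over one end (for reporting)."""
    windows, component = _end_windows(profile, end, k)
    scores: Dict[str, float] = {}
    for w in windows:
        for target, vals in w.groups.items():
            scores[target] = scores.get(target, 0.0) + vals[component]
    return {t: s for t, s in scores.items() if s > 0}


def call_links(
    profiles: Sequence[LinkProfile],
    libraries: Dict[str, LibrarySpec],
    min_score: float = 4.0,
    max_noise_ratio: float = 0.5,
) -> Tuple[List[LinkCall], List[LinkCall]]:
    """Call reciprocal scaffold links from end-window peak evidence.

    For each scaffold end (the terminal ``ceil(insert_max / step)`` windows,
    so evidence beyond the reach of any insert is ignored) the dominant
    peak target is a candidate when its peak reaches ``min_score`` and the
    same window's noise stays below ``max_noise_ratio`` of the peak —
    repeat-driven ends link many targets at once and fail the noise test.
    Only *reciprocal* candidates — the target end's dominant peak points
    back — are emitted as links; one-sided candidates are returned
    separately as suggestions for curation.
    """
    if not profiles:
        return [], []
    steps = {p.step_bp for p in profiles}
    if len(steps) != 1:
        raise ValueError("profiles must share identical windowing")
    step_bp = steps.pop()
    k = _terminal_window_count(libraries, step_bp)

    by_scaffold = {p.source_scaffold: p for p in profiles}
    candidates: Dict[Tuple[str, str], Tuple[str, float]] = {}
    for p in profiles:
        for end in ("L", "R"):
            dom = _dominant_window(p, end, k)
            if dom is None:
                continue
            target, peak, noise = dom
            if peak >= min_score and noise <= max_noise_ratio * peak:
                candidates[(p.source_scaffold, end)] = (target, peak)

    links: List[LinkCall] = []
    suggestions: List[LinkCall] = []
    used: Set[Tuple[str, str]] = set()
    for (sid, end), (target, score) in sorted(candidates.items()):
        if (sid, end) in used:
            continue
        back = None
        for t_end in ("L", "R"):
            entry = candidates.get((target, t_end))
            if entry and entry[0] == sid:
                back = (t_end, entry[1])
                break
        if back is not None:
            t_end, back_score = back
            links.append(
                LinkCall(
                    scaffold_a=sid,
                    end_a=end,
                    scaffold_b=target,
                    end_b=t_end,
                    score_ab=score,
                    score_ba=back_score,
                    reciprocal=True,
                    implied_relative_orientation=relative_orientation(end, t_end),
                )
            )
            used.add((sid, end))
            used.add((target, t_end))
        else:
            # best guess at the target end from the target's own (sub-threshold)
            # evidence back toward the source
            t_end = "L"
            t_profile = by_scaffold.get(target)
            if t_profile is not None:
                back_l = _end_candidates(t_profile, "L", k).get(sid, 0.0)
                back_r = _end_candidates(t_profile, "R", k).get(sid, 0.0)
                t_end = "R" if back_r > back_l else "L"
            suggestions.append(
                LinkCall(
                    scaffold_a=sid,
                    end_a=end,
                    scaffold_b=target,
                    end_b=t_end,
                    score_ab=score,
                    score_ba=0.0,
                    reciprocal=False,
                    implied_relative_orientation=relative_orientation(end, t_end),
                )
            )
    return links, suggestions


def relative_orientation(end_a: str, end_b: str) -> str:
    """R-L / L-R end pairing means same strand; R-R / L-L means opposite."""
    return "same" if end_a != end_b else "opposite"


def propagate_orientations(
    links: Iterable[LinkCall],
) -> Tuple[Dict[str, int], List[Set[str]], int, Set[str]]:
    """Propagate relative orientations over the reciprocal link graph.

    Breadth-first traversal assigns each scaffold a sign (+1/-1) relative to
    its component root.  A component containing a parity-conflicting cycle
    has all its members flagged unoriented instead.

    Returns (signs, components, n_conflicts, conflicted_scaffolds).
    """
    graph = nx.Graph()
    for link in links:
        if not link.reciprocal:
            continue
        graph.add_edge(link.scaffold_a, link.scaffold_b, parity=link.parity)

    signs: Dict[str, int] = {}
    components: List[Set[str]] = []
    conflicted: Set[str] = set()
    n_conflicts = 0
    for component in nx.connected_components(graph):
        components.append(set(component))
        root = min(component)
        local = {root: 1}
        ok = True
        for u, v in nx.bfs_edges(graph, root):
            local[v] = local[u] * graph[u][v]["parity"]
        for u, v, data in graph.subgraph(component).edges(data=True):
            if local[u] * data["parity"] != local[v]:
                ok = False
                n_conflicts += 1
        if ok:
            signs.update(local)
        else:
            conflicted.update(component)
            log.warning("orientation conflict in component %s", sorted(component))
    return signs, components, n_conflicts, conflicted


# ---------------------------------------------------------------------------
# wiggle export


def profiles_to_wiggle(profiles: Sequence[LinkProfile]) -> List[WiggleTrack]:
    """Signed peak tracks (right-directed positive) plus noise tracks."""
    tracks: List[WiggleTrack] = []
    for p in profiles:
        peaks = []
        noises = []
        for w in p.windows:
            sign = -1.0 if w.direction == "left" else 1.0
            peaks.append(sign * w.peak_score)
            noises.append(w.noise_score)
        tracks.append(
            WiggleTrack(
                target_id=p.source_scaffold,
                start=1,
                step=p.step_bp,
                span=p.step_bp,
                values=peaks,
                name=f"link_peak:{p.source_scaffold}",
            )
        )
        tracks.append(
            WiggleTrack(
                target_id=p.source_scaffold,
                start=1,
                step=p.step_bp,
                span=p.step_bp,
                values=noises,
                name=f"link_noise:{p.source_scaffold}",
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# I/O


def read_pairs_tsv(path) -> List[MatePairRecord]:
    pairs: List[MatePairRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            pairs.append(
                MatePairRecord(
                    pair_id=f[0],
                    lib_id=f[1],
                    scaffold1=f[2],
                    pos1=int(f[3]),
                    strand1=f[4],
                    scaffold2=f[5],
                    pos2=int(f[6]),
                    strand2=f[7],
                    mapq_ok=(f[8] == "1") if len(f) > 8 else True,
                )
            )
    return pairs


def write_pairs_tsv(pairs: Iterable[MatePairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#pair\tlib\tscaffold1\tpos1\tstrand1\tscaffold2\tpos2\tstrand2\tmapq_ok\n")
        for p in pairs:
            fh.write(
                f"{p.pair_id}\t{p.lib_id}\t{p.scaffold1}\t{p.pos1}\t{p.strand1}\t"
                f"{p.scaffold2}\t{p.pos2}\t{p.strand2}\t{1 if p.mapq_ok else 0}\n"
            )


def read_libraries_yaml(path) -> Dict[str, LibrarySpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    libs: Dict[str, LibrarySpec] = {}
    for lib_id, spec in raw.items():
        libs[lib_id] = LibrarySpec(
            lib_id=lib_id,
            origin=spec["origin"],
            kind=spec["kind"],
            insert_mean=float(spec["insert_mean"]),
            insert_sd=float(spec["insert_sd"]),
            value_weight=float(spec["value_weight"]),
        )
    return libs


def write_libraries_yaml(libraries: Dict[str, LibrarySpec], path) -> None:
    raw = {
        lib.lib_id: {
            "origin": lib.origin,
            "kind": lib.kind,
            "insert_mean": lib.insert_mean,
            "insert_sd": lib.insert_sd,
            "value_weight": lib.value_weight,
        }
        for lib in libraries.values()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
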