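"""Core domain records shared across the toolkit.

All *internal* coordinates are 0-based half-open.  Standard file formats
(AGP, GFF3, wiggle, BLAST tables) keep their native conventions and are
converted only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: fixed inter-scaffold gap written between placed components (bp)
DEFAULT_GAP_BP = 50_000
DEFAULT_GAP_TYPE = "contig"
DEFAULT_GAP_LINKAGE = "no"


@dataclass
class ScaffoldSeq:
    """A scaffold (or pseudomolecule) with a known length and optional sequence."""

    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"scaffold {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"scaffold {self.id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class AGPRecord:
    """One row of an AGP 2.0 layout: a placed component (W) or a gap (U).

    Coordinates here are the *native* AGP convention, 1-based inclusive,
    because the record mirrors the file row exactly.
    """

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'U'
    component_id: Optional[str] = None
    component_beg: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None  # '+', '-', '?'
    gap_length: Optional[int] = None
    gap_type: Optional[str] = None
    linkage: Optional[str] = None
    evidence: Optional[str] = None

    def __post_init__(self):
        if self.object_end < self.object_beg:
            raise ValueError(f"{self.object_id}: object_end < object_beg")
        if self.part_number < 1:
            raise ValueError(f"{self.object_id}: part_number must be >= 1")
        if self.component_type == "W":
            if None in (self.component_id, self.component_beg, self.component_end):
                raise ValueError(f"{self.object_id}: W record missing component fields")
            if self.orientation not in ("+", "-", "?"):
                raise ValueError(f"{self.object_id}: bad orientation {self.orientation!r}")
            comp_span = self.component_end - self.component_beg
            obj_span = self.object_end - self.object_beg
            if comp_span != obj_span:
                raise ValueError(
                    f"{self.object_id} part {self.part_number}: component span "
                    f"{comp_span + 1} != object span {obj_span + 1}"
                )
        elif self.component_type == "U":
            if self.gap_type is None:
                self.gap_type = DEFAULT_GAP_TYPE
            if self.linkage is None:
                self.linkage = DEFAULT_GAP_LINKAGE
            if self.evidence is None:
                self.evidence = "na"
            if self.gap_length is None or self.gap_length < 1:
                raise ValueError(f"{self.object_id}: U record needs gap_length >= 1")
            if self.gap_length != self.object_end - self.object_beg + 1:
                raise ValueError(f"{self.object_id}: gap_length != object span")
        else:
            raise ValueError(f"unsupported component_type {self.component_type!r}")

    @property
    def span(self) -> int:
        return self.object_end - self.object_beg + 1


@dataclass
class Pseudomolecule:
    """An ordered AGP layout for one chromosome-scale object."""

    chromosome: str
    records: list  # of AGPRecord, part_number order
    total_length: int

    def __post_init__(self):
        if self.records:
            covered = sum(r.span for r in self.records)
            if covered != self.total_length:
                raise ValueError(
                    f"{self.chromosome}: records cover {covered} bp, "
                    f"declared {self.total_length}"
                )


@dataclass
class WiggleTrack:
    """A fixedStep value track along one target sequence."""

    target_id: str
    start: int  # 1-based, wiggle native
    step: int
    span: int
    values: list
    name: str = ""

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("wiggle step must be >= 1")
        if self.span > self.step:
            raise ValueError("wiggle span must be <= step")


@dataclass
class GenericAlignment:
    """A pairwise alignment normalized to 0-based half-open coordinates."""

    query_id: str
    q_beg: int
    q_end: int
    target_id: str
    t_beg: int
    t_end: int
    strand: str
    score: float
    identity_pct: float = 100.0
    match_length: int = 0

    def __post_init__(self):
        if self.q_end <= self.q_beg:
            raise ValueError(f"{self.query_id}: q_end <= q_beg")
        if self.t_end <= self.t_beg:
            raise ValueError(f"{self.query_id}: t_end <= t_beg")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.match_length == 0:
            self.match_length = self.q_end - self.q_beg

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_beg

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_beg


@dataclass
class MarkerHit:
    """A grouped, indel-tolerant alignment 'hit' of one marker on one scaffold."""

    marker_id: str
    scaffold_id: str
    beg: int
    end: int
    strand: str
    score: float
    n_blocks: int = 1

    def __post_init__(self):
        if self.end <= self.beg:
            raise ValueError("hit end must exceed beg")
        if self.score <= 0:
            raise ValueError("hit score must be positive")

    @property
    def midpoint(self) -> int:
        return (self.beg + self.end) // 2


@dataclass
class AnchorPoint:
    """A marker (or proxy) tying a scaffold coordinate to a genetic position."""

    marker_id: str
    scaffold_id: str
    position_bp: int
    linkage_group: str
    position_cM: float
    source_map: str = "DM"  # DM | RH | TOM
    marker_class: str = "SNP"
    weight: float = 1.0

    def __post_init__(self):
        if self.source_map not in ("DM", "RH", "TOM"):
            raise ValueError(f"bad source_map {self.source_map!r}")


@dataclass
class GeneticMapEntry:
    marker_id: str
    linkage_group: str
    position_cM: float

    def __post_init__(self):
        if self.position_cM < 0:
            raise ValueError("map position must be >= 0")


@dataclass
class DistortionResult:
    """Per-locus chi-square test against the 1:1 backcross expectation."""

    locus_id: str
    n_A: int
    n_H: int
    chi2: float
    p_value: float
    flagged: bool = False  # True when no calls were observed


@dataclass
class LibrarySpec:
    """A mate-pair/paired-end library with its empirical link-score weight."""

    lib_id: str
    origin: str  # DM | RH | TOM
    kind: str  # clone_end | long_insert_454
    insert_mean: float
    insert_sd: float
    value_weight: float

    def __post_init__(self):
        if self.value_weight <= 0:
            raise ValueError("value_weight must be positive")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")


@dataclass
class MatePairRecord:
    """Both end mappings of one mate pair; positions are scaffold 0-based."""

    pair_id: str
    lib_id: str
    scaffold1: str
    pos1: int
    strand1: str
    scaffold2: str
    pos2: int
    strand2: str
    mapq_ok: bool = True


@dataclass
class LinkWindowScores:
    """Per-window link evidence grouped by target scaffold.

    ``groups`` maps target scaffold id -> (total, rightward, leftward) summed
    library weights; ``direction`` is the side implied by the peak group's
    majority strand configuration.
    """

    start: int
    peak_target: Optional[str]
    peak_score: float
    direction: str  # left | right | none
    noise_score: float
    tie: bool = False
    groups: dict = field(default_factory=dict)


@dataclass
class LinkProfile:
    source_scaffold: str
    scaffold_length: int
    window_bp: int
    step_bp: int
    windows: list  # of LinkWindowScores


@dataclass
class LinkCall:
    scaffold_a: str
    end_a: str  # L | R
    scaffold_b: str
    end_b: str
    score_ab: float
    score_ba: float
    reciprocal: bool
    implied_relative_orientation: str  # same | opposite

    @property
    def parity(self) -> int:
        """+1 when the two scaffolds lie on the same strand, -1 otherwise."""
        return 1 if self.implied_relative_orientation == "same" else -1


@dataclass
class BackboneBin:
    """Scaffold segments sharing one genetic position on a chromosome."""

    chromosome: str
    cM: float
    scaffolds: list
    ordered: bool = True  # False when >1 member and no resolving evidence


@dataclass
class ChimeraBreakpoint:
    scaffold_id: str
    breakpoint_bp: int
    left_assignment: tuple  # (chromosome, (cM_lo, cM_hi))
    right_assignment: tuple
    support_left: int
    support_right: int


@dataclass
class CloneEndHit:
    clone_id: str
    end: str  # L | R
    alignment: GenericAlignment
    bit_score: float
    match_length: int

    def __post_init__(self):
        if self.match_length < 1:
            raise ValueError("match_length must be >= 1")


@dataclass
class WGPTagHit:
    """Alignment of one 25-nt whole-genome-profiling tag of a clone."""

    clone_id: str
    scaffold_id: str
    position_bp: int
    unique: bool
    tag_seq_len: int = 25

    def __post_init__(self):
        if self.tag_seq_len != 25:
            raise ValueError("WGP tags are 25 nt by definition")


@dataclass
class SyntenyMatch:
    ref_scaffold: str
    ref_beg: int
    ref_end: int
    other_chromosome: str
    other_beg: int
    other_end: int
    identity_pct: float
    strand: str

    def __post_init__(self):
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")

    @property
    def length_bp(self) -> int:
        return self.ref_end - self.ref_beg


@dataclass
class InversionInterval:
    """A known inversion between the backbone genome and a related genome."""

    chromosome: str
    ref_beg: int
    ref_end: int
    note: str = ""

    def __post_init__(self):
        if self.ref_end <= self.ref_beg:
            raise ValueError("inversion interval must have end > beg")
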