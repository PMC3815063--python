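"""Seeded simulator of scaffold assemblies with known truth.

The generator emulates the statistical structure the anchoring pipeline
assumes: chromosomes with a recombinationally silent pericentromeric block
and marker-dense euchromatin, a lognormal scaffold length spectrum with a
few planted inter-chromosomal false joins (chimeras), several mate-pair
libraries of different insert sizes and evidential weight, a backcross
genotype matrix with missing data and transmission-distorted loci, and
repeat-mimicking decoy marker alignments.  Everything is coordinate-level
(no nucleotides are needed for anchoring); FASTA emission is optional for
end-to-end I/O tests.

All draws flow from one :class:`numpy.random.Generator` seeded by
``SimConfig.seed``, so any run is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AnchorPoint, GenericAlignment, LibrarySpec, MatePairRecord, ScaffoldSeq


def default_libraries() -> Dict[str, LibrarySpec]:
    """Three libraries mirroring a clone-end + two long-insert 454 design.

    Weights follow the rule of giving more value to libraries from the
    reference genotype and to longer, more reliably aligned inserts.
    """
    libs = [
        LibrarySpec("DM_BAC", "DM", "clone_end", 100_000.0, 10_000.0, 3.0),
        LibrarySpec("DM_454_20k", "DM", "long_insert_454", 20_000.0, 2_000.0, 2.0),
        LibrarySpec("DM_454_8k", "DM", "long_insert_454", 8_000.0, 800.0, 1.5),
    ]
    return {lib.lib_id: lib for lib in libs}


#: physical (insert) coverage per library used to size the pair sets
DEFAULT_COVERAGE = {"DM_BAC": 8.0, "DM_454_20k": 8.0, "DM_454_8k": 5.0}


@dataclass
class SimConfig:
    """Study conditions for the simulator (all dials in one place).

    The defaults describe a desk-scale genome: 3 chromosomes of 20 Mb with
    the central 30% recombinationally silent, ~1 Mb scaffolds (about 60 in
    total), 2 planted chimeras, a 180-clone backcross population genotyped
    at 5% missingness, and one 2:1 transmission-distorted region.
    """

    n_chromosomes: int = 3
    chromosome_Mb: float = 20.0
    scaffold_len_log_mean: float = math.log(1e6) - 0.08  # lognormal mean ~1 Mb
    scaffold_len_log_sd: float = 0.4
    min_scaffold_bp: int = 100_000
    chimera_count: int = 2
    min_chimera_part_bp: int = 800_000
    pericentromere_frac: float = 0.3
    euchromatin_cM_per_Mb: float = 6.0
    marker_density_eu: float = 20.0  # markers / Mb in euchromatin
    marker_density_peri: float = 2.0
    marker_span_bp: int = 500
    repeat_marker_frac: float = 0.05
    ambiguous_marker_frac: float = 0.02
    n_individuals: int = 180
    missing_rate: float = 0.05
    distortion_loci: List[Tuple[str, float, float]] = field(
        default_factory=lambda: [("chr01", 0.25, 2.0)]
    )  # (chromosome, fractional position, A:H transmission ratio)
    noise_pair_frac: float = 0.02
    coverage: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    foreign_map_dropout: float = 0.3
    seed: int = 42

    def __post_init__(self):
        for frac in (
            self.pericentromere_frac,
            self.repeat_marker_frac,
            self.ambiguous_marker_frac,
            self.missing_rate,
            self.noise_pair_frac,
            self.foreign_map_dropout,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("all fractions must lie in [0, 1]")
        if self.marker_density_eu <= 0 and self.marker_density_peri <= 0:
            raise ValueError("marker density must be positive somewhere")


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class ChromosomeTruth:
    name: str
    length_bp: int
    peri_beg: int
    peri_end: int
    # piecewise-linear genetic map: cM(bp) interpolates these nodes
    map_bp: List[int] = field(default_factory=list)
    map_cM: List[float] = field(default_factory=list)

    def cM_of(self, bp) -> np.ndarray:
        return np.interp(bp, self.map_bp, self.map_cM)

    def bp_of_cM(self, cm) -> np.ndarray:
        return np.interp(cm, self.map_cM, self.map_bp)

    @property
    def total_cM(self) -> float:
        return self.map_cM[-1]


@dataclass
class PartTruth:
    """One contiguous chromosome interval inside a scaffold."""

    chromosome: str
    chrom_beg: int
    chrom_end: int  # half-open
    orientation: str  # scaffold vs chromosome
    scaffold_offset: int = 0

    @property
    def length(self) -> int:
        return self.chrom_end - self.chrom_beg


@dataclass
class ScaffoldTruth:
    id: str
    length: int
    parts: List[PartTruth]
    breakpoints: List[int] = field(default_factory=list)  # scaffold coords

    @property
    def is_chimeric(self) -> bool:
        return len(self.parts) > 1

    def part_key(self, idx: int) -> str:
        if not self.is_chimeric:
            return self.id
        return f"{self.id}_p{idx + 1}"


@dataclass
class TruthSet:
    chromosomes: List[ChromosomeTruth]
    scaffolds: Dict[str, ScaffoldTruth]
    order: Dict[str, List[str]]  # chromosome -> part keys in physical order
    orientation: Dict[str, str]  # part key -> '+'/'-'
    adjacencies: frozenset = frozenset()  # frozenset of frozenset part-key pairs

    def chromosome(self, name: str) -> ChromosomeTruth:
        return next(c for c in self.chromosomes if c.name == name)

    def locate(self, chrom_name: str, g: int) -> Tuple[str, int, int]:
        """Map a genome position to (scaffold, scaffold_pos, strand_flip)."""
        for sid, sc in self.scaffolds.items():
            for part in sc.parts:
                if part.chromosome == chrom_name and part.chrom_beg <= g < part.chrom_end:
                    if part.orientation == "+":
                        pos = part.scaffold_offset + (g - part.chrom_beg)
                        return sid, pos, 1
                    pos = part.scaffold_offset + (part.chrom_end - 1 - g)
                    return sid, pos, -1
        raise KeyError(f"position {chrom_name}:{g} not covered by any scaffold")


class _Locator:
    """Vectorized genome->scaffold coordinate mapper built once per truth."""

    def __init__(self, truth: TruthSet):
        self.tables: Dict[str, dict] = {}
        for chrom in truth.chromosomes:
            rows = []
            for sid, sc in truth.scaffolds.items():
                for part in sc.parts:
                    if part.chromosome == chrom.name:
                        rows.append((part.chrom_beg, part.chrom_end, sid, part))
            rows.sort()
            self.tables[chrom.name] = {
                "begs": np.array([r[0] for r in rows]),
                "ends": np.array([r[1] for r in rows]),
                "rows": rows,
            }

    def locate(self, chrom_name: str, g: int) -> Tuple[str, int, int]:
        t = self.tables[chrom_name]
        i = int(np.searchsorted(t["begs"], g, side="right")) - 1
        if i < 0 or g >= t["ends"][i]:
            raise KeyError(f"position {chrom_name}:{g} uncovered")
        _, _, sid, part = t["rows"][i]
        if part.orientation == "+":
            return sid, part.scaffold_offset + (g - part.chrom_beg), 1
        return sid, part.scaffold_offset + (part.chrom_end - 1 - g), -1


# ---------------------------------------------------------------------------
# generators


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> List[ChromosomeTruth]:
    """Lay out chromosomes with a pericentromeric zero-recombination block.

    The genetic map is piecewise linear: constant ``euchromatin_cM_per_Mb``
    on the arms, flat across the central ``pericentromere_frac`` block, so
    the total genetic length equals the integral of the rate landscape.
    """
    rng = rng or np.random.default_rng(config.seed)
    chroms: List[ChromosomeTruth] = []
    L = int(round(config.chromosome_Mb * 1e6))
    for i in range(config.n_chromosomes):
        peri_span = int(round(config.pericentromere_frac * L))
        peri_beg = (L - peri_span) // 2
        peri_end = peri_beg + peri_span
        rate = config.euchromatin_cM_per_Mb / 1e6  # cM per bp
        c1 = peri_beg * rate
        c_total = c1 + (L - peri_end) * rate
        chroms.append(
            ChromosomeTruth(
                name=f"chr{i + 1:02d}",
                length_bp=L,
                peri_beg=peri_beg,
                peri_end=peri_end,
                map_bp=[0, peri_beg, peri_end, L],
                map_cM=[0.0, c1, c1, c_total],
            )
        )
    return chroms


def fragment_into_scaffolds(
    chromosomes: List[ChromosomeTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> TruthSet:
    """Cut chromosomes into scaffolds and plant the configured chimeras."""
    parts_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in chromosomes:
        cuts = [0]
        while cuts[-1] < chrom.length_bp:
            ln = int(rng.lognormal(config.scaffold_len_log_mean, config.scaffold_len_log_sd))
            ln = max(ln, config.min_scaffold_bp)
            cuts.append(min(cuts[-1] + ln, chrom.length_bp))
        parts_by_chrom[chrom.name] = list(zip(cuts, cuts[1:]))

    # candidate parts for chimera planting: fully euchromatic and large
    all_parts: List[Tuple[str, int]] = []  # (chrom, part index)
    for chrom in chromosomes:
        for idx, (b, e) in enumerate(parts_by_chrom[chrom.name]):
            euchromatic = e <= chrom.peri_beg or b >= chrom.peri_end
            if euchromatic and (e - b) >= config.min_chimera_part_bp:
                all_parts.append((chrom.name, idx))
    n_parts_total = sum(len(v) for v in parts_by_chrom.values())
    if config.chimera_count > n_parts_total // 2:
        raise ValueError("chimera_count exceeds available scaffold parts")

    chimera_pairs: List[Tuple[Tuple[str, int], Tuple[str, int]]] = []
    used: set = set()
    perm = rng.permutation(len(all_parts))
    for i in perm:
        if len(chimera_pairs) == config.chimera_count:
            break
        a = all_parts[i]
        if a in used:
            continue
        partner = next(
            (
                all_parts[j]
                for j in perm
                if all_parts[j] not in used and all_parts[j][0] != a[0]
            ),
            None,
        )
        if partner is None:
            continue
        used.add(a)
        used.add(partner)
        chimera_pairs.append((a, partner))
    if len(chimera_pairs) < config.chimera_count:
        raise ValueError("could not place all requested chimeras")

    # assemble scaffold truth
    scaffolds: Dict[str, ScaffoldTruth] = {}
    part_owner: Dict[Tuple[str, int], Tuple[str, int]] = {}  # -> (sid, part idx)
    n_scaffolds = n_parts_total - len(chimera_pairs)
    ids = [f"scf{i + 1:04d}" for i in rng.permutation(n_scaffolds)]
    next_id = iter(ids)

    def _mk_part(chrom_name: str, idx: int) -> PartTruth:
        b, e = parts_by_chrom[chrom_name][idx]
        orientation = "+" if rng.random() < 0.5 else "-"
        return PartTruth(chromosome=chrom_name, chrom_beg=b, chrom_end=e, orientation=orientation)

    for (a, b) in chimera_pairs:
        sid = next(next_id)
        p1 = _mk_part(*a)
        p2 = _mk_part(*b)
        p2.scaffold_offset = p1.length
        scaffolds[sid] = ScaffoldTruth(
            id=sid,
            length=p1.length + p2.length,
            parts=[p1, p2],
            breakpoints=[p1.length],
        )
        part_owner[a] = (sid, 0)
        part_owner[b] = (sid, 1)
    for chrom in chromosomes:
        for idx in range(len(parts_by_chrom[chrom.name])):
            key = (chrom.name, idx)
            if key in part_owner:
                continue
            sid = next(next_id)
            part = _mk_part(chrom.name, idx)
            scaffolds[sid] = ScaffoldTruth(id=sid, length=part.length, parts=[part])
            part_owner[key] = (sid, 0)

    order: Dict[str, List[str]] = {}
    orientation: Dict[str, str] = {}
    adjacencies = set()
    for chrom in chromosomes:
        keys = []
        for idx in range(len(parts_by_chrom[chrom.name])):
            sid, part_idx = part_owner[(chrom.name, idx)]
            sc = scaffolds[sid]
            key = sc.part_key(part_idx)
            keys.append(key)
            orientation[key] = sc.parts[part_idx].orientation
        order[chrom.name] = keys
        for x, y in zip(keys, keys[1:]):
            adjacencies.add(frozenset((x, y)))

    return TruthSet(
        chromosomes=chromosomes,
        scaffolds=scaffolds,
        order=order,
        orientation=orientation,
        adjacencies=frozenset(adjacencies),
    )


def simulate_matepairs(
    truth: TruthSet,
    config: SimConfig,
    libraries: Dict[str, LibrarySpec],
    rng: np.random.Generator,
) -> List[MatePairRecord]:
    """Draw mate pairs uniformly on the true genome, mapped to scaffolds.

    Fragment starts are uniform, inserts are truncated-normal per library;
    each end becomes a (scaffold, position, strand) mapping through the
    truth layout.  A ``noise_pair_frac`` fraction of pairs get random ends,
    emulating mismapped/chimeric read pairs.
    """
    locator = _Locator(truth)
    genome = [(c.name, c.length_bp) for c in truth.chromosomes]
    total_bp = sum(l for _, l in genome)
    chrom_p = np.array([l / total_bp for _, l in genome])
    sid_list = sorted(truth.scaffolds)
    lengths = {sid: truth.scaffolds[sid].length for sid in sid_list}

    pairs: List[MatePairRecord] = []
    for lib_id in sorted(libraries):
        lib = libraries[lib_id]
        cov = config.coverage.get(lib_id, 5.0)
        n = int(cov * total_bp / lib.insert_mean)
        chrom_idx = rng.choice(len(genome), size=n, p=chrom_p)
        inserts = rng.normal(lib.insert_mean, lib.insert_sd, size=n)
        inserts = np.clip(inserts, 1000, None).astype(int)
        noise = rng.random(n) < config.noise_pair_frac
        for i in range(n):
            pid = f"{lib_id}_{i:06d}"
            if noise[i]:
                s1, s2 = rng.choice(sid_list, size=2)
                pairs.append(
                    MatePairRecord(
                        pair_id=pid,
                        lib_id=lib_id,
                        scaffold1=str(s1),
                        pos1=int(rng.integers(0, lengths[str(s1)])),
                        strand1="+" if rng.random() < 0.5 else "-",
                        scaffold2=str(s2),
                        pos2=int(rng.integers(0, lengths[str(s2)])),
                        strand2="+" if rng.random() < 0.5 else "-",
                    )
                )
                continue
            cname, clen = genome[chrom_idx[i]]
            ins = min(int(inserts[i]), clen - 2)
            start = int(rng.integers(0, clen - ins))
            g1, g2 = start, start + ins
            sid1, pos1, flip1 = locator.locate(cname, g1)
            sid2, pos2, flip2 = locator.locate(cname, g2)
            pairs.append(
                MatePairRecord(
                    pair_id=pid,
                    lib_id=lib_id,
                    scaffold1=sid1,
                    pos1=pos1,
                    strand1="+" if flip1 > 0 else "-",
                    scaffold2=sid2,
                    pos2=pos2,
                    strand2="-" if flip2 > 0 else "+",
                )
            )
    return pairs


def simulate_markers_and_genotypes(
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, List[GenericAlignment], pd.DataFrame, Dict[str, Tuple[str, float]]]:
    """Markers, decoy-laden alignments, backcross genotypes and the map.

    Returns (marker metadata frame, alignment list, genotype matrix,
    genetic map dict marker -> (linkage group, cM)).
    """
    locator = _Locator(truth)
    sid_list = sorted(truth.scaffolds)
    lengths = {sid: truth.scaffolds[sid].length for sid in sid_list}

    rows = []
    for chrom in truth.chromosomes:
        spans = [
            (0, chrom.peri_beg, config.marker_density_eu),
            (chrom.peri_beg, chrom.peri_end, config.marker_density_peri),
            (chrom.peri_end, chrom.length_bp, config.marker_density_eu),
        ]
        positions: List[int] = []
        for b, e, dens in spans:
            n = rng.poisson(dens * (e - b) / 1e6)
            positions.extend(int(p) for p in rng.integers(b, max(b + 1, e), size=n))
        positions = sorted(set(positions))
        for j, g in enumerate(positions):
            sid, pos, flip = locator.locate(chrom.name, g)
            rows.append(
                {
                    "marker_id": f"mk_{chrom.name}_{j:05d}",
                    "chromosome": chrom.name,
                    "chrom_bp": g,
                    "cM": float(chrom.cM_of(g)),
                    "scaffold_id": sid,
                    "scaffold_bp": pos,
                    "strand": "+" if flip > 0 else "-",
                    "marker_class": str(rng.choice(["SNP", "DArT", "SSR"], p=[0.3, 0.6, 0.1])),
                    "kind": "clean",
                }
            )
    markers = pd.DataFrame(rows)
    n_markers = len(markers)
    draws = rng.random(n_markers)
    markers.loc[draws < config.repeat_marker_frac, "kind"] = "repeat"
    markers.loc[
        (draws >= config.repeat_marker_frac)
        & (draws < config.repeat_marker_frac + config.ambiguous_marker_frac),
        "kind",
    ] = "ambiguous"

    half = config.marker_span_bp // 2
    alignments: List[GenericAlignment] = []
    for row in markers.itertuples():
        sc_len = lengths[row.scaffold_id]
        t_beg = max(0, row.scaffold_bp - half)
        t_end = min(sc_len, row.scaffold_bp + half)
        true_score = float(t_end - t_beg) * 2.0
        alignments.append(
            GenericAlignment(
                query_id=row.marker_id,
                q_beg=0,
                q_end=config.marker_span_bp,
                target_id=row.scaffold_id,
                t_beg=t_beg,
                t_end=t_end,
                strand=row.strand,
                score=true_score,
                identity_pct=100.0,
            )
        )
        if row.kind == "repeat":
            n_decoys = 6
        elif row.kind == "ambiguous":
            n_decoys = 1
        else:
            n_decoys = 0
        for _ in range(n_decoys):
            decoy_sid = str(rng.choice(sid_list))
            decoy_len = lengths[decoy_sid]
            decoy_pos = int(rng.integers(half, max(half + 1, decoy_len - half)))
            decoy_score = true_score * (0.95 if row.kind == "repeat" else 1.0)
            alignments.append(
                GenericAlignment(
                    query_id=row.marker_id,
                    q_beg=0,
                    q_end=config.marker_span_bp,
                    target_id=decoy_sid,
                    t_beg=max(0, decoy_pos - half),
                    t_end=min(decoy_len, decoy_pos + half),
                    strand="+" if rng.random() < 0.5 else "-",
                    score=decoy_score,
                    identity_pct=95.0,
                )
            )

    genetic_map = {
        row.marker_id: (row.chromosome, row.cM) for row in markers.itertuples()
    }

    genotypes = _simulate_backcross(truth, config, markers, rng)
    return markers, alignments, genotypes, genetic_map


def _simulate_backcross(
    truth: TruthSet,
    config: SimConfig,
    markers: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Backcross genotypes by Poisson crossovers along the true map."""
    distortion = {
        chrom: (float(frac), float(ratio))
        for chrom, frac, ratio in config.distortion_loci
    }
    calls: Dict[str, np.ndarray] = {}
    for chrom in truth.chromosomes:
        sub = markers[markers["chromosome"] == chrom.name]
        mpos = sub["chrom_bp"].to_numpy()
        locus_ids = sub["marker_id"].tolist()
        total_morgans = chrom.total_cM / 100.0
        dist = distortion.get(chrom.name)
        d_bp = int(dist[0] * chrom.length_bp) if dist else None
        mat = np.zeros((len(locus_ids), config.n_individuals), dtype=np.int8)
        for ind in range(config.n_individuals):
            while True:
                k = rng.poisson(total_morgans)
                if k:
                    xo_cm = np.sort(rng.uniform(0.0, chrom.total_cM, size=k))
                    xo_bp = chrom.bp_of_cM(xo_cm)
                else:
                    xo_bp = np.array([])
                start = int(rng.random() < 0.5)
                allele = (start + np.searchsorted(xo_bp, mpos)) % 2
                if dist is not None:
                    at = (start + np.searchsorted(xo_bp, d_bp)) % 2
                    # viability selection: heterozygotes survive 1/ratio
                    if at == 1 and rng.random() > 1.0 / dist[1]:
                        continue
                break
            mat[:, ind] = allele
        for i, locus in enumerate(locus_ids):
            calls[locus] = mat[i]

    data = {}
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]
    for locus, alleles in calls.items():
        vals = np.where(alleles == 1, "H", "A").astype(object)
        miss = rng.random(len(vals)) < config.missing_rate
        vals[miss] = np.nan
        data[locus] = vals
    df = pd.DataFrame.from_dict(data, orient="index", columns=individuals)
    return df.loc[markers["marker_id"]]


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimBundle:
    config: SimConfig
    truth: TruthSet
    libraries: Dict[str, LibrarySpec]
    scaffolds: Dict[str, ScaffoldSeq]
    pairs: List[MatePairRecord]
    markers: pd.DataFrame
    alignments: List[GenericAlignment]
    genotypes: pd.DataFrame
    genetic_map: Dict[str, Tuple[str, float]]


def simulate_all(config: Optional[SimConfig] = None) -> SimBundle:
    """Run every generator under one seed and return the full bundle."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    chroms = simulate_genome(config, rng)
    truth = fragment_into_scaffolds(chroms, config, rng)
    libraries = default_libraries()
    pairs = simulate_matepairs(truth, config, libraries, rng)
    markers, alignments, genotypes, genetic_map = simulate_markers_and_genotypes(
        truth, config, rng
    )
    scaffolds = {
        sid: ScaffoldSeq(id=sid, length=sc.length)
        for sid, sc in truth.scaffolds.items()
    }
    return SimBundle(
        config=config,
        truth=truth,
        libraries=libraries,
        scaffolds=scaffolds,
        pairs=pairs,
        markers=markers,
        alignments=alignments,
        genotypes=genotypes,
        genetic_map=genetic_map,
    )


def write_bundle(bundle: SimBundle, outdir, fasta: bool = False) -> None:
    """Write the bundle as the standard TSV/YAML/JSON file set."""
    import os

    from .aligntab import write_alignment_table
    from .anchoring import write_anchors_tsv  # noqa: F401  (kept for CLI symmetry)
    from .linkpeak import write_libraries_yaml, write_pairs_tsv
    from .mapqc import write_genotype_matrix

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "scaffolds.tsv"), "w") as fh:
        fh.write("#scaffold\tlength\n")
        for sid in sorted(bundle.scaffolds):
            fh.write(f"{sid}\t{bundle.scaffolds[sid].length}\n")
    write_pairs_tsv(bundle.pairs, os.path.join(outdir, "pairs.tsv"))
    write_libraries_yaml(bundle.libraries, os.path.join(outdir, "libraries.yaml"))
    bundle.markers.to_csv(os.path.join(outdir, "markers.tsv"), sep="\t", index=False)
    write_alignment_table(bundle.alignments, os.path.join(outdir, "alignments.tsv"))
    write_genotype_matrix(bundle.genotypes, os.path.join(outdir, "genotypes.tsv"))
    with open(os.path.join(outdir, "map.tsv"), "w") as fh:
        fh.write("#marker\tlinkage_group\tposition_cM\n")
        for marker, (lg, cm) in sorted(bundle.genetic_map.items()):
            fh.write(f"{marker}\t{lg}\t{cm:.6f}\n")
    truth = {
        "order": bundle.truth.order,
        "orientation": bundle.truth.orientation,
        "chimeras": {
            sid: sc.breakpoints
            for sid, sc in bundle.truth.scaffolds.items()
            if sc.is_chimeric
        },
        "config": {k: v for k, v in asdict(bundle.config).items()},
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    if fasta:
        from .seqio import write_fasta

        rng = np.random.default_rng(bundle.config.seed + 1)
        seqs = []
        for sid in sorted(bundle.scaffolds):
            n = bundle.scaffolds[sid].length
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
            seqs.append(ScaffoldSeq(id=sid, length=n, sequence=seq))
        write_fasta(seqs, os.path.join(outdir, "scaffolds.fa"))


def true_backbone_positions(truth: TruthSet) -> Dict[str, Tuple[str, float]]:
    """Oracle (chromosome, cM) per part key — handy for foreign-map tests."""
    positions: Dict[str, Tuple[str, float]] = {}
    for sid, sc in truth.scaffolds.items():
        for idx, part in enumerate(sc.parts):
            chrom = truth.chromosome(part.chromosome)
            mid = (part.chrom_beg + part.chrom_end) // 2
            positions[sc.part_key(idx)] = (part.chromosome, float(chrom.cM_of(mid)))
    return positions
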