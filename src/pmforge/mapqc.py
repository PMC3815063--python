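"""Genetic-map utilities: genotype QC, distortion scan, Kosambi conversion.

The genotype matrix uses two-state backcross coding: each call is ``A``
(homozygous, recurrent-parent allele) or ``H`` (heterozygous); missing data
are ``NaN`` in memory and ``-`` on disk.  Loci are rows, individuals are
columns.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import DistortionResult, GeneticMapEntry

MISSING = "-"


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# genotype matrix I/O and QC


def read_genotype_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.replace(MISSING, np.nan)


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.fillna(MISSING).to_csv(path, sep="\t")


def filter_genotype_matrix(
    matrix: pd.DataFrame, max_missing: float = 0.20
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Drop loci and individuals whose missing fraction reaches ``max_missing``.

    Removal order follows standard linkage-map preprocessing: loci first,
    then individuals, then one locus re-check (individual removal can push a
    borderline locus over the threshold).  The threshold is inclusive: a
    locus with exactly 20% missing calls is removed at the default.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must lie in (0, 1]")
    if matrix.empty:
        raise ValueError("empty genotype matrix")

    removed_loci: List[str] = []
    removed_individuals: List[str] = []

    def _drop_loci(m: pd.DataFrame) -> pd.DataFrame:
        frac = m.isna().mean(axis=1)
        bad = frac[frac >= max_missing].index.tolist()
        removed_loci.extend(bad)
        return m.drop(index=bad)

    m = _drop_loci(matrix)
    frac_ind = m.isna().mean(axis=0)
    bad_ind = frac_ind[frac_ind >= max_missing].index.tolist()
    removed_individuals.extend(bad_ind)
    m = m.drop(columns=bad_ind)
    m = _drop_loci(m)
    return m, removed_loci, removed_individuals


def collapse_cosegregating(
    matrix: pd.DataFrame,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Retain one representative per set of identically segregating loci.

    Two loci co-segregate when their call vectors (including the missing
    pattern) are identical.  The representative is the lexicographically
    smallest locus id of its group; ``groups`` maps each representative to
    all members (itself included) so collapsed markers can later inherit the
    representative's map position during anchoring.
    """
    keys = matrix.fillna("\0").apply(lambda row: tuple(row), axis=1)
    groups: Dict[str, List[str]] = {}
    by_key: Dict[tuple, List[str]] = {}
    for locus, key in keys.items():
        by_key.setdefault(key, []).append(locus)
    representatives = []
    for members in by_key.values():
        rep = min(members)
        representatives.append(rep)
        groups[rep] = sorted(members)
    representatives = [loc for loc in matrix.index if loc in set(representatives)]
    return matrix.loc[representatives], groups


def segregation_distortion(matrix: pd.DataFrame) -> List[DistortionResult]:
    """Chi-square scan of each locus against the 1:1 backcross expectation.

    Distorted loci are reported, never removed: distorted markers still map
    to their correct linkage groups and carry anchoring information.
    """
    results: List[DistortionResult] = []
    for locus, row in matrix.iterrows():
        calls = row.dropna()
        n_a = int((calls == "A").sum())
        n_h = int((calls == "H").sum())
        n = n_a + n_h
        if n == 0:
            results.append(
                DistortionResult(locus, 0, 0, float("nan"), float("nan"), flagged=True)
            )
            continue
        expected = n / 2.0
        chi2 = (n_a - expected) ** 2 / expected + (n_h - expected) ** 2 / expected
        p = float(stats.chi2.sf(chi2, df=1))
        results.append(DistortionResult(locus, n_a, n_h, chi2, max(p, 5e-324)))
    return results


# ---------------------------------------------------------------------------
# map-function conversions and summary statistics


def kosambi_cM(r: float) -> float:
    """Kosambi map distance (cM) for a recombination fraction ``r`` in [0, 0.5)."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def inverse_kosambi(d_cM: float) -> float:
    """Recombination fraction for a Kosambi distance in cM."""
    if d_cM < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * math.tanh(d_cM / 50.0)


def map_interval_spacing(map_length_cM: float, n_mapped: int, n_groups: int = 1) -> float:
    """Average marker spacing: map length over the number of intervals.

    A single linkage group of *n* markers has *n - 1* intervals; a combined
    map over *g* groups has *n - g* intervals.  The result is reported
    rounded half-up to two decimals, matching the convention of published
    map-summary tables.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_mapped <= n_groups:
        raise ValueError("need more mapped markers than linkage groups")
    intervals = n_mapped - n_groups if n_groups > 1 else n_mapped - 1
    return round_half_up(map_length_cM / intervals, 2)


# ---------------------------------------------------------------------------
# map-table I/O


def read_map_table(path) -> List[GeneticMapEntry]:
    entries: List[GeneticMapEntry] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            marker, group, cm = line.split("\t")[:3]
            entries.append(GeneticMapEntry(marker, group, float(cm)))
    return entries


def write_map_table(entries, path) -> None:
    with open(path, "w") as fh:
        fh.write("#marker\tlinkage_group\tposition_cM\n")
        for e in entries:
            fh.write(f"{e.marker_id}\t{e.linkage_group}\t{e.position_cM:g}\n")
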