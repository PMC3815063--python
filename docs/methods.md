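# Methods

This note documents the models, parameter choices and numerical conventions
behind `pmforge`, and what the simulator-based tests do and do not
demonstrate about real data.

## Coordinate conventions

All internal coordinates are 0-based half-open. Emitted standard formats
use their native conventions — AGP and GFF3 are 1-based inclusive, wiggle
fixedStep is 1-based — and conversion happens only at the I/O boundary.
The BLAST tab (`blast6`) reader maps 1-based inclusive spans `(b, e)` to
half-open `(b−1, e)` and encodes a descending subject interval as the minus
strand with ascending coordinates; span length is invariant under the
conversion (property-tested on random rows).

Reported table-style values are rounded half-up at the printed precision
(two decimals for cM spacings, one for percentages); full precision is kept
internally.

## Marker anchoring cascade

1. **Repeat-depth filter.** An alignment is removed iff the fraction of its
   length covered by ≥ `max_competitors` (default 5) other alignments is
   ≥ `frac` (default 0.20). "Competing" means other alignments of the same
   query over the same query region (default), with a target-region mode
   available, since crowding can be diagnosed in either space. Alignments
   that merely touch a short repeat are never removed — removal always
   requires the coverage-fraction condition. The implementation is
   per-base exact and is tested against a brute-force per-base oracle.
2. **Hit grouping.** Same-scaffold, same-strand blocks whose target gaps
   are ≤ 1 kb merge into one hit (score = sum, span = union), so small
   indels do not fragment a placement.
3. **Pair filter.** For two-read markers, only convergently oriented pairs
   on one scaffold with outer span within the expected separation (default
   50 bp – 5 kb for PCR-amplicon-class markers, configurable per class)
   survive; single-read markers skip this stage.
4. **Unique placement.** A marker anchors at its best hit only when that
   hit is unique or out-scores the runner-up by `min_ratio` (default 1.2;
   this margin is a package choice, surfaced in the run report). The
   anchor coordinate is the hit-span midpoint — a deliberate convention,
   since nothing in the evidence distinguishes a better point.

Markers designed a priori against the assembly (their positions known by
construction) bypass the cascade. Markers removed from the map as
co-segregating inherit the map position of their group representative:
they are genetically redundant but physically distinct anchors.

## Genetic-map QC

The genotype model is a two-state backcross coding (A homozygous / H
heterozygous). The missing-data filter removes loci, then individuals,
then re-checks loci once, at an inclusive ≥ 20% threshold. Co-segregation
collapse keys on the full call vector including the missing pattern and
keeps the lexicographically smallest id. The segregation-distortion scan
is χ² against 1:1 with df = 1, reported per locus and never used to remove
markers (distorted markers still map and anchor); no multiple-testing
correction is applied — downstream thresholds belong to the caller.
Kosambi conversion is `d = 25·ln((1+2r)/(1−2r))` with the closed-form
inverse `r = tanh(d/50)/2`; the round trip is exact to 1e−12 across the
domain.

The interval-spacing summary divides map length by the number of
intervals: markers − 1 within one linkage group, markers − g for a
combined map over g groups.

## Marey profiling and pericentromere calling

Anchor cM values are regularized with an isotonic (monotone) fit before
differencing — marker maps are locally noisy but recombination cannot be
negative. Windowed rates are finite differences of the fitted curve over
sliding windows (default 5 Mb window, 1 Mb step). The pericentromere is
the longest maximal run of windows with rate < 0.1 cM/Mb spanning ≥ 2 Mb;
ties go to the smaller start coordinate (a fixed, reproducible rule where
manual curation with auxiliary bin-density data would otherwise decide).

## In-silico anchoring

Clone-end hits keep `match_length ≥ 400` and `bit score > 700` (the length
bound is a stated minimum, hence inclusive; the score bound is strict);
synteny matches keep `length > 1000 bp` and `identity > 97%` (both
strict). WGP-tagged clones place on the scaffold holding ≥ 80% of their
unique 25-nt tags when that count is ≥ 3, at the min–max tag span. Bin
positions of an ultra-high-density map convert to pseudo-cM by a
configured bin width (default 0.8 cM) at the bin-interval midpoint; clones
spanning ≥ 5 bins are down-weighted 0.5× as positionally inaccurate.

Cross-map projection fits, per linkage group, a monotone piecewise-linear
transform through (foreign cM, backbone cM) pairs of scaffolds anchored in
both maps; ≥ 2 shared scaffolds are required, otherwise the group is
skipped with a warning. Beyond the terminal shared points the terminal
segment extrapolates linearly and the result is flagged. Declared
inversions are supplied as foreign-map cM intervals per linkage group
(the catalogued intervals are physical; converting them to map intervals
is configuration, because the foreign map is the space in which the local
order is reversed); anchors inside an interval are reflected about its
midpoint before transformation.

## Link-peak scoring

Unsatisfied mate pairs — reliable end mappings on two different,
non-adjoining scaffolds — are binned into sliding windows (default 10 kb
window, 5 kb step; unstated in the original strategy, chosen to resolve
junctions at sub-insert scale). Per window, pairs group by target
scaffold; a group scores the sum of its pairs' library weights. Default
weights follow the stated principle of favouring the reference genotype's
libraries and longer inserts: clone ends 3.0, 20-kb 454 2.0, 8-kb 454 1.5,
foreign-genotype libraries below that; all configurable. The window peak
is the best group, the noise the summed rest — a window whose evidence
splits over many targets is repeat-driven. Direction follows read strand:
forward-strand evidence points off the right scaffold end.

Link calling inspects each scaffold end's terminal `⌈reach/step⌉` windows
(reach = max library insert mean + 3 sd, so evidence beyond any insert's
range is ignored). The end's candidate is the target of its **dominant
outward window** (largest outward per-target peak), accepted when peak ≥ 4.0
and that window's noise/peak ≤ 0.5. The dominant-window formulation is
deliberate: aggregating noise across all terminal windows lets scattered
genome-wide mismapped pairs veto genuinely weak junctions, which inverts
the noise score's purpose (flagging *co-located* multi-target evidence).
Only reciprocal candidates become links; one-sided peaks are emitted as
suggestions for curation. Pairs bridging two segments of one split
(chimeric) scaffold are classified satisfied — they echo the original
false join, not independent linkage.

Relative orientation from end pairing (R–L same, R–R/L–L opposite) is
propagated by breadth-first traversal over the reciprocal-link graph;
parity-conflicting components are left wholly unoriented and counted.

## Pseudomolecule building

Chromosome assignment requires a 2/3 anchor-weight supermajority
(inclusive); scaffolds below it go to chimera screening rather than being
placed whole. Scaffold cM is the median anchor cM; equal-cM scaffolds
share a bin. Bins that form a simple path in the link graph are
linearized and directed toward their neighbour bins; otherwise they keep
input order and are flagged partially unordered.

Chimera detection segments each scaffold's anchors into maximal runs
consistent in chromosome and local cM (jump tolerance 10 cM); adjacent
runs with ≥ 3 supporting anchors each and discordant assignment yield a
breakpoint at the midpoint of the flanking anchor gap, at most 3 per
scaffold. Splitting produces `parent_p1…p(n+1)` half-open slices that
cover the parent exactly; total assembly length is conserved (tested).

Foreign-only scaffolds insert between backbone neighbours when the
projected cM lies in their interval and, if two foreign maps place the
scaffold, both agree on the interval; disagreements are reported and the
scaffold stays unplaced. Projections beyond a chromosome's terminal
backbone anchor insert at the end and are flagged "terminal" — uniformly
sampled dropout necessarily includes chromosome-terminal scaffolds, which
an interior-only rule could never recover.

Orientation: link-graph components are pinned to an absolute strand by the
majority of their members' Theil–Sen cM-vs-bp slopes; slopes under
0.1 cM/Mb abstain so zero-recombination (pericentromeric) anchors never
vote. Unlinked scaffolds fall back to their own slope; everything else is
`?`. The final AGP alternates W rows with fixed `U` gaps of 50,000 bp
(`gap_type=contig`, `linkage=no` — the AGP vocabulary is a package choice;
no gap sizes are estimated). Unplaced segments collect in a `chr00`
unanchored bin with `?` orientation. `?` components render as forward
strand in FASTA output and are listed in a sidecar report.

Statistics: anchored/oriented counts and Mb per chromosome; the oriented
percentage is size-based (oriented Mb / anchored Mb, half-up to one
decimal — verified against two published row pairs); any non-`?`
orientation counts as oriented. N50 is the classic half-total threshold.
The Total row sums counts and sizes but *averages* per-chromosome N50s and
percentages, matching the summary-table convention it mirrors.

Clone-assembly validation builds a graph of segments, clone contigs and
clone labels; an AGP join is validated when a cycle through a clone label
connects its two segments, a clone bridging non-adjacent segments is a
contradiction, and untouched joins are untested.

## The simulator

The generator emulates the statistical structure the pipeline assumes, at
desk scale: 3 chromosomes × 20 Mb; a central 30% block with zero
recombination and 6 cM/Mb on the arms (piecewise-linear true map); ~1 Mb
lognormal scaffolds (σ_log = 0.4, ≥ 100 kb, ≈ 60 per run) with 2 planted
inter-chromosomal chimeras built from ≥ 0.8 Mb euchromatic segments;
marker densities 20/Mb (euchromatin) and 2/Mb (pericentromere) with 5%
repeat-placed markers (six decoy alignments each) and 2% near-ambiguous
ones; three mate-pair libraries (clone ends 100 kb ± 10 kb at 8×
physical coverage; 20 kb ± 2 kb at 8×; 8 kb ± 0.8 kb at 5×) with 2%
random-end noise pairs; a 180-individual backcross population with 5%
missing calls and one 2:1 transmission-distorted region. These defaults
are the package's study conditions; problem sizes were chosen so a full
simulate-and-assemble cycle runs in seconds.

Crossovers are Poisson in map distance with positions drawn through the
inverse map function — effectively a no-interference (Haldane-like)
process. This is a simplification: at 10 cM the implied recombination
fraction (0.0906) differs from the Kosambi inverse (0.0987) by less than
half a phenotypic standard error at n = 180, so map-scale checks cannot
distinguish the two, but interference-sensitive statistics should not be
calibrated against this generator.

What passing the recovery suite shows: under clean coordinate-level
evidence with known library inserts, the cascade + link-peak + builder
stack reconstructs order (Kendall τ ≥ 0.9 per chromosome), orientation
(no link-derived mis-orientations) and planted chimeras (breakpoint error
below the largest insert mean). What it does not show: robustness to
alignment artefacts of real repeat families, mis-estimated insert-size
distributions, genotyping error in the map itself, or segmental
duplications — real projects should expect more manual curation,
particularly in heterochromatin, where the original strategy also relied
on it.

## Known limitations

- Genetic-map estimation (grouping/ordering) is out of scope; maps are
  inputs. Four-allele outbred codings are reduced to backcross coding.
- The inversion catalogue is configuration; novel inversions are not
  detected.
- Gap sizes are never estimated; every join is a fixed 50-kb gap.
- Pericentromeric bins with no link path keep input order (flagged), so
  order inside deep heterochromatin is only as good as its link coverage.
- Chimera breakpoints are anchor-midpoint estimates; their precision is
  bounded by the local marker spacing, not by the mate-pair data.
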