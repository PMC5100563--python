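# Methods

## Problem setting

Two de novo assemblies of one genome rarely break in the same places:
a long-read-only assembly and a hybrid assembly typically show
*complementary contiguity*, where a gap in one is spanned by an intact
contig of the other. `metamerge` exploits this by splicing contigs from
a donor (reference) assembly into an acceptor (query) assembly. The
package deliberately separates the merge logic from alignment
generation so the algorithm can be driven by MUMmer output, by the
built-in aligner, or by exact truth alignments from the simulator.

All coordinates are 0-based half-open internally; 1-based inclusive
MUMmer conventions are converted at the parser boundary. Reverse-strand
query coordinates are always stored forward-normalized with a strand
flag, so the splicer deals with a single convention.

## One-to-one alignment filtering

Repeats and duplications produce conflicting multi-placements. Two
alignments conflict when they overlap by more than 10% of the shorter
one on a shared reference contig or shared query contig. The filter
keeps the conflict-free subset maximizing total aligned length x
identity. Conflict components of at most 20 alignments are solved
exactly by branch and bound; larger components fall back to a greedy
ordering by weight. This is equivalent in effect to MUMmer's
`delta-filter -r -q` (each reference and each query position is covered
by essentially one alignment), but is stated — and tested — as a single
joint optimization, because filtering the two sides independently and
intersecting the results is provably suboptimal on instances where a
reference conflict and a query conflict share one alignment. The filter
is idempotent.

## HCO scoring

Alignments are pooled per (reference contig, query contig, orientation).
The pair's layout offset — where the oriented query sits on the
reference axis — is the weighted median of per-alignment offsets
(weight = aligned length x identity), which tolerates a minority of
spurious alignments. With the overlap span `O` measured on the reference
axis and `A` the union of aligned reference intervals clipped to the
overlap:

    U = O − A,   HCO = A / max(U, 1)

The 1 bp denominator floor keeps fully aligned overlaps finite while
still maximal; pooling per pair (rather than per alignment) reflects
that the score describes the relationship between two contigs, not one
local alignment.

Each pair is classified from its layout with an end tolerance of 100 bp:
a dovetail at the reference's left or right end, a containment (the
projection of one contig lies inside the other *and* at least 95% of the
contained contig's length is aligned — "completely contained" needs
slack for alignment end-fraying), or internal otherwise. Internal and
containment pairs are never walked.

## Graph, anchors, greedy walk

Edges are dovetail pairs with `HCO >= hco_cutoff` (default 1.5) and
overlap span at least `min_overlap_span` (default 5 kb, a guard against
spurious short dovetails). Anchors are donor contigs longer than
`anchor_len` with at least one edge of `HCO > anchor_hco` (default 5.0).
`anchor_len` should scale with the genome: 1 Mb suits a ~130 Mb genome
and 5 Mb a human-sized one; the synthetic fixtures (2 Mb) use 200 kb,
which every fixture's largest donor contig exceeds by construction.

Anchors are processed longest first. From each anchor the walk extends
right, then left; at each step it considers unused neighbours whose
overlap extends past the exposed end of the current contig (in path
coordinates, tracking each contig's orientation), preferring highest
HCO, then longest contig, then lexicographic id — the tie-breaks are
fixed so runs are deterministic. Every chained contig is marked used
globally, so no contig appears in two paths and cycles are impossible.
A walk never forces an orientation flip: a neighbour whose layout does
not extend the current end is simply not a candidate.

## Splicing and provenance

Chain members are placed on a common path axis via the pairwise layout
offsets. At each junction the cut sits at the donor member's boundary,
so all disputed overlap bases come from the donor assembly. A junction
whose layout implies a gap (next contig starts after the previous ends)
splits the path there with a warning instead of forcing a join. Output
contigs are concatenations of the retained segments (reverse-complemented
for minus-orientation members), and every segment is recorded as a
provenance interval (output interval, source assembly, contig, interval,
strand). The provenance tiles each output contig exactly and no source
base is emitted twice — both properties are asserted by tests.

Acceptor contigs contained in a donor contig are excluded from the
pass-through output to prevent duplication. When the containing donor
contig is not itself part of any merge path, it is emitted once in
place of the removed acceptor contig; without this substitution a
self-merge (donor = acceptor) would return an empty assembly, whereas
with it the identity merge returns the donor's content exactly. Paths
that never extended beyond their anchor are not emitted (their content
remains in the pass-through), and unused donor contigs that contain
nothing are likewise not emitted.

## Metrics

`nx`/`ngx` use the standard sort-descending-and-accumulate definition;
NG50 against a genome size G is reported as 0 with an explicit
`defined=False` flag when the assembly is smaller than G/2, so stats
tables still render for tiny assemblies. Junction windows default to
201 bp with the breakpoint at the 101th base (0-based offset 100, the
last base of the upstream segment); windows truncated by contig ends
are flagged.

## Downsampling

"50%" always means 50% of total bases, and a boundary read that first
crosses a threshold is included — both choices are fixed for
reproducibility. `longest_fraction` keeps the longest reads holding the
requested base fraction. `sample_groups` draws one seeded random order
of cell ids and returns prefixes, making subsets additive and nested by
construction. `match_length_distribution` and `quality_partition`
operate within length bins (default 1 kb): distribution matching scales
the target shape down to the largest total the source can supply per
bin, then samples reads without replacement inside each bin; the
quality partition sorts each bin by mean phred and cuts at half the
bin's bases, which preserves the length distribution of each half by
construction. The binned procedures are this package's own explicit
constructions; their parameters (bin width, boundary rule) are exposed
and seeded.

## Synthetic data generator

The generator emulates the merge-relevant structure of real projects:

* **Genome**: i.i.d. uniform background with planted interspersed repeat
  families, each copy independently substituted at the family's
  divergence. Defaults: one 2 Mb replicon with 2 kb x 20 @ 2%,
  5 kb x 8 @ 1%, and 500 bp x 100 @ 5% — enough repeat structure to
  exercise the one-to-one filter while keeping tests at the
  seconds scale.
* **Assembly pair**: each assembly is the truth minus its own gap
  intervals (4 gaps of 10-30 kb by default). All gaps of both assemblies
  are mutually separated by >= 50 kb, which guarantees complementarity:
  every gap of one assembly lies inside a contig of the other with
  >= 50 kb flanks, the precondition for complete reconstruction.
  Optional per-contig substitutions and a single inverted acceptor
  contig exercise noisy and minus-strand merging; contigs are error-free
  by default.
* **Reads**: truncated-lognormal lengths (median ~6.7 kb, truncated to
  [500 bp, 60 kb]), truncated-normal per-read mean phred (10 +- 3 in
  [5, 40]), cell ids in consecutive blocks (42 cells), drawn until the
  requested coverage (total bases / genome length) is reached.

Everything is a pure function of the `SimConfig` seed. What the
generator does **not** model: indels in assemblies or reads, realistic
long-read error profiles, chimeric reads or heterozygosity. Passing
tests therefore demonstrate the correctness of the merge logic,
layout arithmetic and bookkeeping — not robustness to structural
assembly errors, which on real data is delegated to the HCO cutoff and
the conservative walk termination.

## Built-in aligner

`builtin_align` finds k-mers (default k = 21, exact 2-bit packing)
that occur exactly once in the donor (forward strand) and exactly once
in the acceptor (both strands), then chains collinear anchors per
contig pair and strand: a chain breaks when the diagonal drifts more
than 50 bp or consecutive anchors are more than 2 kb apart on the
reference. Each chain becomes one alignment record spanning its
anchors; identity is estimated as anchored bases over chain span, and
chains under 1 kb are dropped. Unique-k-mer anchoring is exact for the
substitution-only synthetic data this package targets; on indel-rich
real data chains fragment at indels (the per-pair pooling in HCO
scoring absorbs this), and its placements are cross-checked against
minimap2 in the test suite. Alignment records end at their outermost
anchors, so they may stop short of the true overlap ends by up to the
distance to the nearest unique k-mer; scoring and splicing use
contig-geometry layouts rather than alignment endpoints, so merges are
still exact.

## Problem sizes used in tests

Unit tests run reduced conditions (300-600 kb genomes, 2 gaps); the
end-to-end suite and the acceptance script run the full default
conditions: 20 seeded 2 Mb fixtures merged through the built-in aligner,
1000 random HCO configurations against a per-base boolean oracle,
200 random filter instances against exhaustive enumeration, 1000 random
length multisets for the statistics, 100 random read sets plus a
10,000-read lognormal set for the downsampling properties, and
10 cutoff levels x 5 noisy fixtures for monotonicity.

## Known limitations

* Merging more than two assemblies requires iterating externally.
* No gap-filling with N's: the output contains only sequence inherited
  from the inputs.
* The one-to-one filter's exact solver is exponential in the worst
  case; components larger than 20 alignments use a greedy fallback.
* `parse_delta` consumes but does not retain per-alignment indel
  offsets, so base-level alignment reconstruction (CIGAR) is out of
  scope.
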