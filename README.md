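# metamerge

`metamerge` is a meta-assembler: it merges two de novo assemblies of the
*same* genome — typically a long-read-only assembly and a hybrid
(long + short read) assembly — into a single, more contiguous assembly.
The two inputs tend to break in *complementary* places: a gap in one
assembly is often spanned by an intact contig in the other, so splicing
contigs across assemblies can close gaps neither assembler closed alone.

It is aimed at genome-assembly practitioners who already have two
assemblies (or want to test merging strategies on simulated data), and
ships with everything needed to run end to end without external tools:
a MUMmer `delta`/`show-coords` parser, a built-in unique-k-mer anchor
aligner, contiguity statistics, long-read downsampling operators, and a
synthetic genome/assembly/read simulator.

## The algorithm

One assembly is the **donor** (reference; its sequence is preferentially
retained), the other the **acceptor** (query; its gaps are bridged).

1. **Align** the assemblies (MUMmer output or the built-in aligner) and
   reduce the alignments to a one-to-one set, discarding the ambiguous
   multi-placements that repeats and duplications induce.
2. **Score** every contig pair with the high-confidence-overlap score

       HCO = A / max(U, 1)

   where, under the layout implied by the pair's pooled alignments, `O`
   is the co-extension (overlap) of the two contigs, `A` the aligned
   bases within the overlap, and `U = O − A` the overlapping-but-
   unaligned bases. Unrelated sequences have small `A` and large `U`;
   true dovetail overlaps score high.
3. **Build a graph** whose edges are contig pairs with `HCO ≥ hco`
   (default 1.5) and overlap span at least `min_overlap` (default 5 kb).
   Donor contigs longer than `l` (default 1 Mb; scale with genome size)
   with an edge of `HCO > c` (default 5.0) become **anchor** nodes.
4. **Walk greedily** left and right from each anchor, at each step
   choosing the unused neighbor that extends the growing chain past its
   current end (highest HCO first, then longest contig). Each contig is
   used at most once across all paths.
5. **Splice** every chain into one merged contig, placing each junction
   cut so that all disputed overlap bases come from the donor. Acceptor
   contigs wholly contained in a donor contig are removed (the donor
   copy is kept); remaining unused acceptor contigs pass through.

Every output base carries provenance (source assembly, contig, interval,
strand) in a BED-like table, and 201 bp windows centred on each splice
joint (breakpoint at the 101th base) can be extracted for validation.

## Worked example

Simulate a 600 kb genome fragmented into two assemblies with
complementary gaps, then merge them with the built-in aligner:

```sh
metamerge simulate --genome-len 600000 --gaps 2 --seed 5 --prefix sim
metamerge merge sim.donor.fasta sim.acceptor.fasta \
    --builtin-align --l 60000 --genome-size 600000 --prefix merged
cat merged.report.txt
```

```
metamerge 0.1.0 merge report
parameters: hco=1.5 c=5.0 l=60000 min_overlap=5000
donor: sim.donor.fasta (3 contigs, 560744 bp)
acceptor: sim.acceptor.fasta (3 contigs, 562372 bp)
paths: 1
splices: 3
contained_removed: 1
pass_through: 0
containment_substituted: 0
output: 1 contigs, 600000 bp
ng50_donor: 199603
ng50_acceptor: 221182
ng50_merged: 600000
```

Both 3-contig inputs (NG50 ≈ 200 kb) merge into a single 600 kb contig:
one greedy path spliced the chain with 3 junctions, and the one acceptor
contig fully contained in a donor contig was removed. The merged contig
is byte-identical to the simulated truth genome. `metamerge stats`
prints the same N50/NG50 table for any FASTA, and

```sh
metamerge junctions merged.fasta merged.provenance.tsv --out junctions.fasta
```

writes the 201 bp splice-joint windows
(`>junction_1 contig=merged_1 pos=169699 ... breakpoint_offset=100`),
each of which occurs verbatim in the truth genome.

Read downsampling mirrors common long-read experiment designs:

```sh
metamerge downsample reads.fastq --mode longest --fraction 0.5   # longest 50% of bases
metamerge downsample reads.fastq --mode quality --seed 1         # low/high/random halves
```

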