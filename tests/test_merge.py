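"""Merge pipeline: graph construction, greedy walks, splicing, provenance."""

import numpy as np
import pytest

from metamerge import (
    Assembly,
    Contig,
    MergeParams,
    build_graph,
    builtin_align,
    extend_paths,
    merge_assemblies,
    score_overlaps,
    truth_alignments,
)
from metamerge.merge import splice
from metamerge import AlignmentRecord, AlignmentSet
from metamerge.synthetic import complementary_pair, simulate_genome

from conftest import check_provenance, small_merge_params, small_sim_config


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _bridge_fixture():
    """100 kb truth; acceptor covers [0,40k) and [35k,100k); a donor contig
    covering [20k,60k) bridges the acceptor junction."""
    rng = np.random.default_rng(99)
    truth = _random_seq(rng, 100_000)
    acceptor = Assembly(
        [Contig("a1", truth[:40_000]), Contig("a2", truth[35_000:])], role="acceptor"
    )
    donor = Assembly([Contig("d1", truth[20_000:60_000])], role="donor")
    recs = [
        AlignmentRecord("d1", "a1", 0, 20_000, 20_000, 40_000, "+", 1.0, 40_000, 40_000),
        AlignmentRecord("d1", "a2", 15_000, 40_000, 0, 25_000, "+", 1.0, 40_000, 65_000),
    ]
    return truth, donor, acceptor, AlignmentSet(recs, source="truth")


def test_bridge_merge_reconstructs_truth_with_donor_overlap_bases():
    truth, donor, acceptor, alns = _bridge_fixture()
    params = MergeParams(anchor_len=10_000, min_overlap_span=1_000)
    # the two alignments legitimately share 5 kb of the donor (the acceptor
    # contigs overlap in the genome), so they enter pre-filtered
    merged = merge_assemblies(donor, acceptor, alns, params, prefilter=False)
    assert len(merged.assembly) == 1
    out = merged.assembly.contigs[0]
    assert out.seq == truth
    # the disputed [35k,40k) region must be attributed to the donor
    prov = merged.provenance[out.id]
    sources = [(iv.out_start, iv.out_end, iv.source_asm) for iv in prov]
    assert sources == [
        (0, 20_000, "acceptor"),
        (20_000, 60_000, "donor"),
        (60_000, 100_000, "acceptor"),
    ]
    check_provenance(merged, donor, acceptor)


def test_single_contig_path_splice_is_identity():
    _, donor, acceptor, alns = _bridge_fixture()
    params = MergeParams(anchor_len=10_000, min_overlap_span=1_000)
    pairs = score_overlaps(alns, params)
    graph = build_graph(pairs, params)
    paths = extend_paths(graph, params)
    (path,) = paths
    solo = type(path)(path.anchor_id, [path.entries[1]], [])  # the donor entry alone
    (piece,) = splice(solo, donor, acceptor)
    assert piece.seq == donor["d1"].seq
    assert piece.splices == []


def test_edge_below_hco_cutoff_is_dropped():
    # aligned 1200 of a 2200 overlap -> hco = 1.2 < 1.5 default
    rec = AlignmentRecord("d", "a", 8800, 10_000, 1000, 2200, "+", 1.0, 10_000, 10_000)
    # force unaligned flanks by extending the implied overlap via offset:
    # offset = 8800-1000 = 7800; overlap = [7800, 10000) of len 2200, A=1200
    pairs = score_overlaps(AlignmentSet([rec]), MergeParams())
    (p,) = pairs
    assert p.hco == pytest.approx(1200 / 1000)
    graph = build_graph(pairs, MergeParams(min_overlap_span=1000))
    assert graph.edges == []


def test_anchor_selection_under_defaults():
    """A 2 Mb donor contig with an hco-6 edge anchors under c=5, l=1 Mb."""
    rec = AlignmentRecord(
        "d", "a", 1_994_000, 2_000_000, 0, 6_000, "+", 1.0, 2_000_000, 100_000
    )
    params = MergeParams()
    pairs = score_overlaps(AlignmentSet([rec]), params)
    # fully aligned overlap: hco is huge; force hco=6 via a gappy overlap
    (p,) = pairs
    p.hco = 6.0
    graph = build_graph(pairs, params)
    assert graph.anchors == ["d"]
    p.hco = 4.9
    graph = build_graph(pairs, params)
    assert graph.anchors == []


def test_competing_anchors_used_once_bookkeeping():
    """Two anchors share one bridging acceptor contig: the longer anchor's
    path consumes it and the second anchor's walk terminates immediately."""
    rng = np.random.default_rng(17)
    truth = _random_seq(rng, 200_000)
    # both donor contigs overlap the bridge's left region; the bridge
    # extends right past both of them
    donor = Assembly(
        [Contig("dlong", truth[:80_000]), Contig("dshort", truth[40_000:100_000])],
        role="donor",
    )
    acceptor = Assembly([Contig("bridge", truth[60_000:140_000])], role="acceptor")
    recs = [
        AlignmentRecord("dlong", "bridge", 60_000, 80_000, 0, 20_000, "+", 1.0, 80_000, 80_000),
        AlignmentRecord("dshort", "bridge", 20_000, 60_000, 0, 40_000, "+", 1.0, 60_000, 80_000),
    ]
    params = MergeParams(anchor_len=50_000, min_overlap_span=5_000)
    graph = build_graph(score_overlaps(AlignmentSet(recs), params), params)
    assert graph.anchors == ["dlong", "dshort"]  # longest first
    paths = extend_paths(graph, params)
    assert len(paths) == 2
    assert [e.contig_id for e in paths[0].entries] == ["dlong", "bridge"]
    assert [e.contig_id for e in paths[1].entries] == ["dshort"]


def test_zero_anchors_passes_acceptor_through():
    _, donor, acceptor, alns = _bridge_fixture()
    params = MergeParams(anchor_len=1_000_000, min_overlap_span=1_000)
    merged = merge_assemblies(donor, acceptor, alns, params)
    assert [c.seq for c in merged.assembly] == [c.seq for c in acceptor]
    assert merged.report["paths"] == 0


def test_self_merge_preserves_content(small_pair):
    truth, pair = small_pair
    alns = builtin_align(pair.donor, pair.donor)
    merged = merge_assemblies(pair.donor, pair.donor, alns, small_merge_params())
    assert sorted(c.seq for c in merged.assembly) == sorted(c.seq for c in pair.donor)
    assert merged.report["contained_removed"] == len(pair.donor)


def test_disjoint_assemblies_pass_through():
    rng = np.random.default_rng(23)
    donor = Assembly([Contig("d", _random_seq(rng, 30_000))], role="donor")
    acceptor = Assembly([Contig("a", _random_seq(rng, 30_000))], role="acceptor")
    merged = merge_assemblies(donor, acceptor, builtin_align(donor, acceptor))
    assert [c.seq for c in merged.assembly] == [acceptor["a"].seq]


def test_complementary_pair_reconstruction_with_truth_alignments():
    for seed in (0, 1, 2):
        cfg = small_sim_config(seed=seed)
        truth = simulate_genome(cfg)
        pair = complementary_pair(truth, cfg)
        merged = merge_assemblies(
            pair.donor, pair.acceptor, truth_alignments(pair), small_merge_params()
        )
        assert len(merged.assembly) == 1
        assert merged.assembly.contigs[0].seq == truth.contigs[0].seq
        check_provenance(merged, pair.donor, pair.acceptor)


def test_inverted_acceptor_contig_round_trip():
    """A minus-strand acceptor contig is spliced via reverse complement and
    the merged sequence still equals the truth."""
    cfg = small_sim_config(seed=5, invert_one_acceptor_contig=True)
    truth = simulate_genome(cfg)
    pair = complementary_pair(truth, cfg)
    assert any(p.strand == "-" for p in pair.acceptor_placements)
    merged = merge_assemblies(
        pair.donor, pair.acceptor, truth_alignments(pair), small_merge_params()
    )
    assert len(merged.assembly) == 1
    assert merged.assembly.contigs[0].seq == truth.contigs[0].seq
    strands = {
        iv.strand for iv in merged.provenance[merged.assembly.contigs[0].id]
    }
    assert "-" in strands
    check_provenance(merged, pair.donor, pair.acceptor)


def test_empty_alignments_return_acceptor(small_pair):
    _, pair = small_pair
    merged = merge_assemblies(pair.donor, pair.acceptor, AlignmentSet([]))
    assert [c.seq for c in merged.assembly] == [c.seq for c in pair.acceptor]


def test_contained_acceptor_contig_removed_partial_retained():
    rng = np.random.default_rng(31)
    truth = _random_seq(rng, 60_000)
    donor = Assembly([Contig("d", truth[:50_000])], role="donor")
    acceptor = Assembly(
        [Contig("inside", truth[10_000:20_000]), Contig("partial", truth[40_000:60_000])],
        role="acceptor",
    )
    recs = [
        AlignmentRecord("d", "inside", 10_000, 20_000, 0, 10_000, "+", 1.0, 50_000, 10_000),
        AlignmentRecord("d", "partial", 40_000, 50_000, 0, 10_000, "+", 1.0, 50_000, 20_000),
    ]
    params = MergeParams(anchor_len=100_000)
    merged = merge_assemblies(donor, acceptor, AlignmentSet(recs), params)
    ids = [c.id for c in merged.assembly]
    assert "inside" not in ids  # fully contained: removed, donor kept instead
    assert "partial" in ids  # only 50% aligned inside: retained
    assert "d" in ids  # containment substitution keeps the donor copy
    assert merged.report["contained_removed"] == 1


def test_hco_cutoff_monotonicity():
    """Raising the HCO cutoff never adds edges or splices."""
    prev_edges = prev_splices = None
    for seed in range(3):
        cfg = small_sim_config(seed=seed, assembly_sub_rate=0.01)
        truth = simulate_genome(cfg)
        pair = complementary_pair(truth, cfg)
        alns = builtin_align(pair.donor, pair.acceptor)
        prev_edges = prev_splices = None
        for cutoff in (1.0, 1.5, 2.5, 4.0, 8.0, 16.0, 64.0, 256.0, 1024.0, 1e6):
            params = small_merge_params(hco_cutoff=cutoff, anchor_hco=max(cutoff, 5.0))
            pairs = score_overlaps(alns, params)
            graph = build_graph(pairs, params)
            merged = merge_assemblies(pair.donor, pair.acceptor, alns, params)
            if prev_edges is not None:
                assert len(graph.edges) <= prev_edges
                assert merged.report["splices"] <= prev_splices
            prev_edges = len(graph.edges)
            prev_splices = merged.report["splices"]


def test_path_count_non_increasing_in_anchor_len():
    cfg = small_sim_config(seed=2)
    truth = simulate_genome(cfg)
    pair = complementary_pair(truth, cfg)
    alns = truth_alignments(pair)
    prev = None
    for anchor_len in (10_000, 30_000, 60_000, 120_000, 1_000_000):
        params = small_merge_params(anchor_len=anchor_len)
        merged = merge_assemblies(pair.donor, pair.acceptor, alns, params)
        if prev is not None:
            assert merged.report["paths"] <= prev
        prev = merged.report["paths"]
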