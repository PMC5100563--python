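import numpy as np
import pytest

from metamerge import (
    MergeParams,
    SimConfig,
    complementary_pair,
    reverse_complement,
    simulate_genome,
)


def small_sim_config(seed=0, **overrides):
    """A fast, reduced-scale study condition for unit tests: 300 kb genome,
    2 gaps per assembly, 20 kb separation."""
    kwargs = dict(
        genome_len=300_000,
        gaps_per_assembly=2,
        gap_len_range=(5_000, 10_000),
        min_gap_separation=20_000,
        repeat_families=[(1000, 5, 0.02), (300, 20, 0.05)],
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def small_merge_params(**overrides):
    kwargs = dict(anchor_len=30_000, min_overlap_span=2_000)
    kwargs.update(overrides)
    return MergeParams(**kwargs)


@pytest.fixture(scope="session")
def small_pair():
    cfg = small_sim_config(seed=11)
    truth = simulate_genome(cfg)
    return truth, complementary_pair(truth, cfg)


def check_provenance(merged, donor, acceptor):
    """Provenance invariants: intervals tile each output contig exactly,
    each interval's bytes equal the (strand-resolved) source subsequence,
    and no source base is claimed twice."""
    claimed = {}
    for contig in merged.assembly:
        ivs = merged.provenance[contig.id]
        pos = 0
        for iv in ivs:
            assert iv.out_start == pos, f"{contig.id}: gap/overlap at {iv.out_start}"
            pos = iv.out_end
            src_asm = donor if iv.source_asm == "donor" else acceptor
            src_seq = src_asm[iv.source_contig].seq[iv.source_start : iv.source_end]
            if iv.strand == "-":
                src_seq = reverse_complement(src_seq)
            assert contig.seq[iv.out_start : iv.out_end] == src_seq, (
                f"{contig.id}: bytes differ from source {iv.source_contig}"
            )
            key = (iv.source_asm, iv.source_contig)
            for s, e in claimed.get(key, []):
                assert iv.source_end <= s or iv.source_start >= e, (
                    f"source bases of {key} used twice"
                )
            claimed.setdefault(key, []).append((iv.source_start, iv.source_end))
        assert pos == contig.length, f"{contig.id}: provenance does not tile"


def random_alignment_instance(rng, n_max=8):
    """A random small alignment instance for filter-oracle tests."""
    from metamerge import AlignmentRecord, AlignmentSet

    n = int(rng.integers(1, n_max + 1))
    ref_ids = ["r1", "r2"]
    qry_ids = ["q1", "q2"]
    records = []
    for i in range(n):
        ref_id = ref_ids[int(rng.integers(0, 2))]
        qry_id = qry_ids[int(rng.integers(0, 2))]
        ref_len = qry_len = 10_000
        rs = int(rng.integers(0, 9_000))
        re = rs + int(rng.integers(100, min(2_000, ref_len - rs) + 1))
        qs = int(rng.integers(0, 9_000))
        qe = qs + int(rng.integers(100, min(2_000, qry_len - qs) + 1))
        records.append(
            AlignmentRecord(
                ref_id=ref_id,
                qry_id=qry_id,
                ref_start=rs,
                ref_end=re,
                qry_start=qs,
                qry_end=qe,
                strand="+" if rng.random() < 0.5 else "-",
                identity=float(rng.uniform(0.8, 1.0)),
                ref_len=ref_len,
                qry_len=qry_len,
            )
        )
    return AlignmentSet(records, source="truth")
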