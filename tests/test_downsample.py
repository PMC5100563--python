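"""Read downsampling operators: determinism, nestedness, stratification."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from metamerge import (
    LengthHistogram,
    ReadSet,
    SeqRead,
    SimConfig,
    longest_fraction,
    match_length_distribution,
    quality_partition,
    sample_groups,
    simulate_genome,
    simulate_reads,
)


def _reads(lengths, quals=None, cells=None):
    reads = []
    for i, L in enumerate(lengths):
        reads.append(
            SeqRead(
                f"r{i:05d}",
                int(L),
                mean_quality=None if quals is None else float(quals[i]),
                cell_id=None if cells is None else str(cells[i]),
            )
        )
    return ReadSet(reads)


@pytest.fixture(scope="module")
def lognormal_reads():
    rng = np.random.default_rng(12)
    lengths = np.clip(rng.lognormal(8.8, 0.6, size=10_000), 500, 60_000).astype(int)
    quals = np.clip(rng.normal(10, 3, size=10_000), 5, 40)
    return _reads(lengths, quals)


def test_longest_fraction_boundary_rule():
    rs = _reads([10, 8, 6, 4, 2])
    out = longest_fraction(rs, 0.5)
    assert sorted(r.length for r in out) == [8, 10]  # cumulative 18 >= 15


def test_longest_fraction_identity():
    rs = _reads([5, 3, 1])
    assert len(longest_fraction(rs, 1.0)) == 3
    with pytest.raises(ValueError):
        longest_fraction(ReadSet([]), 0.5)


def test_longest_fraction_sort_property_and_nestedness():
    rng = np.random.default_rng(77)
    for _ in range(100):
        lengths = rng.integers(100, 10_000, size=int(rng.integers(2, 60)))
        rs = _reads(lengths)
        f1, f2 = sorted(rng.uniform(0.05, 1.0, size=2))
        s1 = {r.id for r in longest_fraction(rs, f1)}
        s2 = {r.id for r in longest_fraction(rs, f2)}
        assert s1 <= s2
        kept = longest_fraction(rs, f1)
        kept_ids = {r.id for r in kept}
        min_kept = min(r.length for r in kept)
        discarded = [r for r in rs if r.id not in kept_ids]
        assert all(r.length <= min_kept for r in discarded)


def test_sample_groups_additive_nesting():
    rng = np.random.default_rng(5)
    cells = rng.integers(0, 42, size=2_000)
    rs = _reads(rng.integers(500, 5_000, size=2_000), cells=[f"c{c}" for c in cells])
    s15, s20 = sample_groups(rs, [15, 20], seed=3)
    ids15 = {r.id for r in s15}
    ids20 = {r.id for r in s20}
    assert ids15 <= ids20
    assert len({r.cell_id for r in s15}) == 15
    assert len({r.cell_id for r in s20}) == 20
    # full draw returns everything
    (full,) = sample_groups(rs, [42], seed=3)
    assert len(full) == len(rs)
    # determinism
    again = sample_groups(rs, [15, 20], seed=3)
    assert {r.id for r in again[0]} == ids15


def test_sample_groups_requires_cell_ids():
    rs = _reads([100, 200])
    with pytest.raises(ValueError, match="cell_id"):
        sample_groups(rs, [1], seed=0)


def test_match_length_distribution_self_target(lognormal_reads):
    hist = LengthHistogram.from_reads(lognormal_reads, 1000)
    out = match_length_distribution(lognormal_reads, hist, seed=1)
    assert len(out) == len(lognormal_reads)  # scale 1.0: the full set


def test_match_length_distribution_infeasible(lognormal_reads):
    target = LengthHistogram(1000, np.zeros(200, int), np.zeros(200, int))
    target.bases[150] = 10_000  # 150-151 kb bin: source has nothing there
    out = match_length_distribution(lognormal_reads, target, seed=1)
    assert len(out) == 0


def test_match_length_distribution_shifted_target(lognormal_reads):
    """Matching a shorter-read target reproduces its per-bin base fractions
    within 2 percentage points."""
    rng = np.random.default_rng(13)
    tgt_lengths = np.clip(rng.lognormal(8.4, 0.5, size=10_000), 500, 60_000).astype(int)
    target = LengthHistogram.from_reads(_reads(tgt_lengths), 1000)
    out = match_length_distribution(lognormal_reads, target, seed=2)
    assert out.total_bases > 0
    got = LengthHistogram.from_reads(out, 1000)
    nb = max(len(got.bases), len(target.bases))
    gf = np.zeros(nb)
    tf = np.zeros(nb)
    gf[: len(got.bases)] = got.bases / got.total_bases
    tf[: len(target.bases)] = target.bases / target.total_bases
    assert np.max(np.abs(gf - tf)) <= 0.02


def test_quality_partition_exact_split(lognormal_reads):
    low, high, rand = quality_partition(lognormal_reads, seed=4)
    ids_low = {r.id for r in low}
    ids_high = {r.id for r in high}
    assert ids_low.isdisjoint(ids_high)
    assert ids_low | ids_high == {r.id for r in lognormal_reads}
    # per length bin, low-quality reads never exceed the high half (up to
    # the single boundary read)
    by_bin = {}
    for r in lognormal_reads:
        by_bin.setdefault(r.length // 1000, []).append(r)
    for b, pool in by_bin.items():
        lo_q = [r.mean_quality for r in pool if r.id in ids_low]
        hi_q = [r.mean_quality for r in pool if r.id in ids_high]
        if lo_q and hi_q:
            assert max(lo_q) <= min(hi_q)


def test_quality_partition_base_balance_and_lengths(lognormal_reads):
    low, high, rand = quality_partition(lognormal_reads, seed=4)
    by_bin_total = {}
    for r in lognormal_reads:
        by_bin_total[r.length // 1000] = by_bin_total.get(r.length // 1000, 0) + r.length
    for part in (low, high, rand):
        by_bin = {}
        for r in part:
            by_bin[r.length // 1000] = by_bin.get(r.length // 1000, 0) + r.length
        for b, total in by_bin_total.items():
            if (b + 1) * 1000 > 0.02 * total:
                continue  # one boundary read alone could exceed the bound
            assert abs(by_bin.get(b, 0) - total / 2) <= 0.02 * total
    ks = ks_2samp([r.length for r in low], [r.length for r in high]).statistic
    assert ks <= 0.05


def test_quality_partition_requires_quality():
    rs = _reads([1000, 2000])
    with pytest.raises(ValueError, match="mean_quality"):
        quality_partition(rs, seed=0)


def test_total_bases_conserved_under_partitions(lognormal_reads):
    low, high, _ = quality_partition(lognormal_reads, seed=6)
    assert low.total_bases + high.total_bases == lognormal_reads.total_bases


def test_operators_deterministic_under_seed(lognormal_reads):
    a = quality_partition(lognormal_reads, seed=9)
    b = quality_partition(lognormal_reads, seed=9)
    for x, y in zip(a, b):
        assert [r.id for r in x] == [r.id for r in y]
    hist = LengthHistogram.from_reads(lognormal_reads, 1000)
    m1 = match_length_distribution(lognormal_reads, hist, seed=9)
    m2 = match_length_distribution(lognormal_reads, hist, seed=9)
    assert [r.id for r in m1] == [r.id for r in m2]
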