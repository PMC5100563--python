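"""Synthetic genomes, complementary assembly pairs, truth alignments and reads.

The generator emulates the situation the merge algorithm exploits:
a genome with interspersed repeat families is fragmented into two
assemblies whose gap positions are complementary — every gap of one
assembly lies well inside a contig of the other — so merging can in
principle reconstruct each replicon completely. All artifacts are pure
functions of a SimConfig (bitwise reproducible under its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .alignment import AlignmentRecord, AlignmentSet
from .io import Assembly, Contig, ReadSet, SeqRead, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic substrate.

    Defaults: one 2 Mb replicon with three interspersed repeat families
    (2 kb x 20 copies at 2% divergence, 5 kb x 8 at 1%, 500 bp x 100 at
    5%), four 10-30 kb gaps per assembly separated by >= 50 kb
    (guaranteeing complementary contiguity), error-free contigs. Read
    lengths are lognormal (median ~6.7 kb, mean ~8 kb) truncated to
    [500, 60000] bp; per-read mean phred is normal(10, 3) truncated to
    [5, 40]; reads are grouped into 42 cells.
    """

    genome_len: int = 2_000_000
    n_replicons: int = 1
    repeat_families: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(2000, 20, 0.02), (5000, 8, 0.01), (500, 100, 0.05)]
    )
    gaps_per_assembly: int = 4
    gap_len_range: tuple[int, int] = (10_000, 30_000)
    min_gap_separation: int = 50_000
    assembly_sub_rate: float = 0.0
    invert_one_acceptor_contig: bool = False
    read_log_mu: float = 8.807
    read_log_sigma: float = 0.6
    read_len_range: tuple[int, int] = (500, 60_000)
    quality_mean: float = 10.0
    quality_sd: float = 3.0
    quality_range: tuple[float, float] = (5.0, 40.0)
    n_cells: int = 42
    seed: int = 0


@dataclass
class Placement:
    """Truth placement of one assembly contig: replicon interval + strand."""

    contig_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ComplementaryPair:
    donor: Assembly
    acceptor: Assembly
    donor_placements: list[Placement]
    acceptor_placements: list[Placement]
    truth_gaps: dict[str, list[tuple[str, int, int]]]  # assembly -> (replicon, start, end)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _diverge(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently at ``rate`` (always to a different base)."""
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def simulate_genome(cfg: SimConfig) -> Assembly:
    """Uniform-background replicons with planted diverged repeat copies."""
    if cfg.genome_len < 100_000:
        raise ValueError("genome_len must be >= 100 kb per replicon")
    rng = np.random.default_rng(cfg.seed)
    contigs = []
    for rep in range(cfg.n_replicons):
        seq = _random_seq(rng, cfg.genome_len)
        total_repeat = sum(u * c for u, c, _ in cfg.repeat_families)
        if total_repeat > 0.5 * cfg.genome_len:
            raise ValueError("repeat families exceed half the replicon capacity")
        occupied: list[tuple[int, int]] = []
        for unit_len, copies, divergence in cfg.repeat_families:
            consensus = _random_seq(rng, unit_len)
            placed = 0
            attempts = 0
            while placed < copies:
                attempts += 1
                if attempts > 1000 * copies:
                    raise ValueError("could not place repeat copies without overlap")
                pos = int(rng.integers(0, cfg.genome_len - unit_len))
                if any(pos < e and pos + unit_len > s for s, e in occupied):
                    continue
                occupied.append((pos, pos + unit_len))
                seq[pos : pos + unit_len] = _diverge(rng, consensus, divergence)
                placed += 1
        contigs.append(Contig(f"replicon_{rep + 1}", seq.tobytes().decode("ascii")))
    return Assembly(contigs, role="unspecified")


def _sample_gap_intervals(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Disjoint gap intervals for the two assemblies on one replicon.

    All 2 * gaps_per_assembly gaps are mutually separated (and separated
    from the replicon ends) by >= min_gap_separation, then split randomly
    between the assemblies.
    """
    n = 2 * cfg.gaps_per_assembly
    lo, hi = cfg.gap_len_range
    sep = cfg.min_gap_separation
    lens = rng.integers(lo, hi + 1, size=n)
    free = cfg.genome_len - int(lens.sum()) - sep * (n + 1)
    if free < 0:
        raise ValueError("gaps plus separations exceed the replicon length")
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    gaps = []
    cum = 0
    for i in range(n):
        start = int(offsets[i]) + sep * (i + 1) + cum
        gaps.append((start, start + int(lens[i])))
        cum += int(lens[i])
    which = rng.permutation(n)
    donor_gaps = sorted(gaps[i] for i in which[: cfg.gaps_per_assembly])
    acceptor_gaps = sorted(gaps[i] for i in which[cfg.gaps_per_assembly :])
    return donor_gaps, acceptor_gaps


def _segments(genome_len: int, gaps: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = []
    prev = 0
    for s, e in gaps:
        if s > prev:
            segs.append((prev, s))
        prev = e
    if prev < genome_len:
        segs.append((prev, genome_len))
    return segs


def complementary_pair(truth: Assembly, cfg: SimConfig) -> ComplementaryPair:
    """Fragment a truth genome into two assemblies with complementary gaps.

    Each assembly is the truth minus its own gap intervals; contigs are
    the inter-gap segments. Optional per-contig substitutions
    (``assembly_sub_rate``) and inversion of the middle acceptor contig
    (``invert_one_acceptor_contig``) exercise noisy and minus-strand
    merging.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    donor = Assembly([], role="donor")
    acceptor = Assembly([], role="acceptor")
    donor_placements: list[Placement] = []
    acceptor_placements: list[Placement] = []
    truth_gaps: dict[str, list[tuple[str, int, int]]] = {"donor": [], "acceptor": []}
    for replicon in truth:
        if cfg.gaps_per_assembly > 0:
            d_gaps, a_gaps = _sample_gap_intervals(rng, cfg)
        else:
            d_gaps, a_gaps = [], []
        truth_gaps["donor"].extend((replicon.id, s, e) for s, e in d_gaps)
        truth_gaps["acceptor"].extend((replicon.id, s, e) for s, e in a_gaps)
        for side, gaps, asm, placements in (
            ("d", d_gaps, donor, donor_placements),
            ("a", a_gaps, acceptor, acceptor_placements),
        ):
            segs = _segments(replicon.length, gaps)
            for i, (s, e) in enumerate(segs, start=1):
                cid = f"{replicon.id}_{side}{i}"
                seq = replicon.seq[s:e]
                if cfg.assembly_sub_rate > 0:
                    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                    arr = _diverge(rng, arr, cfg.assembly_sub_rate)
                    seq = arr.tobytes().decode("ascii")
                strand = "+"
                if (
                    cfg.invert_one_acceptor_contig
                    and side == "a"
                    and i == (len(segs) + 1) // 2
                    and len(segs) > 1
                ):
                    seq = reverse_complement(seq)
                    strand = "-"
                asm.add(Contig(cid, seq, description=f"{replicon.id}:{s}-{e}:{strand}"))
                placements.append(Placement(cid, replicon.id, s, e, strand))
    return ComplementaryPair(donor, acceptor, donor_placements, acceptor_placements, truth_gaps)


def truth_alignments(pair: ComplementaryPair, identity: Optional[float] = None) -> AlignmentSet:
    """Exact alignments implied by the truth placements.

    One record per overlapping (donor, acceptor) contig pair; identity
    defaults to 1.0 for error-free simulations (pass the expected value,
    e.g. 1 - 2*sub_rate, when contigs carry substitutions).
    """
    if identity is None:
        identity = 1.0
    records = []
    donor_lens = {c.id: c.length for c in pair.donor}
    acceptor_lens = {c.id: c.length for c in pair.acceptor}
    for dp in pair.donor_placements:
        for ap in pair.acceptor_placements:
            if dp.replicon_id != ap.replicon_id:
                continue
            s = max(dp.start, ap.start)
            e = min(dp.end, ap.end)
            if e <= s:
                continue
            ref_start = s - dp.start
            ref_end = e - dp.start
            if ap.strand == "+":
                qry_start, qry_end = s - ap.start, e - ap.start
                strand = "+"
            else:
                qry_start, qry_end = ap.end - e, ap.end - s
                strand = "-"
            records.append(
                AlignmentRecord(
                    ref_id=dp.contig_id,
                    qry_id=ap.contig_id,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    qry_start=qry_start,
                    qry_end=qry_end,
                    strand=strand,
                    identity=identity,
                    ref_len=donor_lens[dp.contig_id],
                    qry_len=acceptor_lens[ap.contig_id],
                )
            )
    return AlignmentSet(records, source="truth")


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: int, hi: int, n: int
) -> np.ndarray:
    out = np.empty(0, dtype=np.int64)
    while len(out) < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - len(out)) + 16).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, draw])
    return out[:n]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = np.empty(0, dtype=np.float64)
    while len(out) < n:
        draw = rng.normal(mean, sd, size=2 * (n - len(out)) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, draw])
    return out[:n]


def simulate_reads(
    truth: Assembly, coverage: float, cfg: SimConfig, with_sequence: bool = False
) -> ReadSet:
    """Draw reads from seeded random positions until total bases reach
    coverage x genome length.

    Lengths are truncated-lognormal (clipped at the replicon end), mean
    quality truncated-normal, and cell ids are assigned in consecutive
    blocks to emulate per-cell grouping.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(cfg.seed + 2)
    genome_len = truth.total_length
    target = coverage * genome_len
    reads: list[SeqRead] = []
    total = 0
    batch = max(64, int(target / (np.exp(cfg.read_log_mu + cfg.read_log_sigma**2 / 2))))
    contigs = truth.contigs
    cum = np.cumsum([c.length for c in contigs])
    i = 0
    while total < target:
        lens = _truncated_lognormal(
            rng, cfg.read_log_mu, cfg.read_log_sigma, *cfg.read_len_range, batch
        )
        starts = rng.integers(0, genome_len, size=batch)
        quals = _truncated_normal(
            rng, cfg.quality_mean, cfg.quality_sd, *cfg.quality_range, batch
        )
        for L, g, q in zip(lens, starts, quals):
            rep_idx = int(np.searchsorted(cum, g, side="right"))
            rep = contigs[rep_idx]
            local = int(g) - (int(cum[rep_idx - 1]) if rep_idx else 0)
            L = int(min(L, rep.length - local))
            if L < cfg.read_len_range[0]:
                continue
            i += 1
            seq = rep.seq[local : local + L] if with_sequence else None
            reads.append(SeqRead(f"read_{i}", L, seq=seq, mean_quality=float(q)))
            total += L
            if total >= target:
                break
    block = max(1, (len(reads) + cfg.n_cells - 1) // cfg.n_cells)
    for j, r in enumerate(reads):
        r.cell_id = f"cell_{j // block + 1}"
    return ReadSet(reads)


# Merge parameters scaled to the default synthetic fixture: the anchor
# length cutoff follows the genome size (2 Mb here vs 1 Mb for a 130 Mb
# genome); with 4 donor gaps the largest donor contig always exceeds
# (2 Mb - 4*30 kb) / 5 = 376 kb, so 200 kb anchors are geometry-safe.
def fixture_merge_params():
    from .merge import MergeParams

    return MergeParams(anchor_len=200_000)
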