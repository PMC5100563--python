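"""Assembly contiguity statistics and splice-junction extraction.

N50 is the smallest contig length L such that contigs of length >= L
hold at least half the assembly; NG50 replaces the assembly size with a
stated genome size G (so NG50 of two 65 Mb contigs against G = 130 Mb is
65 Mb). NG statistics are undefined when the assembly is smaller than
the required fraction of G; that case is reported as 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .merge import MergedAssembly


def nx(lengths: Sequence[int], x: float = 50) -> int:
    """Nx statistic: smallest L with cumulative descending sum >= x% of total."""
    if not lengths:
        raise ValueError("nx: empty length collection")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    threshold = x / 100.0 * sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= threshold:
            return length
    return min(lengths)  # unreachable; guards float edge cases


def ngx(lengths: Sequence[int], genome_size: int, x: float = 50) -> tuple[int, bool]:
    """NGx statistic against genome size G.

    Returns (value, defined). When the total assembly is below x% of G
    the statistic is undefined and (0, False) is returned.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    threshold = x / 100.0 * genome_size
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= threshold:
            return length, True
    return 0, False


def lx(lengths: Sequence[int], x: float = 50) -> int:
    """Number of largest contigs needed to reach x% of the assembly."""
    if not lengths:
        raise ValueError("lx: empty length collection")
    threshold = x / 100.0 * sum(lengths)
    acc = 0
    for i, length in enumerate(sorted(lengths, reverse=True), start=1):
        acc += length
        if acc >= threshold:
            return i
    return len(lengths)


def lgx(lengths: Sequence[int], genome_size: int, x: float = 50) -> tuple[int, bool]:
    threshold = x / 100.0 * genome_size
    acc = 0
    for i, length in enumerate(sorted(lengths, reverse=True), start=1):
        acc += length
        if acc >= threshold:
            return i, True
    return 0, False


def coverage_fold(total_bases: float, genome_size: int) -> float:
    """Sequencing depth: total bases of data divided by genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return total_bases / genome_size


def cumulative_curve(lengths: Sequence[int]) -> list[tuple[int, int]]:
    """(rank, cumulative bp) pairs over lengths sorted descending."""
    if not lengths:
        raise ValueError("cumulative_curve: empty length collection")
    out = []
    acc = 0
    for i, length in enumerate(sorted(lengths, reverse=True), start=1):
        acc += length
        out.append((i, acc))
    return out


@dataclass
class AssemblyStats:
    n_contigs: int
    total_len: int
    max_len: int
    mean_len: float
    n50: int
    l50: int
    genome_size: Optional[int] = None
    ng50: int = 0
    ng50_defined: bool = False
    lg50: int = 0


def assembly_stats(lengths: Sequence[int], genome_size: Optional[int] = None) -> AssemblyStats:
    lengths = list(lengths)
    if not lengths:
        raise ValueError("assembly_stats: empty length collection")
    stats = AssemblyStats(
        n_contigs=len(lengths),
        total_len=sum(lengths),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        n50=nx(lengths, 50),
        l50=lx(lengths, 50),
        genome_size=genome_size,
    )
    if genome_size is not None:
        stats.ng50, stats.ng50_defined = ngx(lengths, genome_size, 50)
        stats.lg50, _ = lgx(lengths, genome_size, 50)
    return stats


@dataclass
class Junction:
    """A window around one splice joint in a merged contig.

    ``breakpoint_offset`` is 0-based: for the default 201 bp window it is
    100, i.e. the 101th base is the last base coming from the upstream
    source contig. Windows truncated by a contig end are flagged.
    """

    id: str
    out_contig: str
    position: int  # boundary position in the merged contig (0-based)
    sequence: str
    breakpoint_offset: int
    left_source: str
    right_source: str
    truncated: bool


def extract_junctions(merged: MergedAssembly, window: int = 201) -> list[Junction]:
    """Windows around every provenance boundary between different source contigs.

    The window is centered so the breakpoint falls on base (window+1)/2:
    a boundary at merged-contig position b yields the window
    [b - (window+1)//2, b - (window+1)//2 + window).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = (window + 1) // 2
    junctions: list[Junction] = []
    n = 0
    for contig in merged.assembly:
        ivs = merged.provenance[contig.id]
        for left, right in zip(ivs, ivs[1:]):
            if (left.source_asm, left.source_contig) == (
                right.source_asm,
                right.source_contig,
            ):
                continue
            b = left.out_end
            start = b - half
            end = start + window
            t_start = max(0, start)
            t_end = min(contig.length, end)
            truncated = (t_start != start) or (t_end != end)
            n += 1
            junctions.append(
                Junction(
                    id=f"junction_{n}",
                    out_contig=contig.id,
                    position=b,
                    sequence=contig.seq[t_start:t_end],
                    breakpoint_offset=b - 1 - t_start,
                    left_source=f"{left.source_asm}:{left.source_contig}",
                    right_source=f"{right.source_asm}:{right.source_contig}",
                    truncated=truncated,
                )
            )
    return junctions


def write_junction_fasta(junctions: list[Junction], path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f">{j.id} contig={j.out_contig} pos={j.position} "
                f"left={j.left_source} right={j.right_source} "
                f"breakpoint_offset={j.breakpoint_offset} truncated={int(j.truncated)}\n"
                f"{j.sequence}\n"
            )


def write_stats_tsv(stats_by_name: dict[str, AssemblyStats], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#assembly\tn_contigs\ttotal_len\tmax_len\tmean_len\tn50\tl50\t"
            "genome_size\tng50\tng50_defined\tlg50\n"
        )
        for name, s in stats_by_name.items():
            fh.write(
                f"{name}\t{s.n_contigs}\t{s.total_len}\t{s.max_len}\t{s.mean_len:.1f}\t"
                f"{s.n50}\t{s.l50}\t{s.genome_size if s.genome_size else '.'}\t"
                f"{s.ng50}\t{int(s.ng50_defined)}\t{s.lg50}\n"
            )
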