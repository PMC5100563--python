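"""Long-read downsampling operators.

Four schemes used when studying how read length, quality and coverage
shape assembly contiguity:

* ``longest_fraction`` — keep the longest reads holding a given fraction
  of total bases ("longest 50%/75%" datasets);
* ``sample_groups`` — additive random sampling of whole sequencing cells,
  so larger subsets strictly extend smaller ones;
* ``match_length_distribution`` — subsample so the binned base-length
  distribution matches a target histogram;
* ``quality_partition`` — split into low-quality / high-quality / random
  halves of equal base content while preserving the length distribution
  (stratified within length bins).

Throughout, "50% of the reads" means 50% of total bases, not read count,
and a boundary read that first crosses a base threshold is included.
All randomness flows from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ReadSet, SeqRead


@dataclass
class LengthHistogram:
    """Binned bases-per-length-bin histogram; bins contiguous from 0."""

    bin_width: int
    counts: np.ndarray  # reads per bin
    bases: np.ndarray  # total bases per bin

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bases = np.asarray(self.bases, dtype=np.int64)
        if len(self.counts) != len(self.bases):
            raise ValueError("counts and bases must have equal length")

    @property
    def total_bases(self) -> int:
        return int(self.bases.sum())

    @classmethod
    def from_reads(cls, reads: ReadSet, bin_width: int = 1000) -> "LengthHistogram":
        lengths = np.asarray(reads.lengths(), dtype=np.int64)
        if len(lengths) == 0:
            return cls(bin_width, np.zeros(1, np.int64), np.zeros(1, np.int64))
        nbins = int(lengths.max() // bin_width) + 1
        bins = lengths // bin_width
        counts = np.bincount(bins, minlength=nbins)
        bases = np.bincount(bins, weights=lengths, minlength=nbins).astype(np.int64)
        return cls(bin_width, counts, bases)

    @classmethod
    def from_tsv(cls, path, bin_width: int = 1000) -> "LengthHistogram":
        """Two-column TSV: bin_start, bases (lines starting '#' ignored)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start_s, bases_s = line.split("\t")[:2]
                entries.append((int(start_s), int(float(bases_s))))
        if not entries:
            raise ValueError(f"{path}: empty histogram")
        nbins = max(s for s, _ in entries) // bin_width + 1
        bases = np.zeros(nbins, dtype=np.int64)
        for start, b in entries:
            if start % bin_width:
                raise ValueError(f"{path}: bin start {start} not a multiple of {bin_width}")
            bases[start // bin_width] += b
        return cls(bin_width, np.zeros(nbins, np.int64), bases)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#bin_start\tbases\n")
            for i, b in enumerate(self.bases):
                fh.write(f"{i * self.bin_width}\t{int(b)}\n")


def _sorted_reads(reads: ReadSet) -> list[SeqRead]:
    return sorted(reads, key=lambda r: (-r.length, r.id))


def longest_fraction(reads: ReadSet, fraction: float) -> ReadSet:
    """Keep the longest reads holding >= ``fraction`` of total bases.

    Reads are taken longest-first (ties by id) until the cumulative base
    count first reaches the threshold; the boundary read is included.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(reads) == 0:
        raise ValueError("longest_fraction: empty read set")
    threshold = fraction * reads.total_bases
    kept: list[SeqRead] = []
    acc = 0
    for r in _sorted_reads(reads):
        kept.append(r)
        acc += r.length
        if acc >= threshold:
            break
    return ReadSet(kept)


def sample_groups(reads: ReadSet, sizes: Sequence[int], seed: int) -> list[ReadSet]:
    """Additive random sampling of whole cells.

    Draws a seeded random order of the distinct cell ids once; the subset
    for each requested size is the reads of the first ``size`` cells in
    that order, so every larger subset extends the smaller ones (nested
    by construction).
    """
    cells = sorted({r.cell_id for r in reads if r.cell_id is not None})
    missing = [r.id for r in reads if r.cell_id is None]
    if missing:
        raise ValueError(f"reads without cell_id (first: {missing[0]!r})")
    for size in sizes:
        if not 0 < size <= len(cells):
            raise ValueError(f"group size {size} outside [1, {len(cells)}]")
    rng = np.random.default_rng(seed)
    order = [cells[i] for i in rng.permutation(len(cells))]
    out = []
    for size in sizes:
        chosen = set(order[:size])
        out.append(ReadSet([r for r in reads if r.cell_id in chosen]))
    return out


def match_length_distribution(
    reads: ReadSet, target: LengthHistogram, seed: int
) -> ReadSet:
    """Subsample so per-bin base proportions match the target histogram.

    The output size is the largest total for which every target bin can
    be filled from the source (bins the source lacks entirely are dropped
    from the scaling with a warning-by-omission: the rest of the shape is
    preserved). Within each bin, reads are drawn in seeded random order
    until the bin's base quota is first reached.
    """
    if target.total_bases == 0:
        raise ValueError("empty target histogram")
    source = LengthHistogram.from_reads(reads, target.bin_width)
    nbins = max(len(source.bases), len(target.bases))
    src = np.zeros(nbins, dtype=np.float64)
    tgt = np.zeros(nbins, dtype=np.float64)
    src[: len(source.bases)] = source.bases
    tgt[: len(target.bases)] = target.bases
    frac = tgt / tgt.sum()
    feasible = (frac > 0) & (src > 0)
    if not feasible.any():
        return ReadSet([])
    scale = float(np.min(src[feasible] / frac[feasible]))
    quota = frac * scale  # bases wanted per bin; zero where source lacks the bin
    quota[~feasible] = 0.0
    rng = np.random.default_rng(seed)
    by_bin: dict[int, list[SeqRead]] = {}
    for r in sorted(reads, key=lambda r: r.id):
        by_bin.setdefault(r.length // target.bin_width, []).append(r)
    kept: list[SeqRead] = []
    for b in sorted(by_bin):
        want = quota[b] if b < nbins else 0.0
        if want <= 0:
            continue
        pool = by_bin[b]
        order = rng.permutation(len(pool))
        acc = 0
        for i in order:
            kept.append(pool[i])
            acc += pool[i].length
            if acc >= want:
                break
    return ReadSet(kept)


def quality_partition(
    reads: ReadSet, bin_width: int = 1000, seed: int = 0
) -> tuple[ReadSet, ReadSet, ReadSet]:
    """Split reads into (low-quality, high-quality, random) halves.

    Within each length bin, reads sorted by mean quality are taken bottom
    up until half the bin's bases (boundary read included) — those are the
    low half; the rest are the high half; a third, independent seeded
    draw takes ~half the bin's bases at random. Stratifying within bins
    preserves the length distribution of every output by construction;
    low and high are an exact partition of the input.
    """
    for r in reads:
        if r.mean_quality is None:
            raise ValueError(f"read {r.id!r} lacks mean_quality")
    rng = np.random.default_rng(seed)
    by_bin: dict[int, list[SeqRead]] = {}
    for r in sorted(reads, key=lambda r: r.id):
        by_bin.setdefault(r.length // bin_width, []).append(r)
    low: list[SeqRead] = []
    high: list[SeqRead] = []
    rand: list[SeqRead] = []
    for b in sorted(by_bin):
        pool = by_bin[b]
        total = sum(r.length for r in pool)
        half = total / 2
        acc = 0
        cut = len(pool)
        ordered = sorted(pool, key=lambda r: (r.mean_quality, r.id))
        for i, r in enumerate(ordered):
            acc += r.length
            if acc >= half:
                cut = i + 1
                break
        low.extend(ordered[:cut])
        high.extend(ordered[cut:])
        acc = 0
        for i in rng.permutation(len(pool)):
            if acc >= half:
                break
            rand.append(pool[i])
            acc += pool[i].length
    return ReadSet(low), ReadSet(high), ReadSet(rand)
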