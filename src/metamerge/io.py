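"""Sequence containers and FASTA/FASTQ input/output.

Coordinates everywhere in this package are 0-based, half-open; the format
readers and writers convert at the boundary. Sequences are uppercased on
input and restricted to the alphabet {A, C, G, T, N}; anything else is
mapped to N with a counted warning.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_CLEAN_TABLE = {c: c for c in "ACGTN"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class Contig:
    """A named, gapless nucleotide sequence — the unit being merged."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of contigs with unique ids."""

    contigs: list[Contig] = field(default_factory=list)
    role: str = "unspecified"  # donor | acceptor | unspecified

    def __post_init__(self) -> None:
        self._index = {}
        for c in self.contigs:
            if c.id in self._index:
                raise ValueError(f"duplicate contig id {c.id!r}")
            self._index[c.id] = c

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._index

    def __getitem__(self, contig_id: str) -> Contig:
        return self._index[contig_id]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def lengths(self) -> list[int]:
        return [c.length for c in self.contigs]

    def add(self, contig: Contig) -> None:
        if contig.id in self._index:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self.contigs.append(contig)
        self._index[contig.id] = contig


@dataclass
class SeqRead:
    """A single long read; sequence and quality are optional.

    ``mean_quality`` is the mean per-base phred score (0-93). ``cell_id``
    is an opaque grouping label emulating the sequencing cell the read
    came from, used by grouped downsampling.
    """

    id: str
    length: int
    seq: Optional[str] = None
    mean_quality: Optional[float] = None
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"read {self.id!r}: length must be >= 1")
        if self.seq is not None and len(self.seq) != self.length:
            raise ValueError(f"read {self.id!r}: |seq| != length")
        if self.mean_quality is not None and not 0 <= self.mean_quality <= 93:
            raise ValueError(f"read {self.id!r}: mean_quality outside [0, 93]")


@dataclass
class ReadSet:
    """A collection of reads; ``total_bases`` is conserved under any partition."""

    reads: list[SeqRead] = field(default_factory=list)

    def __iter__(self) -> Iterator[SeqRead]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.reads)

    def lengths(self) -> list[int]:
        return [r.length for r in self.reads]


def clean_sequence(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and map characters outside {A,C,G,T,N} to N.

    Returns the cleaned sequence and the number of substituted characters.
    """
    up = raw.upper()
    if set(up) <= _ALPHABET:
        return up, 0
    cleaned = "".join(c if c in _ALPHABET else "N" for c in up)
    n_bad = sum(1 for c in up if c not in _ALPHABET)
    return cleaned, n_bad


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; raises on other characters."""
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"reverse_complement: characters outside ACGTN: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path, role: str = "unspecified") -> Assembly:
    """Read a (possibly gzipped) FASTA file into an Assembly.

    The record id is the header token before the first whitespace; the
    remainder is kept as an opaque description. Non-ACGTN characters are
    mapped to N; the substitution count is logged as a warning.
    """
    contigs: list[Contig] = []
    n_bad_total = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq, n_bad = clean_sequence(str(rec.seq))
            n_bad_total += n_bad
            contigs.append(Contig(rec.id, seq, description=rec.description))
    if n_bad_total:
        logger.warning("%s: mapped %d non-ACGTN characters to N", path, n_bad_total)
    if not contigs:
        logger.warning("%s: no FASTA records found", path)
    return Assembly(contigs, role=role)


def write_fasta(assembly: Assembly, path, line_width: int = 80) -> None:
    """Write an Assembly as FASTA, wrapping sequence at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with _open_text(path, "wt") as fh:
        for contig in assembly:
            header = contig.id
            desc = contig.description
            if desc and desc != contig.id:
                # SeqIO-style description includes the id; strip it.
                if desc.startswith(contig.id + " "):
                    desc = desc[len(contig.id) + 1 :]
                    header = f"{contig.id} {desc}"
                elif desc != contig.id:
                    header = f"{contig.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, contig.length, line_width):
                fh.write(contig.seq[i : i + line_width] + "\n")


def read_reads(path, fmt: Optional[str] = None) -> ReadSet:
    """Read a FASTA or FASTQ file (optionally gzipped) into a ReadSet.

    ``fmt`` is "fasta" or "fastq"; when omitted it is guessed from the
    file name. FASTQ records get ``mean_quality`` = mean per-base phred.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {fmt!r}")
    reads: list[SeqRead] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                seq, _ = clean_sequence(str(rec.seq))
                mq = None
                if fmt == "fastq":
                    quals = rec.letter_annotations["phred_quality"]
                    mq = float(sum(quals)) / len(quals) if quals else 0.0
                reads.append(SeqRead(rec.id, len(seq), seq=seq, mean_quality=mq))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    return ReadSet(reads)


def write_reads(readset: ReadSet, path, fmt: str = "fasta") -> None:
    """Write reads as FASTA or FASTQ (quality = flat per-read mean, rounded)."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {fmt!r}")
    with _open_text(path, "wt") as fh:
        for r in readset:
            if r.seq is None:
                raise ValueError(f"read {r.id!r} has no sequence to write")
            if fmt == "fasta":
                fh.write(f">{r.id}\n{r.seq}\n")
            else:
                q = int(round(r.mean_quality)) if r.mean_quality is not None else 0
                q = min(max(q, 0), 93)
                fh.write(f"@{r.id}\n{r.seq}\n+\n{chr(q + 33) * r.length}\n")
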