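"""Pairwise local alignments between two assemblies.

Covers parsing of MUMmer ``show-coords -T -r -c -l`` tab output and
``delta`` files, a one-to-one repeat filter equivalent in intent to
``delta-filter -r -q``, and a built-in unique-k-mer anchor aligner so the
merge pipeline runs without any external aligner.

Query coordinates are always stored forward-normalized with a strand
flag; all internal coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Assembly

logger = logging.getLogger(__name__)


@dataclass
class AlignmentRecord:
    """One local alignment between a reference (donor) and query (acceptor) contig.

    ``qry_start``/``qry_end`` are on the query contig in forward
    orientation regardless of strand; ``strand`` is the orientation of
    the query relative to the reference.
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str  # "+" or "-"
    identity: float  # fraction in (0, 1]
    ref_len: int
    qry_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end <= self.ref_len):
            raise ValueError(
                f"{self.ref_id}/{self.qry_id}: bad reference interval "
                f"[{self.ref_start},{self.ref_end}) on length {self.ref_len}"
            )
        if not (0 <= self.qry_start < self.qry_end <= self.qry_len):
            raise ValueError(
                f"{self.ref_id}/{self.qry_id}: bad query interval "
                f"[{self.qry_start},{self.qry_end}) on length {self.qry_len}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 < self.identity <= 1:
            raise ValueError(f"identity {self.identity} outside (0,1]")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def weight(self) -> float:
        """Filter/scoring weight: aligned reference length times identity."""
        return self.ref_span * self.identity

    @property
    def layout_offset(self) -> int:
        """Start of the (oriented) query contig on the reference axis implied
        by this alignment alone."""
        if self.strand == "+":
            return self.ref_start - self.qry_start
        return self.ref_start - (self.qry_len - self.qry_end)


@dataclass
class AlignmentSet:
    records: list[AlignmentRecord] = field(default_factory=list)
    source: str = "unspecified"  # coords | delta | builtin | truth

    def __post_init__(self) -> None:
        self._check_lengths()

    def _check_lengths(self) -> None:
        ref_lens: dict[str, int] = {}
        qry_lens: dict[str, int] = {}
        for r in self.records:
            for table, key, val in ((ref_lens, r.ref_id, r.ref_len), (qry_lens, r.qry_id, r.qry_len)):
                if key in table and table[key] != val:
                    raise ValueError(
                        f"inconsistent length for contig {key!r}: {table[key]} vs {val}"
                    )
                table[key] = val

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# MUMmer format parsing

_COORDS_HEADER_LINES = 4


def parse_coords(path) -> AlignmentSet:
    """Parse MUMmer ``show-coords -T -r -c -l`` tab output.

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ [COVR COVQ] REFTAG QRYTAG,
    1-based inclusive. S2 > E2 encodes a minus-strand alignment and is
    forward-normalized here.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= _COORDS_HEADER_LINES or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) not in (11, 13):
            raise ValueError(
                f"{path}:{lineno}: expected 11 or 13 tab-separated columns, got {len(fields)}"
            )
        try:
            s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
            idy = float(fields[6])
            ref_len = int(fields[7])
            qry_len = int(fields[8])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate field ({exc})") from exc
        ref_tag, qry_tag = fields[-2], fields[-1]
        if not ref_tag or not qry_tag:
            raise ValueError(f"{path}:{lineno}: missing contig tag columns")
        if s2 <= e2:
            strand, qs, qe = "+", s2 - 1, e2
        else:
            strand, qs, qe = "-", e2 - 1, s2
        records.append(
            AlignmentRecord(
                ref_id=ref_tag,
                qry_id=qry_tag,
                ref_start=s1 - 1,
                ref_end=e1,
                qry_start=qs,
                qry_end=qe,
                strand=strand,
                identity=idy / 100.0,
                ref_len=ref_len,
                qry_len=qry_len,
            )
        )
    return AlignmentSet(records, source="coords")


def write_coords(alns: AlignmentSet, path) -> None:
    """Write an AlignmentSet in the show-coords -T -r -c -l tab dialect."""
    with open(path, "w") as fh:
        fh.write("metamerge alignment interchange\nNUCMER\n\n")
        fh.write(
            "[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[LEN R]\t[LEN Q]\t"
            "[COV R]\t[COV Q]\t[TAGS]\n"
        )
        for r in alns:
            if r.strand == "+":
                s2, e2 = r.qry_start + 1, r.qry_end
            else:
                s2, e2 = r.qry_end, r.qry_start + 1
            cov_r = 100.0 * r.ref_span / r.ref_len
            cov_q = 100.0 * r.qry_span / r.qry_len
            fh.write(
                f"{r.ref_start + 1}\t{r.ref_end}\t{s2}\t{e2}\t{r.ref_span}\t{r.qry_span}\t"
                f"{100.0 * r.identity:.2f}\t{r.ref_len}\t{r.qry_len}\t"
                f"{cov_r:.2f}\t{cov_q:.2f}\t{r.ref_id}\t{r.qry_id}\n"
            )


def parse_delta(path) -> AlignmentSet:
    """Parse a NUCMER delta file.

    Identity is computed as 1 - errors / max(ref span, qry span) — a
    conservative, deterministic estimate; per-alignment indel offsets are
    consumed and validated (the terminating 0 is required) but not stored.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        tokens_by_line = [ln.rstrip("\n") for ln in fh]
    if len(tokens_by_line) < 2:
        raise ValueError(f"{path}: truncated delta file")
    # line 0: input paths; line 1: program (NUCMER/PROMER)
    i = 2
    ref_id = qry_id = None
    ref_len = qry_len = 0
    lengths: dict[str, int] = {}
    n = len(tokens_by_line)
    while i < n:
        line = tokens_by_line[i].strip()
        if not line:
            i += 1
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed block header {line!r}")
            ref_id, qry_id = parts[0], parts[1]
            ref_len, qry_len = int(parts[2]), int(parts[3])
            for key, val in ((ref_id, ref_len), (qry_id, qry_len)):
                if key in lengths and lengths[key] != val:
                    raise ValueError(
                        f"{path}: contig {key!r} has mismatched lengths across blocks"
                    )
                lengths[key] = val
            i += 1
            continue
        if ref_id is None:
            raise ValueError(f"{path}: alignment record before any block header")
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}: malformed alignment record {line!r}")
        rs, re_, qs, qe, errs, _simerrs, _stops = (int(x) for x in parts)
        # consume indel offsets until the terminating 0
        i += 1
        terminated = False
        while i < n:
            tok = tokens_by_line[i].strip()
            i += 1
            if tok == "0":
                terminated = True
                break
            if not tok.lstrip("-").isdigit():
                raise ValueError(f"{path}: non-integer delta offset {tok!r}")
        if not terminated:
            raise ValueError(f"{path}: alignment record missing terminating 0")
        if qs <= qe:
            strand, q0, q1 = "+", qs - 1, qe
        else:
            strand, q0, q1 = "-", qe - 1, qs
        span = max(re_ - rs + 1, q1 - q0)
        identity = 1.0 - errs / span
        records.append(
            AlignmentRecord(
                ref_id=ref_id,
                qry_id=qry_id,
                ref_start=rs - 1,
                ref_end=re_,
                qry_start=q0,
                qry_end=q1,
                strand=strand,
                identity=identity,
                ref_len=ref_len,
                qry_len=qry_len,
            )
        )
    return AlignmentSet(records, source="delta")


# ---------------------------------------------------------------------------
# One-to-one repeat filtering (delta-filter -r -q equivalent in effect)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _conflicts(a: AlignmentRecord, b: AlignmentRecord, tol: float) -> bool:
    if a.ref_id == b.ref_id:
        ov = _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end)
        if ov > tol * min(a.ref_span, b.ref_span):
            return True
    if a.qry_id == b.qry_id:
        ov = _overlap(a.qry_start, a.qry_end, b.qry_start, b.qry_end)
        if ov > tol * min(a.qry_span, b.qry_span):
            return True
    return False


def _exact_mwis(weights: list[float], adj: list[set[int]]) -> list[int]:
    """Exact maximum-weight independent set by branch and bound.

    Vertices are branched in decreasing weight order; the bound is the
    sum of remaining weights. Intended for small conflict components.
    """
    order = sorted(range(len(weights)), key=lambda i: -weights[i])
    best_weight = -1.0
    best_set: list[int] = []
    suffix = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + weights[order[i]]

    def recurse(pos: int, chosen: list[int], blocked: set[int], total: float) -> None:
        nonlocal best_weight, best_set
        if total + suffix[pos] <= best_weight:
            return
        if pos == len(order):
            if total > best_weight:
                best_weight = total
                best_set = list(chosen)
            return
        v = order[pos]
        if v not in blocked:
            chosen.append(v)
            recurse(pos + 1, chosen, blocked | adj[v], total + weights[v])
            chosen.pop()
        recurse(pos + 1, chosen, blocked, total)

    recurse(0, [], set(), 0.0)
    return best_set


def _greedy_mwis(weights: list[float], adj: list[set[int]]) -> list[int]:
    chosen: list[int] = []
    blocked: set[int] = set()
    for v in sorted(range(len(weights)), key=lambda i: -weights[i]):
        if v not in blocked:
            chosen.append(v)
            blocked |= adj[v]
    return chosen


def one_to_one_filter(
    alns: AlignmentSet, overlap_tol: float = 0.1, exact_limit: int = 20
) -> AlignmentSet:
    """Reduce an alignment set to its best one-to-one tiling.

    Two alignments conflict when they overlap by more than ``overlap_tol``
    of the shorter one on a shared reference contig or on a shared query
    contig. The filter keeps the conflict-free subset maximizing total
    (aligned length x identity): exact branch-and-bound on conflict
    components of up to ``exact_limit`` alignments, greedy-by-weight on
    larger ones. Idempotent; removes the multi-placements that genome
    repeats and duplications induce.
    """
    records = sorted(
        alns.records,
        key=lambda r: (r.ref_id, r.ref_start, r.ref_end, r.qry_id, r.qry_start, r.strand),
    )
    n = len(records)
    if n == 0:
        return AlignmentSet([], source=alns.source)
    # Conflict graph; candidate pairs share a ref or qry contig.
    adj: list[set[int]] = [set() for _ in range(n)]
    by_contig: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        by_contig.setdefault(("r", r.ref_id), []).append(i)
        by_contig.setdefault(("q", r.qry_id), []).append(i)
    seen_pairs: set[tuple[int, int]] = set()
    for members in by_contig.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if (i, j) in seen_pairs:
                    continue
                seen_pairs.add((i, j))
                if _conflicts(records[i], records[j], overlap_tol):
                    adj[i].add(j)
                    adj[j].add(i)
    # Connected components of the conflict graph.
    comp = [-1] * n
    n_comp = 0
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = n_comp
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if comp[w] < 0:
                    comp[w] = n_comp
                    stack.append(w)
        n_comp += 1
    kept: list[AlignmentRecord] = []
    for c in range(n_comp):
        members = [i for i in range(n) if comp[i] == c]
        if len(members) == 1:
            kept.append(records[members[0]])
            continue
        local = {g: l for l, g in enumerate(members)}
        weights = [records[g].weight for g in members]
        ladj = [set(local[w] for w in adj[g] if w in local) for g in members]
        if len(members) <= exact_limit:
            sol = _exact_mwis(weights, ladj)
        else:
            sol = _greedy_mwis(weights, ladj)
        kept.extend(records[members[l]] for l in sorted(sol))
    kept.sort(key=lambda r: (r.ref_id, r.ref_start, r.qry_id, r.qry_start))
    return AlignmentSet(kept, source=alns.source)


# ---------------------------------------------------------------------------
# Built-in unique-k-mer anchor aligner

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed k-mer integers for every window, plus a validity mask
    (windows containing N are invalid). Exact for k <= 31."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        vals = vals * 4 + codes[j : j + n].astype(np.int64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return vals, valid


def _assembly_kmers(
    assembly: Assembly, k: int, both_strands: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(values, contig_index, forward_position, strand_code) over all contigs.

    strand_code 0 = forward scan, 1 = reverse-complement scan; for the rc
    scan, positions are already converted to forward coordinates of the
    k-mer's first base.
    """
    vals_l, ci_l, pos_l, st_l = [], [], [], []
    from .io import reverse_complement

    for idx, contig in enumerate(assembly):
        scans = [(0, contig.seq)]
        if both_strands:
            scans.append((1, reverse_complement(contig.seq)))
        for strand_code, seq in scans:
            codes = _encode(seq)
            vals, valid = _kmer_values(codes, k)
            pos = np.nonzero(valid)[0]
            if strand_code == 1:
                pos_fwd = contig.length - k - pos
            else:
                pos_fwd = pos
            vals_l.append(vals[pos])
            ci_l.append(np.full(len(pos), idx, dtype=np.int64))
            pos_l.append(pos_fwd.astype(np.int64))
            st_l.append(np.full(len(pos), strand_code, dtype=np.int8))
    if not vals_l:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), e.copy(), np.empty(0, dtype=np.int8)
    return (
        np.concatenate(vals_l),
        np.concatenate(ci_l),
        np.concatenate(pos_l),
        np.concatenate(st_l),
    )


def _unique_entries(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Entries whose value occurs exactly once in ``vals``.

    Returns (sorted unique values, their indices into ``vals``)."""
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    is_new = np.concatenate(([True], sv[1:] != sv[:-1]))
    group_id = np.cumsum(is_new) - 1
    counts = np.bincount(group_id)
    uniq_sorted = counts[group_id] == 1
    return sv[uniq_sorted], order[uniq_sorted]


def builtin_align(
    donor: Assembly,
    acceptor: Assembly,
    k: int = 21,
    min_chain: int = 1000,
    max_gap: int = 2000,
    diag_band: int = 50,
) -> AlignmentSet:
    """Anchor-based whole-assembly aligner using k-mers unique in both
    assemblies (both strands of the acceptor).

    Collinear consistent anchors per contig pair and strand are chained
    with gap tolerance ``max_gap`` and diagonal drift ``diag_band``; each
    chain becomes one AlignmentRecord spanning its anchors, with identity
    estimated as anchored bases / chain span. Chains whose reference span
    is below ``min_chain`` are discarded.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 11 <= k <= 31:
        raise ValueError("k must be in [11, 31]")
    d_vals, d_ci, d_pos, _ = _assembly_kmers(donor, k, both_strands=False)
    a_vals, a_ci, a_pos, a_st = _assembly_kmers(acceptor, k, both_strands=True)
    if len(d_vals) == 0 or len(a_vals) == 0:
        return AlignmentSet([], source="builtin")
    d_vals_s, d_idx = _unique_entries(d_vals)
    a_vals_s, a_idx = _unique_entries(a_vals)
    if len(d_vals_s) == 0 or len(a_vals_s) == 0:
        return AlignmentSet([], source="builtin")
    idx = np.searchsorted(d_vals_s, a_vals_s)
    idx_clip = np.minimum(idx, len(d_vals_s) - 1)
    hit_rows = np.nonzero(d_vals_s[idx_clip] == a_vals_s)[0]
    a_hit = a_idx[hit_rows]
    d_hit = d_idx[idx_clip[hit_rows]]
    if len(a_hit) == 0:
        return AlignmentSet([], source="builtin")
    # Anchor table: donor contig, donor pos, acceptor contig, acceptor fwd pos, strand
    dc = d_ci[d_hit]
    dp = d_pos[d_hit]
    ac = a_ci[a_hit]
    ap = a_pos[a_hit]
    st = a_st[a_hit].astype(np.int64)
    # diagonal: constant along a gapless collinear run
    diag = np.where(st == 0, dp - ap, dp + ap)
    # one composite sort key: (pair+strand group, diagonal, reference position)
    group = (dc * (len(acceptor.contigs) + 1) + ac) * 2 + st
    span = np.int64(1) << np.int64(23)  # |diag|, dp < 2^22 after offsetting
    max_coord = max(
        int(dp.max()), int(np.abs(diag).max()), 1
    )
    if max_coord < (1 << 22) and int(group.max()) < (1 << 17):
        key = (group * span + (diag + (span >> 1))) * span + dp
        order = np.argsort(key, kind="stable")
    else:  # contigs too long for the packed key; fall back to lexsort
        order = np.lexsort((dp, diag, st, ac, dc))
    dc, dp, ac, ap, st, diag = (arr[order] for arr in (dc, dp, ac, ap, st, diag))

    records: list[AlignmentRecord] = []
    donor_contigs = donor.contigs
    acceptor_contigs = acceptor.contigs

    def emit(i0: int, i1: int) -> None:
        """Emit one chain covering anchor rows [i0, i1)."""
        ref_c = donor_contigs[dc[i0]]
        qry_c = acceptor_contigs[ac[i0]]
        rp = np.sort(dp[i0:i1])
        qp = ap[i0:i1]
        ref_s = int(rp[0])
        ref_e = int(rp[-1]) + k
        if ref_e - ref_s < min_chain:
            return
        qry_s = int(qp.min())
        qry_e = int(qp.max()) + k
        # anchored bases: union of k-length windows on the reference
        starts = rp.astype(np.int64)
        gaps = np.maximum(0, starts[1:] - starts[:-1] - k)
        anchored = (ref_e - ref_s) - int(gaps.sum())
        identity = min(1.0, anchored / (ref_e - ref_s))
        records.append(
            AlignmentRecord(
                ref_id=ref_c.id,
                qry_id=qry_c.id,
                ref_start=ref_s,
                ref_end=ref_e,
                qry_start=qry_s,
                qry_end=qry_e,
                strand="+" if st[i0] == 0 else "-",
                identity=identity,
                ref_len=ref_c.length,
                qry_len=qry_c.length,
            )
        )

    n = len(dc)
    breaks = (
        (dc[1:] != dc[:-1])
        | (ac[1:] != ac[:-1])
        | (st[1:] != st[:-1])
        | (np.abs(diag[1:] - diag[:-1]) > diag_band)
        | (dp[1:] - dp[:-1] > max_gap)
    )
    bounds = np.concatenate(([0], np.nonzero(breaks)[0] + 1, [n]))
    for g in range(len(bounds) - 1):
        emit(int(bounds[g]), int(bounds[g + 1]))
    return AlignmentSet(records, source="builtin")
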