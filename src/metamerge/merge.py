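"""Assembly merging via HCO-scored contig overlaps.

The high-confidence-overlap (HCO) score of a contig pair is the ratio of
overlapping-aligned to overlapping-unaligned bases under the layout
implied by their pooled one-to-one alignments. Pairs above an HCO cutoff
form the edges of a bipartite contig graph (donor contigs vs acceptor
contigs); long donor contigs with a strong edge seed greedy walks to the
left and right, and each resulting chain is spliced into one merged
contig, preferentially retaining donor sequence across every junction.
Every output base carries provenance back to a unique source base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .alignment import AlignmentRecord, AlignmentSet, one_to_one_filter
from .io import Assembly, Contig, reverse_complement

logger = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"


@dataclass
class MergeParams:
    """Tunables of the merge algorithm.

    hco_cutoff: minimum HCO for a pair to become a graph edge (flag "hco").
    anchor_hco: minimum edge HCO for a donor contig to seed a walk ("c").
    anchor_len: minimum donor contig length, bp, for anchoring ("l");
        scale with genome size (1 Mb suits a ~130 Mb genome, 5 Mb a human
        genome, proportionally less for small test genomes).
    min_overlap_span: minimum co-extension, bp, for a pair to be an edge.
    end_tol: slack, bp, when classifying which contig end an overlap sits on.
    containment_frac: aligned fraction of the contained contig required to
        call containment.
    """

    hco_cutoff: float = 1.5
    anchor_hco: float = 5.0
    anchor_len: int = 1_000_000
    min_overlap_span: int = 5_000
    end_tol: int = 100
    containment_frac: float = 0.95
    tie_break: str = "hco_then_length"

    def __post_init__(self) -> None:
        if not self.hco_cutoff > 0:
            raise ValueError("hco_cutoff must be > 0")
        if self.anchor_hco < self.hco_cutoff:
            raise ValueError("anchor_hco must be >= hco_cutoff")
        if self.anchor_len <= 0:
            raise ValueError("anchor_len must be > 0")
        if self.tie_break != "hco_then_length":
            raise ValueError("only the hco_then_length tie break is defined")


# end_class values
REF_LEFT = "ref_left"  # overlap at the reference's left end (query extends left)
REF_RIGHT = "ref_right"  # overlap at the reference's right end (query extends right)
CONTAIN_R_Q = "containment_ref_contains_qry"
CONTAIN_Q_R = "containment_qry_contains_ref"
INTERNAL = "internal"

_DOVETAILS = (REF_LEFT, REF_RIGHT)


@dataclass
class OverlapPair:
    """A contig pair with its pooled alignments and HCO score — a graph edge.

    ``layout_offset`` places the (oriented) query contig on the reference
    axis; the overlap span O is the co-extension of the two contigs under
    that layout, A is the aligned union clipped to the overlap, U = O - A,
    and hco = A / max(U, 1).
    """

    ref_id: str
    qry_id: str
    orientation: str
    alignments: list[AlignmentRecord]
    ref_len: int
    qry_len: int
    layout_offset: int
    overlap_span: int
    aligned_len: int
    unaligned_len: int
    hco: float
    end_class: str


def _weighted_median(values: list[int], weights: list[float]) -> int:
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(weights)
    acc = 0.0
    for i in order:
        acc += weights[i]
        if acc >= total / 2:
            return values[i]
    return values[order[-1]]


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def score_overlaps(alns: AlignmentSet, params: MergeParams) -> list[OverlapPair]:
    """Pool alignments per (ref, qry, orientation) and score each pair.

    The layout offset is the weight-median of per-alignment offsets
    (weight = aligned length x identity); O is measured on the reference
    axis. The end class records which contig extends past which end, or
    containment when one contig's projection lies wholly inside the other
    with at least ``containment_frac`` of its length aligned.
    """
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for rec in alns:
        groups.setdefault((rec.ref_id, rec.qry_id, rec.strand), []).append(rec)
    pairs: list[OverlapPair] = []
    for (ref_id, qry_id, strand), recs in sorted(groups.items()):
        ref_len = recs[0].ref_len
        qry_len = recs[0].qry_len
        offsets = [r.layout_offset for r in recs]
        weights = [r.weight for r in recs]
        off = _weighted_median(offsets, weights)
        lo = max(0, off)
        hi = min(ref_len, off + qry_len)
        overlap = max(0, hi - lo)
        clipped = [
            (max(r.ref_start, lo), min(r.ref_end, hi)) for r in recs
        ]
        aligned = _interval_union_length(clipped)
        unaligned = overlap - aligned
        hco = aligned / max(unaligned, 1)
        end_class = _classify(
            off, ref_len, qry_len, aligned, params.end_tol, params.containment_frac
        )
        pairs.append(
            OverlapPair(
                ref_id=ref_id,
                qry_id=qry_id,
                orientation=strand,
                alignments=recs,
                ref_len=ref_len,
                qry_len=qry_len,
                layout_offset=off,
                overlap_span=overlap,
                aligned_len=aligned,
                unaligned_len=unaligned,
                hco=hco,
                end_class=end_class,
            )
        )
    return pairs


def _classify(
    off: int, ref_len: int, qry_len: int, aligned: int, tol: int, contain_frac: float
) -> str:
    left_ext = -off  # how far the query extends left of the reference start
    right_ext = off + qry_len - ref_len  # ... right of the reference end
    if left_ext <= tol and right_ext <= tol:
        # query projection inside the reference (flush ends allowed)
        if aligned >= contain_frac * qry_len:
            return CONTAIN_R_Q
        return INTERNAL
    if (
        left_ext >= -tol
        and right_ext >= -tol
        and aligned >= contain_frac * ref_len
    ):
        return CONTAIN_Q_R
    ext_l = left_ext > tol
    ext_r = right_ext > tol
    if ext_l and ext_r:
        return INTERNAL  # sticks out both sides without confident containment
    if ext_l:
        return REF_LEFT
    if ext_r:
        return REF_RIGHT
    return INTERNAL


# ---------------------------------------------------------------------------
# Contig graph


@dataclass
class ContigGraph:
    """Bipartite overlap graph: donor contigs vs acceptor contigs.

    ``edges`` hold dovetail pairs passing the HCO and span thresholds;
    containment pairs are recorded separately and never walked.
    Node keys are (side, contig_id) with side "donor" or "acceptor".
    """

    edges: list[OverlapPair] = field(default_factory=list)
    containments: list[OverlapPair] = field(default_factory=list)
    adjacency: dict[tuple[str, str], list[OverlapPair]] = field(default_factory=dict)
    anchors: list[str] = field(default_factory=list)  # donor contig ids
    donor_lengths: dict[str, int] = field(default_factory=dict)
    qry_lengths: dict[str, int] = field(default_factory=dict)


def build_graph(pairs: list[OverlapPair], params: MergeParams) -> ContigGraph:
    """Threshold scored pairs into a graph and flag anchor nodes.

    A donor contig is an anchor when its length exceeds ``anchor_len``
    and it has at least one dovetail edge with hco > ``anchor_hco``.
    """
    g = ContigGraph()
    anchor_set: set[str] = set()
    for p in pairs:
        g.donor_lengths[p.ref_id] = p.ref_len
        g.qry_lengths[p.qry_id] = p.qry_len
        if p.end_class in (CONTAIN_R_Q, CONTAIN_Q_R):
            g.containments.append(p)
            continue
        if p.end_class == INTERNAL:
            continue
        if p.hco < params.hco_cutoff or p.overlap_span < params.min_overlap_span:
            continue
        g.edges.append(p)
        g.adjacency.setdefault((DONOR, p.ref_id), []).append(p)
        g.adjacency.setdefault((ACCEPTOR, p.qry_id), []).append(p)
        if p.ref_len > params.anchor_len and p.hco > params.anchor_hco:
            anchor_set.add(p.ref_id)
    g.anchors = sorted(anchor_set, key=lambda cid: (-g.donor_lengths[cid], cid))
    return g


# ---------------------------------------------------------------------------
# Greedy path extension


@dataclass
class ChainEntry:
    side: str  # donor | acceptor
    contig_id: str
    orient: str  # orientation in path coordinates
    path_start: int
    length: int

    @property
    def path_end(self) -> int:
        return self.path_start + self.length

    @property
    def node(self) -> tuple[str, str]:
        return (self.side, self.contig_id)


@dataclass
class MergePath:
    anchor_id: str
    entries: list[ChainEntry]  # sorted by path_start
    edges: list[OverlapPair]


def _partner_block(edge: OverlapPair, at_ref: bool) -> tuple[int, int]:
    """Interval of the partner contig in the current contig's forward
    coordinates, under the edge layout."""
    off, lr, lq = edge.layout_offset, edge.ref_len, edge.qry_len
    if at_ref:
        return off, off + lq
    if edge.orientation == "+":
        return -off, -off + lr
    return lq + off - lr, lq + off


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def extend_paths(graph: ContigGraph, params: MergeParams) -> list[MergePath]:
    """Walk greedily left and right from each anchor.

    Anchors are processed longest first. At each step the walk considers
    unused neighbors whose overlap extends past the current contig's
    exposed end, preferring highest HCO, then longest contig, then id.
    Every chained contig (anchor included) is marked used globally, so no
    contig appears in two paths.
    """
    used: set[tuple[str, str]] = set()
    paths: list[MergePath] = []
    for anchor_id in graph.anchors:
        node = (DONOR, anchor_id)
        if node in used:
            continue
        used.add(node)
        anchor_entry = ChainEntry(DONOR, anchor_id, "+", 0, graph.donor_lengths[anchor_id])
        entries = [anchor_entry]
        edges_used: list[OverlapPair] = []
        for direction in ("right", "left"):
            cur = anchor_entry
            while True:
                step = _best_step(graph, cur, direction, used, params)
                if step is None:
                    break
                entry, edge = step
                used.add(entry.node)
                entries.append(entry)
                edges_used.append(edge)
                cur = entry
        entries.sort(key=lambda e: (e.path_start, e.contig_id))
        base = entries[0].path_start
        for e in entries:
            e.path_start -= base
        paths.append(MergePath(anchor_id=anchor_id, entries=entries, edges=edges_used))
    return paths


def _best_step(
    graph: ContigGraph,
    cur: ChainEntry,
    direction: str,
    used: set[tuple[str, str]],
    params: MergeParams,
) -> Optional[tuple[ChainEntry, OverlapPair]]:
    # exposed end of the current contig in its own forward coordinates
    fwd_dir = direction if cur.orient == "+" else ("left" if direction == "right" else "right")
    candidates = []
    for edge in graph.adjacency.get(cur.node, []):
        at_ref = cur.side == DONOR
        partner_side = ACCEPTOR if at_ref else DONOR
        partner_id = edge.qry_id if at_ref else edge.ref_id
        partner_node = (partner_side, partner_id)
        if partner_node in used:
            continue
        b0, b1 = _partner_block(edge, at_ref)
        cur_len = cur.length
        if fwd_dir == "right":
            if b1 <= cur_len + params.end_tol:
                continue
        else:
            if b0 >= -params.end_tol:
                continue
        partner_len = edge.qry_len if at_ref else edge.ref_len
        candidates.append((edge, partner_node, partner_len, (b0, b1)))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0].hco, -c[2], c[1]))
    edge, (partner_side, partner_id), partner_len, (b0, b1) = candidates[0]
    # convert the partner block from current-forward to path coordinates
    if cur.orient == "+":
        p0 = cur.path_start + b0
    else:
        p0 = cur.path_start + cur.length - b1
    partner_orient = edge.orientation if cur.orient == "+" else _flip(edge.orientation)
    entry = ChainEntry(partner_side, partner_id, partner_orient, p0, partner_len)
    return entry, edge


# ---------------------------------------------------------------------------
# Splicing


@dataclass
class ProvenanceInterval:
    out_start: int
    out_end: int
    source_asm: str  # donor | acceptor
    source_contig: str
    source_start: int
    source_end: int
    strand: str


@dataclass
class SplicedContig:
    seq: str
    provenance: list[ProvenanceInterval]
    splices: list[tuple[str, str, int, int]]  # (left id, right id, cut on left, cut on right)
    entries: list[ChainEntry]


def splice(path: MergePath, donor: Assembly, acceptor: Assembly) -> list[SplicedContig]:
    """Splice a chain into merged contig(s).

    The cut at each junction sits at the boundary of the overlap such
    that every disputed base is taken from the donor-assembly member of
    the pair. A junction whose layout implies a gap (the next contig
    starts after the current one ends) splits the path there with a
    warning instead of forcing a join. Returns one SplicedContig per
    resulting piece.
    """
    pieces: list[list[ChainEntry]] = [[]]
    for entry in path.entries:
        if pieces[-1] and entry.path_start > pieces[-1][-1].path_end:
            logger.warning(
                "path %s: inconsistent layout between %s and %s; splitting",
                path.anchor_id,
                pieces[-1][-1].contig_id,
                entry.contig_id,
            )
            pieces.append([])
        pieces[-1].append(entry)
    out: list[SplicedContig] = []
    for piece in pieces:
        out.append(_splice_piece(piece, donor, acceptor))
    return out


def _source_assembly(side: str, donor: Assembly, acceptor: Assembly) -> Assembly:
    return donor if side == DONOR else acceptor


def _splice_piece(
    entries: list[ChainEntry], donor: Assembly, acceptor: Assembly
) -> SplicedContig:
    cuts: list[int] = []
    prev_cut = entries[0].path_start
    splices: list[tuple[str, str, int, int]] = []
    for left, right in zip(entries, entries[1:]):
        if left.side == DONOR:
            cut = left.path_end
        else:
            cut = right.path_start
        cut = max(cut, prev_cut)
        cut = min(cut, right.path_end)
        cuts.append(cut)
        prev_cut = cut
    bounds = [entries[0].path_start] + cuts + [entries[-1].path_end]
    seq_parts: list[str] = []
    provenance: list[ProvenanceInterval] = []
    out_pos = 0
    for i, entry in enumerate(entries):
        a, b = bounds[i], bounds[i + 1]
        a = max(a, entry.path_start)
        b = min(b, entry.path_end)
        if b <= a:
            continue
        src = _source_assembly(entry.side, donor, acceptor)[entry.contig_id]
        if entry.orient == "+":
            s0 = a - entry.path_start
            s1 = b - entry.path_start
            segment = src.seq[s0:s1]
        else:
            s0 = entry.path_start + entry.length - b
            s1 = entry.path_start + entry.length - a
            segment = reverse_complement(src.seq[s0:s1])
        seq_parts.append(segment)
        provenance.append(
            ProvenanceInterval(
                out_start=out_pos,
                out_end=out_pos + (b - a),
                source_asm=entry.side,
                source_contig=entry.contig_id,
                source_start=s0,
                source_end=s1,
                strand=entry.orient,
            )
        )
        out_pos += b - a
    for i, (left, right) in enumerate(zip(entries, entries[1:])):
        cut = cuts[i]

        def to_fwd(entry: ChainEntry, pathpos: int) -> int:
            if entry.orient == "+":
                return pathpos - entry.path_start
            return entry.path_start + entry.length - pathpos

        splices.append(
            (left.contig_id, right.contig_id, to_fwd(left, cut), to_fwd(right, cut))
        )
    return SplicedContig(
        seq="".join(seq_parts), provenance=provenance, splices=splices, entries=entries
    )


# ---------------------------------------------------------------------------
# Containment removal and the full pipeline


def contained_acceptor_ids(graph: ContigGraph) -> dict[str, str]:
    """Acceptor contigs wholly contained in a donor contig.

    Returns {acceptor contig id: containing donor contig id}.
    """
    out: dict[str, str] = {}
    for p in graph.containments:
        if p.end_class == CONTAIN_R_Q and p.qry_id not in out:
            out[p.qry_id] = p.ref_id
    return out


def remove_contained(graph: ContigGraph, acceptor: Assembly) -> Assembly:
    """Acceptor assembly minus contigs contained within donor contigs."""
    removed = contained_acceptor_ids(graph)
    kept = [c for c in acceptor if c.id not in removed]
    return Assembly(list(kept), role=acceptor.role)


@dataclass
class MergedAssembly:
    assembly: Assembly
    provenance: dict[str, list[ProvenanceInterval]]
    paths: list[MergePath]
    report: dict


def merge_assemblies(
    donor: Assembly,
    acceptor: Assembly,
    alns: AlignmentSet,
    params: Optional[MergeParams] = None,
    prefilter: bool = True,
) -> MergedAssembly:
    """Run the full merge pipeline.

    one-to-one filter -> overlap scoring -> graph -> greedy paths ->
    splicing; unused acceptor contigs pass through, minus those contained
    in donor contigs. A contained acceptor contig whose containing donor
    contig is not in any path is replaced by that donor contig (emitted
    once), so containment removal never loses sequence content.
    Deterministic for fixed inputs and parameters.
    """
    if params is None:
        params = MergeParams()
    if len(alns) == 0:
        logger.warning("empty alignment set: output is the acceptor assembly unchanged")
        prov = {
            c.id: [ProvenanceInterval(0, c.length, ACCEPTOR, c.id, 0, c.length, "+")]
            for c in acceptor
        }
        report = _report(0, 0, 0, len(acceptor), 0)
        return MergedAssembly(
            Assembly([Contig(c.id, c.seq, c.description) for c in acceptor], role="merged"),
            prov,
            [],
            report,
        )
    filtered = one_to_one_filter(alns) if prefilter else alns
    pairs = score_overlaps(filtered, params)
    graph = build_graph(pairs, params)
    paths = extend_paths(graph, params)

    out = Assembly([], role="merged")
    provenance: dict[str, list[ProvenanceInterval]] = {}
    used: set[tuple[str, str]] = set()
    n_splices = 0
    n_merged = 0
    kept_paths: list[MergePath] = []
    for path in paths:
        for e in path.entries:
            used.add(e.node)
        if len(path.entries) < 2:
            continue  # nothing spliced; content stays in pass-through
        kept_paths.append(path)
        for piece in splice(path, donor, acceptor):
            if len(piece.entries) < 2:
                continue
            n_merged += 1
            name = f"merged_{n_merged}"
            out.add(Contig(name, piece.seq))
            provenance[name] = piece.provenance
            n_splices += len(piece.splices)

    contained = contained_acceptor_ids(graph)
    existing = {c.id for c in out}

    def unique_name(base: str) -> str:
        name = base
        i = 1
        while name in existing:
            i += 1
            name = f"{base}_{i}"
        existing.add(name)
        return name

    # containment substitution: keep the donor copy when it is not already
    # represented in a path
    n_substituted = 0
    emitted_donors: set[str] = set()
    for c in acceptor:
        if c.id not in contained or (ACCEPTOR, c.id) in used:
            continue
        donor_id = contained[c.id]
        if (DONOR, donor_id) in used or donor_id in emitted_donors:
            continue
        emitted_donors.add(donor_id)
        n_substituted += 1
        src = donor[donor_id]
        name = unique_name(donor_id)
        out.add(Contig(name, src.seq))
        provenance[name] = [
            ProvenanceInterval(0, src.length, DONOR, donor_id, 0, src.length, "+")
        ]

    n_removed = 0
    n_pass = 0
    for c in acceptor:
        if (ACCEPTOR, c.id) in used:
            continue
        if c.id in contained:
            n_removed += 1
            continue
        n_pass += 1
        name = unique_name(c.id)
        out.add(Contig(name, c.seq))
        provenance[name] = [
            ProvenanceInterval(0, c.length, ACCEPTOR, c.id, 0, c.length, "+")
        ]

    report = _report(len(kept_paths), n_splices, n_removed, n_pass, n_substituted)
    return MergedAssembly(out, provenance, kept_paths, report)


def _report(n_paths, n_splices, n_contained, n_pass, n_substituted) -> dict:
    return {
        "paths": n_paths,
        "splices": n_splices,
        "contained_removed": n_contained,
        "pass_through": n_pass,
        "containment_substituted": n_substituted,
    }


def write_provenance(merged: MergedAssembly, path) -> None:
    """BED-like TSV: out_contig, out_start, out_end, source_asm,
    source_contig, source_start, source_end, strand (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(
            "#out_contig\tout_start\tout_end\tsource_asm\tsource_contig\t"
            "source_start\tsource_end\tstrand\n"
        )
        for contig in merged.assembly:
            for iv in merged.provenance[contig.id]:
                fh.write(
                    f"{contig.id}\t{iv.out_start}\t{iv.out_end}\t{iv.source_asm}\t"
                    f"{iv.source_contig}\t{iv.source_start}\t{iv.source_end}\t{iv.strand}\n"
                )
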