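"""Paired-end scaffolding over a contig graph.

Reads are aligned back to the contigs (seed-and-extend, ungapped).
Edges between oriented contig ends come from splints (single reads
whose alignment bridges two contig ends) and spans (read pairs whose
mates align to different contigs); each edge carries a support count
and a gap estimate. The graph is traversed from the longest contig
down, resolving forks by searching for a unique nearby vertex whose
depth matches the running walk depth — which is what lets a walk step
across a short high-depth repeat and come out the other side — with
fallbacks to much longer alignments or much better-supported edges.
Conflicting paths are resolved speculatively (a path is discarded when
a longer path claims one of its vertices, and orphaned vertices are
re-walked), gaps are filled by a consensus vote walk over the edge's
own reads, and the whole procedure repeats for a configured number of
rounds, each round trading a contiguity gain for a small error risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .config import AssemblyConfig
from .contigs import Contig
from .io import Read
from .sequtils import revcomp

End = Tuple[int, str]  # (contig id, "L" | "R")


@dataclass
class ReadAlignment:
    """Ungapped alignment of a read interval onto a contig.

    ``read_start``/``read_end`` are in forward-read coordinates
    regardless of ``orient``; contig coordinates are 0-based half-open.
    """

    read_id: str
    contig_id: int
    contig_start: int
    contig_end: int
    read_start: int
    read_end: int
    orient: str  # "fwd" | "rc"
    matches: int
    pair_id: str = ""
    mate: str = "unpaired"


@dataclass
class ContigEdge:
    """A splint/span-derived link between two oriented contig ends."""

    end_a: End
    end_b: End
    kind: str  # "splint" | "span" | "both"
    support: int
    gap: float
    gap_sd: float
    read_ids: List[str] = field(default_factory=list)
    mean_aln_len: float = 0.0

    def other(self, end: End) -> End:
        return self.end_b if end == self.end_a else self.end_a


@dataclass
class ScaffoldPath:
    """Ordered, oriented contig walk with per-junction gap estimates."""

    steps: List[Tuple[int, str]]  # (contig id, "+" | "-")
    gaps: List[float]
    edges: List[ContigEdge]
    total_bp: int = 0
    walk_depth: float = 0.0
    seed_rank: int = 0


@dataclass
class Scaffold:
    id: str
    sequence: str
    path: ScaffoldPath
    depth: float


class ContigGraph:
    """Vertices are contigs; edges link oriented contig ends."""

    def __init__(self, contigs: Iterable[Contig], edges: Iterable[ContigEdge]):
        self.contigs: Dict[int, Contig] = {c.id: c for c in contigs}
        self.edges: List[ContigEdge] = list(edges)
        self.adjacency: Dict[End, List[ContigEdge]] = {}
        for e in self.edges:
            self.adjacency.setdefault(e.end_a, []).append(e)
            self.adjacency.setdefault(e.end_b, []).append(e)


# ---------------------------------------------------------------------------
# read-to-contig alignment


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def align_reads_to_contigs(
    reads: Iterable[Read],
    contigs: Iterable[Contig],
    seed_len: int,
    max_mismatches: int = 2,
    max_hits_per_seed: int = 50,
) -> List[ReadAlignment]:
    """Seed-and-extend ungapped alignment of reads against contigs.

    At most two alignments are reported per read — the best one, plus
    the best alignment covering a mostly disjoint read interval (to
    permit splints). Ties break deterministically by (contig id,
    position).
    """
    contigs = list(contigs)
    index: Dict[str, List[Tuple[int, int]]] = {}
    for c in contigs:
        seq = c.sequence
        for p in range(0, len(seq) - seed_len + 1):
            key = seq[p : p + seed_len]
            hits = index.setdefault(key, [])
            if len(hits) < max_hits_per_seed:
                hits.append((c.id, p))
    by_id = {c.id: c for c in contigs}

    out: List[ReadAlignment] = []
    stride = max(1, seed_len // 2)
    for read in reads:
        rl = len(read.sequence)
        if rl < seed_len:
            continue
        cand: Dict[Tuple[int, int, str], None] = {}
        for orient in ("fwd", "rc"):
            r = read.sequence if orient == "fwd" else revcomp(read.sequence)
            positions = list(range(0, rl - seed_len + 1, stride))
            if positions[-1] != rl - seed_len:
                positions.append(rl - seed_len)
            for rp in positions:
                for cid, p in index.get(r[rp : rp + seed_len], ()):
                    cand[(cid, p - rp, orient)] = None
        alns: List[ReadAlignment] = []
        for cid, diag, orient in cand:
            contig = by_id[cid]
            t = contig.sequence
            r = read.sequence if orient == "fwd" else revcomp(read.sequence)
            r0 = max(0, -diag)
            r1 = min(rl, len(t) - diag)
            if r1 - r0 < seed_len:
                continue
            mm = _count_mismatches(r[r0:r1], t[diag + r0 : diag + r1], max_mismatches)
            if mm > max_mismatches:
                continue
            if orient == "fwd":
                rs, re = r0, r1
            else:
                rs, re = rl - r1, rl - r0
            alns.append(
                ReadAlignment(
                    read_id=read.id,
                    contig_id=cid,
                    contig_start=diag + r0,
                    contig_end=diag + r1,
                    read_start=rs,
                    read_end=re,
                    orient=orient,
                    matches=(r1 - r0) - mm,
                    pair_id=read.pair_id,
                    mate=read.mate,
                )
            )
        if not alns:
            continue
        alns.sort(key=lambda a: (-a.matches, a.contig_id, a.contig_start, a.orient))
        best = alns[0]
        out.append(best)
        for a in alns[1:]:
            new = max(0, a.read_end - a.read_start
                      - _interval_overlap(a, best))
            if new >= seed_len:
                out.append(a)
                break
    return out


def _interval_overlap(a: ReadAlignment, b: ReadAlignment) -> int:
    return max(
        0, min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
    )


# ---------------------------------------------------------------------------
# edge construction


def _exit_end_and_tail(a: ReadAlignment, contig_len: int) -> Tuple[str, int]:
    """Contig end through which the read continues rightward (in forward
    read coordinates) past this alignment, and the contig tail beyond
    the alignment in that direction."""
    if a.orient == "fwd":
        return "R", contig_len - a.contig_end
    return "L", a.contig_start


def _entry_end_and_tail(a: ReadAlignment, contig_len: int) -> Tuple[str, int]:
    """Contig end through which the read enters this alignment, coming
    from lower forward-read coordinates."""
    if a.orient == "fwd":
        return "L", a.contig_start
    return "R", contig_len - a.contig_end


def _outer_tail(a: ReadAlignment, contig_len: int) -> Tuple[str, int]:
    """For a span mate: the linking contig end (the one the rest of the
    fragment lies beyond) and the distance from the mate's outermost
    (5') base to that end."""
    if a.orient == "fwd":
        start = a.contig_start - a.read_start  # projected read base 0
        return "R", contig_len - start
    return "L", a.contig_end + a.read_start


def build_edges(
    alignments: List[ReadAlignment],
    contigs: Iterable[Contig],
    insert_mu: float,
    insert_sigma: float,
    min_edge_support: int,
) -> List[ContigEdge]:
    """Aggregate splint and span observations into contig-graph edges.

    Per oriented end pair: support is the number of distinct
    reads/pairs, the gap estimate is the mean of the per-observation
    estimates (negative = overlap) and gap_sd their sample SD. Span
    pairs whose geometry would require an overlap larger than 3 sigma
    (gap < -3 sigma) are discarded as chimeric, as are edges with
    support below ``min_edge_support``.
    """
    lens = {c.id: len(c.sequence) for c in contigs}
    obs: Dict[Tuple[End, End], List[Tuple[float, str, str, int]]] = {}

    def record(e1: End, e2: End, gap: float, kind: str, rid: str, alen: int):
        key = (e1, e2) if e1 <= e2 else (e2, e1)
        obs.setdefault(key, []).append((gap, kind, rid, alen))

    by_read: Dict[str, List[ReadAlignment]] = {}
    by_pair: Dict[str, Dict[str, ReadAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)

    # splints: one read, two contigs
    for rid in sorted(by_read):
        alns = by_read[rid]
        if len(alns) == 2 and alns[0].contig_id != alns[1].contig_id:
            a1, a2 = sorted(alns, key=lambda a: a.read_start)
            exit_side, tail1 = _exit_end_and_tail(a1, lens[a1.contig_id])
            entry_side, tail2 = _entry_end_and_tail(a2, lens[a2.contig_id])
            gap = (a2.read_start - a1.read_end) - tail1 - tail2
            record(
                (a1.contig_id, exit_side),
                (a2.contig_id, entry_side),
                float(gap),
                "splint",
                rid,
                min(a1.matches, a2.matches),
            )
        best = max(alns, key=lambda a: a.matches)
        if best.mate in ("R1", "R2"):
            by_pair.setdefault(best.pair_id, {})[best.mate] = best

    # spans: two mates, two contigs
    for pid in sorted(by_pair):
        mates = by_pair[pid]
        if "R1" not in mates or "R2" not in mates:
            continue
        a1, a2 = mates["R1"], mates["R2"]
        if a1.contig_id == a2.contig_id:
            continue
        side1, tail1 = _outer_tail(a1, lens[a1.contig_id])
        side2, tail2 = _outer_tail(a2, lens[a2.contig_id])
        gap = insert_mu - (tail1 + tail2)
        if gap < -3.0 * insert_sigma:
            continue  # geometrically implausible; likely chimeric
        record(
            (a1.contig_id, side1),
            (a2.contig_id, side2),
            float(gap),
            "span",
            pid,
            min(a1.matches, a2.matches),
        )

    edges: List[ContigEdge] = []
    for (e1, e2) in sorted(obs):
        rows = obs[(e1, e2)]
        ids = sorted({rid for _g, _k, rid, _l in rows})
        if len(ids) < min_edge_support:
            continue
        gaps = [g for g, _k, _r, _l in rows]
        mean = sum(gaps) / len(gaps)
        if len(gaps) > 1:
            sd = math.sqrt(sum((g - mean) ** 2 for g in gaps) / (len(gaps) - 1))
        else:
            sd = 0.0
        kinds = {k for _g, k, _r, _l in rows}
        edges.append(
            ContigEdge(
                end_a=e1,
                end_b=e2,
                kind="both" if len(kinds) > 1 else kinds.pop(),
                support=len(ids),
                gap=mean,
                gap_sd=sd,
                read_ids=ids,
                mean_aln_len=sum(l for _g, _k, _r, l in rows) / len(rows),
            )
        )
    return edges


# ---------------------------------------------------------------------------
# traversal


def _reachable_depth_match(
    graph: ContigGraph,
    start_end: End,
    walk_depth: float,
    ratio: float,
    max_edges: int,
    exclude: set,
) -> bool:
    """Bounded DFS from an entry end: does any vertex within
    ``max_edges`` edges have depth within ``ratio`` of ``walk_depth``?"""

    def similar(d: float) -> bool:
        lo, hi = min(d, walk_depth), max(d, walk_depth)
        return lo > 0 and hi / lo <= ratio

    stack = [(start_end, 0)]
    seen = set()
    while stack:
        (cid, side), depth_used = stack.pop()
        if cid in seen:
            continue
        seen.add(cid)
        if cid not in exclude and similar(graph.contigs[cid].depth):
            return True
        if depth_used >= max_edges:
            continue
        out_end = (cid, "R" if side == "L" else "L")
        for e in graph.adjacency.get(out_end, ()):
            nxt = e.other(out_end)
            stack.append((nxt, depth_used + 1))
    return False


def resolve_fork(
    graph: ContigGraph,
    path: ScaffoldPath,
    fork_end: End,
    fork_search_depth: int,
    depth_similarity_ratio: float,
    candidates: Optional[List[ContigEdge]] = None,
) -> Optional[ContigEdge]:
    """Pick one edge out of a fork, or None to terminate the walk.

    An edge wins if it alone leads (within ``fork_search_depth`` edges)
    to a vertex whose depth is within ``depth_similarity_ratio`` of the
    running walk depth. If that is ambiguous, an edge with supporting
    alignments at least twice as long as every rival's wins; failing
    that, an edge with at least twice every rival's support wins.
    """
    if candidates is None:
        candidates = list(graph.adjacency.get(fork_end, ()))
    if len(candidates) < 2:
        raise ValueError("resolve_fork requires >= 2 candidate edges")
    in_path = {cid for cid, _o in path.steps}
    winners = [
        e
        for e in candidates
        if _reachable_depth_match(
            graph,
            e.other(fork_end),
            path.walk_depth,
            depth_similarity_ratio,
            fork_search_depth,
            in_path,
        )
    ]
    if len(winners) == 1:
        return winners[0]
    for key in (lambda e: e.mean_aln_len, lambda e: e.support):
        ranked = sorted(candidates, key=key, reverse=True)
        if len(ranked) > 1 and key(ranked[0]) >= 2 * key(ranked[1]) > 0:
            return ranked[0]
    return None


def _walk_one_direction(
    graph: ContigGraph,
    path_steps: List[Tuple[int, str]],
    gaps: List[float],
    edges: List[ContigEdge],
    allowed: set,
    config: AssemblyConfig,
    state: ScaffoldPath,
) -> None:
    """Extend the path rightward in place."""
    while True:
        cid, orient = path_steps[-1]
        exit_end = (cid, "R" if orient == "+" else "L")
        in_path = {c for c, _o in path_steps}
        cands = [
            e
            for e in graph.adjacency.get(exit_end, ())
            if e.other(exit_end)[0] in allowed
            and e.other(exit_end)[0] not in in_path
        ]
        if not cands:
            return
        state.steps = path_steps
        if len(cands) == 1:
            edge = cands[0]
        else:
            edge = resolve_fork(
                graph,
                state,
                exit_end,
                config.fork_search_depth,
                config.depth_similarity_ratio,
                candidates=cands,
            )
            if edge is None:
                return
        nxt_cid, nxt_side = edge.other(exit_end)
        nxt_orient = "+" if nxt_side == "L" else "-"
        path_steps.append((nxt_cid, nxt_orient))
        gaps.append(edge.gap)
        edges.append(edge)
        c = graph.contigs[nxt_cid]
        state.total_bp += len(c)
        tot_before = state.total_bp - len(c)
        state.walk_depth = (
            state.walk_depth * tot_before + c.depth * len(c)
        ) / state.total_bp


def _walk_path(
    graph: ContigGraph, seed: int, allowed: set, config: AssemblyConfig, rank: int
) -> ScaffoldPath:
    c = graph.contigs[seed]
    state = ScaffoldPath(
        steps=[(seed, "+")],
        gaps=[],
        edges=[],
        total_bp=len(c),
        walk_depth=c.depth,
        seed_rank=rank,
    )
    _walk_one_direction(
        graph, state.steps, state.gaps, state.edges, allowed, config, state
    )
    # walk the other direction by reversing the path
    state.steps = [(cid, "-" if o == "+" else "+") for cid, o in state.steps[::-1]]
    state.gaps = state.gaps[::-1]
    state.edges = state.edges[::-1]
    _walk_one_direction(
        graph, state.steps, state.gaps, state.edges, allowed, config, state
    )
    return state


def traverse(graph: ContigGraph, config: AssemblyConfig) -> List[ScaffoldPath]:
    """Seed walks from every contig, longest first, and resolve path
    conflicts speculatively until every contig is in exactly one path."""
    remaining = set(graph.contigs)
    accepted: List[ScaffoldPath] = []
    while remaining:
        order = sorted(
            remaining, key=lambda cid: (-len(graph.contigs[cid]), cid)
        )
        paths = [
            _walk_path(graph, seed, remaining, config, rank)
            for rank, seed in enumerate(order)
        ]
        paths.sort(key=lambda p: (-p.total_bp, p.seed_rank))
        claimed: set = set()
        for p in paths:
            cids = {cid for cid, _o in p.steps}
            if cids & claimed:
                continue  # discarded: a longer path owns one of its vertices
            accepted.append(p)
            claimed |= cids
        remaining -= claimed
    return accepted


# ---------------------------------------------------------------------------
# gap closing


def _orient_seq(contig: Contig, orient: str) -> str:
    return contig.sequence if orient == "+" else revcomp(contig.sequence)


def _try_overlap_merge(
    left: str, right: str, gap: float, min_overlap: int, sigma: float
) -> Optional[str]:
    """Merge a negative-gap junction by exact end overlap (<= 1 mismatch),
    preferring the overlap length closest to the estimate."""
    max_olap = min(len(left), len(right), int(-gap + 3 * sigma) + 1)
    lengths = sorted(
        range(min_overlap, max_olap + 1), key=lambda L: (abs(L + gap), L)
    )
    for L in lengths:
        if _count_mismatches(left[-L:], right[:L], 1) <= 1:
            return left + right[L:]
    return None


def _gap_vote_walk(
    left: str,
    right: str,
    gap: float,
    support_reads: List[Read],
    qual_floor: int,
    seed_len: int,
    sigma: float,
    min_votes: int = 2,
    anchor: int = 15,
) -> Optional[str]:
    """Walk from the left end toward the right contig using only the
    edge's supporting reads; success means reaching a ``seed_len``-mer
    of the right contig's leading region."""
    m = min(seed_len, len(right))
    search_to = min(len(right), int(max(gap, 0) + 3 * sigma) + m + 50)
    window = right[:search_to]
    seqs = []
    for r in support_reads:
        seqs.append((r.sequence, r.quals))
        seqs.append((revcomp(r.sequence), list(r.quals[::-1])))
    work = left
    max_steps = int(max(gap, 0) + 3 * sigma) + 50
    for _ in range(max_steps + 1):
        idx = window.find(work[-m:])
        if idx != -1:
            return work + right[idx + m :]
        a = work[-anchor:]
        votes: Dict[str, int] = {}
        for seq, quals in seqs:
            start = 0
            while True:
                j = seq.find(a, start)
                if j == -1:
                    break
                nxt = j + anchor
                if nxt < len(seq) and quals[nxt] >= qual_floor:
                    votes[seq[nxt]] = votes.get(seq[nxt], 0) + 1
                start = j + 1
        winners = [b for b, v in votes.items() if v >= min_votes]
        if len(winners) != 1:
            return None
        work += winners[0]
    return None


def close_gaps(
    path: ScaffoldPath,
    contigs_by_id: Dict[int, Contig],
    reads_by_id: Dict[str, Read],
    pair_index: Dict[str, List[str]],
    qual_floor: int,
    config: AssemblyConfig,
    min_overlap: Optional[int] = None,
    scaffold_id: str = "scaffold_0",
) -> Scaffold:
    """Render a path into sequence, filling gaps where the edge's own
    reads support a consensus walk and N-padding otherwise."""
    if min_overlap is None:
        min_overlap = config.k_list[-1] - 1
    first_cid, first_orient = path.steps[0]
    seq = _orient_seq(contigs_by_id[first_cid], first_orient)
    for i, (cid, orient) in enumerate(path.steps[1:]):
        right = _orient_seq(contigs_by_id[cid], orient)
        gap = path.gaps[i]
        edge = path.edges[i]
        support_reads: List[Read] = []
        seen = set()
        for rid in edge.read_ids:
            for mate_id in pair_index.get(rid, [rid]):
                if mate_id in reads_by_id and mate_id not in seen:
                    seen.add(mate_id)
                    support_reads.append(reads_by_id[mate_id])
        merged = None
        if gap < 0:
            merged = _try_overlap_merge(
                seq, right, gap, min_overlap, config.insert_sigma
            )
            if merged is None:
                merged = seq + "N" + right
        else:
            merged = _gap_vote_walk(
                seq,
                right,
                gap,
                support_reads,
                qual_floor,
                config.seed_len,
                config.insert_sigma,
            )
            if merged is None:
                merged = seq + "N" * max(1, round(gap)) + right
        seq = merged
    total = sum(len(contigs_by_id[cid]) for cid, _o in path.steps)
    depth = (
        sum(
            contigs_by_id[cid].depth * len(contigs_by_id[cid])
            for cid, _o in path.steps
        )
        / total
    )
    return Scaffold(id=scaffold_id, sequence=seq, path=path, depth=depth)


def scaffold_rounds(
    contigs: List[Contig],
    reads: List[Read],
    config: AssemblyConfig,
) -> List[Scaffold]:
    """Full scaffolding: align, build edges, traverse, close gaps, and
    feed the scaffolds back in as contigs for ``scaffold_rounds`` rounds."""
    reads = list(reads)
    reads_by_id = {r.id: r for r in reads}
    pair_index: Dict[str, List[str]] = {}
    for r in reads:
        if r.mate in ("R1", "R2"):
            pair_index.setdefault(r.pair_id, []).append(r.id)
    # edge.read_ids holds read ids for splints and pair ids for spans;
    # map either to the full list of reads of the pair
    pair_of: Dict[str, List[str]] = dict(pair_index)
    for ids in pair_index.values():
        for rid in ids:
            pair_of[rid] = ids

    current = list(contigs)
    scaffolds: List[Scaffold] = []
    for _round in range(config.scaffold_rounds):
        alignments = align_reads_to_contigs(reads, current, config.seed_len)
        edges = build_edges(
            alignments,
            current,
            config.insert_mu,
            config.insert_sigma,
            config.min_edge_support,
        )
        graph = ContigGraph(current, edges)
        paths = traverse(graph, config)
        by_id = {c.id: c for c in current}
        scaffolds = []
        for n, p in enumerate(
            sorted(paths, key=lambda p: (-p.total_bp, p.seed_rank))
        ):
            scaffolds.append(
                close_gaps(
                    p,
                    by_id,
                    reads_by_id,
                    pair_of,
                    config.qual_floor,
                    config,
                    scaffold_id=f"scaffold_{n}",
                )
            )
        k = config.k_list[-1]
        current = [
            Contig(
                id=n,
                sequence=s.sequence,
                depth=s.depth,
                kmer_count=max(1, len(s.sequence) - k + 1),
            )
            for n, s in enumerate(scaffolds)
        ]
    return scaffolds
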