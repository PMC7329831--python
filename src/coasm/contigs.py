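"""De Bruijn traversal into contigs, and contig-graph refinement.

Traversal seeds from every unused k-mer in deterministic (lexicographic)
order and extends bidirectionally. At each step the single-base
extension must be the unique one whose count reaches the adaptive
threshold t_hq(c) = max(floor, ceil(alpha*c)), where c is the count of
the k-mer being extended — higher-coverage k-mers demand stronger
evidence, which lets both high- and low-coverage genomes assemble
without a single static cutoff. A traversal stops at a fork (two or
more qualifying extensions), a deadend (none), or an already-used
k-mer, so every table k-mer ends up in exactly one contig.

The refinement stage works on an explicit unitig graph whose junctions
are the (k-1)-base interfaces at forks: bubbles (short parallel paths
between the same two junctions) are merged into the deeper branch,
hairs (short low-depth dead ends) are clipped, and fork branches whose
depth is discordant with their neighbours are disconnected; unbranched
chains are then re-concatenated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .kmers import DEADEND, FORK, KmerTable
from .sequtils import revcomp

_B2I = {65: 0, 67: 1, 71: 2, 84: 3}
_I2B = b"ACGT"
_COMPI = (3, 2, 1, 0)


@dataclass
class ThresholdPolicy:
    """Adaptive extension threshold t_hq(c) = max(floor, ceil(alpha*c))."""

    alpha: float = 0.1
    floor: int = 2


def adaptive_threshold(count: int, policy: ThresholdPolicy) -> int:
    if count < 1:
        raise ValueError("count must be >= 1")
    return max(policy.floor, math.ceil(policy.alpha * count))


@dataclass
class EndInfo:
    """Why a traversal stopped at one contig end.

    ``status`` is "fork", "deadend" or "used". For forks,
    ``fork_bases`` lists the qualifying outward extension bases when
    the contig is oriented with this end rightmost.
    """

    status: str
    fork_bases: Tuple[str, ...] = ()


@dataclass
class Contig:
    id: int
    sequence: str
    depth: float
    kmer_count: int
    left_info: Optional[EndInfo] = None
    right_info: Optional[EndInfo] = None

    def __len__(self) -> int:
        return len(self.sequence)


def _oriented_right_exts(table: KmerTable, cur: bytes) -> Tuple[int, List[int]]:
    """(count, 4 extension counts) to the right of ``cur`` in its own
    orientation, reading from the canonical record."""
    rc = revcomp(cur)
    canon = cur if cur <= rc else rc
    entry = table.raw(canon)
    if entry is None:
        return 0, [0, 0, 0, 0]
    if canon == cur:
        return entry[0], entry[2]
    left = entry[1]
    return entry[0], [left[3], left[2], left[1], left[0]]


def _walk_right(table, policy, start: bytes, used: set):
    """Extend ``start`` rightward; returns (appended bases, counts, EndInfo).

    A step from the current k-mer to its successor requires mutual
    uniqueness: the successor must be the only qualifying extension
    forward, and the current k-mer the only qualifying predecessor of
    the successor. Convergent junctions are thereby recorded as forks
    on both sides regardless of which contig is walked first.
    """
    cur = start
    appended = bytearray()
    counts: List[int] = []
    while True:
        cnt, exts = _oriented_right_exts(table, cur)
        t = adaptive_threshold(cnt, policy)
        qual = [i for i in range(4) if exts[i] >= t]
        if not qual:
            return bytes(appended), counts, EndInfo("deadend")
        if len(qual) > 1:
            bases = tuple(chr(_I2B[i]) for i in qual)
            return bytes(appended), counts, EndInfo("fork", bases)
        nxt = cur[1:] + _I2B[qual[0] : qual[0] + 1]
        rc = revcomp(nxt)
        ncanon = nxt if nxt <= rc else rc
        entry = table.raw(ncanon)
        if entry is None:
            # extension evidence without a surviving neighbour k-mer
            return bytes(appended), counts, EndInfo("deadend")
        # predecessors of nxt, seen as right extensions of revcomp(nxt)
        bcnt, bexts = _oriented_right_exts(table, rc)
        tb = adaptive_threshold(bcnt, policy)
        bqual = [i for i in range(4) if bexts[i] >= tb]
        if len(bqual) > 1:
            bases = tuple(chr(_I2B[_COMPI[i]]) for i in bqual)
            return bytes(appended), counts, EndInfo("fork", bases)
        if len(bqual) == 1 and _I2B[_COMPI[bqual[0]]] != cur[0]:
            return bytes(appended), counts, EndInfo("deadend")
        if ncanon in used:
            return bytes(appended), counts, EndInfo("used")
        used.add(ncanon)
        appended += nxt[-1:]
        counts.append(entry[0])
        cur = nxt


def walk_contigs(table: KmerTable, policy: ThresholdPolicy) -> List[Contig]:
    """Partition the k-mer table into contigs by adaptive traversal.

    Deterministic: seeds are taken in lexicographic order of the
    canonical k-mers and each contig is emitted in its canonical
    orientation (min of sequence and reverse complement).
    """
    k = table.k
    used: set = set()
    contigs: List[Contig] = []
    for seed in table.sorted_kmers():
        if seed in used:
            continue
        used.add(seed)
        seed_count = table.raw(seed)[0]
        right_app, right_counts, rinfo = _walk_right(table, policy, seed, used)
        seq = seed + right_app
        left_app, left_counts, linfo = _walk_right(table, policy, revcomp(seq)[-k:], used)
        # left extension was walked on the reverse strand
        seq = revcomp(left_app) + seq
        counts = left_counts[::-1] + [seed_count] + right_counts
        sequence = seq.decode()
        rc_sequence = revcomp(sequence)
        if rc_sequence < sequence:
            sequence = rc_sequence
            linfo, rinfo = rinfo, linfo
        contigs.append(
            Contig(
                id=len(contigs),
                sequence=sequence,
                depth=sum(counts) / len(counts),
                kmer_count=len(counts),
                left_info=linfo,
                right_info=rinfo,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# unitig graph


def _end_oriented(seq: str, side: str) -> str:
    """The contig oriented so that ``side`` ('L' or 'R') is its right end."""
    return seq if side == "R" else revcomp(seq)


def _interface(seq: str, side: str, k: int) -> str:
    """Canonical (k-1)-mer interface just outside the given contig end."""
    tail = _end_oriented(seq, side)[-(k - 1):]
    rc = revcomp(tail)
    return tail if tail <= rc else rc


class UnitigGraph:
    """Contigs as vertices; fork junctions keyed by their canonical
    (k-1)-base interface, each holding the attached contig ends."""

    def __init__(self, k: int):
        self.k = k
        self.contigs: Dict[int, Contig] = {}
        self.junctions: Dict[str, List[Tuple[int, str]]] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add_contig(self, contig: Contig) -> None:
        self.contigs[contig.id] = contig
        self._next_id = max(self._next_id, contig.id + 1)

    def attached(self, cid: int, side: str) -> Optional[str]:
        for key, ends in self.junctions.items():
            if (cid, side) in ends:
                return key
        return None

    def _detach(self, cid: int, side: str) -> None:
        for key in list(self.junctions):
            ends = self.junctions[key]
            if (cid, side) in ends:
                ends.remove((cid, side))
            if not ends:
                del self.junctions[key]

    def remove_contig(self, cid: int) -> None:
        self._detach(cid, "L")
        self._detach(cid, "R")
        del self.contigs[cid]

    def total_bp(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    def end_junction_map(self) -> Dict[Tuple[int, str], str]:
        out = {}
        for key, ends in self.junctions.items():
            for end in ends:
                out[end] = key
        return out

    def to_contigs(self) -> List[Contig]:
        """Final contig list, renumbered deterministically by sequence."""
        ordered = sorted(self.contigs.values(), key=lambda c: c.sequence)
        return [
            Contig(i, c.sequence, c.depth, c.kmer_count, c.left_info, c.right_info)
            for i, c in enumerate(ordered)
        ]


def build_unitig_graph(
    contigs: List[Contig], table: KmerTable, policy: ThresholdPolicy,
    validate: bool = True,
) -> UnitigGraph:
    """Link contig ends that meet at fork k-mers into junctions.

    A junction is the (k-1)-base interface shared by a fork k-mer and
    all its qualifying successors; every contig end whose terminal
    interface matches a fork interface attaches to that junction, which
    keeps the graph strand-symmetric and gives each end at most one
    junction.
    """
    k = table.k
    if validate:
        for c in contigs:
            if len(c.sequence) < k:
                raise ValueError(f"contig {c.id} shorter than k={k}")
            for i in range(0, len(c.sequence) - k + 1, max(1, k // 2)):
                kmer = c.sequence[i : i + k]
                rc = revcomp(kmer)
                if (kmer if kmer <= rc else rc) not in table:
                    raise ValueError(
                        f"contig {c.id} contains k-mer absent from the table"
                    )
    graph = UnitigGraph(k)
    for c in contigs:
        graph.add_contig(c)

    fork_keys = set()
    for c in contigs:
        for side, info in (("L", c.left_info), ("R", c.right_info)):
            if info is not None and info.status == "fork":
                fork_keys.add(_interface(c.sequence, side, k))
    for key in sorted(fork_keys):
        graph.junctions[key] = []
    for c in sorted(graph.contigs):
        contig = graph.contigs[c]
        for side in ("L", "R"):
            key = _interface(contig.sequence, side, k)
            if key in graph.junctions:
                graph.junctions[key].append((contig.id, side))
    for key in [key for key, ends in graph.junctions.items() if len(ends) < 2]:
        del graph.junctions[key]
    return graph


# ---------------------------------------------------------------------------
# refinement


def merge_bubbles(graph: UnitigGraph, bubble_len_factor: int) -> UnitigGraph:
    """Merge short parallel branches between the same two junctions.

    Of each parallel pair with both lengths <= bubble_len_factor*k, the
    lower-depth branch is deleted and its depth added to the survivor
    (ties broken by lexicographic sequence), repeated to fixpoint.
    """
    gate = bubble_len_factor * graph.k
    while True:
        end_j = graph.end_junction_map()
        groups: Dict[Tuple[str, str], List[int]] = {}
        for cid in sorted(graph.contigs):
            jl = end_j.get((cid, "L"))
            jr = end_j.get((cid, "R"))
            if jl is None or jr is None or jl == jr:
                continue
            if len(graph.contigs[cid]) > gate:
                continue
            groups.setdefault((min(jl, jr), max(jl, jr)), []).append(cid)
        changed = False
        for pair in sorted(groups):
            cids = groups[pair]
            if len(cids) < 2:
                continue
            cids.sort(key=lambda c: (-graph.contigs[c].depth, graph.contigs[c].sequence))
            survivor = graph.contigs[cids[0]]
            for loser_id in cids[1:]:
                survivor.depth += graph.contigs[loser_id].depth
                graph.remove_contig(loser_id)
                changed = True
        if not changed:
            return graph


def remove_hairs(graph: UnitigGraph, hair_len_factor: int) -> UnitigGraph:
    """Clip short low-depth dead-end branches, then re-concatenate chains.

    A hair has exactly one junction-attached end, length <=
    hair_len_factor*k, and depth below the maximum depth of the other
    contigs at that junction.
    """
    gate = hair_len_factor * graph.k
    while True:
        end_j = graph.end_junction_map()
        doomed = []
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            jl = end_j.get((cid, "L"))
            jr = end_j.get((cid, "R"))
            if (jl is None) == (jr is None):
                continue  # isolated or both ends attached
            if len(c) > gate:
                continue
            key = jl if jl is not None else jr
            others = [
                graph.contigs[oc].depth
                for (oc, _s) in graph.junctions[key]
                if oc != cid
            ]
            if others and c.depth < max(others):
                doomed.append(cid)
        if not doomed:
            break
        for cid in doomed:
            if cid in graph.contigs:
                graph.remove_contig(cid)
    _compact_chains(graph)
    return graph


def prune_forks(
    graph: UnitigGraph, prune_ratio: float, prune_max_iters: int
) -> UnitigGraph:
    """Sever junction links to branches much shallower than the deepest
    branch (depth < prune_ratio * max), iterating to fixpoint; then
    re-concatenate unbranched chains."""
    if not 0.0 < prune_ratio < 1.0:
        raise ValueError("prune_ratio must lie in (0, 1)")
    for _ in range(prune_max_iters):
        changed = False
        for key in sorted(graph.junctions):
            ends = graph.junctions[key]
            depths = {end: graph.contigs[end[0]].depth for end in ends}
            maxd = max(depths.values())
            for end in [e for e in list(ends) if depths[e] < prune_ratio * maxd]:
                ends.remove(end)
                changed = True
            if not ends:
                del graph.junctions[key]
        if not changed:
            break
    _compact_chains(graph)
    return graph


def _try_merge_pair(
    graph: UnitigGraph, e1: Tuple[int, str], e2: Tuple[int, str]
) -> bool:
    """Merge the two contig ends of a 2-end junction if they overlap by
    k-1 bases in sequence (i.e. one enters where the other leaves)."""
    k = graph.k
    (c1, s1), (c2, s2) = e1, e2
    if c1 == c2:
        return False
    a = _end_oriented(graph.contigs[c1].sequence, s1)
    b_contig = graph.contigs[c2].sequence
    b = b_contig if s2 == "L" else revcomp(b_contig)
    if a[-(k - 1):] != b[: k - 1]:
        return False
    ca, cb = graph.contigs[c1], graph.contigs[c2]
    newseq = a + b[k - 1:]
    kc = len(newseq) - k + 1
    depth = (ca.depth * ca.kmer_count + cb.depth * cb.kmer_count) / (
        ca.kmer_count + cb.kmer_count
    )
    # outer end metadata survives the merge
    left_info = ca.left_info if s1 == "R" else ca.right_info
    right_info = cb.right_info if s2 == "L" else cb.left_info
    # remap junction attachments of the two outer ends
    outer1 = (c1, "L" if s1 == "R" else "R")
    outer2 = (c2, "R" if s2 == "L" else "L")
    j1 = graph.attached(*outer1)
    j2 = graph.attached(*outer2)
    graph.remove_contig(c1)
    graph.remove_contig(c2)
    new_id = graph._next_id
    rc_new = revcomp(newseq)
    flipped = rc_new < newseq
    if flipped:
        newseq = rc_new
        left_info, right_info = right_info, left_info
        j1, j2 = j2, j1
    merged = Contig(new_id, newseq, depth, kc, left_info, right_info)
    graph.add_contig(merged)
    if j1 is not None and j1 in graph.junctions:
        graph.junctions[j1].append((new_id, "L"))
    if j2 is not None and j2 in graph.junctions:
        graph.junctions[j2].append((new_id, "R"))
    return True


def _compact_chains(graph: UnitigGraph) -> None:
    """Repeatedly merge across junctions that connect exactly two
    compatible contig ends."""
    while True:
        merged_any = False
        for key in sorted(graph.junctions):
            ends = graph.junctions.get(key)
            if ends is None or len(ends) != 2:
                continue
            e1, e2 = sorted(ends)
            ok = _try_merge_pair(graph, e1, e2) or _try_merge_pair(graph, e2, e1)
            if ok:
                if key in graph.junctions:
                    # junction consumed by the merge
                    remaining = [
                        e for e in graph.junctions[key] if e[0] in graph.contigs
                    ]
                    if remaining:
                        graph.junctions[key] = remaining
                    else:
                        del graph.junctions[key]
                merged_any = True
                break
        if not merged_any:
            return
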