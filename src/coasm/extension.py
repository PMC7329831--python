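"""Localized contig extension past global-graph forks.

Reads are anchored to contig termini by exact shared seeds and verified
by ungapped comparison; the overhanging read bases then vote, one
position at a time, on how to extend the contig. A base is appended
only when at least ``min_votes`` high-quality reads agree and no
competing base reaches ``min_votes`` (a local fork stops the walk).
Because voting is a pure tally it is independent of read input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .contigs import Contig
from .io import Read
from .sequtils import revcomp


@dataclass
class EndAlignment:
    """A read anchored over one contig terminus.

    ``offset`` is the position, in the oriented read, of the first base
    extending past the contig end (== read length when the read lies
    entirely within the contig). ``seq``/``quals`` hold the read in the
    orientation matching the contig end oriented rightmost.
    """

    read_id: str
    contig_id: int
    contig_end: str  # "left" | "right"
    offset: int
    orient: str  # "fwd" | "rc"
    overlap: int
    mismatches: int
    seq: str
    quals: Sequence[int]


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def recruit_end_reads(
    contigs: Iterable[Contig],
    reads: Iterable[Read],
    seed_len: int,
    window: Optional[int] = None,
    max_mismatches: int = 2,
) -> Dict[Tuple[int, str], List[EndAlignment]]:
    """Anchor reads over contig termini.

    Reads sharing an exact ``seed_len``-mer with the terminal ``window``
    bases of a contig end (default 2x read length) are verified by
    ungapped comparison allowing ``max_mismatches`` in the overlap.
    Each read is assigned to at most one contig end — the one with the
    longest verified overlap; ties are discarded.
    """
    contigs = list(contigs)
    reads = list(reads)
    if not contigs or not reads:
        return {}
    if window is None:
        window = 2 * max(len(r.sequence) for r in reads)

    # oriented terminal sequences: end placed rightmost
    oriented: Dict[Tuple[int, str], str] = {}
    index: Dict[str, List[Tuple[int, str, int]]] = {}
    for c in contigs:
        for end in ("left", "right"):
            t = c.sequence if end == "right" else revcomp(c.sequence)
            oriented[(c.id, end)] = t
            lo = max(0, len(t) - window)
            for p in range(lo, len(t) - seed_len + 1):
                index.setdefault(t[p : p + seed_len], []).append((c.id, end, p))

    stride = max(1, seed_len // 2)
    best: Dict[str, List[EndAlignment]] = {}
    for read in reads:
        rl = len(read.sequence)
        if rl < seed_len:
            continue
        hits: Dict[Tuple[int, str, int, str], None] = {}
        for orient in ("fwd", "rc"):
            r = read.sequence if orient == "fwd" else revcomp(read.sequence)
            positions = list(range(0, rl - seed_len + 1, stride))
            if positions[-1] != rl - seed_len:
                positions.append(rl - seed_len)
            for rp in positions:
                for cid, end, p in index.get(r[rp : rp + seed_len], ()):
                    hits[(cid, end, p - rp, orient)] = None
        alns: List[EndAlignment] = []
        for cid, end, diag, orient in hits:
            t = oriented[(cid, end)]
            r = read.sequence if orient == "fwd" else revcomp(read.sequence)
            q = read.quals if orient == "fwd" else read.quals[::-1]
            r0 = max(0, -diag)
            r1 = min(rl, len(t) - diag)
            overlap = r1 - r0
            if overlap < seed_len:
                continue
            mm = _count_mismatches(r[r0:r1], t[diag + r0 : diag + r1], max_mismatches)
            if mm > max_mismatches:
                continue
            dist = len(t) - (diag + r1)  # gap between alignment and terminus
            alns.append(
                (
                    dist,
                    EndAlignment(
                        read_id=read.id,
                        contig_id=cid,
                        contig_end=end,
                        offset=min(rl, len(t) - diag),
                        orient=orient,
                        overlap=overlap,
                        mismatches=mm,
                        seq=r,
                        quals=q,
                    ),
                )
            )
        if not alns:
            continue
        alns.sort(
            key=lambda d_a: (
                -d_a[1].overlap,
                d_a[1].mismatches,
                d_a[0],
                d_a[1].contig_id,
                d_a[1].contig_end,
            )
        )
        (dist0, top) = alns[0]
        if len(alns) > 1:
            dist1, second = alns[1]
            if (
                second.overlap == top.overlap
                and second.mismatches == top.mismatches
                and dist1 == dist0
                and (second.contig_id, second.contig_end)
                != (top.contig_id, top.contig_end)
            ):
                continue  # genuinely ambiguous between two ends
        best.setdefault(read.id, []).append(top)

    out: Dict[Tuple[int, str], List[EndAlignment]] = {}
    for alns in best.values():
        a = alns[0]
        out.setdefault((a.contig_id, a.contig_end), []).append(a)
    for key in out:
        out[key].sort(key=lambda a: a.read_id)
    return out


def _vote_walk(
    overhangs: List[Tuple[str, Sequence[int]]],
    qual_floor: int,
    min_votes: int,
    max_steps: Optional[int] = None,
) -> str:
    """Consensus walk over overhang strings; stops at the first position
    without a unique base reaching ``min_votes`` high-quality reads."""
    ext = []
    pos = 0
    while max_steps is None or pos < max_steps:
        votes: Dict[str, int] = {}
        for seq, quals in overhangs:
            if pos < len(seq) and quals[pos] >= qual_floor:
                votes[seq[pos]] = votes.get(seq[pos], 0) + 1
        winners = [b for b, v in votes.items() if v >= min_votes]
        if len(winners) != 1:
            break
        ext.append(winners[0])
        pos += 1
    return "".join(ext)


def extend_contig(
    contig: Contig,
    end_alignments: Dict[Tuple[int, str], List[EndAlignment]],
    qual_floor: int = 20,
    min_votes: int = 2,
) -> Contig:
    """Extend a contig at both termini by overhang consensus voting.

    The input sequence is preserved verbatim as an infix of the output;
    depth is not recomputed over the extended bases.
    """
    if min_votes < 2:
        raise ValueError("min_votes must be >= 2")
    k = len(contig.sequence) - contig.kmer_count + 1
    seq = contig.sequence
    for end in ("right", "left"):
        t = seq if end == "right" else revcomp(seq)
        alns = end_alignments.get((contig.id, end), [])
        overhangs = []
        for a in alns:
            if a.offset < len(a.seq):
                overhangs.append((a.seq[a.offset :], list(a.quals[a.offset :])))
        if not overhangs:
            continue
        ext = _vote_walk(overhangs, qual_floor, min_votes)
        if not ext:
            continue
        t = t + ext
        seq = t if end == "right" else revcomp(t)
    return Contig(
        id=contig.id,
        sequence=seq,
        depth=contig.depth,
        kmer_count=len(seq) - k + 1,
        left_info=contig.left_info,
        right_info=contig.right_info,
    )
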