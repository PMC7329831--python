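"""Outer multi-k loop: contig generation repeated with increasing k.

Small k keeps the de Bruijn graph connected for genomes sampled at low
depth; large k spans repeats. Each iteration's contigs are treated as
long error-free reads: their (k+s)-mers are added to the next
iteration's k-mer table with count max(min_count, round(depth)) and the
single extension implied by the contig context, so low-abundance
genomes assembled early survive into the later, more repeat-resolving
iterations.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional

from .config import AssemblyConfig
from .contigs import (
    Contig,
    ThresholdPolicy,
    build_unitig_graph,
    merge_bubbles,
    prune_forks,
    remove_hairs,
    walk_contigs,
)
from .extension import extend_contig, recruit_end_reads
from .io import Read
from .kmers import KmerTable, count_kmers
from .sequtils import revcomp

_B2I = {65: 0, 67: 1, 71: 2, 84: 3}


def contigs_to_kmers(
    contigs: Iterable[Contig],
    k_next: int,
    qual_floor: int = 20,
    min_count: int = 2,
) -> KmerTable:
    """Re-express contigs as longer k-mers seeding the next iteration.

    Every ``k_next``-mer of every contig (shorter contigs are skipped)
    is emitted with count max(min_count, round(depth)) and with the
    unique flanking extension implied by the contig, at maximal
    quality. The result is merged additively with read-derived counts.
    """
    table = KmerTable(k_next)
    k = k_next
    for contig in contigs:
        seq = contig.sequence
        L = len(seq)
        if L < k:
            continue
        c = max(min_count, round(contig.depth))
        sb = seq.encode()
        rb = revcomp(sb)
        for i in range(L - k + 1):
            fwd = sb[i : i + k]
            rev = rb[L - k - i : L - i]
            left = (_B2I[sb[i - 1]], c) if i > 0 else None
            right = (_B2I[sb[i + k]], c) if i + k < L else None
            if fwd <= rev:
                table.add_counts(fwd, c, left=left, right=right)
            else:
                cl = (3 - right[0], right[1]) if right else None
                cr = (3 - left[0], left[1]) if left else None
                table.add_counts(rev, c, left=cl, right=cr)
    return table


def run_iteration(
    reads: List[Read],
    prev_contigs: List[Contig],
    k: int,
    config: AssemblyConfig,
) -> List[Contig]:
    """One contig-generation iteration at a single k."""
    table = count_kmers(reads, k, config.qual_floor, config.min_count)
    if prev_contigs:
        table.merge_add(
            contigs_to_kmers(
                prev_contigs, k, config.qual_floor, config.min_count
            )
        )
    policy = ThresholdPolicy(alpha=config.alpha, floor=config.min_count)
    contigs = walk_contigs(table, policy)
    # contigs too short to contribute k-mers pass through unchanged, so
    # low-depth content assembled at smaller k is never lost
    leftovers = [c for c in prev_contigs if len(c.sequence) < k]
    if contigs:
        graph = build_unitig_graph(contigs, table, policy, validate=False)
        merge_bubbles(graph, config.bubble_len_factor)
        remove_hairs(graph, config.hair_len_factor)
        prune_forks(graph, config.prune_ratio, config.prune_max_iters)
        contigs = graph.to_contigs()
        ends = recruit_end_reads(contigs, reads, config.seed_len)
        contigs = [
            extend_contig(c, ends, config.qual_floor, min_votes=2)
            for c in contigs
        ]
    out = list(contigs)
    for c in leftovers:
        out.append(
            Contig(
                id=len(out),
                sequence=c.sequence,
                depth=c.depth,
                kmer_count=c.kmer_count,
            )
        )
    return out


def run_all(
    reads: List[Read],
    config: AssemblyConfig,
    on_iteration: Optional[Callable[[int, List[Contig]], None]] = None,
) -> List[Contig]:
    """Fold :func:`run_iteration` over the configured k schedule."""
    reads = list(reads)
    contigs: List[Contig] = []
    for k in config.k_list:
        contigs = run_iteration(reads, contigs, k, config)
        if on_iteration is not None:
            on_iteration(k, contigs)
    return contigs
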