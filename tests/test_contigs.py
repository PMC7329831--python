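"""De Bruijn traversal, unitig-graph construction, and refinement."""

import pytest
from hypothesis import given, settings, strategies as st

from coasm.contigs import (
    Contig,
    EndInfo,
    ThresholdPolicy,
    UnitigGraph,
    adaptive_threshold,
    build_unitig_graph,
    merge_bubbles,
    prune_forks,
    remove_hairs,
    walk_contigs,
    _interface,
)
from coasm.kmers import canonicalize, count_kmers
from coasm.io import Read

from conftest import random_dna, rc, tiling_reads

POLICY = ThresholdPolicy(alpha=0.1, floor=2)
K = 21


def _reads(*seqs, copies=2, read_len=100, stride=20):
    reads = []
    for seq in seqs:
        batch = tiling_reads(seq, read_len=min(read_len, len(seq)),
                             stride=stride, copies=copies)
        for i, r in enumerate(batch):
            r.id = f"{len(reads)+i}"
        reads.extend(batch)
    return reads


def _assemble(table):
    return walk_contigs(table, POLICY)


class TestAdaptiveThreshold:
    def test_arithmetic(self):
        assert adaptive_threshold(10, POLICY) == 2
        assert adaptive_threshold(100, POLICY) == 10
        assert adaptive_threshold(1, POLICY) == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    def test_monotone(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert adaptive_threshold(lo, POLICY) <= adaptive_threshold(hi, POLICY)


class TestWalkContigs:
    def test_reconstructs_single_genome(self, rng):
        genome = random_dna(rng, 1000)
        table = count_kmers(_reads(genome, copies=3), K)
        contigs = _assemble(table)
        assert len(contigs) == 1
        assert contigs[0].sequence in (genome, rc(genome))
        assert contigs[0].depth >= 2

    def test_two_disjoint_genomes_give_two_contigs(self, rng):
        g1, g2 = random_dna(rng, 500), random_dna(rng, 500)
        table = count_kmers(_reads(g1, g2), K)
        contigs = _assemble(table)
        assert len(contigs) == 2
        assert {c.sequence for c in contigs} == {
            min(g1, rc(g1)), min(g2, rc(g2))
        }

    def test_empty_table_empty_list(self):
        table = count_kmers([], K)
        assert _assemble(table) == []

    def test_partition_and_path_validity(self, rng):
        genome = random_dna(rng, 1500)
        table = count_kmers(_reads(genome), K)
        contigs = _assemble(table)
        seen = set()
        for c in contigs:
            assert c.kmer_count == len(c.sequence) - K + 1
            for i in range(c.kmer_count):
                kmer = canonicalize(c.sequence[i : i + K])
                assert kmer in table
                assert kmer not in seen  # each table k-mer in one contig
                seen.add(kmer)
        assert len(seen) == len(table)

    def test_strand_invariance_of_assembly(self, rng):
        genome = random_dna(rng, 900)
        reads = _reads(genome)
        flipped = [
            Read(id=r.id, sequence=rc(r.sequence), quals=list(r.quals[::-1]))
            for r in reads
        ]
        a = {c.sequence for c in _assemble(count_kmers(reads, K))}
        b = {c.sequence for c in _assemble(count_kmers(flipped, K))}
        assert a == b


def _fork_fixture(rng):
    """Trunk forking into two branches sharing the first k-1 interface."""
    trunk = random_dna(rng, 300)
    b1 = trunk[-(K - 1) :] + "A" + random_dna(rng, 200)
    b2 = trunk[-(K - 1) :] + "C" + random_dna(rng, 200)
    return trunk + b1[K - 1 :], trunk + b2[K - 1 :]


class TestUnitigGraph:
    def test_linear_genome_has_no_junctions(self, rng):
        genome = random_dna(rng, 600)
        table = count_kmers(_reads(genome), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        assert len(graph.contigs) == 1
        assert len(graph.junctions) == 0

    def test_two_way_fork_makes_one_junction(self, rng):
        v1, v2 = _fork_fixture(rng)
        table = count_kmers(_reads(v1, v2, copies=3), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        assert len(graph.contigs) == 3  # trunk + two branches
        assert len(graph.junctions) == 1
        (ends,) = graph.junctions.values()
        assert len(ends) == 3

    def test_x_repeat_fixture(self, rng):
        # two sequences sharing an interior repeat run longer than k
        repeat = random_dna(rng, 40)
        s1 = random_dna(rng, 300) + repeat + random_dna(rng, 300)
        s2 = random_dna(rng, 300) + repeat + random_dna(rng, 300)
        table = count_kmers(_reads(s1, s2, copies=3), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        assert len(graph.contigs) == 5  # 4 arms + shared repeat contig
        assert len(graph.junctions) == 2

    def test_inconsistent_contig_table_pair_raises(self, rng):
        genome = random_dna(rng, 200)
        table = count_kmers(_reads(genome), K)
        rogue = [Contig(0, random_dna(rng, 100), 2.0, 80)]
        with pytest.raises(ValueError):
            build_unitig_graph(rogue, table, POLICY, validate=True)


class TestMergeBubbles:
    def test_short_bubble_merges_into_deeper_branch(self, rng):
        v1, v2 = _bubble_fixture(rng)
        table = count_kmers(_reads(v1, copies=10) + _reads(v2, copies=2), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        branches = [
            c for c in graph.contigs.values() if len(c.sequence) < 2 * K
        ]
        assert len(branches) == 2
        d1, d2 = sorted(c.depth for c in branches)
        merge_bubbles(graph, 3)
        survivors = [
            c for c in graph.contigs.values() if len(c.sequence) < 2 * K
        ]
        assert len(survivors) == 1
        assert survivors[0].depth == pytest.approx(d1 + d2)

    def test_long_parallel_paths_untouched(self, rng):
        shared1, shared2 = random_dna(rng, 300), random_dna(rng, 300)
        mid1, mid2 = random_dna(rng, 500), random_dna(rng, 500)
        v1 = shared1 + mid1 + shared2
        v2 = shared1 + mid2 + shared2
        table = count_kmers(_reads(v1, v2, copies=3), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        n = len(graph.contigs)
        merge_bubbles(graph, 3)
        assert len(graph.contigs) == n

    def test_no_parallel_paths_is_identity(self, rng):
        genome = random_dna(rng, 400)
        table = count_kmers(_reads(genome), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        merge_bubbles(graph, 3)
        assert len(graph.contigs) == 1


def _bubble_fixture(rng):
    """Two variants of one genome differing by a single mid-sequence SNP."""
    left = random_dna(rng, 300)
    right = random_dna(rng, 300)
    return left + "A" + right, left + "C" + right


class TestRemoveHairs:
    def test_low_depth_tip_clipped_and_chain_rejoined(self, rng):
        trunk = random_dna(rng, 500)
        tip = trunk[:250][-(K - 1) :] + "A" + random_dna(rng, 20)
        # tip diverges from trunk position 250 with a 21+20bp dead end;
        # deep enough to fork (above the adaptive threshold) but
        # shallower than the trunk
        tip_path = trunk[:250] + tip[K - 1 :]
        table = count_kmers(_reads(trunk, copies=10) + _reads(tip_path, copies=3), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        assert len(graph.contigs) >= 3
        remove_hairs(graph, 2)
        assert len(graph.contigs) == 1
        (survivor,) = graph.contigs.values()
        assert survivor.sequence in (trunk, rc(trunk))

    def test_isolated_contig_never_removed(self, rng):
        genome = random_dna(rng, 100)
        table = count_kmers(_reads(genome, read_len=100), K)
        graph = build_unitig_graph(_assemble(table), table, POLICY)
        remove_hairs(graph, 2)
        assert len(graph.contigs) == 1

    def test_long_dead_end_retained(self, rng):
        trunk = random_dna(rng, 500)
        spur = trunk[:250][-(K - 1) :] + "A" + random_dna(rng, 200)
        spur_path = trunk[:250] + spur[K - 1 :]
        table = count_kmers(_reads(trunk, copies=10) + _reads(spur_path, copies=3), K)
        graph = build_unitig_graph(_assemble(table), table, POLICY)
        n = len(graph.contigs)
        assert len(graph.junctions) == 1  # the fork is real
        remove_hairs(graph, 2)  # spur is ~221bp > 2k: kept
        assert len(graph.contigs) == n


def _manual_junction_graph(rng, depth_trunk, depth_b1, depth_b2):
    """Hand-built graph: trunk forking into two branches."""
    trunk = random_dna(rng, 120)
    iface = trunk[-(K - 1) :]
    b1 = iface + "A" + random_dna(rng, 100)
    b2 = iface + "C" + random_dna(rng, 100)

    def canon(seq):
        return min(seq, rc(seq))

    graph = UnitigGraph(K)
    contigs = {}
    for i, (seq, depth) in enumerate(
        [(trunk, depth_trunk), (b1, depth_b1), (b2, depth_b2)]
    ):
        cseq = canon(seq)
        flipped = cseq != seq
        c = Contig(i, cseq, depth, len(seq) - K + 1)
        contigs[i] = (c, flipped)
        graph.add_contig(c)
    key = _interface(trunk, "R", K)
    ends = []
    ends.append((0, "L" if contigs[0][1] else "R"))
    for i in (1, 2):
        ends.append((i, "R" if contigs[i][1] else "L"))
    graph.junctions[key] = ends
    return graph


class TestPruneForks:
    def test_weak_branch_severed_and_chain_concatenated(self, rng):
        graph = _manual_junction_graph(rng, 50.0, 50.0, 3.0)
        prune_forks(graph, 0.1, 10)
        # depth-3 link cut; trunk and strong branch concatenated
        lens = sorted(len(c.sequence) for c in graph.contigs.values())
        assert len(graph.contigs) == 2
        assert lens == [121, 221]
        assert len(graph.junctions) == 0

    def test_similar_branches_both_kept(self, rng):
        graph = _manual_junction_graph(rng, 50.0, 50.0, 40.0)
        prune_forks(graph, 0.1, 10)
        assert len(graph.contigs) == 3
        assert len(graph.junctions) == 1

    def test_idempotent_at_fixpoint(self, rng):
        graph = _manual_junction_graph(rng, 50.0, 50.0, 3.0)
        prune_forks(graph, 0.1, 10)
        snapshot = {c.id: c.sequence for c in graph.contigs.values()}
        prune_forks(graph, 0.1, 10)
        assert {c.id: c.sequence for c in graph.contigs.values()} == snapshot


class TestRefinementInvariants:
    def test_refinement_never_increases_total_length(self, rng):
        v1, v2 = _bubble_fixture(rng)
        table = count_kmers(_reads(v1, copies=8) + _reads(v2, copies=2), K)
        contigs = _assemble(table)
        graph = build_unitig_graph(contigs, table, POLICY)
        before = graph.total_bp()
        merge_bubbles(graph, 3)
        remove_hairs(graph, 2)
        prune_forks(graph, 0.1, 10)
        assert graph.total_bp() <= before
        # no k-mer outside the source table is ever created
        for c in graph.contigs.values():
            for i in range(len(c.sequence) - K + 1):
                assert canonicalize(c.sequence[i : i + K]) in table
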