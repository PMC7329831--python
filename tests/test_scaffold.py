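"""Read alignment, splint/span edges, graph traversal, and gap closing."""

import pytest

from coasm.config import AssemblyConfig
from coasm.contigs import Contig
from coasm.io import Read
from coasm.scaffold import (
    ContigEdge,
    ContigGraph,
    ScaffoldPath,
    align_reads_to_contigs,
    build_edges,
    close_gaps,
    resolve_fork,
    scaffold_rounds,
    traverse,
)
from coasm.simulate import GenomeSpec, ReadSimParams, generate_genomes, sample_from_depths

from conftest import random_dna, rc

CFG = AssemblyConfig(rng_seed=1)


def _contig(cid, seq, depth=20.0):
    return Contig(cid, seq, depth, max(1, len(seq) - 20))


def _read(rid, seq, mate="unpaired", pair_id=""):
    return Read(id=rid, sequence=seq, quals=[40] * len(seq), mate=mate,
                pair_id=pair_id or rid)


class TestAlign:
    def test_read_inside_contig_single_alignment(self, rng):
        genome = random_dna(rng, 500)
        contigs = [_contig(0, genome)]
        (aln,) = align_reads_to_contigs([_read("r", genome[100:250])], contigs, 31)
        assert (aln.contig_start, aln.contig_end) == (100, 250)
        assert (aln.read_start, aln.read_end) == (0, 150)
        assert aln.matches == 150

    def test_straddling_read_gets_two_alignments(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        contigs = [_contig(0, a), _contig(1, b)]
        read = _read("r", a[-75:] + b[:75])
        alns = align_reads_to_contigs([read], contigs, 31)
        assert len(alns) == 2
        assert {x.contig_id for x in alns} == {0, 1}
        intervals = sorted((x.read_start, x.read_end) for x in alns)
        assert intervals == [(0, 75), (75, 150)]

    def test_unmatched_read_gives_nothing(self, rng):
        contigs = [_contig(0, random_dna(rng, 400))]
        assert align_reads_to_contigs([_read("r", random_dna(rng, 150))], contigs, 31) == []


class TestBuildEdges:
    def test_splint_between_abutting_contigs_gap_near_zero(self, rng):
        genome = random_dna(rng, 800)
        contigs = [_contig(0, genome[:400]), _contig(1, genome[400:])]
        reads = [
            _read(f"r{i}", genome[330 + i * 10 : 480 + i * 10]) for i in range(3)
        ]
        alns = align_reads_to_contigs(reads, contigs, 31)
        edges = build_edges(alns, contigs, 270.0, 30.0, min_edge_support=2)
        assert len(edges) == 1
        e = edges[0]
        assert {e.end_a, e.end_b} == {(0, "R"), (1, "L")}
        assert e.kind == "splint"
        assert abs(e.gap) <= 2

    def test_span_gap_estimate_calibrated(self, rng):
        genomes = generate_genomes([GenomeSpec("g", length=1300)], seed=5)
        gseq = genomes[0][1]
        contigs = [_contig(0, gseq[:600]), _contig(1, gseq[700:])]  # gap 100
        params = ReadSimParams(sub_error_rate=0.0, rng_seed=5)
        reads, _ = sample_from_depths(genomes, [60.0], params, 5)
        alns = align_reads_to_contigs(reads, contigs, 31)
        edges = build_edges(alns, contigs, 270.0, 30.0, min_edge_support=2)
        (e,) = [e for e in edges if {e.end_a, e.end_b} == {(0, "R"), (1, "L")}]
        assert e.support >= 10
        assert abs(e.gap - 100) <= 30

    def test_single_pair_below_support_gate(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        contigs = [_contig(0, a), _contig(1, b)]
        reads = [
            _read("p/1", a[200:350], mate="R1", pair_id="p"),
            _read("p/2", rc(b[50:200]), mate="R2", pair_id="p"),
        ]
        alns = align_reads_to_contigs(reads, contigs, 31)
        edges = build_edges(alns, contigs, 270.0, 30.0, min_edge_support=2)
        assert edges == []

    def test_implausible_span_geometry_dropped(self, rng):
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        contigs = [_contig(0, a), _contig(1, b)]
        reads = []
        for i in range(3):  # mates deep inside each contig: overlap < -3 sigma
            reads.append(_read(f"p{i}/1", a[800:950], mate="R1", pair_id=f"p{i}"))
            reads.append(_read(f"p{i}/2", rc(b[800:950]), mate="R2", pair_id=f"p{i}"))
        alns = align_reads_to_contigs(reads, contigs, 31)
        assert build_edges(alns, contigs, 270.0, 30.0, 2) == []


def _chain_graph(n=5, length=1000, depth=20.0):
    contigs = [_contig(i, random_dna_static(i, length), depth) for i in range(n)]
    edges = [
        ContigEdge((i, "R"), (i + 1, "L"), "span", 10, 50.0, 5.0,
                   read_ids=[f"e{i}"], mean_aln_len=140.0)
        for i in range(n - 1)
    ]
    return ContigGraph(contigs, edges)


def random_dna_static(seed, n):
    import numpy as np

    rng = np.random.default_rng(1000 + seed)
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=n
    ).tobytes().decode()


class TestTraverse:
    def test_linear_chain_single_path(self):
        graph = _chain_graph(5)
        paths = traverse(graph, CFG)
        assert len(paths) == 1
        assert [cid for cid, _o in paths[0].steps] in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])

    def test_no_edges_all_singletons(self):
        graph = ContigGraph([_contig(i, random_dna_static(i, 300)) for i in range(4)], [])
        paths = traverse(graph, CFG)
        assert len(paths) == 4
        assert all(len(p.steps) == 1 for p in paths)

    def test_conflicting_paths_resolved_vertex_disjoint(self):
        # A and B both link to M; the longer path wins, B re-walked alone
        contigs = [
            _contig(0, random_dna_static(0, 1000)),
            _contig(1, random_dna_static(1, 900)),
            _contig(2, random_dna_static(2, 500)),
        ]
        edges = [
            ContigEdge((0, "R"), (2, "L"), "span", 5, 40.0, 5.0),
            ContigEdge((1, "R"), (2, "L"), "span", 5, 40.0, 5.0),
        ]
        paths = traverse(ContigGraph(contigs, edges), CFG)
        by_len = {frozenset(cid for cid, _o in p.steps) for p in paths}
        assert by_len == {frozenset({0, 2}), frozenset({1})}

    def test_every_contig_in_exactly_one_path(self):
        graph = _chain_graph(6)
        # add a conflicting shortcut
        graph.edges.append(
            ContigEdge((0, "R"), (3, "L"), "span", 3, 60.0, 4.0)
        )
        graph = ContigGraph(list(graph.contigs.values()), graph.edges)
        paths = traverse(graph, CFG)
        seen = [cid for p in paths for cid, _o in p.steps]
        assert sorted(seen) == sorted(graph.contigs)


class TestResolveFork:
    def _graph_with_fork(self, repeat_depth=100.0, other_depth=95.0):
        contigs = [
            _contig(0, random_dna_static(0, 1000), 10.0),  # walk origin
            _contig(1, random_dna_static(1, 200), repeat_depth),  # repeat
            _contig(2, random_dna_static(2, 800), 10.0),  # re-emergence
            _contig(3, random_dna_static(3, 300), other_depth),  # wrong branch
        ]
        edges = [
            ContigEdge((0, "R"), (1, "L"), "span", 5, 50.0, 5.0, mean_aln_len=100),
            ContigEdge((1, "R"), (2, "L"), "span", 5, 50.0, 5.0, mean_aln_len=100),
            ContigEdge((0, "R"), (3, "L"), "span", 5, 50.0, 5.0, mean_aln_len=100),
        ]
        return ContigGraph(contigs, edges)

    def _path(self, graph):
        return ScaffoldPath(
            steps=[(0, "+")], gaps=[], edges=[], total_bp=1000, walk_depth=10.0
        )

    def test_depth_similar_vertex_beyond_repeat_wins(self):
        graph = self._graph_with_fork()
        path = self._path(graph)
        edge = resolve_fork(graph, path, (0, "R"), 5, 2.0)
        assert edge is not None
        assert edge.other((0, "R")) == (1, "L")  # through the repeat

    def test_two_similar_branches_terminate_walk(self):
        graph = self._graph_with_fork(other_depth=12.0)
        # both branches now reach depth-similar vertices
        edge = resolve_fork(graph, self._path(graph), (0, "R"), 5, 2.0)
        assert edge is None

    def test_support_refinement_breaks_depth_ties(self):
        contigs = [
            _contig(0, random_dna_static(0, 1000), 10.0),
            _contig(1, random_dna_static(1, 400), 90.0),
            _contig(2, random_dna_static(2, 400), 95.0),
        ]
        edges = [
            ContigEdge((0, "R"), (1, "L"), "span", 20, 50.0, 5.0, mean_aln_len=100),
            ContigEdge((0, "R"), (2, "L"), "span", 2, 50.0, 5.0, mean_aln_len=100),
        ]
        graph = ContigGraph(contigs, edges)
        path = ScaffoldPath(steps=[(0, "+")], gaps=[], edges=[], total_bp=1000,
                            walk_depth=10.0)
        edge = resolve_fork(graph, path, (0, "R"), 5, 2.0)
        assert edge is not None and edge.support == 20


class TestCloseGaps:
    def test_gap_filled_exactly_with_covering_reads(self, rng):
        genomes = generate_genomes([GenomeSpec("g", length=1300)], seed=9)
        gseq = genomes[0][1]
        contigs = [_contig(0, gseq[:600], 30.0), _contig(1, gseq[650:], 30.0)]
        params = ReadSimParams(sub_error_rate=0.0, rng_seed=9)
        reads, _ = sample_from_depths(genomes, [40.0], params, 9)
        alns = align_reads_to_contigs(reads, contigs, 31)
        edges = build_edges(alns, contigs, 270.0, 30.0, 2)
        (e,) = [e for e in edges if {e.end_a, e.end_b} == {(0, "R"), (1, "L")}]
        path = ScaffoldPath(steps=[(0, "+"), (1, "+")], gaps=[e.gap], edges=[e])
        reads_by_id = {r.id: r for r in reads}
        pairs = {}
        for r in reads:
            pairs.setdefault(r.pair_id, []).append(r.id)
        lookup = dict(pairs)
        for ids in pairs.values():
            for rid in ids:
                lookup[rid] = ids
        scaffold = close_gaps(
            path, {c.id: c for c in contigs}, reads_by_id, lookup, 20, CFG
        )
        assert scaffold.sequence == gseq

    def test_unfillable_gap_padded_with_ns(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        contigs = {0: _contig(0, a), 1: _contig(1, b)}
        e = ContigEdge((0, "R"), (1, "L"), "span", 3, 37.0, 5.0, read_ids=[])
        path = ScaffoldPath(steps=[(0, "+"), (1, "+")], gaps=[37.0], edges=[e])
        scaffold = close_gaps(path, contigs, {}, {}, 20, CFG)
        assert scaffold.sequence == a + "N" * 37 + b

    def test_negative_gap_merged_by_true_overlap(self, rng):
        genome = random_dna(rng, 900)
        a, b = genome[:500], genome[485:]  # 15 bp true overlap
        contigs = {0: _contig(0, a), 1: _contig(1, b)}
        e = ContigEdge((0, "R"), (1, "L"), "span", 3, -15.0, 4.0, read_ids=[])
        path = ScaffoldPath(steps=[(0, "+"), (1, "+")], gaps=[-15.0], edges=[e])
        cfg = AssemblyConfig(k_list=[15], rng_seed=1)  # min overlap k-1 = 14
        scaffold = close_gaps(path, contigs, {}, {}, 20, cfg)
        assert scaffold.sequence == genome
        assert "N" not in scaffold.sequence


class TestScaffoldRounds:
    def test_edge_free_input_passes_through(self, rng):
        contigs = [
            Contig(i, random_dna(rng, 600), 20.0, 580) for i in range(3)
        ]
        scaffolds = scaffold_rounds(contigs, [], CFG)
        assert sorted(s.sequence for s in scaffolds) == sorted(
            c.sequence for c in contigs
        )

    def test_deterministic(self, rng):
        genomes = generate_genomes([GenomeSpec("g", length=4000)], seed=3)
        gseq = genomes[0][1]
        params = ReadSimParams(sub_error_rate=0.0, rng_seed=3)
        reads, _ = sample_from_depths(genomes, [30.0], params, 3)
        pieces = [
            Contig(0, gseq[:1000], 30.0, 980),
            Contig(1, gseq[1050:2500], 30.0, 1430),
            Contig(2, gseq[2550:], 30.0, 1400),
        ]
        a = [s.sequence for s in scaffold_rounds(pieces, reads, CFG)]
        b = [s.sequence for s in scaffold_rounds(pieces, reads, CFG)]
        assert a == b
        assert len(a) == 1  # and the pieces were joined
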