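"""Canned desk-scale experiments exercising the full pipeline.

Each experiment generates its own ground-truthed community, runs the
assembler, and measures the outcome with the evaluation module. They
encode the package's study conditions — coassembly versus per-sample
multiassembly, multi-k behaviour, scaffolder gap calibration, strain
collapse — at sizes a single CPU handles in minutes. All randomness
derives from the experiment seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AssemblyConfig
from .evaluate import (
    RefAlignment,
    align_contigs_to_refs,
    assign_reads_to_contigs,
    break_at_n_runs,
    chimericity,
    dedupe,
    duplication_ratio,
    filter_min_len,
    genome_fraction,
    is_chimeric,
    multiassembly,
)
from .pipeline import run_all
from .scaffold import build_edges, align_reads_to_contigs, scaffold_rounds
from .simulate import (
    GenomeSpec,
    ReadSimParams,
    generate_genomes,
    sample_from_depths,
    simulate_sample,
)

MIN_EVAL_LEN = 500  # reference-evaluator convention


def _spawn_seeds(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def _assemble(reads, config) -> List[Tuple[str, str]]:
    contigs = run_all(reads, config)
    scaffolds = scaffold_rounds(contigs, reads, config)
    return [(s.id, s.sequence) for s in scaffolds]


def _eval_asm(assembly) -> List[Tuple[str, str]]:
    return filter_min_len(break_at_n_runs(assembly), MIN_EVAL_LEN)


# ---------------------------------------------------------------------------


def reconstruction_experiment(
    seed: int, error_rate: float = 0.0, genome_len: int = 20000, depth: float = 30.0
) -> Dict[str, float]:
    """Single-genome reconstruction at the default k schedule.

    Reports genome fraction, duplication ratio, scaffold count (>= 500
    bp), length-weighted consensus identity, and the chimericity
    summary of the assembly (trivially pure for a single genome).
    """
    genomes = generate_genomes(
        [GenomeSpec("g0", length=genome_len)], seed=seed
    )
    params = ReadSimParams(sub_error_rate=error_rate, rng_seed=seed)
    reads, _truth = sample_from_depths(genomes, [depth], params, seed)
    config = AssemblyConfig(k_list=[21, 33, 55], rng_seed=seed)
    assembly = _assemble(reads, config)
    eval_asm = _eval_asm(assembly)
    blocks = align_contigs_to_refs(eval_asm, genomes)
    total = sum(b.length for b in blocks)
    identity = (
        sum(b.identity * b.length for b in blocks) / total if total else 0.0
    )
    profiles = assign_reads_to_contigs(reads, eval_asm)
    n_chim = sum(1 for p in profiles.values() if is_chimeric(p))
    return {
        "genome_fraction": genome_fraction(blocks, genomes[0]),
        "duplication_ratio": duplication_ratio(blocks, genomes[0]),
        "n_scaffolds": len(eval_asm),
        "consensus_identity": identity,
        "fraction_chimeric": (n_chim / len(profiles)) if profiles else 0.0,
    }


def repeat_resolution_experiment(seed: int) -> Dict[str, int]:
    """A 25 bp exact repeat separating unique arms: fragmented with
    k=21 alone, resolved into one contig once k grows past the repeat."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n):
        return rng.choice(bases, size=n).tobytes().decode()

    rep = rand(25)
    genome = rand(3000) + rep + rand(3000) + rep + rand(3000)
    genomes = [("g0", genome)]
    params = ReadSimParams(sub_error_rate=0.0, rng_seed=seed)
    reads, _ = sample_from_depths(genomes, [30.0], params, seed)
    out = {}
    for label, klist in (("k21", [21]), ("k21_33", [21, 33])):
        config = AssemblyConfig(k_list=klist, rng_seed=seed)
        contigs = run_all(reads, config)
        out[f"n_contigs_{label}"] = len(
            [c for c in contigs if len(c.sequence) >= MIN_EVAL_LEN]
        )
    return out


def low_abundance_iteration_experiment(seed: int) -> Dict[str, float]:
    """Two genomes at depths 4 and 60: the low-depth genome assembled in
    the early iteration must survive the full k schedule."""
    genomes = generate_genomes(
        [GenomeSpec("lo", length=8000), GenomeSpec("hi", length=8000)], seed=seed
    )
    params = ReadSimParams(sub_error_rate=0.005, rng_seed=seed)
    reads, _ = sample_from_depths(genomes, [4.0, 60.0], params, seed)
    out = {}
    for label, klist in (("k21", [21]), ("full", [21, 33])):
        config = AssemblyConfig(k_list=klist, rng_seed=seed)
        contigs = run_all(reads, config)
        asm = [(f"c{c.id}", c.sequence) for c in contigs]
        blocks = align_contigs_to_refs(asm, genomes)
        out[f"lo_fraction_{label}"] = genome_fraction(blocks, genomes[0])
        out[f"hi_fraction_{label}"] = genome_fraction(blocks, genomes[1])
    return out


# ---------------------------------------------------------------------------


COMMUNITY_SPECS = [
    ("g_low", 12000, 3.0),  # the low-abundance genome (aggregate depth 12)
    ("g_dup", 10000, 50.0),  # high depth in every sample
    ("g2", 15000, 12.0),
    ("g3", 18000, 12.0),
    ("g4", 22000, 12.0),
    ("g5", 30000, 12.0),
]
N_SAMPLES = 4
COMMUNITY_ERROR_RATE = 0.005


def community_experiment(
    seed: int, compute_chimericity: bool = False
) -> Dict[str, float]:
    """Coassembly versus multiassembly on a six-genome community.

    Four replicate samples; one genome at per-sample depth 3 (aggregate
    12), one at 50 in every sample, four at 12. Assembles each sample
    alone and all samples together, forms the concatenated
    multiassembly and its containment-deduplicated version, and
    measures genome fraction and duplication ratio per genome.
    """
    specs = [GenomeSpec(g, length=L) for g, L, _d in COMMUNITY_SPECS]
    genomes = generate_genomes(specs, seed=seed)
    depths = np.array([d for _g, _L, d in COMMUNITY_SPECS])
    lens = np.array([len(s) for _g, s in genomes], dtype=float)
    params = ReadSimParams(sub_error_rate=COMMUNITY_ERROR_RATE, rng_seed=seed)
    children = _spawn_seeds(seed, N_SAMPLES)
    config = AssemblyConfig(k_list=[21, 33], rng_seed=seed)

    sample_reads = []
    for s in range(N_SAMPLES):
        n_pairs = int(round((depths * lens).sum() / (2 * params.read_len)))
        reads, _truth = simulate_sample(
            genomes, depths / depths.sum(), n_pairs, params, children[s],
            sample_name=f"s{s}",
        )
        sample_reads.append(reads)

    all_reads = [r for reads in sample_reads for r in reads]
    co = _assemble(all_reads, config)
    singles = [_assemble(reads, config) for reads in sample_reads]
    multi = multiassembly(singles)
    deduped = dedupe(multi)

    def metrics(assembly):
        eval_asm = _eval_asm(assembly)
        blocks = align_contigs_to_refs(eval_asm, genomes)
        return {
            g: (genome_fraction(blocks, (g, s)), duplication_ratio(blocks, (g, s)))
            for g, s in genomes
        }

    m_co = metrics(co)
    m_singles = [metrics(a) for a in singles]
    m_multi = metrics(multi)
    m_dd = metrics(deduped)

    mid = ["g2", "g3", "g4", "g5"]
    out = {
        "co_low_fraction": m_co["g_low"][0],
        "best_single_low_fraction": max(m["g_low"][0] for m in m_singles),
        "multi_low_fraction": m_multi["g_low"][0],
        "co_dup_high": m_co["g_dup"][1],
        "multi_dup_high": m_multi["g_dup"][1],
        "dedup_dup_high": m_dd["g_dup"][1],
        "multi_dup_mid_max": max(m_multi[g][1] for g in mid),
        "dedup_dup_mid_max": max(m_dd[g][1] for g in mid),
        "co_mean_fraction": float(np.mean([m_co[g][0] for g, _s in genomes])),
        "multi_mean_fraction": float(
            np.mean([m_multi[g][0] for g, _s in genomes])
        ),
    }
    if compute_chimericity:
        eval_co = _eval_asm(co)
        profiles = assign_reads_to_contigs(all_reads, eval_co)
        if profiles:
            values = [(chimericity(p), is_chimeric(p)) for p in profiles.values()]
            chim = [h for h, c in values if c]
            out["co_fraction_chimeric"] = len(chim) / len(values)
            out["co_mean_chimericity_all"] = float(
                np.mean([h for h, _c in values])
            )
            out["co_mean_chimericity_chimeric"] = (
                float(np.mean(chim)) if chim else 0.0
            )
    return out


# ---------------------------------------------------------------------------


def gap_calibration_experiment(
    seed: int, n_junctions: int = 100, depth: float = 80.0
) -> Dict[str, float]:
    """Span gap-estimate calibration over simulated two-contig junctions.

    Each junction: two 600 bp contigs separated by a known gap in
    [20, 200]; reads simulated over the joined genome at the given
    depth. Junctions are generated until ``n_junctions`` of them carry
    an edge with support >= 10 (wide gaps near the insert size are
    inherently support-poor, so a few draws do not qualify).
    """
    rng = np.random.default_rng(seed)
    max_attempts = 3 * n_junctions
    children = _spawn_seeds(seed, max_attempts)
    errors = []
    supports = []
    from .contigs import Contig

    for j in range(max_attempts):
        if len(errors) >= n_junctions:
            break
        true_gap = int(rng.integers(20, 201))
        genomes = generate_genomes(
            [GenomeSpec("g", length=1200 + true_gap)], seed=int(rng.integers(2**31))
        )
        gseq = genomes[0][1]
        left = gseq[:600]
        right = gseq[600 + true_gap :]
        params = ReadSimParams(sub_error_rate=0.0, rng_seed=seed)
        reads, _ = sample_from_depths(genomes, [depth], params, children[j])
        contigs = [
            Contig(0, left, depth, len(left) - 30),
            Contig(1, right, depth, len(right) - 30),
        ]
        alns = align_reads_to_contigs(reads, contigs, seed_len=31)
        edges = build_edges(alns, contigs, 270.0, 30.0, min_edge_support=2)
        for e in edges:
            ends = {e.end_a, e.end_b}
            if ends == {(0, "R"), (1, "L")} and e.support >= 10:
                errors.append(abs(e.gap - true_gap))
                supports.append(e.support)
    return {
        "n_junctions_measured": len(errors),
        "mean_abs_gap_error": float(np.mean(errors)) if errors else float("nan"),
        "mean_support": float(np.mean(supports)) if supports else 0.0,
    }


def shatter_experiment(seed: int) -> Dict[str, float]:
    """A 10 kb genome shattered into 4 contigs: paired reads should
    rescaffold it into one sequence nearly identical to the truth."""
    genomes = generate_genomes([GenomeSpec("g0", length=10000)], seed=seed)
    gseq = genomes[0][1]
    params = ReadSimParams(sub_error_rate=0.0, rng_seed=seed)
    reads, _ = sample_from_depths(genomes, [30.0], params, seed)
    from .contigs import Contig

    cuts = [(0, 2400), (2480, 5000), (5090, 7500), (7560, 10000)]
    contigs = [
        Contig(i, gseq[a:b], 30.0, b - a - 30) for i, (a, b) in enumerate(cuts)
    ]
    out = {}
    for rounds in (1, 2):
        config = AssemblyConfig(
            k_list=[21, 33, 55], scaffold_rounds=rounds, rng_seed=seed
        )
        scaffolds = scaffold_rounds(contigs, reads, config)
        out[f"n_scaffolds_round{rounds}"] = len(scaffolds)
        if rounds == 2:
            asm = [(s.id, s.sequence) for s in scaffolds]
            blocks = align_contigs_to_refs(asm, genomes)
            total = sum(b.length for b in blocks)
            out["identity"] = (
                sum(b.identity * b.length for b in blocks) / total if total else 0.0
            )
            out["fraction"] = genome_fraction(blocks, genomes[0])
    return out


# ---------------------------------------------------------------------------


def strain_specific_fraction(
    assembly: Sequence[Tuple[str, str]],
    refs: Sequence[Tuple[str, str]],
    strain_id: str,
) -> float:
    """Percent of the strain reference covered by contigs whose best
    reference (by matched bases) is the strain itself."""
    blocks = align_contigs_to_refs(assembly, refs)
    score: Dict[str, Dict[str, float]] = {}
    for b in blocks:
        score.setdefault(b.contig_id, {}).setdefault(b.ref_id, 0.0)
        score[b.contig_id][b.ref_id] += b.identity * b.length
    strain_best = {
        cid
        for cid, per_ref in score.items()
        if max(sorted(per_ref), key=lambda r: per_ref[r]) == strain_id
    }
    strain_ref = next((r for r in refs if r[0] == strain_id))
    keep = [b for b in blocks if b.contig_id in strain_best and b.ref_id == strain_id]
    return genome_fraction(keep, strain_ref)


def strain_experiment(seed: int) -> Dict[str, float]:
    """Strain collapse under coassembly.

    A parent genome and a 1%-divergent strain. The coassembly pools
    four samples in which the parent outweighs the strain 10:1
    (30x vs 3x); a separate strain-enriched sample (strain 30x, parent
    3x) is assembled alone. Reported: the strain-specific fraction
    (bases attributed uniquely to the strain) under each approach.
    """
    genomes = generate_genomes(
        [
            GenomeSpec("parent", length=20000),
            GenomeSpec("strain", derived_from="parent", divergence=0.01),
        ],
        seed=seed,
    )
    params = ReadSimParams(sub_error_rate=0.005, rng_seed=seed)
    children = _spawn_seeds(seed, N_SAMPLES + 1)
    config = AssemblyConfig(k_list=[21, 33], rng_seed=seed)

    co_reads = []
    for s in range(N_SAMPLES):
        reads, _ = sample_from_depths(
            genomes, [30.0, 3.0], params, children[s], sample_name=f"s{s}"
        )
        co_reads.extend(reads)
    enriched_reads, _ = sample_from_depths(
        genomes, [3.0, 30.0], params, children[N_SAMPLES], sample_name="enr"
    )

    co = _eval_asm(_assemble(co_reads, config))
    enriched = _eval_asm(_assemble(enriched_reads, config))
    return {
        "co_strain_specific_fraction": strain_specific_fraction(
            co, genomes, "strain"
        ),
        "enriched_strain_specific_fraction": strain_specific_fraction(
            enriched, genomes, "strain"
        ),
    }
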