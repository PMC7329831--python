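"""Ground-truthed synthetic metagenome communities and paired reads.

The simulator emulates a multi-sample injection design: a base
community abundance profile is drawn from a lognormal distribution and
perturbed per sample with lognormal replicate noise, so all samples
share a correlated community structure. Reads are 150 bp pairs with
insert sizes Normal(270, 30) by default, substitution-only errors, and
headers carrying ``genome=<id> pos=<start>`` provenance tokens — the
ground truth that chimericity and per-depth evaluation rely on.
Everything is deterministic per seed, with per-sample sub-seeds spawned
from (seed, sample index).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import Read, write_fasta, write_fastq
from .sequtils import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSpec:
    """Recipe for one synthetic genome.

    Either a random sequence of ``length`` at the requested ``gc``,
    optionally with ``repeat_len`` x ``repeat_copies`` planted exact
    repeats, or a strain derived from ``derived_from`` by i.i.d.
    substitutions at rate ``divergence``.
    """

    genome_id: str
    length: int = 10000
    gc: float = 0.5
    repeat_len: int = 0
    repeat_copies: int = 0
    derived_from: Optional[str] = None
    divergence: float = 0.0


@dataclass
class ReadSimParams:
    read_len: int = 150
    insert_mu: float = 270.0
    insert_sigma: float = 30.0
    sub_error_rate: float = 0.0
    mean_qual: int = 38
    qual_jitter: int = 3
    rng_seed: int = 1

    def __post_init__(self):
        if not 0.0 <= self.sub_error_rate <= 0.1:
            raise ValueError("sub_error_rate must lie in [0, 0.1]")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    arr = rng.choice(_BASES, size=length, p=probs)
    return arr.tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    idx = np.where(mask)[0]
    if len(idx):
        # replace with one of the three other bases
        cur = arr[idx]
        shift = rng.integers(1, 4, size=len(idx))
        base_idx = np.searchsorted(_BASES, cur)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def generate_genomes(
    specs: Sequence[GenomeSpec], seed: int = 1
) -> List[Tuple[str, str]]:
    """Deterministically generate genome sequences from specs.

    Strains must reference an earlier genome in the list.
    """
    out: List[Tuple[str, str]] = []
    seqs: Dict[str, str] = {}
    children = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        if spec.derived_from is not None:
            if spec.derived_from not in seqs:
                raise ValueError(
                    f"{spec.genome_id}: parent {spec.derived_from!r} not defined"
                )
            seq = _mutate(rng, seqs[spec.derived_from], spec.divergence)
        else:
            seq = _random_seq(rng, spec.length, spec.gc)
            if spec.repeat_len and spec.repeat_copies >= 2:
                rep = _random_seq(rng, spec.repeat_len, spec.gc)
                gap = len(seq) // (spec.repeat_copies + 1)
                for i in range(spec.repeat_copies):
                    pos = (i + 1) * gap
                    seq = seq[:pos] + rep + seq[pos + spec.repeat_len :]
        seqs[spec.genome_id] = seq
        out.append((spec.genome_id, seq))
    return out


def draw_abundances(
    n_genomes: int, mu: float = 1.0, sigma: float = 2.0, seed: int = 1
) -> np.ndarray:
    """Base community profile: normalized lognormal(mu, sigma) draws."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=mu, sigma=sigma, size=n_genomes)
    return draws / draws.sum()


def replicate_samples(
    base_abundance: Sequence[float],
    n_samples: int,
    replicate_sigma: float,
    seed: int = 1,
) -> np.ndarray:
    """Per-sample profiles: base * lognormal(0, replicate_sigma) noise,
    renormalized, so samples are noisy replicates of one community."""
    base = np.asarray(base_abundance, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, len(base)))
    for s in range(n_samples):
        if replicate_sigma > 0:
            noise = rng.lognormal(mean=0.0, sigma=replicate_sigma, size=len(base))
        else:
            noise = np.ones(len(base))
        row = base * noise
        out[s] = row / row.sum()
    return out


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    abundances: np.ndarray
    read_origins: List[Tuple[str, str, int, str]]  # (read id, genome, pos, strand)
    bases_per_genome: Dict[str, int]


def simulate_sample(
    genomes: Sequence[Tuple[str, str]],
    abundances: Sequence[float],
    n_pairs: int,
    params: ReadSimParams,
    seed,
    sample_name: str = "s0",
) -> Tuple[List[Read], SampleTruth]:
    """Simulate one sample's read pairs.

    A pair's genome is chosen with probability proportional to
    abundance x genome length; the fragment start is uniform and the
    insert Normal(insert_mu, insert_sigma), truncated to
    [read_len, genome length]. R1 is the fragment prefix and R2 the
    reverse complement of the fragment suffix. Substitution errors are
    i.i.d. with the erroneous base's Phred drawn low.
    """
    rng = np.random.default_rng(seed)
    rl = params.read_len
    names = [g for g, _ in genomes]
    seqs = {g: s for g, s in genomes}
    lens = np.array([len(s) for _g, s in genomes], dtype=float)
    ab = np.asarray(abundances, dtype=float)
    weights = ab * lens
    weights = weights / weights.sum()

    gidx = rng.choice(len(genomes), size=n_pairs, p=weights)
    reads: List[Read] = []
    origins: List[Tuple[str, str, int, str]] = []
    bases: Dict[str, int] = {g: 0 for g in names}

    def make_seq(template: str) -> Tuple[str, List[int]]:
        arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
        quals = np.clip(
            np.rint(rng.normal(params.mean_qual, params.qual_jitter, len(arr))),
            2,
            41,
        ).astype(int)
        if params.sub_error_rate > 0:
            mask = rng.random(len(arr)) < params.sub_error_rate
            idx = np.where(mask)[0]
            if len(idx):
                cur = np.searchsorted(_BASES, arr[idx])
                shift = rng.integers(1, 4, size=len(idx))
                arr[idx] = _BASES[(cur + shift) % 4]
                quals[idx] = rng.integers(2, 21, size=len(idx))
        return arr.tobytes().decode(), quals.tolist()

    for n in range(n_pairs):
        gid = names[gidx[n]]
        gseq = seqs[gid]
        glen = len(gseq)
        for _attempt in range(100):
            insert = int(round(rng.normal(params.insert_mu, params.insert_sigma)))
            insert = max(insert, rl)
            if insert <= glen:
                break
        else:
            insert = min(glen, rl)
        start = int(rng.integers(0, glen - insert + 1))
        frag = gseq[start : start + insert]
        pid = f"{sample_name}p{n}"
        r1_seq, r1_q = make_seq(frag[:rl])
        r2_seq, r2_q = make_seq(revcomp(frag)[:rl])
        reads.append(
            Read(
                id=f"{pid}/1", sequence=r1_seq, quals=r1_q, mate="R1",
                pair_id=pid, provenance=gid,
            )
        )
        reads.append(
            Read(
                id=f"{pid}/2", sequence=r2_seq, quals=r2_q, mate="R2",
                pair_id=pid, provenance=gid,
            )
        )
        origins.append((f"{pid}/1", gid, start, "+"))
        origins.append((f"{pid}/2", gid, start + insert - rl, "-"))
        bases[gid] += 2 * rl
    truth = SampleTruth(
        abundances=np.asarray(abundances, dtype=float),
        read_origins=origins,
        bases_per_genome=bases,
    )
    return reads, truth


def simulate_reads(
    genomes: Sequence[Tuple[str, str]],
    sample_abundances: np.ndarray,
    params: ReadSimParams,
    pairs_per_sample: Sequence[int],
) -> Tuple[List[List[Read]], List[SampleTruth]]:
    """Simulate all samples with sub-seeds spawned from the base seed."""
    n_samples = len(sample_abundances)
    children = np.random.SeedSequence(params.rng_seed).spawn(n_samples)
    all_reads: List[List[Read]] = []
    truths: List[SampleTruth] = []
    for s in range(n_samples):
        reads, truth = simulate_sample(
            genomes,
            sample_abundances[s],
            int(pairs_per_sample[s]),
            params,
            children[s],
            sample_name=f"s{s}",
        )
        all_reads.append(reads)
        truths.append(truth)
    return all_reads, truths


def sample_from_depths(
    genomes: Sequence[Tuple[str, str]],
    depths: Sequence[float],
    params: ReadSimParams,
    seed,
    sample_name: str = "s0",
) -> Tuple[List[Read], SampleTruth]:
    """Simulate one sample targeting an expected per-genome depth.

    Depth d on a genome of length L contributes d*L/(2*read_len)
    expected pairs; abundances proportional to depth deliver them.
    """
    lens = np.array([len(s) for _g, s in genomes], dtype=float)
    depths = np.asarray(depths, dtype=float)
    n_pairs = int(round((depths * lens).sum() / (2 * params.read_len)))
    ab = depths / depths.sum()
    return simulate_sample(genomes, ab, n_pairs, params, seed, sample_name)


def realized_depths(
    truth: SampleTruth, genomes: Sequence[Tuple[str, str]]
) -> Dict[str, float]:
    return {
        g: truth.bases_per_genome.get(g, 0) / len(s) for g, s in genomes
    }


def write_truth(
    out_dir: str,
    genomes: Sequence[Tuple[str, str]],
    sample_abundances: np.ndarray,
    truths: Sequence[SampleTruth],
) -> None:
    """Write the ground-truth manifest (genomes, abundances, read origins)."""
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    write_fasta(genomes, os.path.join(truth_dir, "genomes.fasta"))
    with open(os.path.join(truth_dir, "abundances.tsv"), "w") as fh:
        fh.write("sample\tgenome\tabundance\trealized_depth\n")
        for s, truth in enumerate(truths):
            depths = realized_depths(truth, genomes)
            for (g, _seq), ab in zip(genomes, sample_abundances[s]):
                fh.write(f"s{s}\t{g}\t{ab:.6g}\t{depths[g]:.4f}\n")
    with open(os.path.join(truth_dir, "reads.tsv"), "w") as fh:
        fh.write("read_id\tgenome\tpos\tstrand\n")
        for truth in truths:
            for rid, g, pos, strand in truth.read_origins:
                fh.write(f"{rid}\t{g}\t{pos}\t{strand}\n")


def write_sample_fastqs(
    out_dir: str, sample_reads: Sequence[List[Read]], gzip_out: bool = True
) -> List[Tuple[str, str]]:
    """Write per-sample R1/R2 FASTQ files; returns the path pairs."""
    os.makedirs(out_dir, exist_ok=True)
    ext = ".fastq.gz" if gzip_out else ".fastq"
    paths = []
    for s, reads in enumerate(sample_reads):
        p1 = os.path.join(out_dir, f"sample_{s}_R1{ext}")
        p2 = os.path.join(out_dir, f"sample_{s}_R2{ext}")
        write_fastq([r for r in reads if r.mate == "R1"], p1)
        write_fastq([r for r in reads if r.mate == "R2"], p2)
        paths.append((p1, p2))
    return paths
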