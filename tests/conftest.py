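"""Shared fixtures: independent oracles and session-scoped experiments."""

from __future__ import annotations

import numpy as np
import pytest

from coasm.io import Read

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_kmer_table(reads, k, qual_floor=20, min_count=2):
    """Brute-force dictionary k-mer counter: the oracle for the Bloom
    two-pass scheme. Returns {kmer: (count, left dict, right dict)}
    with singletons removed; written independently of the package's
    counting code path.
    """
    table = {}
    for read in reads:
        seq = read.sequence
        quals = read.quals
        # maximal N-free stretches with their offsets
        stretches = []
        start = None
        for i, c in enumerate(seq + "N"):
            if c == "N":
                if start is not None:
                    stretches.append((start, seq[start:i]))
                    start = None
            elif start is None:
                start = i
        for off, stretch in stretches:
            for i in range(len(stretch) - k + 1):
                window = stretch[i : i + k]
                flip = rc(window) < window
                canon = rc(window) if flip else window
                if canon not in table:
                    table[canon] = [0, {}, {}]
                entry = table[canon]
                entry[0] += 1
                left = (stretch[i - 1], quals[off + i - 1]) if i > 0 else None
                right = (
                    (stretch[i + k], quals[off + i + k])
                    if i + k < len(stretch)
                    else None
                )
                if flip:
                    left, right = (
                        (_COMP[right[0]], right[1]) if right else None,
                        (_COMP[left[0]], left[1]) if left else None,
                    )
                for side, flank in ((1, left), (2, right)):
                    if flank is not None and flank[1] >= qual_floor:
                        entry[side][flank[0]] = entry[side].get(flank[0], 0) + 1
    return {
        kmer: (c, l, r)
        for kmer, (c, l, r) in table.items()
        if c >= min_count
    }


def tiling_reads(seq: str, read_len: int = 100, stride: int = 20, copies: int = 2):
    """Error-free reads tiling a sequence so every k-mer occurs >= copies."""
    reads = []
    n = 0
    positions = list(range(0, max(1, len(seq) - read_len + 1), stride))
    if positions[-1] != len(seq) - read_len and len(seq) > read_len:
        positions.append(len(seq) - read_len)
    for _c in range(copies):
        for p in positions:
            chunk = seq[p : p + read_len]
            reads.append(
                Read(
                    id=f"t{n}",
                    sequence=chunk,
                    quals=[40] * len(chunk),
                )
            )
            n += 1
    return reads


def random_dna(rng, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- session-scoped experiment results (shared across acceptance tests) -----


@pytest.fixture(scope="session")
def recon_clean():
    from coasm.experiments import reconstruction_experiment

    return reconstruction_experiment(1, error_rate=0.0)


@pytest.fixture(scope="session")
def recon_errors():
    from coasm.experiments import reconstruction_experiment

    return reconstruction_experiment(1, error_rate=0.005)


@pytest.fixture(scope="session")
def community_result():
    from coasm.experiments import community_experiment

    return community_experiment(1)


@pytest.fixture(scope="session")
def strain_result():
    from coasm.experiments import strain_experiment

    return strain_experiment(1)


@pytest.fixture(scope="session")
def gap_result():
    from coasm.experiments import gap_calibration_experiment

    return gap_calibration_experiment(1)


@pytest.fixture(scope="session")
def shatter_result():
    from coasm.experiments import shatter_experiment

    return shatter_experiment(1)
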