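"""Canonical k-mer extraction and Bloom-filtered two-pass counting.

k-mers are stored in canonical form (the lexicographic minimum of the
k-mer and its reverse complement); k must be odd so no k-mer is its own
reverse complement. Counting is two-pass: the first pass inserts every
k-mer into a Bloom filter and promotes to the exact table only k-mers
already present in the filter (i.e. seen at least twice, modulo false
positives); the second pass counts the promoted k-mers exactly and
accumulates the per-side single-base extension counts, gated on the
flanking base's Phred quality. Finalization drops records below
``min_count``, which also removes any singleton promoted by a Bloom
false positive — the retained counts are therefore exactly those of a
naive full-dictionary counter. Because low-count k-mers are
overwhelmingly sequencing errors, this scheme removes errors without
any read preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .io import Read
from .sequtils import BASES, BASE_INDEX, COMP_INDEX, revcomp

FORK = "FORK"
DEADEND = "DEADEND"

_B2I = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T (byte values)
_I2B = b"ACGT"


def canonicalize(seq: str) -> str:
    """Canonical form of a k-mer: min(seq, revcomp(seq)).

    Requires odd length and no N (split reads at N before calling).
    Idempotent, and invariant under reverse complement of the input.
    """
    if len(seq) % 2 == 0:
        raise ValueError(f"k must be odd, got k={len(seq)}")
    if "N" in seq:
        raise ValueError("k-mer contains N; split the read at Ns first")
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class KmerRecord:
    """A canonical k-mer with its count and per-side extension counts.

    ``left_ext``/``right_ext`` count high-quality flanking bases seen
    immediately before/after the k-mer in its canonical orientation.
    """

    kmer: str
    count: int
    left_ext: Dict[str, int]
    right_ext: Dict[str, int]


def hq_extension(record: KmerRecord, side: str, threshold: int):
    """Decide the traversal step at one side of a k-mer.

    Returns the unique base whose extension count is >= ``threshold``,
    or :data:`FORK` if two or more bases qualify, or :data:`DEADEND`
    if none does.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    ext = record.left_ext if side == "left" else record.right_ext
    hits = [b for b in BASES if ext.get(b, 0) >= threshold]
    if not hits:
        return DEADEND
    if len(hits) > 1:
        return FORK
    return hits[0]


class KmerTable:
    """Mapping canonical k-mer -> (count, left extensions, right extensions).

    Internal storage is ``bytes -> [count, [4 left counts], [4 right
    counts]]`` for speed; the :class:`KmerRecord` view is built on
    access.
    """

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self._data: Dict[bytes, list] = {}
        self.stats: Dict[str, int] = {"windows": 0, "kept": 0, "dropped_low_count": 0}

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, kmer) -> bool:
        if isinstance(kmer, str):
            kmer = kmer.encode()
        return kmer in self._data

    def raw(self, kmer_bytes: bytes):
        return self._data.get(kmer_bytes)

    def get(self, kmer) -> Optional[KmerRecord]:
        if isinstance(kmer, str):
            kb = kmer.encode()
        else:
            kb = kmer
        entry = self._data.get(kb)
        if entry is None:
            return None
        return KmerRecord(
            kmer=kb.decode(),
            count=entry[0],
            left_ext={BASES[i]: entry[1][i] for i in range(4) if entry[1][i]},
            right_ext={BASES[i]: entry[2][i] for i in range(4) if entry[2][i]},
        )

    def sorted_kmers(self) -> List[bytes]:
        return sorted(self._data)

    def records(self) -> Iterator[KmerRecord]:
        for kb in self.sorted_kmers():
            yield self.get(kb)

    def add_counts(
        self, kmer_bytes: bytes, count: int, left: Optional[Tuple[int, int]] = None,
        right: Optional[Tuple[int, int]] = None,
    ) -> None:
        """Additively merge ``count`` occurrences plus optional extension
        evidence ``(base_index, count)`` on either side."""
        entry = self._data.get(kmer_bytes)
        if entry is None:
            entry = [0, [0, 0, 0, 0], [0, 0, 0, 0]]
            self._data[kmer_bytes] = entry
        entry[0] += count
        if left is not None:
            entry[1][left[0]] += left[1]
        if right is not None:
            entry[2][right[0]] += right[1]

    def merge_add(self, other: "KmerTable") -> None:
        if other.k != self.k:
            raise ValueError(f"cannot merge k={other.k} into k={self.k}")
        for kb, entry in other._data.items():
            mine = self._data.get(kb)
            if mine is None:
                self._data[kb] = [entry[0], list(entry[1]), list(entry[2])]
            else:
                mine[0] += entry[0]
                for i in range(4):
                    mine[1][i] += entry[1][i]
                    mine[2][i] += entry[2][i]

    def finalize(self, min_count: int) -> None:
        drop = [kb for kb, e in self._data.items() if e[0] < min_count]
        for kb in drop:
            del self._data[kb]
        self.stats["dropped_low_count"] += len(drop)
        self.stats["kept"] = len(self._data)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write("kmer\tcount\tACGT_left\tACGT_right\n")
            for kb in self.sorted_kmers():
                e = self._data[kb]
                out.write(
                    f"{kb.decode()}\t{e[0]}\t"
                    f"{','.join(map(str, e[1]))}\t{','.join(map(str, e[2]))}\n"
                )


class BloomFilter:
    """Plain bit-array Bloom filter keyed on Python's bytes hash.

    Correctness of the pipeline does not depend on the false-positive
    rate: a false positive can only promote a singleton k-mer, which
    finalization removes. The filter only bounds the memory of the
    exact table.
    """

    def __init__(self, expected_items: int, bits_per_item: int = 10, n_hashes: int = 4):
        self.m = max(1024, expected_items * bits_per_item)
        self.n_hashes = n_hashes
        self._bits = bytearray((self.m + 7) // 8)

    def add_and_test(self, item: bytes) -> bool:
        """Insert ``item``; return True iff it was (apparently) present."""
        h = hash(item)
        h1 = h & 0xFFFFFFFFFFFFFFFF
        h2 = ((h >> 7) * 0x9E3779B97F4A7C15 + 1) & 0xFFFFFFFFFFFFFFFF | 1
        bits = self._bits
        m = self.m
        present = True
        for i in range(self.n_hashes):
            idx = (h1 + i * h2) % m
            byte, mask = idx >> 3, 1 << (idx & 7)
            if not bits[byte] & mask:
                present = False
                bits[byte] |= mask
        return present


def _stretches(seq: str) -> Iterator[Tuple[int, str]]:
    """Maximal N-free stretches of a read as (offset, substring)."""
    start = None
    for i, c in enumerate(seq):
        if c == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


def extract_kmers(read: Read, k: int):
    """Enumerate canonical k-mer windows of a read with their flanks.

    Yields ``(canonical_kmer, left, right)`` where ``left``/``right``
    are ``(base, phred)`` tuples oriented to match the canonical k-mer
    (swapped and complemented when the window was reverse-complemented)
    or ``None`` at the stretch boundary. The quality gate is applied by
    the counter, not here.
    """
    out = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    quals = read.quals
    for off, stretch in _stretches(read.sequence):
        L = len(stretch)
        if L < k:
            continue
        rc = revcomp(stretch)
        for i in range(L - k + 1):
            fwd = stretch[i : i + k]
            rev = rc[L - k - i : L - i]
            lb = (stretch[i - 1], quals[off + i - 1]) if i > 0 else None
            rb = (stretch[i + k], quals[off + i + k]) if i + k < L else None
            if fwd <= rev:
                out.append((fwd, lb, rb))
            else:
                left = (comp[rb[0]], rb[1]) if rb else None
                right = (comp[lb[0]], lb[1]) if lb else None
                out.append((rev, left, right))
    return out


def count_kmers(
    reads: Iterable[Read],
    k: int,
    qual_floor: int = 20,
    min_count: int = 2,
    bloom_bits_per_item: int = 10,
) -> KmerTable:
    """Exact singleton-filtered k-mer counts via the two-pass Bloom scheme.

    Pass 1 streams all canonical k-mers through a Bloom filter and
    promotes repeat sightings to an exact set; pass 2 recounts the
    promoted k-mers exactly, accumulating extension counts for flanking
    bases with Phred >= ``qual_floor``. After finalization the table
    equals a naive dictionary counter with singletons removed.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not isinstance(reads, (list, tuple)):
        reads = list(reads)

    total_bases = sum(len(r.sequence) for r in reads)
    bloom = BloomFilter(max(total_bases, 1), bits_per_item=bloom_bits_per_item)
    promoted: set = set()
    table = KmerTable(k)
    windows = 0

    # pass 1: promotion
    for read in reads:
        seq = read.sequence
        for _off, stretch in _stretches(seq):
            L = len(stretch)
            if L < k:
                continue
            sb = stretch.encode()
            rb = revcomp(sb)
            for i in range(L - k + 1):
                fwd = sb[i : i + k]
                rev = rb[L - k - i : L - i]
                canon = fwd if fwd <= rev else rev
                windows += 1
                if bloom.add_and_test(canon):
                    promoted.add(canon)

    # pass 2: exact counting of promoted k-mers with gated extensions
    data = table._data
    for read in reads:
        quals = read.quals
        for off, stretch in _stretches(read.sequence):
            L = len(stretch)
            if L < k:
                continue
            sb = stretch.encode()
            rb = revcomp(sb)
            last = L - k
            for i in range(last + 1):
                fwd = sb[i : i + k]
                rev = rb[L - k - i : L - i]
                if fwd <= rev:
                    canon, flipped = fwd, False
                else:
                    canon, flipped = rev, True
                if canon not in promoted:
                    continue
                entry = data.get(canon)
                if entry is None:
                    entry = [0, [0, 0, 0, 0], [0, 0, 0, 0]]
                    data[canon] = entry
                entry[0] += 1
                if i > 0 and quals[off + i - 1] >= qual_floor:
                    bi = _B2I[sb[i - 1]]
                    if flipped:
                        entry[2][COMP_INDEX[bi]] += 1
                    else:
                        entry[1][bi] += 1
                if i < last and quals[off + i + k] >= qual_floor:
                    bi = _B2I[sb[i + k]]
                    if flipped:
                        entry[1][COMP_INDEX[bi]] += 1
                    else:
                        entry[2][bi] += 1

    table.stats["windows"] = windows
    table.finalize(min_count)
    return table
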