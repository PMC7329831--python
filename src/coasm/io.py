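"""FASTQ/FASTA readers and writers.

FASTQ is Phred+33 only (the modern default). Gzip is handled
transparently by extension sniffing. Paired input is either two files
paired positionally or a single interleaved file. Read headers produced
by the simulator carry a ``genome=<id>`` token in the comment field;
when present it is parsed into :attr:`Read.provenance` so that
chimericity can be computed downstream.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sequtils import revcomp

_PROVENANCE_RE = re.compile(r"genome=(\S+)")
_MATE_SUFFIX_RE = re.compile(r"/[12]$")


class FastqError(ValueError):
    """Malformed or inconsistent FASTQ input."""


@dataclass
class Read:
    """A single sequencing read.

    ``mate`` is one of ``"R1"``, ``"R2"`` or ``"unpaired"``; mates of a
    pair share ``pair_id``. ``provenance`` is the source genome id for
    simulated reads, parsed from the header, or ``None``.
    """

    id: str
    sequence: str
    quals: Sequence[int]
    mate: str = "unpaired"
    pair_id: str = ""
    provenance: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise FastqError(f"read {self.id!r}: empty sequence")
        if len(self.quals) != len(self.sequence):
            raise FastqError(
                f"read {self.id!r}: {len(self.quals)} quality scores for "
                f"{len(self.sequence)} bases"
            )
        if not self.pair_id:
            self.pair_id = _MATE_SUFFIX_RE.sub("", self.id)


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq_records(path: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (title, seq, qual-string); wrap parser errors with context."""
    count = 0
    try:
        with _open_text(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                count += 1
                yield title, seq, qual
    except ValueError as exc:
        raise FastqError(
            f"{path}: bad FASTQ record at index {count}: {exc}"
        ) from exc


def _make_read(title: str, seq: str, qual: str, mate: str, pair_id: str = "") -> Read:
    name = title.split(None, 1)
    rid = name[0]
    comment = name[1] if len(name) > 1 else ""
    m = _PROVENANCE_RE.search(comment)
    return Read(
        id=rid,
        sequence=seq.upper(),
        quals=[ord(c) - 33 for c in qual],
        mate=mate,
        pair_id=pair_id,
        provenance=m.group(1) if m else None,
    )


def read_fastq(
    path1: str,
    path2: Optional[str] = None,
    interleaved: bool = False,
) -> Iterator[Read]:
    """Stream reads from one or two FASTQ files.

    Two files are paired positionally; ``interleaved=True`` pairs
    consecutive records of a single file. A mate-count mismatch between
    the two files raises :class:`FastqError`.
    """
    if path2 is not None:
        it1 = _parse_fastq_records(path1)
        it2 = _parse_fastq_records(path2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                short = path1 if r1 is None else path2
                raise FastqError(
                    f"mate-count mismatch: {short} has fewer records"
                )
            read1 = _make_read(*r1, mate="R1")
            yield read1
            yield _make_read(*r2, mate="R2", pair_id=read1.pair_id)
    elif interleaved:
        it = _parse_fastq_records(path1)
        while True:
            r1 = next(it, None)
            if r1 is None:
                return
            r2 = next(it, None)
            if r2 is None:
                raise FastqError(
                    f"{path1}: odd record count in interleaved input"
                )
            read1 = _make_read(*r1, mate="R1")
            yield read1
            yield _make_read(*r2, mate="R2", pair_id=read1.pair_id)
    else:
        for rec in _parse_fastq_records(path1):
            yield _make_read(*rec, mate="unpaired")


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with _open_text(path, "wt") as out:
        for r in reads:
            header = r.id
            if r.provenance is not None:
                header += f" genome={r.provenance}"
            qual = "".join(chr(q + 33) for q in r.quals)
            out.write(f"@{header}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(
    records: Iterable[Tuple[str, str]], path: str, wrap: int = 80
) -> None:
    """Write (id, sequence) records as wrapped FASTA; ids must be unique.

    The id field may contain a description after the first whitespace.
    """
    seen = set()
    with _open_text(path, "wt") as out:
        for rid, seq in records:
            key = rid.split()[0]
            if key in seen:
                raise ValueError(f"duplicate FASTA id {key!r}")
            seen.add(key)
            out.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                out.write(seq[i : i + wrap] + "\n")


def read_fasta(path: str) -> list[Tuple[str, str]]:
    with _open_text(path) as handle:
        return [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")
        ]
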