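"""Reference-based assembly evaluation and multiassembly handling.

Metrics mirror standard reference-based assembly assessment: genome
fraction (percent of a reference covered by at least one alignment
block), duplication ratio (total assembly bases aligned to a
reference divided by the reference length — overlaps count multiply,
so concatenating per-sample assemblies inflates it), per-depth genome
fraction, cumulative aligned-length curves, and chimericity — the
Shannon entropy -sum(p_i ln p_i) of the proportions p_i of a contig's
reads that came from each source genome (0 for a pure contig).

The reference aligner is a desk-scale anchor-and-chain comparator:
exact anchor k-mers grouped per (reference, orientation, diagonal) and
merged into maximal blocks. It is substitution-aware but not
indel-aware, which matches the substitution-only simulator and the
ungapped assembler upstream.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contigs import Contig
from .io import Read
from .scaffold import align_reads_to_contigs
from .sequtils import revcomp


@dataclass
class RefAlignment:
    """One collinear alignment block of a contig against a reference."""

    contig_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int
    orient: str
    identity: float

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ProvenanceProfile:
    """Per-contig counts of reads by source genome; p_i = count_i/total."""

    contig_id: str
    counts: Dict[str, int]

    def proportions(self) -> Dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError(f"contig {self.contig_id}: empty provenance profile")
        return {g: c / total for g, c in self.counts.items() if c > 0}


def chimericity(profile: ProvenanceProfile) -> float:
    """Entropy of the read-origin proportions, natural log; 0 iff pure."""
    p = profile.proportions()
    return -sum(v * math.log(v) for v in p.values() if v > 0)


def is_chimeric(profile: ProvenanceProfile) -> bool:
    return sum(1 for c in profile.counts.values() if c > 0) >= 2


# ---------------------------------------------------------------------------
# contig-to-reference alignment


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def align_contigs_to_refs(
    contigs: Sequence[Tuple[str, str]],
    refs: Sequence[Tuple[str, str]],
    anchor_len: int = 31,
    min_identity: float = 0.95,
    chain_gap: int = 60,
    max_hits_per_anchor: int = 10,
) -> List[RefAlignment]:
    """Anchor-and-chain alignment of contigs against references.

    Exact ``anchor_len``-mers shared between contig and reference are
    grouped per (reference, orientation, diagonal); anchor runs closer
    than ``chain_gap`` are merged into blocks, and each block's
    identity is computed base-by-base over its span. Blocks below
    ``min_identity`` are dropped.
    """
    index: Dict[str, List[Tuple[int, int]]] = {}
    ref_arrays = []
    for ri, (rid, rseq) in enumerate(refs):
        ref_arrays.append(_seq_array(rseq))
        for p in range(0, len(rseq) - anchor_len + 1):
            key = rseq[p : p + anchor_len]
            hits = index.setdefault(key, [])
            if len(hits) < max_hits_per_anchor:
                hits.append((ri, p))

    out: List[RefAlignment] = []
    for cid, cseq in contigs:
        if len(cseq) < anchor_len:
            continue
        for orient in ("fwd", "rc"):
            q = cseq if orient == "fwd" else revcomp(cseq)
            qarr = _seq_array(q)
            qlen = len(q)
            diags: Dict[Tuple[int, int], List[int]] = {}
            for p in range(0, qlen - anchor_len + 1):
                for ri, rp in index.get(q[p : p + anchor_len], ()):
                    diags.setdefault((ri, rp - p), []).append(p)
            for (ri, diag), qpos in sorted(diags.items()):
                rid, rseq = refs[ri]
                rarr = ref_arrays[ri]
                qpos.sort()
                # split anchor positions into chains separated by > chain_gap
                chains: List[Tuple[int, int]] = []
                start = prev = qpos[0]
                for p in qpos[1:]:
                    if p - prev > chain_gap + anchor_len:
                        chains.append((start, prev + anchor_len))
                        start = p
                    prev = p
                chains.append((start, prev + anchor_len))
                for q0, q1 in chains:
                    r0, r1 = q0 + diag, q1 + diag
                    matches = int(
                        (qarr[q0:q1] == rarr[r0:r1]).sum()
                    )
                    identity = matches / (q1 - q0)
                    if identity < min_identity:
                        continue
                    if orient == "fwd":
                        c0, c1 = q0, q1
                    else:
                        c0, c1 = qlen - q1, qlen - q0
                    out.append(
                        RefAlignment(
                            contig_id=cid,
                            ref_id=rid,
                            ref_start=r0,
                            ref_end=r1,
                            contig_start=c0,
                            contig_end=c1,
                            orient=orient,
                            identity=identity,
                        )
                    )
    # a contig aligned fwd and rc over the same region (palindromic or
    # short blocks) is rare; keep all blocks, callers union intervals
    return out


def _union_length(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        if e <= last_end:
            continue
        total += e - max(s, last_end)
        last_end = e
    return total


def genome_fraction(
    alignments: Iterable[RefAlignment], ref: Tuple[str, str]
) -> float:
    """Percent of the reference covered by at least one block."""
    rid, rseq = ref
    intervals = [
        (a.ref_start, a.ref_end) for a in alignments if a.ref_id == rid
    ]
    if not intervals:
        return 0.0
    return 100.0 * _union_length(intervals) / len(rseq)


def duplication_ratio(
    alignments: Iterable[RefAlignment], ref: Tuple[str, str]
) -> float:
    """Aligned assembly bases / reference length; overlaps count multiply."""
    rid, rseq = ref
    total = sum(
        a.contig_end - a.contig_start for a in alignments if a.ref_id == rid
    )
    return total / len(rseq)


# ---------------------------------------------------------------------------
# read provenance


def assign_reads_to_contigs(
    reads: Sequence[Read],
    contigs: Sequence[Tuple[str, str]],
    seed_len: int = 31,
) -> Dict[str, ProvenanceProfile]:
    """Assign each read (with provenance) to its best-aligning contig.

    Ties between contigs are discarded; unaligned reads contribute to
    no profile.
    """
    contig_objs = [
        Contig(id=i, sequence=seq, depth=0.0, kmer_count=max(1, len(seq)))
        for i, (_cid, seq) in enumerate(contigs)
    ]
    names = [cid for cid, _seq in contigs]
    alignments = align_reads_to_contigs(reads, contig_objs, seed_len)
    reads_by_id = {r.id: r for r in reads}
    best: Dict[str, List] = {}
    for a in alignments:
        best.setdefault(a.read_id, []).append(a)
    profiles: Dict[str, ProvenanceProfile] = {
        cid: ProvenanceProfile(cid, {}) for cid in names
    }
    for rid in sorted(best):
        read = reads_by_id[rid]
        if read.provenance is None:
            continue
        alns = sorted(best[rid], key=lambda a: -a.matches)
        if len(alns) > 1 and alns[0].matches == alns[1].matches and (
            alns[0].contig_id != alns[1].contig_id
        ):
            continue  # ambiguous
        cname = names[alns[0].contig_id]
        counts = profiles[cname].counts
        counts[read.provenance] = counts.get(read.provenance, 0) + 1
    return {cid: p for cid, p in profiles.items() if p.counts}


# ---------------------------------------------------------------------------
# multiassembly


def multiassembly(
    per_sample_assemblies: Sequence[Sequence[Tuple[str, str]]],
) -> List[Tuple[str, str]]:
    """Concatenate per-sample assemblies with sample-prefixed ids."""
    out = []
    for s, assembly in enumerate(per_sample_assemblies):
        for cid, seq in assembly:
            out.append((f"s{s}.{cid}", seq))
    return out


def dedupe(
    assembly: Sequence[Tuple[str, str]],
    containment_identity: float = 1.0,
) -> List[Tuple[str, str]]:
    """Remove contigs contained in a longer retained contig.

    Processing longest-first, a contig is dropped when its sequence (or
    reverse complement) is contained in an already-retained contig at
    >= ``containment_identity``; 1.0 means exact substring containment.
    This mirrors naive multiassembly deduplication: overlapping but
    non-contained duplicates are all retained.
    """
    ordered = sorted(assembly, key=lambda r: (-len(r[1]), r[0]))
    kept: List[Tuple[str, str]] = []
    for cid, seq in ordered:
        rc = revcomp(seq)
        contained = False
        for _kid, kseq in kept:
            if len(kseq) < len(seq):
                continue
            if containment_identity >= 1.0:
                if seq in kseq or rc in kseq:
                    contained = True
                    break
            else:
                if _contained_at_identity(seq, kseq, containment_identity) or (
                    _contained_at_identity(rc, kseq, containment_identity)
                ):
                    contained = True
                    break
        if not contained:
            kept.append((cid, seq))
    kept.sort(key=lambda r: r[0])
    return kept


def _contained_at_identity(query: str, target: str, identity: float) -> bool:
    blocks = align_contigs_to_refs(
        [("q", query)], [("t", target)], min_identity=identity
    )
    covered = _union_length(
        [(b.contig_start, b.contig_end) for b in blocks]
    )
    return covered >= identity * len(query)


# ---------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    per_reference: pd.DataFrame  # ref, length, depth, genome_fraction, dup ratio
    per_contig_chimericity: pd.DataFrame
    cumulative: pd.DataFrame  # rank, aligned segment length, cumulative bp
    fraction_chimeric: float
    mean_chimericity_all: float
    mean_chimericity_chimeric: float

    def summary(self) -> dict:
        return {
            "n_references": int(len(self.per_reference)),
            "mean_genome_fraction": float(
                self.per_reference["genome_fraction"].mean()
            ),
            "mean_duplication_ratio": float(
                self.per_reference["duplication_ratio"].mean()
            ),
            "fraction_chimeric": self.fraction_chimeric,
            "mean_chimericity_all": self.mean_chimericity_all,
            "mean_chimericity_chimeric": self.mean_chimericity_chimeric,
        }

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.per_reference.to_csv(
            os.path.join(out_dir, "report.tsv"), sep="\t", index=False
        )
        self.per_contig_chimericity.to_csv(
            os.path.join(out_dir, "chimericity.tsv"), sep="\t", index=False
        )
        self.cumulative.to_csv(
            os.path.join(out_dir, "cumulative.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def filter_min_len(
    assembly: Sequence[Tuple[str, str]], min_len: int
) -> List[Tuple[str, str]]:
    """Drop contigs shorter than ``min_len`` (reference evaluators
    conventionally ignore contigs under 500 bp)."""
    return [(cid, seq) for cid, seq in assembly if len(seq) >= min_len]


_N_RUN_RE = re.compile(r"N{10,}")


def break_at_n_runs(
    assembly: Sequence[Tuple[str, str]], min_run: int = 10
) -> List[Tuple[str, str]]:
    """Split scaffolds at N-runs of >= ``min_run`` bases.

    Reference metrics are computed on the broken pieces so that
    coverage credits recovered sequence, not scaffolding joins.
    """
    pattern = re.compile("N{%d,}" % min_run) if min_run != 10 else _N_RUN_RE
    out: List[Tuple[str, str]] = []
    for cid, seq in assembly:
        parts = [p for p in pattern.split(seq) if p]
        if len(parts) <= 1:
            out.append((cid, seq))
        else:
            out.extend((f"{cid}.{i}", p) for i, p in enumerate(parts))
    return out


def report(
    assembly: Sequence[Tuple[str, str]],
    refs: Sequence[Tuple[str, str]],
    ref_depths: Optional[Dict[str, float]] = None,
    reads: Optional[Sequence[Read]] = None,
    min_identity: float = 0.95,
    seed_len: int = 31,
    min_contig_len: int = 0,
    break_n_run: int = 10,
) -> EvalReport:
    """Full evaluation of an assembly against reference genomes.

    ``ref_depths`` (realized simulated depth per genome, from the truth
    manifest) keys the genome-fraction-vs-depth table; ``reads`` with
    provenance enable the chimericity summary. For the reference
    metrics, scaffolds are first broken at N-runs of >= ``break_n_run``
    and pieces shorter than ``min_contig_len`` are excluded, as
    reference-based evaluators conventionally do (500 bp is the usual
    cutoff). Chimericity is computed on the unbroken contigs.
    """
    eval_asm = break_at_n_runs(assembly, break_n_run) if break_n_run else list(assembly)
    if min_contig_len:
        eval_asm = filter_min_len(eval_asm, min_contig_len)
    if min_contig_len:
        assembly = filter_min_len(assembly, min_contig_len)
    alignments = align_contigs_to_refs(eval_asm, refs, min_identity=min_identity)
    rows = []
    for rid, rseq in refs:
        rows.append(
            {
                "reference": rid,
                "length": len(rseq),
                "depth": (ref_depths or {}).get(rid, float("nan")),
                "genome_fraction": genome_fraction(alignments, (rid, rseq)),
                "duplication_ratio": duplication_ratio(alignments, (rid, rseq)),
            }
        )
    per_ref = pd.DataFrame(rows)

    seg_lengths = sorted(
        (a.contig_end - a.contig_start for a in alignments), reverse=True
    )
    cumulative = pd.DataFrame(
        {
            "rank": np.arange(1, len(seg_lengths) + 1),
            "aligned_length": seg_lengths,
            "cumulative_bp": np.cumsum(seg_lengths) if seg_lengths else [],
        }
    )

    chim_rows = []
    frac_chim = 0.0
    mean_all = 0.0
    mean_chim = 0.0
    if reads is not None:
        profiles = assign_reads_to_contigs(reads, assembly, seed_len=seed_len)
        values = []
        for cid in sorted(profiles):
            p = profiles[cid]
            h = chimericity(p)
            chim_rows.append(
                {
                    "contig": cid,
                    "n_reads": sum(p.counts.values()),
                    "n_genomes": sum(1 for c in p.counts.values() if c > 0),
                    "chimericity": h,
                }
            )
            values.append((h, is_chimeric(p)))
        if values:
            mean_all = sum(h for h, _c in values) / len(values)
            chim_vals = [h for h, c in values if c]
            frac_chim = len(chim_vals) / len(values)
            mean_chim = sum(chim_vals) / len(chim_vals) if chim_vals else 0.0
    per_contig = pd.DataFrame(
        chim_rows, columns=["contig", "n_reads", "n_genomes", "chimericity"]
    )
    return EvalReport(
        per_reference=per_ref,
        per_contig_chimericity=per_contig,
        cumulative=cumulative,
        fraction_chimeric=frac_chim,
        mean_chimericity_all=mean_all,
        mean_chimericity_chimeric=mean_chim,
    )
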