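# Methods

This note documents the models implemented in `coasm`, the parameters
that matter, the synthetic-data generator's scope, the numerical
conventions, and the designs of the canned experiments. Nothing here
states a number the test suite or `scripts/acceptance.py` does not
itself compute.

## k-mer analysis

Sequences are handled as strings over {A,C,G,T,N}; reads are split at
Ns and k-mers are stored canonically (lexicographic minimum of the
k-mer and its reverse complement). k must be odd so no k-mer equals its
own reverse complement and the canonical form is unambiguous.

Counting is two-pass. Pass 1 streams every canonical k-mer through a
Bloom filter (10 bits/item sized from total read bases, 4 hash probes
derived from Python's bytes hash); a k-mer already present is promoted
to an exact set. Pass 2 recounts promoted k-mers in an exact table.
Finalization drops records with count < `min_count` (default 2).
Consequences relied on elsewhere:

- **Exactness.** A Bloom false positive can only promote a singleton,
  which finalization removes, so the finalized table equals a naive
  dictionary counter with singletons removed. This is asserted against
  an independently written brute-force counter in the tests.
- **Process independence.** Hash randomization across processes changes
  only which singletons are transiently promoted, never the finalized
  table, so pipeline output is byte-stable across runs and processes.
- **Error removal.** Since sequencing errors are overwhelmingly
  singletons at desk-scale coverage, the count filter removes them and
  no read preprocessing is performed.

Per-side single-base extension counts are accumulated per occurrence,
in canonical orientation, only when the flanking base's Phred is
≥ `qual_floor` (default 20 ≈ 1% base-error probability, the
conventional high-quality cutoff). The k-mer's own base qualities are
not gated — only the flank's — so an extension count is evidence about
the *next* base specifically.

## Contig generation

Traversal seeds from every unused k-mer in lexicographic order and
extends in both directions; emitted contigs are in canonical
orientation, which makes assembly strand-symmetric by construction. A
step from k-mer x to successor y requires **mutual uniqueness**: y is
the only extension of x whose count reaches the adaptive threshold,
and x is the only qualifying predecessor of y. The backward check
makes convergent junctions visible from both sides regardless of
traversal order; without it a walk entering a junction from the
"straight" side would slide through silently and the graph would miss
the fork.

The adaptive threshold is t_hq(c) = max(floor, ⌈α·c⌉) with α = 0.1 and
floor = `min_count`. The linear form is the simplest monotone rule
that scales evidence demands with coverage: at coverage 10 a branch
needs 2 supporting extensions, at coverage 100 it needs 10. A side
effect worth knowing: a branch below fraction α of the local coverage
is not even a fork — it is suppressed at traversal time, which is the
main mechanism behind strain collapse in deep coassemblies (see the
strain experiment below).

The unitig graph's junctions are keyed by the canonical (k−1)-base
interface shared by a fork k-mer and its qualifying successors. Keying
by interface (rather than by fork k-mer) collapses the in-ends and
out-ends meeting at one (k−1)-overlap into a single junction, which
gives the "each contig end attaches to at most one junction" property
structurally and keeps the graph strand-symmetric.

Refinement defaults, all multiples of k so the gates track the scale
at which the graph can be confused:

| parameter | default | role |
|---|---|---|
| `bubble_len_factor` | 3 | parallel branches ≤ 3k between the same two junctions merge into the deeper one (depths summed, ties broken lexicographically) |
| `hair_len_factor` | 2 | dead-end branches ≤ 2k shallower than their junction's deepest branch are deleted |
| `prune_ratio` | 0.1 | junction links to branches < 0.1× the deepest branch are severed (contig kept) |
| `prune_max_iters` | 10 | pruning fixpoint bound |

Bubble merging keeps the higher-depth branch and adds the loser's
depth, preserving coverage mass; strain-aware bubble retention is
deliberately not attempted. After hair removal and pruning, unbranched
chains re-concatenate (k−1 overlap verified at each join) with
k-mer-count-weighted mean depth. With α = `prune_ratio` = 0.1, walk
forks rarely present branches below the prune ratio (the threshold
already suppressed them), so pruning mostly acts on depths reshaped by
bubble merging and on convergent junctions.

Local extension recruits reads sharing an exact 31-mer with the last
2×read-length bases of a contig end, verifies ungapped with ≤ 2
mismatches, assigns each read to its single best end (longest overlap,
then fewest mismatches, then proximity to the terminus; exact ties are
discarded), and extends one base at a time where ≥ 2 reads with
Phred ≥ 20 agree and no competing base has 2 votes. Voting is a pure
tally, hence independent of read order.

## The multi-k loop

Iterations run the full per-k stage for each k in `k_list` (default
[21, 33, 55] — odd values spanning common short-read practice; the
step s between consecutive k values is what contig-derived k-mers grow
by). Contigs from iteration i enter iteration i+1 as error-free
pseudo-reads: each (k+s)-mer is added with count max(`min_count`,
round(depth)) and the unique flanking extension implied by the contig,
at maximal quality. Contig evidence merges *additively* with read
evidence, so carried depth keeps the adaptive threshold meaningful
across iterations (a consequence: reported contig depth inflates
roughly by the carried amount per iteration; relative depths, which
are what refinement and scaffolding use, are preserved). Contigs
shorter than the next k cannot contribute k-mers and pass through the
iteration unchanged — without this, low-depth fragments die at the
handoff and recovery would not be monotone over iterations.

## Scaffolding

Read-to-contig alignment is seed-and-extend (31-mer seeds sampled
every 15 bases plus the read's last position, ungapped verification,
≤ 2 mismatches). A read reports at most two alignments on mostly
disjoint read intervals so splints are representable.

Edge geometry, with `tail` = contig bases between an alignment and the
linking contig end:

- splint gap = (read interval gap) − tail_left − tail_right,
- span gap = insert_μ − (tail_a + tail_b), where tails run from each
  mate's outermost (5′) base to its contig's linking end.

Span pairs implying gap < −3σ are discarded as geometrically
implausible (the spec's ±3σ insert filter cannot be applied literally
because the implied insert contains the unknown gap; the one-sided
overlap bound is its feasible part — chimeric pairs with deep-interior
alignments imply huge overlaps and are exactly what it removes).
Observations pool per oriented end pair: support = distinct
reads/pairs, gap = mean, gap_sd = sample SD; edges need support ≥
`min_edge_support` (default 2, the minimal-evidence analogue of the
count ≥ 2 rule). Splint and span evidence for the same end pair merge
as kind "both".

Traversal seeds from the longest contig down. Forks resolve by a
bounded DFS (≤ 5 edges) from each candidate: a candidate wins iff it
alone reaches a vertex whose depth is within a factor 2
(`depth_similarity_ratio`) of the running length-weighted walk depth;
fallbacks, in order: mean supporting-alignment length ≥ 2× all rivals,
support ≥ 2× all rivals; otherwise the walk ends. Conflicts between
speculatively built paths resolve by total bases (ties by seed order):
losers dissolve and their vertices re-walk in the next pass, so the
final paths are vertex-disjoint and cover every contig.

Gap closing walks from the left contig end using only the edge's
supporting reads plus their mates (15-base anchor occurrences vote;
≥ 2 high-quality agreeing reads per base), succeeding when the walk
reaches a 31-mer of the right contig; otherwise the junction is padded
with max(1, round(gap)) Ns. Negative gaps first try an exact end
overlap ≥ k−1 with ≤ 1 mismatch, preferring the overlap length closest
to the estimate. Two scaffolding rounds by default; each round feeds
scaffolds back as contigs, and the round count, depth ratio and edge
support are the user-facing contiguity-versus-error knobs.

## Synthetic data

The generator emulates a replicate multi-sample injection design:
i.i.d. random genomes at a requested GC (optionally with planted exact
repeats, or strains derived by i.i.d. substitution at a given
divergence), a lognormal base community profile (defaults μ = 1,
σ = 2), per-sample lognormal replicate noise (σ = 0.3 by default),
and 150 bp read pairs with insert ~ Normal(270, 30) truncated to
[read_len, genome length]. Genomes are linear (fragments never wrap).
Substitution errors are i.i.d. per base (no indels) with the erroneous
base's Phred drawn low (2–20) against a correct-base background of
~38 ± 3; read headers carry `genome=<id> pos=<start>` so chimericity
and per-depth tables have exact ground truth. All randomness derives
from one seed via per-sample spawned substreams.

What this does *not* emulate — and hence what passing tests do not
show about real data: position-dependent error profiles and
high-quality errors, indels, GC/coverage bias, real phylogenetic
k-mer sharing between community members, circular replicons, and
community complexity anywhere near real metagenomes. The
coassembly-versus-multiassembly experiments therefore reproduce the
*direction* of the published contrasts; absolute recoveries at a given
depth are optimistic (a clean synthetic depth-3 sample assembles far
better than a real one, which compresses the coassembly-minus-
multiassembly margin for the low-abundance genome).

## Evaluation

The reference aligner anchors exact 31-mers, groups hits per
(reference, orientation, diagonal), merges anchor runs separated by
≤ 60 bases into blocks, and computes identity base-by-base over each
block span (blocks < `min_identity` = 0.95 are dropped — the value
also governs whether 1%-diverged strains claim each other's
references, which they do). Chaining on a fixed diagonal only is
deliberate: simulator and assembler are substitution-only/ungapped, so
indel-aware chaining would add complexity without coverage. This
aligner is a desk-scale stand-in, not comparable to a full
misassembly-classifying evaluator.

Reference metrics follow evaluator convention: assemblies are broken
at N-runs ≥ 10 (so genome fraction credits recovered sequence, not
scaffolding joins) and pieces < 500 bp are ignored. Chimericity is
computed on unbroken contigs: each provenance-tagged read goes to its
best-aligning contig (ties discarded), pᵢ are the per-genome read
proportions, and chimericity = −Σ pᵢ ln pᵢ (natural log; the entropy
is reported as a nonnegative number, matching the sign and scale of
values reported for this statistic). A contig is chimeric iff two or
more genomes have pᵢ > 0. Multiassembly is concatenation with
sample-prefixed ids; dedupe removes, processing longest-first, any
contig exactly contained (either strand) in a longer retained contig —
containment-only by design, so partially overlapping duplicates
survive, which is the published failure mode of naive deduplication.

## Experiment designs (problem sizes)

All experiments derive every random choice from one seed.

- **Reconstruction**: one 20 kb genome, 30×, k = [21, 33, 55],
  error-free and at 0.5% substitutions.
- **Repeat resolution**: 9 kb genome containing a 25 bp exact repeat
  twice, 30×, error-free; k = [21] versus [21, 33].
- **Low-depth retention**: two 8 kb genomes at 4× and 60×, 0.5%
  errors; k = [21] versus [21, 33].
- **Community (coassembly vs multiassembly)**: six genomes of
  10–30 kb; per-sample depths 3 (the low-abundance genome), 50 (the
  duplication probe), and 12 (four background genomes); four replicate
  samples, 0.5% errors, k = [21, 33], two scaffold rounds. The shorter
  k schedule keeps the pooled run in tens of seconds; the third k adds
  repeat resolution these random genomes do not need.
- **Gap calibration**: two 600 bp contigs with a true gap drawn from
  [20, 200], reads at 80×; junctions are generated until 100 carry an
  edge with support ≥ 10 (wide gaps near the insert size are
  inherently support-poor).
- **Shatter**: a 10 kb genome cut into 4 contigs (gaps 80, 90, 60 bp),
  30× error-free reads, scaffolded for 1 and 2 rounds.
- **Strain collapse**: a 20 kb parent and a 1%-divergent strain;
  coassembly of four samples at parent 30× / strain 3×, versus a
  single strain-enriched sample (strain 30× / parent 3×). The reported
  strain-specific fraction is the strain reference covered by contigs
  whose best reference is the strain.

## Known limitations

- Pure-Python inner loops bound practical input to tens of megabases.
- Ungapped alignment throughout: indel-rich data would fragment.
- The evaluator's block aligner under-reports for diverged references
  below ~90% identity and does not classify misassemblies.
- Contig depth inflates across iterations (additive evidence merge);
  treat depths as relative quantities.
- Containment-dedupe is exact-substring by default; near-duplicate
  removal at < 100% identity is slower and heuristic.
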