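# Methods

## Model

The package operates on the vertex-centric de Bruijn graph DBG_k(S) of
a sequence collection S: vertices are the distinct k-mers, and an arc
(u, v) exists exactly when the (k−1)-suffix of u equals the
(k−1)-prefix of v. The graph is directed on the forward strand; no
reverse-complement canonicalisation is performed, so the successor
relation below is unambiguous. Windows containing characters outside
{A, C, G, T} are dropped, not masked. Vertices are identified with
their 0-based lexicographic rank, which makes every derived structure
(successor arrays, anchors, serialized columns) reproducible
independent of input order. Self-loops (homopolymer k-mers) are
ordinary arcs and count toward both degrees.

An annotation assigns each vertex a label set, stored as a binary
matrix A with one column per label, column-sparse (sorted arrays of
set-row indices).

### The delta transform

Each vertex u with out-degree ≥ 1 has a unique *delta successor*
succ(u): its lexicographically largest out-neighbour. The transform
replaces row A_u by A*_u = A_u ⊕ A_succ(u) for every non-anchor u, and
stores anchor rows verbatim. Reconstruction XOR-accumulates A*
along u, succ(u), succ²(u), … until an anchor. Correctness needs only
the two anchor invariants — every sink anchored, every cycle of the
succ functional graph anchored — which the assignment pass guarantees
by construction and the test suite re-verifies with an independent
cycle enumeration.

### Anchor assignment

Anchors are placed in four sequential phases, each consuming its start
vertices in ascending vertex index (the parallel formulation of the
construction is run sequentially here; a fixed order makes the merge
heuristic, and hence the output, deterministic):

1. **Backward from sinks.** Every sink is an anchor. From each sink,
   walk backward along delta predecessors (u such that succ(u) = v —
   the walk deliberately does not cross predecessors whose delta
   successor is a different vertex), keeping a per-branch counter of
   the distance to the nearest anchor ahead; when it reaches M the
   vertex is anchored and the counter resets. All vertices visited in
   this phase are within M of an anchor and are marked `nearAnchor`.
2. **Forward from sources** not yet visited, following succ.
3. **Forward from unvisited out-neighbours of forks** (out-degree ≥ 2):
   forward traversal can only leave vertices behind at out-branches, so
   these starts cover everything except pure cycles.
4. **Forward from any remaining vertex** — by elimination these lie on
   simple cycles.

Forward traversals count traversed vertices and anchor every M-th one
(so in the M = 1 limit every vertex, including each traversal's start,
becomes an anchor and the transform is the identity). When a forward
traversal ends by merging into an already-visited vertex, the merge
heuristic applies: if the merge vertex is marked `nearAnchor`, nothing
is added; otherwise the merge vertex itself becomes an anchor. Closure
onto the traversal's own path counts as a merge, which is what
guarantees at least one anchor per cycle. `nearAnchor` is maintained as
the minimal bookkeeping of "known distance to the anchor ahead < M":
everything in phase 1; in forward phases, the trailing < M vertices
behind each newly set anchor.

The heuristic trades a small amount of optimality for O(1) extra state:
a vertex that merges into a `nearAnchor` vertex may sit up to
2(M − 1) steps from its anchor, so reconstruction paths are bounded by
2M vertices globally (asserted over the whole random-instance suite),
and by exactly M on merge-free path graphs. Path length is counted in
vertices on the reconstruction path, anchor inclusive.

### Transform and anchor optimization

The transform iterates only the set bits of each column: for a set bit
at row i, the delta at i is set when the bit at succ(i) is clear, and
the delta at each delta predecessor p of i is set when the bit at p is
clear. This touches each set bit O(1 + deg⁻) times, so the
bit-comparison count is bounded by (1 + max in-degree) · popcount(A) —
the implementation carries an operation counter and the suite asserts
the bound. Anchor rows are computed like all others and overwritten
with the original rows afterwards, keeping the set-bit iteration
branch-free.

Anchor optimization then promotes to anchor every vertex whose delta
row is strictly denser than its original row (ties keep the delta), in
a single pass — anchoring v changes only row v, so one sweep reaches
the fixed point. Afterwards no row of A* has more set bits than the
corresponding row of A. Row popcounts use 32-bit counters.

### Streaming contract

Construction is organised for out-of-core scale: the successor array is
produced and written block-by-block (`block_size` vertices, default
4096), and the transform consumes succ/pred in those blocks while
loading columns in batches capped by an encoded-bit budget
(`batch_bit_budget`, always at least one column). Outputs are exactly
invariant to both knobs, which the suite asserts at block sizes
{1, 7, |V|} and one-column batches. In this single-process
implementation the CSR inverse (pred) is derived from succ by an
in-memory counting pass — working memory is O(|V|) words rather than
O(block_size); the block contract is kept for succ production and for
all consumption paths.

### Batched queries

Querying many rows at once (e.g. all k-mers of a query sequence) first
computes the union of their successor paths — each arc walked exactly
once, verified by an arc-visit counter — then fetches every needed
delta row in one pass over the columns and resolves rows in increasing
distance-to-anchor order. The result is element-wise identical to
per-row reconstruction.

## Size model

Compressed sizes use one fixed Elias–Fano formula: a column of m sorted
positions out of n rows costs 64 header bits plus m·w low bits with
w = max(0, ⌊log₂(n/m)⌋), plus m + ⌈n/2^w⌉ unary high bits; an empty
column costs the 64-bit header. This is a normative size model, chosen
over a particular succinct-bitvector library layout so that compression
ratios are platform-independent and exactly reproducible. Reported
ratios |A|/|A*| are ratios of these bit totals over the label columns;
the anchor bitmap is encoded with the same formula and reported
separately (the CLI's `stats.json` carries both).

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| k | per run | k-mer length; larger k → sparser graph → better ratios |
| M | 100 | cap on reconstruction path length (vertices); smaller M → faster queries, more anchors, larger A* |
| block_size | 4096 | rows per streamed successor-index block (no effect on output) |
| batch_bit_budget | 2³⁰ bits | encoded size of one column batch (no effect on output) |

## Synthetic corpora

The generator emulates the one property the transform relies on:
adjacent vertices with near-identical annotations. A corpus is
n_families random ancestors (iid uniform bases) with family_size − 1
copies each, mutated by independent per-base substitutions at a given
rate (indels optional, off by default — substitutions already create
the bubble topologies that stress anchor placement); labels are per
family or per sequence. Randomness is numpy's PCG64 seeded from the
spec, so corpora are bit-reproducible. Defaults (10 families × 5
copies of 200 bp at 1% substitutions) give graphs of a few thousand
vertices with realistic unitig lengths for the tested k range.

What this does *not* emulate: sequencing errors and coverage structure,
shared sequence between families (real pangenomes share far more),
reverse-complement redundancy, and the repeat structure that makes real
small-k graphs dense. Consequently the density trend over k is
reproduced directionally (ratios grow as k grows and the graph gets
sparser) but the span is far narrower than on assembled-genome corpora,
where ratios vary by an order of magnitude. Passing tests demonstrate
exactness and the structural invariants, not absolute compression on
real data.

Adversarial generators produce the topologies that exercise the edge
cases: pure successor cycles (no sinks — anchors must come from cycle
closure), homopolymer self-loops (length-1 cycles), chained merges (the
near-anchor heuristic's worst case), and multi-sink stars. Random draws
are verified against the degree oracle and redrawn deterministically if
an accidental overlap breaks the intended shape.

## Problem sizes in the validation suite

The property suite runs 200 mixed instances (corpora up to ~5,000
vertices and ≤ 64 labels at substitution rates 0–8%, plus adversarial
topologies, M ∈ {1, 2, 3, 5, 10, 100}) through the full pipeline and
checks: exact round trip, the two anchor invariants (cycles enumerated
independently via networkx), per-row sparsity, the 2M path cap, M = 1
identity, block/batch invariance, batched-query equivalence on 1,000
random query sets with arc-exactness on shared paths, and the work
bound. The trend checks use one fixed corpus (100 families × 4 × 200 bp
at 2% substitutions) over k ∈ {15, 19, 23, 31} and one 20 kb path over
M ∈ {10, 25, 100}. `scripts/acceptance.py` re-measures the same
quantities on seed-derived corpora of the same sizes.

## Numerical and degenerate-input choices

- Sink sentinel is |V| (one past the last index) — unambiguous and
  serializable in the plain-text `succ.idx`.
- Empty annotation columns cost exactly one header; an all-empty matrix
  transforms to itself with ratio 1.
- Graphs with no valid k-mer, k < 2, M < 1, block_size < 1, shape
  mismatches and label-map references to unknown records raise typed
  errors; a reconstruction walk exceeding |V| steps raises an anchor
  invariant violation (unreachable for anchors produced by
  `assign_anchors`).
- Label order, vertex order and traversal order are all fixed
  (lexicographic / ascending-index), so every output, including the
  on-disk formats, is byte-identical across reruns.

## Known limitations

- Single process; the column-group distribution the streaming layout
  allows is not implemented.
- Forward strand only; canonical-mode graphs would need a different
  successor definition.
- Binary annotations only (no counts), and one size model — no
  multi-way matrix codes (BRWT-style) on top of the transform.
- `reconstruct_row` is O(|L| log) per path vertex; bulk work should use
  the batched interface.
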