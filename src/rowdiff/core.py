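"""The row-delta transform: successor index, anchors, sparsification, inverse.

The transform replaces each annotation row ``A_u`` with the XOR-delta to
the row of its unique *delta successor* ``succ(u)`` — the lexicographically
largest out-neighbour of ``u``.  Because adjacent vertices of a de Bruijn
graph tend to carry near-identical label sets, most deltas are empty and
the transformed matrix ``A*`` compresses far better than ``A``.

The transform is lossless given an *anchor* set: anchors keep their
original row verbatim, and a row is reconstructed by XOR-accumulating
deltas along the successor path until an anchor is met.  Termination
requires every sink to be an anchor and every cycle of the successor
functional graph to contain one; the assignment pass additionally caps
the distance from any vertex to its downstream anchor (parameter ``M``),
bounding reconstruction work.

Pipeline: :func:`build_succ_pred` -> :func:`assign_anchors` ->
:func:`transform` -> :func:`optimize_anchors`; inverse queries via
:func:`reconstruct_row` / :func:`reconstruct_rows_batched`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .annotation import AnnotationMatrix, SizeReport, ef_encoded_bits, size_report
from .graph import ALPHABET, KmerGraph, predecessors as graph_predecessors, successors as graph_successors

DEFAULT_M = 100
DEFAULT_BLOCK_SIZE = 4096
DEFAULT_BATCH_BITS = 1 << 30


class RowDiffError(RuntimeError):
    """Raised when a structural invariant of the representation is violated."""


# ---------------------------------------------------------------------------
# Successor / predecessor index


@dataclass
class SuccPredIndex:
    """Per-vertex delta successor and its inverse relation.

    ``succ[v]`` is the index of the lexicographically largest out-neighbour
    of ``v``, or the sink sentinel ``n`` (one past the last vertex) when
    ``v`` has out-degree 0.  ``pred`` holds, for each vertex ``v``, the
    sorted list of vertices ``u`` with ``succ[u] == v`` — only the inverse
    of ``succ``, not the full graph predecessor sets.  Stored in CSR form
    (``pred_offsets`` of length ``n+1`` into ``pred_data``).
    """

    n: int
    succ: np.ndarray
    pred_offsets: np.ndarray
    pred_data: np.ndarray

    @property
    def sink_sentinel(self) -> int:
        return self.n

    def preds(self, v: int) -> np.ndarray:
        """Delta predecessors of ``v`` (vertices whose successor is ``v``)."""
        return self.pred_data[self.pred_offsets[v] : self.pred_offsets[v + 1]]

    def iter_blocks(
        self, block_size: int
    ) -> Iterator[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]]:
        """Yield ``(start, stop, succ_block, pred_off_block, pred_data)`` slices.

        ``pred_off_block`` has ``stop - start + 1`` entries indexing into
        the returned ``pred_data`` slice (rebased to 0).
        """
        for start in range(0, self.n, block_size):
            stop = min(start + block_size, self.n)
            off = self.pred_offsets[start : stop + 1]
            data = self.pred_data[off[0] : off[-1]]
            yield start, stop, self.succ[start:stop], off - off[0], data


def rowdiff_successor(g: KmerGraph, v: int) -> int:
    """Delta successor of ``v``: lexicographically largest out-neighbour.

    Returns the sink sentinel ``len(g)`` when ``v`` has no out-neighbour.
    """
    g._check_index(v)
    suffix = g.vertices[v][1:]
    for c in reversed(ALPHABET):
        idx = g.index_of(suffix + c)
        if idx is not None:
            return idx
    return len(g.vertices)


def build_succ_pred(
    g: KmerGraph,
    block_size: int = DEFAULT_BLOCK_SIZE,
    workdir: str | Path | None = None,
) -> SuccPredIndex:
    """Precompute the successor array and its CSR inverse.

    The successor array is produced block by block (``block_size`` vertices
    at a time) and, when ``workdir`` is given, each block is appended to
    ``succ.idx`` on disk as it is computed; ``pred.idx`` is then derived by
    a counting pass over ``succ``.  The result is byte-identical for every
    ``block_size``.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = len(g.vertices)
    succ = np.empty(n, dtype=np.int64)
    workdir = Path(workdir) if workdir is not None else None
    succ_path = workdir / "succ.idx" if workdir is not None else None
    fh = None
    try:
        if succ_path is not None:
            workdir.mkdir(parents=True, exist_ok=True)
            fh = open(succ_path, "w", encoding="utf-8")
            fh.write(f"n={n}\n")
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            block = [rowdiff_successor(g, v) for v in range(start, stop)]
            succ[start:stop] = block
            if fh is not None:
                fh.write("\n".join(str(s) for s in block) + "\n")
    except OSError as exc:
        raise RowDiffError(f"failed writing successor index {succ_path}: {exc}") from exc
    finally:
        if fh is not None:
            fh.close()

    # invert succ: counting pass, then stable placement (pred lists sorted)
    counts = np.zeros(n + 1, dtype=np.int64)
    non_sink = succ[succ < n]
    np.add.at(counts[1:], non_sink, 1)
    offsets = np.cumsum(counts)
    pred_data = np.empty(non_sink.size, dtype=np.int64)
    cursor = offsets[:-1].copy()
    for u in np.flatnonzero(succ < n):  # ascending u keeps pred lists sorted
        v = succ[u]
        pred_data[cursor[v]] = u
        cursor[v] += 1
    idx = SuccPredIndex(n=n, succ=succ, pred_offsets=offsets, pred_data=pred_data)
    if workdir is not None:
        try:
            write_pred(idx, workdir / "pred.idx")
        except OSError as exc:
            raise RowDiffError(
                f"failed writing predecessor index {workdir / 'pred.idx'}: {exc}"
            ) from exc
    return idx


def write_succ(idx: SuccPredIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n={idx.n}\n")
        for s in idx.succ:
            fh.write(f"{int(s)}\n")


def write_pred(idx: SuccPredIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n={idx.n}\n")
        fh.write(" ".join(str(int(o)) for o in idx.pred_offsets) + "\n")
        fh.write(" ".join(str(int(p)) for p in idx.pred_data) + "\n")


def read_succ_pred(succ_path: str | Path, pred_path: str | Path) -> SuccPredIndex:
    """Load the index written by :func:`build_succ_pred`."""
    with open(succ_path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        n = int(header.split("=", 1)[1])
        succ = np.array([int(line) for line in fh if line.strip()], dtype=np.int64)
    if succ.size != n:
        raise RowDiffError(f"{succ_path}: expected {n} entries, found {succ.size}")
    with open(pred_path, encoding="utf-8") as fh:
        n2 = int(fh.readline().strip().split("=", 1)[1])
        if n2 != n:
            raise RowDiffError(f"{pred_path}: n={n2} does not match succ n={n}")
        offsets = np.array(fh.readline().split(), dtype=np.int64)
        data_line = fh.readline().split()
        pred_data = (
            np.array(data_line, dtype=np.int64) if data_line else np.empty(0, np.int64)
        )
    return SuccPredIndex(n=n, succ=succ, pred_offsets=offsets, pred_data=pred_data)


# ---------------------------------------------------------------------------
# Anchor assignment


@dataclass
class AnchorVector:
    """Anchor bitmap plus the maximum-path-length parameter it was built with."""

    bits: np.ndarray  # bool, length n
    M: int

    @property
    def n(self) -> int:
        return self.bits.size

    def count(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits).astype(np.int64)


@dataclass
class TraversalState:
    """Bookkeeping bitmaps of the anchor-assignment traversals."""

    visited: np.ndarray
    near_anchor: np.ndarray


def assign_anchors(
    g: KmerGraph, idx: SuccPredIndex, M: int = DEFAULT_M
) -> tuple[AnchorVector, TraversalState]:
    """Place anchors so reconstruction terminates within about ``M`` steps.

    Four sequential traversal phases over the successor functional graph,
    each processing its start vertices in ascending index order:

    1. backward from every sink along delta predecessors, anchoring every
       M-th vertex (the distance counter resets at anchors);
    2. forward from every still-unvisited source along ``succ``;
    3. forward from every unvisited out-neighbour of a fork;
    4. forward from any remaining unvisited vertex (simple cycles).

    Forward traversals set an anchor at every M-th traversed vertex.  A
    traversal ending on an already-visited vertex applies the merge
    heuristic: if the merge vertex is known to be within distance ``M`` of
    a downstream anchor (``nearAnchor``), no anchor is added; otherwise the
    merge vertex itself becomes an anchor.  This guarantees one anchor per
    successor cycle and a global reconstruction-path cap of ``2M``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    n = idx.n
    anchor = np.zeros(n, dtype=bool)
    visited = np.zeros(n, dtype=bool)
    near = np.zeros(n, dtype=bool)
    succ = idx.succ

    def traverse_bwd(sink: int) -> None:
        anchor[sink] = True
        visited[sink] = True
        near[sink] = True
        stack: list[tuple[int, int]] = [(sink, 0)]
        while stack:
            v, d = stack.pop()
            for u in idx.preds(v):
                u = int(u)
                if visited[u]:
                    continue
                visited[u] = True
                du = d + 1
                if du == M:
                    anchor[u] = True
                    du = 0
                near[u] = True  # distance to the anchor ahead is du < M
                stack.append((u, du))

    def traverse_fwd(start: int) -> None:
        if visited[start]:
            return
        # pending: vertices traversed since the last anchor, oldest first;
        # counter: how many of the traversal's vertices they are
        visited[start] = True
        pending = [start]
        counter = 1
        if counter == M:
            anchor[start] = True
            near[start] = True
            pending, counter = [], 0
        v = start
        while True:
            s = int(succ[v])
            if s == n:  # sinks are visited in phase 1; defensive only
                return
            if visited[s]:
                # merge (or closure onto this traversal's own path)
                if not near[s]:
                    anchor[s] = True
                    near[s] = True
                    if M > 1:
                        # pending[-j] is j steps before s: mark j < M
                        for u in pending[-(M - 1):]:
                            near[u] = True
                return
            visited[s] = True
            pending.append(s)
            counter += 1
            if counter == M:
                anchor[s] = True
                # pending[-j] is j-1 steps before s: mark j-1 < M
                for u in pending[-M:]:
                    near[u] = True
                pending, counter = [], 0
            v = s

    # phase 1: backward from sinks
    for v in np.flatnonzero(succ == n):
        traverse_bwd(int(v))
    # phase 2: forward from sources (no graph predecessor)
    for v in range(n):
        if not visited[v] and not graph_predecessors(g, v):
            traverse_fwd(v)
    # phase 3: forward from unvisited out-neighbours of forks
    for v in range(n):
        succs = graph_successors(g, v)
        if len(succs) >= 2:
            for c in succs:
                if not visited[c]:
                    traverse_fwd(c)
    # phase 4: whatever remains lies on simple cycles
    for v in range(n):
        if not visited[v]:
            traverse_fwd(v)

    return AnchorVector(bits=anchor, M=M), TraversalState(
        visited=visited, near_anchor=near
    )


# ---------------------------------------------------------------------------
# Transform


@dataclass
class TransformStats:
    """Operation counts of one transform run (for the work-bound contract)."""

    bit_comparisons: int = 0
    n_batches: int = 0
    n_blocks: int = 0


def transform(
    columns: AnnotationMatrix,
    idx: SuccPredIndex,
    anchors: AnchorVector,
    block_size: int = DEFAULT_BLOCK_SIZE,
    batch_bit_budget: int = DEFAULT_BATCH_BITS,
    stats: TransformStats | None = None,
) -> AnnotationMatrix:
    """Compute the delta matrix ``A*`` from ``A`` by iterating set bits only.

    For every set bit at row ``i`` of a column ``c``: if ``c[succ[i]]`` is
    clear the delta at ``i`` is set, and every delta predecessor ``p`` of
    ``i`` with ``c[p]`` clear gets its delta set.  Anchor rows are then
    overwritten with the original rows.  Columns are processed in batches
    whose encoded size fits ``batch_bit_budget`` (always at least one
    column per batch) and the successor index is consumed in blocks of
    ``block_size`` rows; the output is independent of both knobs.
    """
    if columns.n_rows != idx.n:
        raise RowDiffError(
            f"annotation has {columns.n_rows} rows but index has {idx.n} vertices"
        )
    if anchors.n != idx.n:
        raise RowDiffError("anchor vector length does not match index")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = idx.n
    anchor_bits = anchors.bits
    out_columns: list[np.ndarray] = [np.empty(0, np.int64)] * columns.n_labels

    # greedy batching by encoded column size (at least one column per batch)
    batches: list[list[int]] = []
    current: list[int] = []
    current_bits = 0
    for j, col in enumerate(columns.columns):
        bits = ef_encoded_bits(col, n)
        if current and current_bits + bits > batch_bit_budget:
            batches.append(current)
            current, current_bits = [], 0
        current.append(j)
        current_bits += bits
    if current:
        batches.append(current)

    for batch in batches:
        if stats is not None:
            stats.n_batches += 1
        dense = {}
        star = {}
        for j in batch:
            c = np.zeros(n, dtype=bool)
            c[columns.columns[j]] = True
            dense[j] = c
            star[j] = np.zeros(n, dtype=bool)
        for start, stop, succ_blk, pred_off, pred_dat in idx.iter_blocks(block_size):
            if stats is not None:
                stats.n_blocks += 1
            for j in batch:
                col = columns.columns[j]
                c = dense[j]
                lo, hi = np.searchsorted(col, [start, stop])
                set_idx = col[lo:hi]
                if set_idx.size == 0:
                    continue
                local = set_idx - start
                # rule 1: bit at i set, bit at succ(i) clear -> delta at i
                s = succ_blk[local]
                interior = s < n
                hit = np.zeros(set_idx.size, dtype=bool)
                hit[interior] = ~c[s[interior]]
                star[j][set_idx[hit]] = True
                # rule 2: bit at i set, bit at delta-pred p clear -> delta at p
                cnt = pred_off[local + 1] - pred_off[local]
                total = int(cnt.sum())
                if total:
                    starts = pred_off[local]
                    pos = np.repeat(starts, cnt) + (
                        np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
                    )
                    ps = pred_dat[pos]
                    star[j][ps[~c[ps]]] = True
                if stats is not None:
                    stats.bit_comparisons += set_idx.size + total
        for j in batch:
            # anchors keep their original row verbatim
            star[j][anchor_bits] = dense[j][anchor_bits]
            out_columns[j] = np.flatnonzero(star[j]).astype(np.int64)

    return AnnotationMatrix(n_rows=n, labels=columns.labels, columns=out_columns)


def optimize_anchors(
    A: AnnotationMatrix,
    A_star: AnnotationMatrix,
    anchors: AnchorVector,
) -> tuple[AnnotationMatrix, AnchorVector]:
    """Anchor every vertex whose delta row is denser than its original row.

    Single pass: turning ``v`` into an anchor replaces only row ``v`` (with
    the original ``A_v``) and affects no other delta row, so one sweep
    reaches the fixed point.  Ties keep the delta row (the rule is a strict
    inequality).  Afterwards every row of the returned matrix has at most
    as many set bits as the corresponding row of ``A``.  Per-row counts use
    32-bit counters.
    """
    pc_orig = A.row_popcounts()
    pc_star = A_star.row_popcounts()
    promote = pc_star > pc_orig
    new_bits = anchors.bits | promote
    new_cols = []
    for col_a, col_s in zip(A.columns, A_star.columns):
        keep_s = col_s[~promote[col_s]]
        add_a = col_a[promote[col_a]]
        new_cols.append(np.union1d(keep_s, add_a).astype(np.int64))
    new_star = AnnotationMatrix(n_rows=A.n_rows, labels=A.labels, columns=new_cols)
    return new_star, AnchorVector(bits=new_bits, M=anchors.M)


# ---------------------------------------------------------------------------
# Reconstruction


@dataclass
class RowDiffAnnotation:
    """Transformed matrix ``A*`` together with its anchor vector."""

    diff: AnnotationMatrix
    anchors: AnchorVector

    def __post_init__(self) -> None:
        if self.diff.n_rows != self.anchors.n:
            raise RowDiffError("diff matrix and anchor vector sizes differ")

    @property
    def n_rows(self) -> int:
        return self.diff.n_rows

    @property
    def labels(self) -> tuple[str, ...]:
        return self.diff.labels


@dataclass
class BatchQueryStats:
    """Traversal accounting for a batched reconstruction."""

    arc_visits: int = 0
    path_vertices: int = 0


def reconstruct_row(rd: RowDiffAnnotation, idx: SuccPredIndex, i: int) -> set[str]:
    """Recover the original label set of vertex ``i``.

    XOR-accumulates delta rows along ``i, succ(i), succ^2(i), ...`` until
    an anchor is met; terminates because every successor path reaches an
    anchor (sinks are anchors and every successor cycle contains one).
    """
    if not 0 <= i < rd.n_rows:
        raise RowDiffError(f"row index {i} out of range")
    n = idx.n
    row = np.zeros(len(rd.labels), dtype=bool)
    v = i
    steps = 0
    while True:
        for j, col in enumerate(rd.diff.columns):
            p = np.searchsorted(col, v)
            if p < col.size and col[p] == v:
                row[j] ^= True
        if rd.anchors.bits[v]:
            break
        v = int(idx.succ[v])
        steps += 1
        if v == n or steps > n:
            raise RowDiffError("anchor invariant violated: path has no anchor")
    return {rd.labels[j] for j in np.flatnonzero(row)}


def _resolve_paths(
    rd: RowDiffAnnotation,
    idx: SuccPredIndex,
    rows: Sequence[int],
    stats: BatchQueryStats | None,
) -> dict[int, np.ndarray]:
    """Shared-path resolution: map each needed vertex to its original bit row.

    Walks the union of successor paths starting at ``rows`` (every arc
    exactly once), fetches all needed delta rows in one batch, and resolves
    rows in increasing distance-to-anchor order.
    """
    n = idx.n
    succ = idx.succ
    anchor = rd.anchors.bits
    depth: dict[int, int] = {}  # path length (in vertices) down to the anchor

    for r in rows:
        if not 0 <= r < n:
            raise RowDiffError(f"row index {r} out of range")
        chain: list[int] = []
        v = int(r)
        while v not in depth:
            chain.append(v)
            if anchor[v]:
                break
            v = int(succ[v])
            if stats is not None:
                stats.arc_visits += 1
            if v == n or len(chain) > n:
                raise RowDiffError("anchor invariant violated: path has no anchor")
        if not chain:
            continue
        base = 1 if anchor[chain[-1]] else depth[v] + 1
        for offset, u in enumerate(reversed(chain)):
            depth[u] = base + offset

    if stats is not None:
        stats.path_vertices = len(depth)
    if not depth:
        return {}

    # fetch all needed delta rows in one pass over the columns
    needed = np.array(sorted(depth), dtype=np.int64)
    rank = {int(v): i for i, v in enumerate(needed)}
    fetched = np.zeros((needed.size, len(rd.labels)), dtype=bool)
    for j, col in enumerate(rd.diff.columns):
        pos = np.searchsorted(col, needed)
        ok = pos < col.size
        ok[ok] = col[pos[ok]] == needed[ok]
        fetched[ok, j] = True

    resolved: dict[int, np.ndarray] = {}
    for v in sorted(depth, key=depth.get):
        bits = fetched[rank[v]]
        if not anchor[v]:
            bits = bits ^ resolved[int(succ[v])]
        resolved[v] = bits
    return resolved


def reconstruct_rows_batched(
    rd: RowDiffAnnotation,
    idx: SuccPredIndex,
    rows: Sequence[int],
    stats: BatchQueryStats | None = None,
) -> list[set[str]]:
    """Recover label sets for many rows, sharing successor-path work.

    Element-wise identical to mapping :func:`reconstruct_row` over
    ``rows``; internally no arc of the involved paths is walked more than
    once and all delta rows are fetched in a single batch.
    """
    resolved = _resolve_paths(rd, idx, rows, stats)
    return [
        {rd.labels[j] for j in np.flatnonzero(resolved[int(r)])} for r in rows
    ]


def reconstruct_matrix(rd: RowDiffAnnotation, idx: SuccPredIndex) -> AnnotationMatrix:
    """Invert the transform for every row, returning the original matrix."""
    resolved = _resolve_paths(rd, idx, range(rd.n_rows), None)
    cols = []
    n = rd.n_rows
    dense = np.zeros((n, len(rd.labels)), dtype=bool)
    for v, bits in resolved.items():
        dense[v] = bits
    for j in range(len(rd.labels)):
        cols.append(np.flatnonzero(dense[:, j]).astype(np.int64))
    return AnnotationMatrix(n_rows=n, labels=rd.labels, columns=cols)


def max_path_length(idx: SuccPredIndex, anchors: AnchorVector) -> int:
    """Longest reconstruction path, counted in vertices (anchor inclusive)."""
    n = idx.n
    depth = np.zeros(n, dtype=np.int64)
    for start in range(n):
        if depth[start]:
            continue
        chain: list[int] = []
        v = start
        while depth[v] == 0:
            chain.append(v)
            if anchors.bits[v]:
                break
            v = int(idx.succ[v])
            if v == n or len(chain) > n:
                raise RowDiffError("anchor invariant violated: path has no anchor")
        base = 1 if (chain and anchors.bits[chain[-1]]) else depth[v] + 1
        for offset, u in enumerate(reversed(chain)):
            depth[u] = base + offset
    return int(depth.max()) if n else 0


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    """Everything produced by one end-to-end sparsification run."""

    rd: RowDiffAnnotation
    index: SuccPredIndex
    report_before: SizeReport
    report_after: SizeReport
    anchor_bits_encoded: int
    transform_stats: TransformStats
    max_path_len: int

    @property
    def compression_ratio(self) -> float:
        """Encoded-size ratio |A| / |A*| over the label columns."""
        return self.report_before.total_bits / self.report_after.total_bits


def rowdiff_pipeline(
    g: KmerGraph,
    A: AnnotationMatrix,
    M: int = DEFAULT_M,
    block_size: int = DEFAULT_BLOCK_SIZE,
    batch_bit_budget: int = DEFAULT_BATCH_BITS,
    workdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full sparsification: index, anchors, transform, optimization."""
    idx = build_succ_pred(g, block_size=block_size, workdir=workdir)
    anchors, _state = assign_anchors(g, idx, M=M)
    tstats = TransformStats()
    A_star = transform(
        A,
        idx,
        anchors,
        block_size=block_size,
        batch_bit_budget=batch_bit_budget,
        stats=tstats,
    )
    A_star, anchors = optimize_anchors(A, A_star, anchors)
    rd = RowDiffAnnotation(diff=A_star, anchors=anchors)
    return PipelineResult(
        rd=rd,
        index=idx,
        report_before=size_report(A),
        report_after=size_report(A_star),
        anchor_bits_encoded=ef_encoded_bits(anchors.indices(), idx.n),
        transform_stats=tstats,
        max_path_len=max_path_length(idx, anchors),
    )
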