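"""Vertex-centric de Bruijn graphs over the DNA alphabet.

A :class:`KmerGraph` stores the set of distinct k-mers of a sequence
collection as its vertices.  An arc ``(u, v)`` exists exactly when the
``k-1``-suffix of ``u`` equals the ``k-1``-prefix of ``v``; arcs are never
materialised, they are answered from the vertex set on demand.  The graph
is directed on the forward strand: no reverse-complement canonicalisation
is performed, so the successor relation used by the delta transform is
well defined and reproducible.

Vertices are indexed by their 0-based lexicographic rank, which makes
every downstream structure (successor arrays, anchors, serialized
columns) deterministic regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

ALPHABET = "ACGT"
_VALID = frozenset(ALPHABET)


class GraphError(ValueError):
    """Raised for invalid graph construction inputs or queries."""


@dataclass(frozen=True)
class KmerGraph:
    """De Bruijn graph of order ``k`` with lexicographically ranked vertices.

    Parameters
    ----------
    k:
        k-mer length, at least 2.
    vertices:
        Distinct k-mers sorted in strictly increasing lexicographic order.
    """

    k: int
    vertices: tuple[str, ...]
    _rank: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._rank:
            object.__setattr__(
                self, "_rank", {km: i for i, km in enumerate(self.vertices)}
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)

    def index_of(self, kmer: str) -> int | None:
        """Lexicographic rank of ``kmer``, or ``None`` if absent."""
        return self._rank.get(kmer)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._rank

    def _check_index(self, v: int) -> None:
        if not 0 <= v < len(self.vertices):
            raise GraphError(f"vertex index {v} out of range [0, {len(self.vertices)})")


def iter_kmers(sequence: str, k: int) -> Iterator[str]:
    """Yield the valid k-mers of ``sequence`` in order of occurrence.

    Windows containing characters outside ``{A, C, G, T}`` are dropped
    entirely (not masked).  Lowercase input is accepted and upcased.
    """
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if _VALID.issuperset(window):
            yield window


def build_graph(sequences: Iterable[str], k: int) -> KmerGraph:
    """Build the order-``k`` de Bruijn graph of a sequence collection.

    The vertex set is the union of distinct valid k-mers over all
    sequences; the result is independent of sequence order.

    Raises
    ------
    GraphError
        If ``k < 2`` or no valid k-mer can be extracted.
    """
    if k < 2:
        raise GraphError(f"k must be >= 2, got {k}")
    kmers: set[str] = set()
    for seq in sequences:
        kmers.update(iter_kmers(seq, k))
    if not kmers:
        raise GraphError("no valid k-mers: all sequences shorter than k or non-ACGT")
    return KmerGraph(k=k, vertices=tuple(sorted(kmers)))


def successors(g: KmerGraph, v: int) -> list[int]:
    """Indices of all out-neighbours of vertex ``v``, sorted ascending."""
    g._check_index(v)
    suffix = g.vertices[v][1:]
    out = []
    for c in ALPHABET:
        idx = g.index_of(suffix + c)
        if idx is not None:
            out.append(idx)
    return out  # ALPHABET is sorted, so candidates come out in rank order


def predecessors(g: KmerGraph, v: int) -> list[int]:
    """Indices of all in-neighbours of vertex ``v``, sorted ascending."""
    g._check_index(v)
    prefix = g.vertices[v][:-1]
    inn = []
    for c in ALPHABET:
        idx = g.index_of(c + prefix)
        if idx is not None:
            inn.append(idx)
    return sorted(inn)


def out_degree(g: KmerGraph, v: int) -> int:
    return len(successors(g, v))


def in_degree(g: KmerGraph, v: int) -> int:
    return len(predecessors(g, v))


def classify_vertices(g: KmerGraph) -> tuple[list[int], list[int], list[int]]:
    """Partition-relevant vertex classes: ``(sinks, sources, forks)``.

    sinks have out-degree 0, sources in-degree 0, forks out-degree >= 2.
    The classes are not disjoint (a source may also be a fork).  Each list
    is sorted ascending.  Self-loop arcs count towards both degrees.
    """
    sinks, sources, forks = [], [], []
    for v in range(len(g.vertices)):
        d_out = len(successors(g, v))
        if d_out == 0:
            sinks.append(v)
        elif d_out >= 2:
            forks.append(v)
        if len(predecessors(g, v)) == 0:
            sources.append(v)
    return sinks, sources, forks


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(record_id, sequence)`` pairs.

    The record id is the token before the first whitespace in the header;
    wrapped sequence lines are concatenated.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    return records


def write_graph(g: KmerGraph, path: str | Path) -> None:
    """Serialize the graph: ``k=<int>`` then one k-mer per line, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"k={g.k}\n")
        for km in g.vertices:
            fh.write(km + "\n")


def read_graph(path: str | Path) -> KmerGraph:
    """Load a graph written by :func:`write_graph`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("k="):
            raise GraphError(f"{path}: malformed graph header {header!r}")
        k = int(header[2:])
        vertices = tuple(line.strip() for line in fh if line.strip())
    for i, km in enumerate(vertices):
        if len(km) != k or not _VALID.issuperset(km):
            raise GraphError(f"{path}: invalid k-mer {km!r} at line {i + 2}")
        if i and km <= vertices[i - 1]:
            raise GraphError(f"{path}: vertices not strictly sorted at line {i + 2}")
    return KmerGraph(k=k, vertices=vertices)
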