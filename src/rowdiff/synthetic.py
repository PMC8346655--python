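"""Synthetic labeled sequence corpora with controllable similarity structure.

The delta transform pays off exactly when adjacent graph vertices carry
similar label sets.  The generator emulates the simplest process with
that property: families of sequences, each family one random ancestor
plus copies mutated by independent per-base substitutions (optionally
indels).  Within a family the copies share most of their k-mers, so the
family's subgraph is a backbone path with substitution bubbles, and with
per-family labels the annotation rows along that backbone are identical.

An adversarial generator emits small sequence sets whose graphs contain
the topologies that stress the anchor-assignment edge cases: pure cycles,
homopolymer self-loops, chained merges and multi-sink stars.

Randomness comes from ``numpy.random.default_rng`` (PCG64) seeded from
the corpus spec, so generation is a pure function of the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .graph import ALPHABET, build_graph, classify_vertices, in_degree, out_degree

LabelScheme = Literal["per_sequence", "per_family"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus; generation is pure in the spec."""

    n_families: int = 10
    family_size: int = 5
    ancestor_length: int = 200
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    label_scheme: LabelScheme = "per_family"
    k: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.family_size, self.ancestor_length) < 1:
            raise ValueError("all corpus counts must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.label_scheme not in ("per_sequence", "per_family"):
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")


@dataclass
class Corpus:
    """Generated records plus their label map."""

    records: list[tuple[str, str]]
    label_map: dict[str, set[str]]
    spec: CorpusSpec

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec_id, seq in self.records:
                fh.write(f">{rec_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def to_label_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# record_id\tlabels\n")
            for rec_id, _ in self.records:
                labs = ",".join(sorted(self.label_map[rec_id]))
                fh.write(f"{rec_id}\t{labs}\n")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, spec: CorpusSpec) -> str:
    seq = ancestor.copy()
    hits = np.flatnonzero(rng.random(seq.size) < spec.substitution_rate)
    if hits.size:
        # substitute with a uniformly chosen different base
        shift = rng.integers(1, 4, size=hits.size)
        seq[hits] = _BASES[(np.searchsorted(_BASES, seq[hits]) + shift) % 4]
    if spec.indel_rate > 0.0:
        out = []
        for b in seq:
            r = rng.random()
            if r < spec.indel_rate / 2:
                continue  # deletion
            out.append(b)
            if r >= spec.indel_rate / 2 and r < spec.indel_rate:
                out.append(_BASES[rng.integers(0, 4)])  # insertion
        seq = np.array(out, dtype=np.uint8) if out else seq[:0]
    return seq.tobytes().decode("ascii")


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate the corpus described by ``spec`` (deterministic in its seed)."""
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    label_map: dict[str, set[str]] = {}
    for f in range(spec.n_families):
        ancestor = _random_sequence(rng, spec.ancestor_length)
        family_label = f"F{f:04d}"
        for c in range(spec.family_size):
            rec_id = f"{family_label}_s{c:03d}"
            if c == 0:
                seq = ancestor.tobytes().decode("ascii")
            else:
                seq = _mutate(rng, ancestor, spec)
            records.append((rec_id, seq))
            if spec.label_scheme == "per_family":
                label_map[rec_id] = {family_label}
            else:
                label_map[rec_id] = {rec_id}
    return Corpus(records=records, label_map=label_map, spec=spec)


# ---------------------------------------------------------------------------
# Adversarial topologies

AdversarialKind = Literal["simple_cycle", "self_loop", "chained_merges", "star_of_sinks"]

_TAILS = [a + b for a in ALPHABET for b in ALPHABET]


def generate_adversarial(
    kind: AdversarialKind, size: int, k: int = 5, seed: int = 0
) -> list[tuple[str, str]]:
    """Emit records whose de Bruijn graph contains the named structure.

    ``simple_cycle``: a graph that is one directed cycle of ``size``
    vertices (no sinks, no sources, all degrees 1).  ``self_loop``: a
    homopolymer run producing a vertex that is its own successor.
    ``chained_merges``: a backbone with ``size`` side branches merging
    into it at staggered positions.  ``star_of_sinks``: a shared prefix
    fanning out into ``size`` distinct sink vertices.

    Constructions involving random sequence are verified against the
    graph-degree oracle and re-drawn if an accidental overlap breaks the
    intended topology; generation is deterministic in ``seed``.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)

    if kind == "simple_cycle":
        for _ in range(1000):
            core = _random_sequence(rng, size).tobytes().decode("ascii")
            # wrap by k-1 characters of the circular string (core may be
            # shorter than k-1, so tile it first)
            seq = core + (core * k)[: k - 1]
            try:
                g = build_graph([seq], k)
            except ValueError:
                continue
            if len(g) != size:
                continue
            degs_ok = all(
                out_degree(g, v) == 1 and in_degree(g, v) == 1 for v in range(len(g))
            )
            sinks, sources, _forks = classify_vertices(g)
            if degs_ok and not sinks and not sources:
                return [("cycle", seq)]
        raise RuntimeError(f"could not realise a simple cycle of {size} {k}-mers")

    if kind == "self_loop":
        flank = _random_sequence(rng, k - 1).tobytes().decode("ascii")
        # a terminal poly-A run longer than k yields the A^k vertex whose
        # only (hence lexicographically largest) successor is itself
        seq = flank.replace("A", "C") + "A" * (k + 2)
        return [("self_loop", seq)]

    if kind == "chained_merges":
        for _ in range(1000):
            backbone = _random_sequence(rng, (size + 2) * k).tobytes().decode("ascii")
            records = [("backbone", backbone)]
            ok = True
            for i in range(size):
                pos = (i + 1) * k
                prefix = _random_sequence(rng, k - 1).tobytes().decode("ascii")
                branch = prefix + backbone[pos : pos + k - 1]
                records.append((f"branch{i:02d}", branch))
            try:
                g = build_graph([s for _, s in records], k)
            except ValueError:
                continue
            merges = sum(1 for v in range(len(g)) if in_degree(g, v) >= 2)
            if merges >= size:
                return records
        raise RuntimeError("could not realise the chained-merge topology")

    if kind == "star_of_sinks":
        if size > len(_TAILS):
            raise ValueError(f"star_of_sinks supports at most {len(_TAILS)} sinks")
        for _ in range(1000):
            prefix = _random_sequence(rng, k + 2).tobytes().decode("ascii")
            records = [
                (f"ray{i:02d}", prefix + _TAILS[i]) for i in range(size)
            ]
            g = build_graph([s for _, s in records], k)
            sinks, _sources, _forks = classify_vertices(g)
            if len(sinks) == size:
                return records
        raise RuntimeError("could not realise the star-of-sinks topology")

    raise ValueError(f"unknown adversarial kind {kind!r}")
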