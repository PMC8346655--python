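"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own adjacency logic:
arcs come from an all-pairs overlap scan, and successor-graph cycles are
enumerated with networkx on explicitly materialised arcs.
"""

from __future__ import annotations

import numpy as np
import pytest

import rowdiff as rdf
from rowdiff.synthetic import CorpusSpec, generate_adversarial, generate_corpus


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_arcs(vertices: tuple[str, ...]) -> set[tuple[int, int]]:
    """All arcs by brute-force (k-1)-overlap test over all ordered pairs."""
    arcs = set()
    for i, u in enumerate(vertices):
        for j, v in enumerate(vertices):
            if u[1:] == v[:-1]:
                arcs.add((i, j))
    return arcs


def oracle_successor(vertices: tuple[str, ...], v: int) -> int:
    """Delta successor by scanning all arcs: lexicographically largest target."""
    targets = [j for (i, j) in oracle_arcs(vertices) if i == v]
    if not targets:
        return len(vertices)
    return max(targets, key=lambda j: vertices[j])


def succ_cycles(succ: np.ndarray) -> list[list[int]]:
    """Cycles of the successor functional graph, via networkx."""
    import networkx as nx

    n = succ.size
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for v in range(n):
        if succ[v] < n:
            G.add_edge(v, int(succ[v]))
    return list(nx.simple_cycles(G))


def dense_transform_oracle(
    dense: np.ndarray, succ: np.ndarray, anchor: np.ndarray
) -> np.ndarray:
    """Reference delta matrix: per-row XOR with the successor row."""
    n = dense.shape[0]
    out = np.zeros_like(dense)
    for v in range(n):
        if anchor[v] or succ[v] == n:
            out[v] = dense[v]
        else:
            out[v] = dense[v] ^ dense[succ[v]]
    return out


# ---------------------------------------------------------------------------
# Instance generation


def make_instance(seed: int) -> dict:
    """One random annotated-graph instance, mixing corpora and adversarial
    topologies across seeds; deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    if seed % 5 == 4:  # every fifth instance exercises an edge-case topology
        kind = ["simple_cycle", "self_loop", "chained_merges", "star_of_sinks"][
            int(rng.integers(0, 4))
        ]
        size = int(rng.integers(3, 9))
        k = int(rng.integers(4, 7))
        records = generate_adversarial(kind, size, k=k, seed=seed)
        label_map = {rid: {rid} for rid, _ in records}
        g = rdf.build_graph([s for _, s in records], k)
        A = rdf.annotate_sequences(g, records, label_map)
        topology = kind
    else:
        spec = CorpusSpec(
            n_families=int(rng.integers(1, 5)),
            family_size=int(rng.integers(1, 6)),
            ancestor_length=int(rng.integers(40, 200)),
            substitution_rate=float(rng.choice([0.0, 0.01, 0.03, 0.08])),
            label_scheme=str(rng.choice(["per_family", "per_sequence"])),
            k=int(rng.choice([7, 11, 15, 21])),
            seed=seed,
        )
        corpus = generate_corpus(spec)
        g = rdf.build_graph(corpus.sequences(), spec.k)
        A = rdf.annotate_sequences(g, corpus.records, corpus.label_map)
        topology = "corpus"
    M = int(rng.choice([1, 2, 3, 5, 10, 100]))
    return {"g": g, "A": A, "M": M, "seed": seed, "topology": topology}


def path_graph(n_vertices: int, seed: int = 1, k: int = 8) -> rdf.KmerGraph:
    """A simple path graph of exactly ``n_vertices`` (degrees all <= 1)."""
    from rowdiff.graph import in_degree, out_degree

    rng = np.random.default_rng(seed)
    for _ in range(10000):
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, n_vertices + k - 1))
        try:
            g = rdf.build_graph([s], k)
        except rdf.GraphError:
            continue
        if len(g) != n_vertices:
            continue
        sinks, sources, forks = rdf.classify_vertices(g)
        if (
            len(sinks) == 1
            and len(sources) == 1
            and not forks
            and all(
                out_degree(g, v) <= 1 and in_degree(g, v) <= 1 for v in range(len(g))
            )
        ):
            return g
    raise RuntimeError(f"could not realise a {n_vertices}-vertex path graph")


def path_order(g: rdf.KmerGraph, idx: rdf.SuccPredIndex) -> list[int]:
    """Vertices of a path graph from source to sink."""
    (source,) = rdf.classify_vertices(g)[1]
    order = [source]
    while int(idx.succ[order[-1]]) != idx.n:
        order.append(int(idx.succ[order[-1]]))
    return order


# ---------------------------------------------------------------------------
# Session-wide instance suite (shared by the acceptance-property tests)

N_SUITE = 200


@pytest.fixture(scope="session")
def instance_suite():
    """200 random instances with their full pipeline results.

    Mixed substitution rates and adversarial topologies; sizes are mostly
    small with a tail of instances up to a few thousand vertices.
    """
    results = []
    for seed in range(N_SUITE):
        inst = make_instance(seed)
        if seed >= 190:  # tail of larger corpora
            spec = CorpusSpec(
                n_families=4,
                family_size=4,
                ancestor_length=150 + 40 * (seed - 190),
                substitution_rate=0.02,
                k=21,
                seed=seed,
            )
            corpus = generate_corpus(spec)
            g = rdf.build_graph(corpus.sequences(), spec.k)
            A = rdf.annotate_sequences(g, corpus.records, corpus.label_map)
            inst = {"g": g, "A": A, "M": 10, "seed": seed, "topology": "corpus"}
        stats = rdf.TransformStats()
        idx = rdf.build_succ_pred(inst["g"])
        anchors, state = rdf.assign_anchors(inst["g"], idx, M=inst["M"])
        A_star_raw = rdf.transform(inst["A"], idx, anchors, stats=stats)
        A_star, anchors = rdf.optimize_anchors(inst["A"], A_star_raw, anchors)
        rd = rdf.RowDiffAnnotation(diff=A_star, anchors=anchors)
        results.append(
            {
                **inst,
                "idx": idx,
                "anchors": anchors,
                "state": state,
                "rd": rd,
                "transform_stats": stats,
            }
        )
    return results
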