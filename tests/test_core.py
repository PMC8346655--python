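"""Successor index, anchor assignment, transform and reconstruction."""

import numpy as np
import pytest

import rowdiff as rdf
from rowdiff.core import read_succ_pred

from conftest import (
    dense_transform_oracle,
    make_instance,
    oracle_successor,
    path_graph,
    path_order,
    succ_cycles,
)


@pytest.fixture(scope="module")
def fork_graph():
    return rdf.build_graph(["ACGA", "ACGT"], 3)


@pytest.fixture(scope="module")
def path10():
    g = path_graph(10)
    idx = rdf.build_succ_pred(g)
    return g, idx, path_order(g, idx)


class TestRowdiffSuccessor:
    def test_picks_lexicographically_largest(self, fork_graph):
        g = fork_graph
        assert rdf.rowdiff_successor(g, g.index_of("ACG")) == g.index_of("CGT")

    def test_sink_gets_sentinel(self):
        g = rdf.build_graph(["ACGTT"], 3)
        assert rdf.rowdiff_successor(g, g.index_of("GTT")) == len(g)

    def test_self_loop_is_own_successor(self):
        g = rdf.build_graph(["AAAA"], 3)
        assert rdf.rowdiff_successor(g, 0) == 0

    @pytest.mark.parametrize("seed", [4, 9, 14, 19, 24, 29])
    def test_matches_all_pairs_oracle(self, seed):
        # adversarial instances stay small enough for the quadratic oracle
        inst = make_instance(seed)
        g = inst["g"]
        assert len(g) <= 200
        for v in range(len(g)):
            assert rdf.rowdiff_successor(g, v) == oracle_successor(g.vertices, v)


class TestBuildSuccPred:
    def test_path_graph_succ_chain(self, path10):
        g, idx, order = path10
        for a, b in zip(order, order[1:]):
            assert idx.succ[a] == b
        assert idx.succ[order[-1]] == idx.sink_sentinel
        for a, b in zip(order, order[1:]):
            assert list(idx.preds(b)) == [a]
        assert list(idx.preds(order[0])) == []

    def test_fork_only_largest_child_has_pred(self, fork_graph):
        g = fork_graph
        idx = rdf.build_succ_pred(g)
        assert list(idx.preds(g.index_of("CGT"))) == [g.index_of("ACG")]
        assert list(idx.preds(g.index_of("CGA"))) == []

    def test_pred_is_exact_inverse_of_succ(self):
        inst = make_instance(3)
        idx = rdf.build_succ_pred(inst["g"])
        pairs_from_pred = {
            (int(u), v) for v in range(idx.n) for u in idx.preds(v)
        }
        pairs_from_succ = {
            (v, int(idx.succ[v])) for v in range(idx.n) if idx.succ[v] < idx.n
        }
        assert pairs_from_pred == pairs_from_succ

    def test_block_size_invariance_and_disk_round_trip(self, tmp_path):
        inst = make_instance(11)
        g = inst["g"]
        outputs = {}
        for bs in (1, 7, len(g)):
            d = tmp_path / f"bs{bs}"
            idx = rdf.build_succ_pred(g, block_size=bs, workdir=d)
            outputs[bs] = (
                (d / "succ.idx").read_bytes(),
                (d / "pred.idx").read_bytes(),
            )
            loaded = read_succ_pred(d / "succ.idx", d / "pred.idx")
            assert np.array_equal(loaded.succ, idx.succ)
            assert np.array_equal(loaded.pred_offsets, idx.pred_offsets)
            assert np.array_equal(loaded.pred_data, idx.pred_data)
        assert outputs[1] == outputs[7] == outputs[len(g)]

    def test_rejects_bad_block_size(self, fork_graph):
        with pytest.raises(ValueError, match="block_size"):
            rdf.build_succ_pred(fork_graph, block_size=0)


class TestAssignAnchors:
    def test_path_anchor_spacing(self, path10):
        g, idx, order = path10
        anchors, state = rdf.assign_anchors(g, idx, M=3)
        sink_distance = {v: len(order) - 1 - i for i, v in enumerate(order)}
        anchored = sorted(sink_distance[v] for v in np.flatnonzero(anchors.bits))
        assert anchored == [0, 3, 6, 9]
        assert state.visited.all()
        # everything on the path is within M of an anchor ahead
        assert state.near_anchor.all()

    def test_simple_cycle_gets_exactly_one_anchor(self):
        records = rdf.generate_adversarial("simple_cycle", 5, k=4)
        g = rdf.build_graph([s for _, s in records], 4)
        idx = rdf.build_succ_pred(g)
        anchors, _ = rdf.assign_anchors(g, idx, M=10)
        assert anchors.count() == 1

    def test_self_loop_anchored(self):
        records = rdf.generate_adversarial("self_loop", 1, k=4)
        g = rdf.build_graph([s for _, s in records], 4)
        idx = rdf.build_succ_pred(g)
        anchors, _ = rdf.assign_anchors(g, idx, M=100)
        loop = g.index_of("AAAA")
        assert idx.succ[loop] == loop
        assert anchors.bits[loop]

    def test_m1_anchors_everything(self):
        inst = make_instance(9)
        idx = rdf.build_succ_pred(inst["g"])
        anchors, _ = rdf.assign_anchors(inst["g"], idx, M=1)
        assert anchors.count() == len(inst["g"])

    @pytest.mark.parametrize("seed", range(0, 50))
    def test_sinks_always_anchored(self, seed):
        inst = make_instance(seed)
        idx = rdf.build_succ_pred(inst["g"])
        anchors, state = rdf.assign_anchors(inst["g"], idx, M=inst["M"])
        sinks = np.flatnonzero(idx.succ == idx.n)
        assert anchors.bits[sinks].all()
        assert state.visited.all()
        # nearAnchor only marks visited vertices
        assert not (state.near_anchor & ~state.visited).any()

    def test_every_succ_cycle_contains_anchor(self):
        for seed in range(0, 40):
            inst = make_instance(seed)
            idx = rdf.build_succ_pred(inst["g"])
            anchors, _ = rdf.assign_anchors(inst["g"], idx, M=inst["M"])
            for cycle in succ_cycles(idx.succ):
                assert anchors.bits[cycle].any(), f"anchor-free cycle, seed {seed}"

    def test_rejects_bad_m(self, fork_graph):
        idx = rdf.build_succ_pred(fork_graph)
        with pytest.raises(ValueError, match="M must be"):
            rdf.assign_anchors(fork_graph, idx, M=0)


class TestTransform:
    def test_path_example(self, path10):
        """Rows [101, 101, 100] on a path become [000, 001, 100]."""
        g, idx, order = path10
        v1, v2, v3 = order[-3:]
        dense = np.zeros((len(g), 3), dtype=bool)
        dense[v1] = [1, 0, 1]
        dense[v2] = [1, 0, 1]
        dense[v3] = [1, 0, 0]
        A = rdf.AnnotationMatrix.from_dense(dense, ["a", "b", "c"])
        anchors, _ = rdf.assign_anchors(g, idx, M=100)
        star = rdf.transform(A, idx, anchors).to_dense()
        assert list(star[v1].astype(int)) == [0, 0, 0]
        assert list(star[v2].astype(int)) == [0, 0, 1]
        assert list(star[v3].astype(int)) == [1, 0, 0]

    def test_identical_rows_vanish_off_anchor(self, path10):
        g, idx, order = path10
        dense = np.ones((len(g), 2), dtype=bool)
        A = rdf.AnnotationMatrix.from_dense(dense, ["a", "b"])
        anchors, _ = rdf.assign_anchors(g, idx, M=100)
        star = rdf.transform(A, idx, anchors).to_dense()
        assert star.sum() == 2  # only the sink anchor row survives
        assert star[order[-1]].all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_xor_oracle(self, seed):
        inst = make_instance(seed)
        idx = rdf.build_succ_pred(inst["g"])
        anchors, _ = rdf.assign_anchors(inst["g"], idx, M=inst["M"])
        star = rdf.transform(inst["A"], idx, anchors)
        expected = dense_transform_oracle(
            inst["A"].to_dense(), idx.succ, anchors.bits
        )
        assert np.array_equal(star.to_dense(), expected)

    def test_invariant_to_tuning_parameters(self):
        inst = make_instance(21)
        g, A = inst["g"], inst["A"]
        idx = rdf.build_succ_pred(g)
        anchors, _ = rdf.assign_anchors(g, idx, M=5)
        reference = rdf.transform(A, idx, anchors)
        for bs in (1, 7, len(g)):
            for budget in (1, 1 << 40):  # 1 bit forces one column per batch
                out = rdf.transform(
                    A, idx, anchors, block_size=bs, batch_bit_budget=budget
                )
                assert out.equal(reference)

    def test_mismatched_rows_rejected(self, fork_graph):
        idx = rdf.build_succ_pred(fork_graph)
        anchors, _ = rdf.assign_anchors(fork_graph, idx, M=2)
        bad = rdf.AnnotationMatrix(n_rows=7, labels=("a",), columns=[[0]])
        with pytest.raises(rdf.RowDiffError, match="rows"):
            rdf.transform(bad, idx, anchors)


class TestOptimizeAnchors:
    def _singleton(self, a_row, star_row):
        A = rdf.AnnotationMatrix.from_dense(np.array([a_row], dtype=bool), ["x", "y", "z"])
        S = rdf.AnnotationMatrix.from_dense(np.array([star_row], dtype=bool), ["x", "y", "z"])
        anchors = rdf.AnchorVector(bits=np.zeros(1, dtype=bool), M=10)
        return rdf.optimize_anchors(A, S, anchors)

    def test_denser_diff_row_promoted(self):
        new_star, new_anchors = self._singleton([1, 0, 0], [0, 1, 1])
        assert new_anchors.bits[0]
        assert list(new_star.to_dense()[0].astype(int)) == [1, 0, 0]

    def test_sparser_diff_row_kept(self):
        new_star, new_anchors = self._singleton([1, 1, 1], [0, 0, 1])
        assert not new_anchors.bits[0]
        assert list(new_star.to_dense()[0].astype(int)) == [0, 0, 1]

    def test_tie_keeps_diff_row(self):
        new_star, new_anchors = self._singleton([1, 0, 0], [0, 1, 0])
        assert not new_anchors.bits[0]
        assert list(new_star.to_dense()[0].astype(int)) == [0, 1, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_rows_never_denser_than_original(self, seed):
        inst = make_instance(seed)
        idx = rdf.build_succ_pred(inst["g"])
        anchors, _ = rdf.assign_anchors(inst["g"], idx, M=inst["M"])
        star = rdf.transform(inst["A"], idx, anchors)
        new_star, _ = rdf.optimize_anchors(inst["A"], star, anchors)
        assert (new_star.row_popcounts() <= inst["A"].row_popcounts()).all()


@pytest.fixture(scope="module")
def pipeline10(path10):
    g, idx, order = path10
    rng = np.random.default_rng(0)
    dense = rng.random((len(g), 4)) < 0.4
    A = rdf.AnnotationMatrix.from_dense(dense, ["a", "b", "c", "d"])
    res = rdf.rowdiff_pipeline(g, A, M=3)
    return g, A, res


class TestReconstruct:
    def test_anchor_row_returned_verbatim(self, pipeline10):
        g, A, res = pipeline10
        for v in res.rd.anchors.indices():
            assert rdf.reconstruct_row(res.rd, res.index, int(v)) == A.row_labels(int(v))

    def test_path_xor_accumulation(self, path10):
        g, idx, order = path10
        v1, v2, v3 = order[-3:]
        dense = np.zeros((len(g), 3), dtype=bool)
        dense[v1] = [1, 0, 1]
        dense[v2] = [1, 0, 1]
        dense[v3] = [1, 0, 0]
        A = rdf.AnnotationMatrix.from_dense(dense, ["a", "b", "c"])
        anchors, _ = rdf.assign_anchors(g, idx, M=100)
        star = rdf.transform(A, idx, anchors)
        rd = rdf.RowDiffAnnotation(diff=star, anchors=anchors)
        assert rdf.reconstruct_row(rd, idx, v1) == {"a", "c"}

    @pytest.mark.parametrize("seed", range(15))
    def test_round_trip_every_row(self, seed):
        inst = make_instance(seed)
        res = rdf.rowdiff_pipeline(inst["g"], inst["A"], M=inst["M"])
        assert rdf.reconstruct_matrix(res.rd, res.index).equal(inst["A"])

    def test_violated_invariant_detected(self):
        records = rdf.generate_adversarial("simple_cycle", 5, k=4)
        g = rdf.build_graph([s for _, s in records], 4)
        idx = rdf.build_succ_pred(g)
        no_anchors = rdf.AnchorVector(bits=np.zeros(len(g), dtype=bool), M=10)
        empty = rdf.AnnotationMatrix(n_rows=len(g), labels=("a",), columns=[[]])
        rd = rdf.RowDiffAnnotation(diff=empty, anchors=no_anchors)
        with pytest.raises(rdf.RowDiffError, match="anchor invariant"):
            rdf.reconstruct_row(rd, idx, 0)
        with pytest.raises(rdf.RowDiffError, match="anchor invariant"):
            rdf.reconstruct_rows_batched(rd, idx, [0])


class TestBatchedReconstruct:
    def test_empty_query(self, path10):
        g, idx, order = path10
        anchors, _ = rdf.assign_anchors(g, idx, M=3)
        empty = rdf.AnnotationMatrix(n_rows=len(g), labels=("a",), columns=[[]])
        rd = rdf.RowDiffAnnotation(diff=empty, anchors=anchors)
        assert rdf.reconstruct_rows_batched(rd, idx, []) == []

    def test_equivalent_to_per_row(self):
        inst = make_instance(13)
        res = rdf.rowdiff_pipeline(inst["g"], inst["A"], M=inst["M"])
        rng = np.random.default_rng(1)
        rows = [int(r) for r in rng.integers(0, len(inst["g"]), size=30)]
        batched = rdf.reconstruct_rows_batched(res.rd, res.index, rows)
        singly = [rdf.reconstruct_row(res.rd, res.index, r) for r in rows]
        assert batched == singly

    def test_full_path_visits_each_arc_once(self, path10):
        g, idx, order = path10
        # uniform rows: the sink stays the only anchor, so the shared
        # reconstruction path spans the whole graph path
        dense = np.tile([True, False], (len(g), 1))
        A = rdf.AnnotationMatrix.from_dense(dense, ["a", "b"])
        res = rdf.rowdiff_pipeline(g, A, M=100)
        stats = rdf.BatchQueryStats()
        out = rdf.reconstruct_rows_batched(res.rd, res.index, order, stats=stats)
        assert stats.arc_visits == len(order) - 1
        assert out == [A.row_labels(v) for v in order]


class TestMaxPathLength:
    def test_exactly_m_on_path(self, path10):
        g, idx, order = path10
        anchors, _ = rdf.assign_anchors(g, idx, M=3)
        assert rdf.max_path_length(idx, anchors) == 3

    def test_one_on_full_anchor_set(self, path10):
        g, idx, _ = path10
        anchors, _ = rdf.assign_anchors(g, idx, M=1)
        assert rdf.max_path_length(idx, anchors) == 1


class TestPipeline:
    def test_identical_annotations_compress(self):
        spec = rdf.CorpusSpec(
            n_families=3, family_size=4, ancestor_length=150,
            substitution_rate=0.0, k=15, seed=2,
        )
        corpus = rdf.generate_corpus(spec)
        g = rdf.build_graph(corpus.sequences(), spec.k)
        A = rdf.annotate_sequences(g, corpus.records, corpus.label_map)
        res = rdf.rowdiff_pipeline(g, A, M=100)
        assert res.compression_ratio > 1.0

    def test_m1_is_identity(self):
        inst = make_instance(6)
        res = rdf.rowdiff_pipeline(inst["g"], inst["A"], M=1)
        assert res.rd.diff.equal(inst["A"])
        assert res.rd.anchors.count() == len(inst["g"])
        assert res.compression_ratio == 1.0

    def test_empty_annotation_ratio_one(self, path10):
        g, _, _ = path10
        A = rdf.AnnotationMatrix(n_rows=len(g), labels=("a", "b"), columns=[[], []])
        res = rdf.rowdiff_pipeline(g, A, M=10)
        assert res.rd.diff.popcount() == 0
        assert res.compression_ratio == 1.0
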