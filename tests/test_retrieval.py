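"""Feature index and nearest-plan search: exactness, ties, payload fidelity."""

import numpy as np
import pytest

from doseret import (
    FeatureIndex,
    build_index,
    end_to_end_query,
    euclidean_distance,
    pair_distance,
    query,
    retrieve_ops,
)
from doseret.retrieval import load_index, save_index


def _unit_rows(rng, n, d=32):
    x = rng.standard_normal((n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


class TestEuclideanDistance:
    def test_zero_iff_equal(self, rng):
        x = rng.standard_normal(32)
        assert euclidean_distance(x, x) == 0.0

    def test_basis_vectors(self):
        e = np.eye(32)
        assert euclidean_distance(e[0], e[1]) == pytest.approx(np.sqrt(2))

    def test_agrees_with_pair_distance_on_unit_vectors(self, rng):
        for _ in range(100):
            a, p = _unit_rows(rng, 2)
            assert euclidean_distance(a, p) == pytest.approx(
                pair_distance(a, p), abs=1e-6
            )

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            x, y, z = rng.standard_normal((3, 32))
            assert euclidean_distance(x, y) == pytest.approx(euclidean_distance(y, x), abs=1e-9)
            assert euclidean_distance(x, z) <= euclidean_distance(x, y) + euclidean_distance(y, z) + 1e-9

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros(32), np.zeros(16))


class TestQuery:
    def _index(self, rng, n):
        return FeatureIndex(
            plan_ids=[f"plan_{i:03d}" for i in range(n)],
            features=_unit_rows(rng, n),
            weights_fingerprint="test",
        )

    def test_self_retrieval_rank1_distance_zero(self, rng):
        idx = self._index(rng, 10)
        res = query(idx, idx.features[4], k=3)
        assert res.hits[0][0] == "plan_004"
        assert res.hits[0][1] < 1e-6

    def test_k_beyond_index_returns_all_sorted(self, rng):
        idx = self._index(rng, 5)
        res = query(idx, rng.standard_normal(32), k=99)
        assert len(res.hits) == 5
        dists = [d for _, d in res.hits]
        assert dists == sorted(dists)

    @pytest.mark.parametrize("k", [1, 3, 50])
    def test_matches_brute_force_sort(self, k, rng):
        idx = self._index(rng, 50)
        fv = rng.standard_normal(32).astype(np.float32)
        res = query(idx, fv, k=k)
        brute = sorted(
            ((float(np.linalg.norm(f.astype(float) - fv.astype(float))), pid)
             for pid, f in zip(idx.plan_ids, idx.features)),
        )
        for (pid, d), (bd, bpid) in zip(res.hits, brute[:k]):
            assert pid == bpid
            assert d == pytest.approx(bd, abs=1e-6)

    def test_ties_broken_by_ascending_plan_id(self):
        feats = np.zeros((3, 32), dtype=np.float32)
        idx = FeatureIndex(plan_ids=["c", "a", "b"], features=feats, weights_fingerprint="t")
        res = query(idx, np.zeros(32), k=3)
        assert [pid for pid, _ in res.hits] == ["a", "b", "c"]

    def test_empty_index_and_bad_depth_rejected(self, rng):
        empty = FeatureIndex(plan_ids=[], features=np.zeros((0, 32)), weights_fingerprint="t")
        with pytest.raises(ValueError, match="empty"):
            query(empty, np.zeros(32))
        idx = self._index(rng, 1)
        with pytest.raises(ValueError):
            query(idx, np.zeros(32), k=0)


class TestBuildIndex:
    def test_one_entry_per_plan_in_manifest_order(self, tiny_cohort, tiny_weights):
        idx = build_index(tiny_weights, tiny_cohort)
        assert idx.plan_ids == tiny_cohort.plan_ids
        assert idx.features.shape == (len(tiny_cohort), 32)

    def test_rebuild_identical(self, tiny_cohort, tiny_weights):
        a = build_index(tiny_weights, tiny_cohort)
        b = build_index(tiny_weights, tiny_cohort)
        np.testing.assert_array_equal(a.features, b.features)
        assert a.weights_fingerprint == b.weights_fingerprint

    def test_fingerprint_tracks_weight_perturbation(self, tiny_cohort, tiny_weights):
        other = tiny_weights.copy()
        key = sorted(k for k in other.state if k.endswith(".w"))[0]
        other.state[key][0] += 1e-4
        a = build_index(tiny_weights, tiny_cohort)
        b = build_index(other, tiny_cohort)
        assert a.weights_fingerprint != b.weights_fingerprint

    def test_index_json_roundtrip(self, tiny_cohort, tiny_weights, tmp_path):
        idx = build_index(tiny_weights, tiny_cohort)
        back = load_index(save_index(idx, tmp_path / "index.json"))
        assert back.plan_ids == idx.plan_ids
        np.testing.assert_allclose(back.features, idx.features, atol=1e-7)


class TestRetrieveOps:
    def test_payloads_in_rank_order_unmodified(self, tiny_cohort, tiny_weights):
        idx = build_index(tiny_weights, tiny_cohort)
        res = query(idx, idx.features[0], k=3)
        payloads = retrieve_ops(tiny_cohort, res)
        assert len(payloads) == 3
        assert payloads[0] == tiny_cohort[res.hits[0][0]].ops_payload

    def test_unknown_hit_id_named_in_error(self, tiny_cohort, tiny_weights):
        from doseret.retrieval import RankedResult

        res = RankedResult(query_id="q", hits=[("ghost", 0.1)], k=1)
        with pytest.raises(KeyError, match="ghost"):
            retrieve_ops(tiny_cohort, res)


class TestEndToEnd:
    def test_identity_virtualizer_retrieves_self_at_rank1(self, tiny_weights):
        import dataclasses

        from conftest import tiny_cohort_spec
        from doseret import VirtualizerSpec, generate_cohort

        spec = dataclasses.replace(
            tiny_cohort_spec(n_plans=4), virtualizer=VirtualizerSpec(0.0, 0.0, 0.0)
        )
        db = generate_cohort(spec)
        idx = build_index(tiny_weights, db)
        rec = db.records[2]
        res, payloads = end_to_end_query(tiny_weights, idx, db, rec, k=3)
        assert res.hits[0][0] == rec.plan_id
        assert payloads[0] == rec.ops_payload

    def test_missing_virtual_dose_rejected(self, tiny_cohort, tiny_weights):
        import copy

        rec = copy.copy(tiny_cohort.records[0])
        rec.virtual_dose = None
        idx = build_index(tiny_weights, tiny_cohort)
        with pytest.raises(ValueError, match="virtual"):
            end_to_end_query(tiny_weights, idx, tiny_cohort, rec)
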