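"""Plan retrieval: feature index construction and nearest-plan queries.

Every stored plan's clinical dose image is embedded once into a feature
vector f_c; a new patient's virtual (predicted) dose embeds to f_v, and the
stored plans are ranked by the Euclidean distance between f_v and each f_c.
The optimization-parameter payloads of the closest plans (Search 1, 2, 3 by
default) seed the new patient's plan optimization.

The search is an exact exhaustive linear scan — at database scales of a few
hundred plans, exactness beats approximate-nearest-neighbour speedups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .core import PlanDatabase, PlanRecord
from .encoder import EncoderWeights, encode_batch, preprocess, weights_fingerprint

__all__ = [
    "FeatureIndex",
    "RankedResult",
    "euclidean_distance",
    "build_index",
    "query",
    "retrieve_ops",
    "end_to_end_query",
    "save_index",
    "load_index",
]


@dataclass
class FeatureIndex:
    """The searchable set of (plan_id, clinical feature vector)."""

    plan_ids: list[str]
    features: np.ndarray  # (n, 32)
    weights_fingerprint: str

    def __post_init__(self) -> None:
        if len(self.plan_ids) != len(set(self.plan_ids)):
            raise ValueError("duplicate plan ids in index")
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.plan_ids):
            raise ValueError("features must be (n_plans, dim)")

    def __len__(self) -> int:
        return len(self.plan_ids)

    def drop(self, plan_id: str) -> "FeatureIndex":
        """A copy of the index without one plan (leave-query-out)."""
        keep = [i for i, pid in enumerate(self.plan_ids) if pid != plan_id]
        return FeatureIndex(
            plan_ids=[self.plan_ids[i] for i in keep],
            features=self.features[keep],
            weights_fingerprint=self.weights_fingerprint,
        )


@dataclass
class RankedResult:
    """Query outcome: plans ordered by ascending feature distance."""

    query_id: str
    hits: list[tuple[str, float]]
    k: int


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Euclidean distance between two feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def build_index(weights: EncoderWeights, db: PlanDatabase) -> FeatureIndex:
    """Embed every plan's clinical dose into the searchable index."""
    if len(db) == 0:
        raise ValueError("empty plan database")
    vols = np.stack(
        [preprocess(r.clinical_dose, r.prescription_gy, weights.spec) for r in db]
    )
    feats = encode_batch(weights, vols)
    return FeatureIndex(
        plan_ids=db.plan_ids,
        features=feats,
        weights_fingerprint=weights_fingerprint(weights),
    )


def query(index: FeatureIndex, fv: np.ndarray, k: int = 3, query_id: str = "query") -> RankedResult:
    """Rank stored plans by distance to *fv*; ties break by ascending id.

    Exhaustive and exact; returns min(k, index size) hits with
    non-decreasing distances.
    """
    if len(index) == 0:
        raise ValueError("empty index")
    if k < 1:
        raise ValueError("k must be >= 1")
    fv = np.asarray(fv, dtype=np.float32).ravel()
    if fv.shape[0] != index.features.shape[1]:
        raise ValueError(
            f"feature dimension {fv.shape[0]} != index dimension {index.features.shape[1]}"
        )
    dists = np.linalg.norm(index.features - fv, axis=1).astype(float)
    order = sorted(range(len(index)), key=lambda i: (dists[i], index.plan_ids[i]))
    depth = min(k, len(index))
    hits = [(index.plan_ids[i], float(dists[i])) for i in order[:depth]]
    return RankedResult(query_id=query_id, hits=hits, k=k)


def retrieve_ops(db: PlanDatabase, result: RankedResult) -> list[Any]:
    """The stored OP payloads of the ranked hits, in rank order, unmodified."""
    payloads = []
    for pid, _ in result.hits:
        try:
            rec = db[pid]
        except KeyError:
            raise KeyError(f"ranked hit {pid!r} not found in database") from None
        payloads.append(rec.ops_payload)
    return payloads


def end_to_end_query(
    weights: EncoderWeights,
    index: FeatureIndex,
    db: PlanDatabase,
    query_record: PlanRecord,
    k: int = 3,
) -> tuple[RankedResult, list[Any]]:
    """Full pipeline: preprocess and embed the virtual dose, rank, fetch OPs."""
    if query_record.virtual_dose is None:
        raise ValueError(f"plan {query_record.plan_id} has no virtual dose to query with")
    vol = preprocess(query_record.virtual_dose, query_record.prescription_gy, weights.spec)
    fv = encode_batch(weights, vol[None])[0]
    result = query(index, fv, k=k, query_id=query_record.plan_id)
    return result, retrieve_ops(db, result)


def save_index(index: FeatureIndex, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "weights_fingerprint": index.weights_fingerprint,
        "entries": [
            {"plan_id": pid, "feature": [float(v) for v in feat]}
            for pid, feat in zip(index.plan_ids, index.features)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_index(path: str | Path) -> FeatureIndex:
    data = json.loads(Path(path).read_text())
    return FeatureIndex(
        plan_ids=[e["plan_id"] for e in data["entries"]],
        features=np.array([e["feature"] for e in data["entries"]], dtype=np.float32),
        weights_fingerprint=data["weights_fingerprint"],
    )
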