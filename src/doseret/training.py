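"""Triplet metric learning with in-batch hard negative mining.

The encoder is trained so that a patient's predicted ("virtual") dose image
(the anchor) embeds close to the same patient's clinically delivered dose
image (the positive) and far from the hardest other patient's dose in the
mini-batch (the mined negative).  For a batch of k patients the k x k
anchor-positive distance matrix D has entries

    D[i, j] = d(a_i, p_j) = sqrt(2 - 2 a_i . p_j),

which for unit vectors equals the Euclidean distance |a_i - p_j|.  The
hardest negative for anchor i is the smallest off-diagonal entry in row i
or column i of D, and the loss is the mean hinge

    Loss = (1/k) sum_i max(0, margin + D[i,i] - hardest_negative_i).

Training uses Adam under an inverse-time learning-rate decay
lr(t) = lr_init / (1 + decay * t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .core import PlanDatabase
from .encoder import EncoderSpec, EncoderWeights, build_network, preprocess

__all__ = [
    "TrainConfig",
    "TrainResult",
    "pair_distance",
    "distance_matrix",
    "batch_hard_loss",
    "learning_rate",
    "train_encoder",
]

_UNIT_TOL = 1e-5


@dataclass
class TrainConfig:
    """Optimization hyperparameters for triplet training."""

    margin: float = 1.0
    lr_init: float = 0.001
    decay: float = 0.01
    batch_size: int = 4
    iterations: int = 300
    seed: int = 0
    lr_policy: str = "inverse-time"  # or "literal"
    mine_negatives: bool = True

    def validate(self) -> None:
        if self.margin <= 0 or self.lr_init <= 0 or self.decay <= 0:
            raise ValueError("margin, lr_init and decay must be positive")
        if self.batch_size < 2 and self.mine_negatives:
            raise ValueError(
                "hard negative mining needs batch_size >= 2; "
                "set mine_negatives=False for k=1"
            )
        if self.lr_policy not in ("inverse-time", "literal"):
            raise ValueError(f"unknown lr policy {self.lr_policy!r}")


@dataclass
class TrainResult:
    weights: EncoderWeights
    loss_history: np.ndarray
    lr_history: np.ndarray


def _check_unit(v: np.ndarray, name: str) -> None:
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} is not unit norm (|{name}| = {n:.6f}); "
                         "enable encoder output normalization")


def pair_distance(a: np.ndarray, p: np.ndarray, check_unit: bool = True) -> float:
    """Anchor-positive distance sqrt(2 - 2 a.p) for unit vectors.

    The inner product is clamped to [-1, 1] before the radical, so the
    result lies in [0, 2]: 0 for identical vectors, sqrt(2) for orthogonal
    ones, 2 for antipodal ones.
    """
    a = np.asarray(a, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if a.shape != p.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {p.shape}")
    if check_unit:
        _check_unit(a, "a")
        _check_unit(p, "p")
    s = float(np.clip(a @ p, -1.0, 1.0))
    return float(np.sqrt(max(2.0 - 2.0 * s, 0.0)))


def distance_matrix(anchors: np.ndarray, positives: np.ndarray, check_unit: bool = True) -> np.ndarray:
    """The k x k mini-batch distance matrix, entry (i, j) = d(a_i, p_j)."""
    A = np.atleast_2d(np.asarray(anchors, dtype=float))
    P = np.atleast_2d(np.asarray(positives, dtype=float))
    if A.shape != P.shape:
        raise ValueError(f"anchor/positive shape mismatch: {A.shape} vs {P.shape}")
    if A.shape[0] < 1:
        raise ValueError("need at least one anchor-positive pair")
    if check_unit:
        for i, v in enumerate(A):
            _check_unit(v, f"a_{i}")
        for i, v in enumerate(P):
            _check_unit(v, f"p_{i}")
    S = np.clip(A @ P.T, -1.0, 1.0)
    return np.sqrt(np.maximum(2.0 - 2.0 * S, 0.0))


def _hardest_negatives(D: np.ndarray, exclude_diagonal: bool) -> np.ndarray:
    """Per anchor, min over off-diagonal row and column entries of D."""
    k = D.shape[0]
    masked = D.copy()
    if exclude_diagonal:
        np.fill_diagonal(masked, np.inf)
    row_min = masked.min(axis=1)
    col_min = masked.min(axis=0)
    return np.minimum(row_min, col_min)


def batch_hard_loss(
    D: np.ndarray, margin: float = 1.0, exclude_diagonal: bool = True
) -> float:
    """Mean hinge loss over anchors with in-batch hard negative mining.

    ``exclude_diagonal`` removes the anchor's own positive from the
    negative candidates; with it included the mined minimum can never
    exceed D[i, i] and the hinge saturates at the margin.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    k = D.shape[0]
    if k < 2:
        raise ValueError(
            "hard negative mining needs k >= 2 (a 1x1 batch has no negatives); "
            "disable mining for k = 1"
        )
    hardest = _hardest_negatives(D, exclude_diagonal)
    terms = np.maximum(0.0, margin + np.diag(D) - hardest)
    return float(terms.mean())


def _batch_hard_loss_grad(D: np.ndarray, margin: float) -> tuple[float, np.ndarray]:
    """Loss and dLoss/dD (subgradient; ties go to the first argmin)."""
    k = D.shape[0]
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    row_arg = masked.argmin(axis=1)
    col_arg = masked.argmin(axis=0)
    row_min = masked[np.arange(k), row_arg]
    col_min = masked[col_arg, np.arange(k)]
    hardest = np.minimum(row_min, col_min)
    terms = margin + np.diag(D) - hardest
    active = terms > 0
    loss = float(np.maximum(terms, 0.0).mean())
    grad = np.zeros_like(D)
    for i in np.flatnonzero(active):
        grad[i, i] += 1.0 / k
        if row_min[i] <= col_min[i]:
            grad[i, row_arg[i]] -= 1.0 / k
        else:
            grad[col_arg[i], i] -= 1.0 / k
    return loss, grad


def learning_rate(
    iteration: int,
    lr_init: float = 0.001,
    decay: float = 0.01,
    policy: str = "inverse-time",
) -> float:
    """Learning rate at a given iteration.

    The default inverse-time decay is lr_init / (1 + decay * iteration):
    strictly decreasing, equal to lr_init at iteration 0, and halved after
    1/decay iterations.  The ``literal`` policy lr_init * (1 + 1/(decay *
    iteration)) is kept for reference; it is not a decay (it approaches
    lr_init from above and diverges at iteration 1 for small decay).
    """
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if policy == "inverse-time":
        return lr_init / (1.0 + decay * iteration)
    if policy == "literal":
        if iteration == 0:
            return lr_init
        return lr_init * (1.0 + 1.0 / (decay * iteration))
    raise ValueError(f"unknown lr policy {policy!r}")


def _batch_indices(rng: np.random.Generator, n: int, k: int):
    """Yield k-sized batches of plan indices, reshuffling each epoch."""
    while True:
        order = rng.permutation(n)
        for start in range(0, n - k + 1, k):
            yield order[start : start + k]


def train_encoder(
    db: PlanDatabase,
    spec: EncoderSpec,
    cfg: TrainConfig,
    init: EncoderWeights | None = None,
) -> TrainResult:
    """Train the dose encoder on a plan database by triplet loss.

    Per iteration: sample ``batch_size`` patients without replacement,
    embed their virtual doses (anchors) and clinical doses (positives) in
    one forward pass, form the distance matrix, apply the batch-hard hinge
    loss, and take one Adam step at the scheduled learning rate.  Fully
    reproducible from ``cfg.seed``.
    """
    cfg.validate()
    spec.validate()
    n = len(db)
    if n < cfg.batch_size:
        raise ValueError(f"batch_size {cfg.batch_size} exceeds database size {n}")
    for rec in db:
        if rec.virtual_dose is None:
            raise ValueError(f"plan {rec.plan_id} has no virtual dose (training anchor)")

    # preprocess once: anchors from virtual doses, positives from clinical
    anchors = np.stack(
        [preprocess(r.virtual_dose, r.prescription_gy, spec) for r in db]
    )
    positives = np.stack(
        [preprocess(r.clinical_dose, r.prescription_gy, spec) for r in db]
    )

    rng = np.random.default_rng(cfg.seed)
    net = build_network(spec, np.random.default_rng(cfg.seed if init is None else init.init_seed))
    if init is not None:
        net.load_state_dict(init.state)
    init_seed = cfg.seed if init is None else init.init_seed
    opt = _nn.Adam(net)
    batches = _batch_indices(rng, n, cfg.batch_size)

    loss_history = np.empty(cfg.iterations)
    lr_history = np.empty(cfg.iterations)
    k = cfg.batch_size
    for it in range(cfg.iterations):
        idx = next(batches)
        batch = np.concatenate([anchors[idx], positives[idx]])[:, None]
        E = net.forward(batch.astype(np.float32), training=True)
        A, P = E[:k], E[k:]
        S = np.clip(A @ P.T, -1.0, 1.0)
        D = np.sqrt(np.maximum(2.0 - 2.0 * S, 1e-12))
        if cfg.mine_negatives and k >= 2:
            loss, dD = _batch_hard_loss_grad(D, cfg.margin)
        else:
            # no mining: hinge on the anchor-positive distance alone
            terms = cfg.margin + np.diag(D)
            loss = float(terms.mean())
            dD = np.eye(k) / k
        dS = dD * (-1.0 / D)  # dD/dS = -1/D
        dS[np.abs(S) >= 1.0] = 0.0  # clamp boundary
        dA = dS @ P
        dP = dS.T @ A
        net.backward(np.concatenate([dA, dP]).astype(np.float32))
        lr = learning_rate(it, cfg.lr_init, cfg.decay, cfg.lr_policy)
        opt.step(lr)
        loss_history[it] = loss
        lr_history[it] = lr

    weights = EncoderWeights(spec=spec, state=net.state_dict(), init_seed=init_seed)
    return TrainResult(weights=weights, loss_history=loss_history, lr_history=lr_history)
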