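"""The 3D convolutional dose-image encoder.

Maps a prescription-normalized 3D dose volume to a unit 32-dimensional
feature vector.  The architecture is five convolutional stages: an initial
3x3x3 convolution quadrupling the channel count (ReLU then batch
normalization), followed by three blocks that each double the channels and
halve every spatial extent with 2x2x2 max pooling, and a fully connected
head producing 32 features.  With a single dose channel the channel
progression is 1 -> 4 -> 8 -> 16 -> 32; after three pooling stages each
spatial extent is input/8, so input extents must be divisible by 8.

The output is L2-normalized by default, which makes the anchor-positive
distance sqrt(2 - 2*a.p) coincide with the plain Euclidean distance used
at query time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _nn
from .core import DoseGrid

__all__ = [
    "EncoderSpec",
    "EncoderWeights",
    "preprocess",
    "init_encoder",
    "encode",
    "encode_batch",
    "build_network",
    "save_weights",
    "load_weights",
    "weights_fingerprint",
]

#: dose is divided by prescription then clipped to this ceiling (150% of Rx)
DOSE_CLIP = 1.5


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture hyperparameters of the dose encoder."""

    input_shape: tuple[int, int, int] = (32, 32, 32)
    in_channels: int = 1
    feature_dim: int = 32
    normalize_output: bool = True
    #: ReLU after BN inside the pooling blocks; without it the three blocks
    #: collapse into a single linear map. Disable for a literal
    #: conv->BN->pool reading.
    relu_in_blocks: bool = True

    def validate(self) -> None:
        if any(n % 8 != 0 or n < 8 for n in self.input_shape):
            raise ValueError(
                f"input extents must be divisible by 8, got {self.input_shape}"
            )

    @property
    def channel_progression(self) -> tuple[int, ...]:
        c = self.in_channels
        return (c, 4 * c, 8 * c, 16 * c, 32 * c)

    @property
    def fc_in_features(self) -> int:
        nx, ny, nz = (n // 8 for n in self.input_shape)
        return nx * ny * nz * self.channel_progression[-1]


@dataclass
class EncoderWeights:
    """All learnable parameters plus batch-norm running statistics."""

    spec: EncoderSpec
    state: dict[str, np.ndarray]
    init_seed: int

    def copy(self) -> "EncoderWeights":
        return EncoderWeights(
            spec=self.spec,
            state={k: v.copy() for k, v in self.state.items()},
            init_seed=self.init_seed,
        )


def build_network(spec: EncoderSpec, rng: np.random.Generator) -> _nn.Sequential:
    """Construct the encoder network with freshly initialized parameters."""
    spec.validate()
    ch = spec.channel_progression
    layers: list[_nn.Layer] = [
        _nn.Conv3d(ch[0], ch[1], rng),
        _nn.ReLU(),
        _nn.BatchNorm3d(ch[1]),
    ]
    for cin, cout in zip(ch[1:-1], ch[2:]):
        layers.append(_nn.Conv3d(cin, cout, rng))
        layers.append(_nn.BatchNorm3d(cout))
        if spec.relu_in_blocks:
            layers.append(_nn.ReLU())
        layers.append(_nn.MaxPool3d())
    layers.append(_nn.Flatten())
    layers.append(_nn.Linear(spec.fc_in_features, spec.feature_dim, rng))
    if spec.normalize_output:
        layers.append(_nn.L2Normalize())
    return _nn.Sequential(layers)


def init_encoder(spec: EncoderSpec, seed: int) -> EncoderWeights:
    """Glorot-normal initialization, zero biases, identity BN statistics.

    Deterministic given *seed*.
    """
    net = build_network(spec, np.random.default_rng(seed))
    return EncoderWeights(spec=spec, state=net.state_dict(), init_seed=seed)


def preprocess(
    dose: DoseGrid | np.ndarray, prescription: float, spec: EncoderSpec
) -> np.ndarray:
    """Normalize a dose volume for the encoder.

    Divides by the prescription, clips to [0, 1.5] (relative dose rarely
    exceeds 150% of Rx in a deliverable plan) and resamples to the encoder
    input shape with trilinear interpolation.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {values.shape}")
    arr = np.clip(values.astype(np.float32) / prescription, 0.0, DOSE_CLIP)
    if arr.shape != tuple(spec.input_shape):
        factors = [t / s for t, s in zip(spec.input_shape, arr.shape)]
        arr = ndimage.zoom(arr, factors, order=1, mode="nearest", grid_mode=True)
        arr = np.clip(arr.astype(np.float32), 0.0, DOSE_CLIP)
        # zoom can be off by one voxel on awkward ratios; enforce the contract
        if arr.shape != tuple(spec.input_shape):
            raise RuntimeError(f"resampling produced {arr.shape}, wanted {spec.input_shape}")
    return arr


def _restore(weights: EncoderWeights) -> _nn.Sequential:
    net = build_network(weights.spec, np.random.default_rng(0))
    net.load_state_dict(weights.state)
    return net


def encode_batch(weights: EncoderWeights, volumes: np.ndarray) -> np.ndarray:
    """Embed a batch of preprocessed volumes, shape (n, *input_shape).

    Evaluation mode: batch-norm uses frozen running statistics, so the
    result is a pure function of (weights, volume) regardless of batching.
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    if volumes.ndim == 3:
        volumes = volumes[None]
    if volumes.shape[1:] != tuple(weights.spec.input_shape):
        raise ValueError(
            f"volume shape {volumes.shape[1:]} != encoder input {weights.spec.input_shape}"
        )
    net = _restore(weights)
    return net.forward(volumes[:, None], training=False)


def encode(weights: EncoderWeights, volume: np.ndarray) -> np.ndarray:
    """Embed one preprocessed volume into a 32-d feature vector."""
    return encode_batch(weights, volume)[0]


def weights_fingerprint(weights: EncoderWeights) -> str:
    """A short checksum identifying a parameter set."""
    import hashlib

    h = hashlib.sha256()
    for k in sorted(weights.state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(weights.state[k]).tobytes())
    return h.hexdigest()[:16]


_FORMAT_VERSION = 1


def save_weights(weights: EncoderWeights, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(
        format_version=_FORMAT_VERSION,
        input_shape=weights.spec.input_shape,
        in_channels=weights.spec.in_channels,
        feature_dim=weights.spec.feature_dim,
        normalize_output=int(weights.spec.normalize_output),
        relu_in_blocks=int(weights.spec.relu_in_blocks),
        init_seed=weights.init_seed,
    )
    np.savez(path, __meta__=np.array([repr(meta)]), **weights.state)
    return path


def load_weights(path: str | Path) -> EncoderWeights:
    import ast

    with np.load(path, allow_pickle=False) as data:
        meta = ast.literal_eval(str(data["__meta__"][0]))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported weights format {meta['format_version']}")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = EncoderSpec(
        input_shape=tuple(meta["input_shape"]),
        in_channels=meta["in_channels"],
        feature_dim=meta["feature_dim"],
        normalize_output=bool(meta["normalize_output"]),
        relu_in_blocks=bool(meta["relu_in_blocks"]),
    )
    return EncoderWeights(spec=spec, state=state, init_seed=meta["init_seed"])
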