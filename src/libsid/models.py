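"""Residual-network classifiers for LIBS spectra.

The family comprises one architecture in two input dimensionalities —
a single spectrum (1D) or the 3-row spectral matrix of one seed (2D) —
and three treatments of the residual shortcut's propagation
coefficient W:

* ``FIXED``     — W = 1 in every block (a plain residual network),
* ``PER_BLOCK`` — four independent trainable scalars W1..W4,
* ``SHARED``    — a single trainable scalar W* used by all four blocks
  and updated synchronously, so W1 = W2 = W3 = W4 = W* at all times.

Layer order: stem convolution (64 channels, kernel 7, padding 3,
stride 2) + BN + ReLU, max pooling (kernel 3, stride 2, padding 1),
four residual blocks with channels 64, 64, 128, 128 (kernel 3,
padding 1, stride 1), global average pooling, and a dense layer to the
class scores.  On 2D inputs the 3-row axis is convolved with the same
kernels; any strided stage switches that axis's stride to 1 once its
size is 2 or less, so the row dimension never collapses below 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum
import numpy as np

from . import nn

__all__ = [
    "PropagationMode",
    "NetworkSpec",
    "Network",
    "build_network",
    "residual_block_forward",
    "trainable_propagation_coefficients",
    "save_checkpoint",
    "load_checkpoint",
]


class PropagationMode(str, Enum):
    FIXED = "fixed"
    PER_BLOCK = "per_block"
    SHARED = "shared"


@dataclass(frozen=True)
class ResBlockSpec:
    """One residual block: kernel 3, padding 1, stride 1 are fixed."""
    channels: int
    kernel: int = 3
    padding: int = 1
    stride: int = 1


@dataclass(frozen=True)
class NetworkSpec:
    dims: int                      # 1 or 2
    input_length: int              # P, number of kept wavelengths
    n_rows: int = 3                # spectra per seed (2D only)
    stem_channels: int = 64
    block_channels: tuple = (64, 64, 128, 128)
    n_classes: int = 10
    mode: PropagationMode = PropagationMode.FIXED
    dtype: str = "float32"

    def __post_init__(self):
        if self.dims not in (1, 2):
            raise ValueError("dims must be 1 or 2")
        if len(self.block_channels) < 1:
            raise ValueError("at least one residual block required")
        if self.input_length < 1:
            raise ValueError("input_length must be positive")


def _guard_stride(size: int, stride: int) -> int:
    """Strided stages keep stride 1 on an axis whose size is <= 2."""
    return 1 if size <= 2 else stride


class Network:
    """A built classifier; see module docstring for the layer order.

    ``forward`` accepts raw arrays shaped ``(N, P)`` (1D) or
    ``(N, rows, P)`` (2D); a trailing channel axis is added internally.
    Intermediate activations at the stem max-pool, the last residual
    block and the dense layer can be captured for feature extraction.
    """

    CAPTURE_LAYERS = ("MaxPool", "Block4", "Dense")

    def __init__(self, spec: NetworkSpec, rng_seed: int = 0):
        self.spec = spec
        dtype = np.dtype(spec.dtype).type
        rng = np.random.default_rng(rng_seed)
        nd = spec.dims
        if nd == 1:
            spatial = (spec.input_length,)
        else:
            spatial = (spec.n_rows, spec.input_length)
        if spec.input_length + 6 < 7:
            raise ValueError("input shorter than the stem receptive field")

        stem_stride = tuple(_guard_stride(s, 2) for s in spatial)
        self.stem_conv = nn.Conv(1, spec.stem_channels, (7,) * nd,
                                 stem_stride, (3,) * nd, rng, dtype,
                                 name="stem")
        self.stem_bn = nn.BatchNorm(spec.stem_channels, dtype, name="stem_bn")
        self.stem_relu = nn.ReLU()
        sp = self.stem_conv.out_shape(spatial)
        pool_stride = tuple(_guard_stride(s, 2) for s in sp)
        self.pool = nn.MaxPool((3,) * nd, pool_stride, (1,) * nd)
        sp = self.pool.out_shape(sp)
        if any(s < 1 for s in sp):
            raise ValueError("input shorter than the stem receptive field")

        # propagation coefficients, initialized to 1.0 (plain ResNet start)
        n_blocks = len(spec.block_channels)
        if spec.mode is PropagationMode.FIXED:
            coeffs = [None] * n_blocks
            self._w_params: list[nn.Parameter] = []
        elif spec.mode is PropagationMode.PER_BLOCK:
            coeffs = [nn.Parameter(np.asarray(1.0, dtype=dtype), name=f"W{i+1}")
                      for i in range(n_blocks)]
            self._w_params = list(coeffs)
        else:  # SHARED: one Parameter object referenced by every block
            shared = nn.Parameter(np.asarray(1.0, dtype=dtype), name="W*")
            coeffs = [shared] * n_blocks
            self._w_params = [shared]

        self.blocks = []
        c_in = spec.stem_channels
        for i, c_out in enumerate(spec.block_channels):
            self.blocks.append(nn.ResidualBlock(
                c_in, c_out, nd, rng, coeffs[i], dtype, name=f"block{i+1}"))
            c_in = c_out
        self.gap = nn.GlobalAvgPool()
        self.dense = nn.Dense(c_in, spec.n_classes, rng, dtype, name="dense")
        self._feature_spatial = sp

    # ------------------------------------------------------------------
    @property
    def parameters(self) -> list[nn.Parameter]:
        ps = (self.stem_conv.parameters + self.stem_bn.parameters)
        for b in self.blocks:
            ps += b.parameters
        ps += self.dense.parameters
        ps += self._w_params
        return ps

    def block_coefficients(self) -> list[float]:
        """The per-block view of W, one value per residual block."""
        return [b.w_value for b in self.blocks]

    # ------------------------------------------------------------------
    def _with_channel(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.spec.dtype)
        expected = 1 + self.spec.dims
        if x.ndim == expected:
            return x[..., None]
        if x.ndim == expected + 1 and x.shape[-1] == 1:
            return x
        raise ValueError(f"expected input of ndim {expected}, got {x.ndim}")

    def forward(self, x, train=False, capture: dict | None = None):
        """Return class logits ``(N, n_classes)``.

        If ``capture`` is a dict it receives the activations at the
        capture layers ("MaxPool", "Block4", "Dense").
        """
        h = self._with_channel(x)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(h, train), train))
        h = self.pool.forward(h, train)
        if capture is not None:
            capture["MaxPool"] = h
        for b in self.blocks:
            h = b.forward(h, train)
        if capture is not None:
            capture["Block4"] = h
        h = self.gap.forward(h, train)
        logits = self.dense.forward(h, train)
        if capture is not None:
            capture["Dense"] = logits
        return logits

    def backward(self, dlogits) -> np.ndarray:
        """Backpropagate to the input; returns d(loss)/d(input)."""
        d = self.dense.backward(dlogits)
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.pool.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        d = self.stem_conv.backward(d)
        return d[..., 0]

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities in evaluation mode."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(nn.softmax(self.forward(x[i:i + batch_size],
                                                train=False)))
        return np.concatenate(outs, axis=0)

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()

    # ------------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {}
        for i, p in enumerate(self.parameters):
            arrs[f"param_{i}"] = p.value
        bns = [self.stem_bn] + [bn for b in self.blocks
                                for bn in (b.bn1, b.bn2)]
        for i, bn in enumerate(bns):
            arrs[f"bn_{i}_mean"] = bn.running_mean
            arrs[f"bn_{i}_var"] = bn.running_var
        return arrs

    def load_state_arrays(self, arrs) -> None:
        for i, p in enumerate(self.parameters):
            p.value[...] = arrs[f"param_{i}"]
        bns = [self.stem_bn] + [bn for b in self.blocks
                                for bn in (b.bn1, b.bn2)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = arrs[f"bn_{i}_mean"]
            bn.running_var[...] = arrs[f"bn_{i}_var"]

    def describe(self) -> str:
        """A human-readable layer table."""
        s = self.spec
        lines = [f"{'layer':<12}{'channels':<10}{'kernel/stride':<16}notes",
                 f"{'stem conv':<12}{s.stem_channels:<10}{'7 / 2':<16}pad 3",
                 f"{'max pool':<12}{'-':<10}{'3 / 2':<16}pad 1"]
        for i, c in enumerate(s.block_channels):
            lines.append(f"{f'RES.Block{i+1}':<12}{c:<10}{'3 / 1':<16}"
                         f"W={self.blocks[i].w_value:+.4f}")
        lines.append(f"{'global avg':<12}{'-':<10}{'-':<16}")
        lines.append(f"{'dense':<12}{s.n_classes:<10}{'-':<16}softmax head")
        lines.append(f"mode={s.mode.value}  dims={s.dims}  "
                     f"input_length={s.input_length}")
        return "\n".join(lines)


def build_network(spec: NetworkSpec, rng_seed: int = 0) -> Network:
    """Build a network with seeded He-normal initialization."""
    return Network(spec, rng_seed=rng_seed)


def residual_block_forward(x: np.ndarray, block: nn.ResidualBlock,
                           train: bool = False) -> np.ndarray:
    """Run one residual block on a channel-last feature map."""
    return block.forward(np.asarray(x), train=train)


def trainable_propagation_coefficients(network: Network) -> list[float]:
    """Current values of the trainable W coefficients.

    FIXED mode has none; PER_BLOCK has four (W1..W4); SHARED has one
    (W*), of which the four per-block views are always identical.
    """
    return [float(p.value) for p in network._w_params]


# ----------------------------------------------------------------------
def save_checkpoint(network: Network, path) -> None:
    """Single-file archive holding the spec and all weights/statistics."""
    spec = asdict(network.spec)
    spec["mode"] = network.spec.mode.value
    arrs = network.state_arrays()
    np.savez(path, spec_json=np.frombuffer(
        json.dumps(spec).encode(), dtype=np.uint8), **arrs)


def load_checkpoint(path) -> Network:
    with np.load(path) as data:
        spec_d = json.loads(bytes(data["spec_json"]).decode())
        spec_d["mode"] = PropagationMode(spec_d["mode"])
        spec_d["block_channels"] = tuple(spec_d["block_channels"])
        spec = NetworkSpec(**spec_d)
        net = Network(spec)
        net.load_state_arrays(data)
    return net
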