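"""UNet++ synthesis generator.

The network is a nested encoder–decoder: an encoder column of residual
bottleneck blocks produces one feature map per scale (five scales in the
full-size preset), and every decoder node X^{i,j} (j > 0) receives the
concatenation of all same-scale predecessors X^{i,0..j-1} with the
bilinearly upsampled X^{i+1,j-1} — the dense skip pathway that
distinguishes UNet++ from a plain U-Net. The synthesis head is a linear
1×1 convolution on X^{0,depth-1}, emitting one channel of normalized
intensities from a 3-channel 2.5-D input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .errors import ConfigurationError, ModelStateError

__all__ = ["ArchConfig", "SynthesisModel", "build_model", "forward", "count_scales",
           "save_checkpoint", "load_checkpoint", "TINY_PRESET", "FULL_PRESET"]


@dataclass
class ArchConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of scales; input spatial size must be divisible
    by ``2**(depth - 1)``. Channel width at scale i is
    ``base_channels * channel_multiplier**i``.
    """

    depth: int = 5
    base_channels: int = 32
    channel_multiplier: int = 2
    encoder_block: str = "bottleneck"  # residual bottleneck encoder stages
    input_channels: int = 3
    output_channels: int = 1

    def validate(self) -> None:
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if self.encoder_block not in ("bottleneck", "double"):
            raise ConfigurationError(f"unknown encoder_block {self.encoder_block!r}")

    def channels(self, scale: int) -> int:
        return self.base_channels * self.channel_multiplier**scale


TINY_PRESET = ArchConfig(depth=3, base_channels=8)
FULL_PRESET = ArchConfig(depth=5, base_channels=32)


def _he_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> ad.Tensor:
    std = np.sqrt(2.0 / (cin * k * k))
    w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
    return ad.Tensor(w, requires_grad=True)


class _Conv:
    def __init__(self, rng, cin, cout, k):
        self.w = _he_conv(rng, cout, cin, k)
        self.b = ad.Tensor(np.zeros((cout, 1, 1, 1), dtype=np.float32), requires_grad=True)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.conv2d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]


class _ResBottleneck:
    """Residual bottleneck stage: 1×1 reduce → 3×3 → 1×1 expand, plus a
    projected identity shortcut (ResNet-style)."""

    def __init__(self, rng, cin, cout):
        mid = max(cout // 2, 4)
        self.c1 = _Conv(rng, cin, mid, 1)
        self.c2 = _Conv(rng, mid, mid, 3)
        self.c3 = _Conv(rng, mid, cout, 1)
        self.proj = _Conv(rng, cin, cout, 1) if cin != cout else None

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        h = ad.relu(self.c1(x))
        h = ad.relu(self.c2(h))
        h = self.c3(h)
        shortcut = self.proj(x) if self.proj is not None else x
        return ad.relu(h + shortcut)

    @property
    def params(self):
        out = self.c1.params + self.c2.params + self.c3.params
        if self.proj is not None:
            out += self.proj.params
        return out


class _DoubleConv:
    """Plain 3×3–3×3 block used for decoder nodes (and the 'double' encoder)."""

    def __init__(self, rng, cin, cout):
        self.c1 = _Conv(rng, cin, cout, 3)
        self.c2 = _Conv(rng, cout, cout, 3)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.relu(self.c2(ad.relu(self.c1(x))))

    @property
    def params(self):
        return self.c1.params + self.c2.params


class SynthesisModel:
    """UNet++ generator with the full nested-skip node set {X^{i,j}: i+j < depth}."""

    def __init__(self, cfg: ArchConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        d = cfg.depth
        enc_cls = _ResBottleneck if cfg.encoder_block == "bottleneck" else _DoubleConv
        self.blocks: dict[tuple[int, int], object] = {}
        for i in range(d):
            cin = cfg.input_channels if i == 0 else cfg.channels(i - 1)
            self.blocks[(i, 0)] = enc_cls(rng, cin, cfg.channels(i))
        for j in range(1, d):
            for i in range(d - j):
                cin = j * cfg.channels(i) + cfg.channels(i + 1)
                self.blocks[(i, j)] = _DoubleConv(rng, cin, cfg.channels(i))
        # residual synthesis head: the network predicts the correction to the
        # center input slice. Zero-initialized, so the untrained model is the
        # identity map — optimization starts from the CBCT instead of noise.
        self.head = _Conv(rng, cfg.channels(0), cfg.output_channels, 1)
        self.head.w.data[:] = 0.0

    # ---- structure -------------------------------------------------------
    @property
    def node_graph(self) -> dict[tuple[int, int], dict]:
        """Wiring of every node: same-scale predecessors + the upsampled one."""
        d = self.cfg.depth
        graph = {}
        for (i, j) in self.blocks:
            if j == 0:
                preds = {"same_scale": [], "upsampled": None,
                         "pooled": (i - 1, 0) if i > 0 else None}
            else:
                preds = {"same_scale": [(i, jj) for jj in range(j)],
                         "upsampled": (i + 1, j - 1), "pooled": None}
            graph[(i, j)] = preds
        graph["head"] = {"same_scale": [(0, d - 1)], "upsampled": None, "pooled": None}
        return graph

    @property
    def parameters(self) -> list[ad.Tensor]:
        out = []
        for key in sorted(self.blocks):
            out += self.blocks[key].params
        out += self.head.params
        return out

    # ---- inference -------------------------------------------------------
    def _check_spatial(self, h: int, w: int) -> None:
        f = 2 ** (self.cfg.depth - 1)
        if h % f or w % f:
            raise ConfigurationError(
                f"spatial size {h}x{w} not divisible by 2^(depth-1) = {f}"
            )

    def forward_graph(self, x: ad.Tensor) -> ad.Tensor:
        """Differentiable forward pass on a channel-first (C, N, H, W) tensor."""
        c, n, h, w = x.data.shape
        if c != self.cfg.input_channels:
            raise ConfigurationError(
                f"expected {self.cfg.input_channels} input channels, got {c}"
            )
        self._check_spatial(h, w)
        d = self.cfg.depth
        nodes: dict[tuple[int, int], ad.Tensor] = {}
        nodes[(0, 0)] = self.blocks[(0, 0)](x)
        for i in range(1, d):
            nodes[(i, 0)] = self.blocks[(i, 0)](ad.maxpool2(nodes[(i - 1, 0)]))
        for j in range(1, d):
            for i in range(d - j):
                inputs = [nodes[(i, jj)] for jj in range(j)]
                inputs.append(ad.upsample2_bilinear(nodes[(i + 1, j - 1)]))
                nodes[(i, j)] = self.blocks[(i, j)](ad.concat(inputs, axis=0))
        center = ad.Tensor(x.data[c // 2 : c // 2 + 1])
        return self.head(nodes[(0, d - 1)]) + center

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference on (N, C, H, W) or (C, H, W); deterministic."""
        arr = np.asarray(batch, dtype=np.float32)
        squeeze = arr.ndim == 3
        if squeeze:
            arr = arr[None]
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in model input")
        cf = np.ascontiguousarray(arr.transpose(1, 0, 2, 3))
        out = self.forward_graph(ad.Tensor(cf)).data.transpose(1, 0, 2, 3)
        return out[0] if squeeze else out

    # ---- (de)serialization ----------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters)}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters
        for i, p in enumerate(params):
            src = arrays[f"p{i}"]
            if src.shape != p.data.shape:
                raise ConfigurationError("checkpoint shape mismatch")
            p.data = src.astype(np.float32).copy()


def build_model(cfg: ArchConfig | None = None, seed: int = 0) -> SynthesisModel:
    """Build a generator with deterministic parameter initialization."""
    return SynthesisModel(cfg if cfg is not None else ArchConfig(), seed)


def forward(model: SynthesisModel, stack) -> np.ndarray:
    """Synthesize one in-plane grid from a 2.5-D slice stack (normalized units)."""
    channels = stack.channels if hasattr(stack, "channels") else np.asarray(stack)
    return model.predict(channels)[0]


def count_scales(model: SynthesisModel) -> int:
    """Number of distinct feature scales (= encoder downsampling stages + 1)."""
    return model.cfg.depth


def save_checkpoint(model: SynthesisModel, path: str | Path, extra: dict | None = None) -> Path:
    """Serialize weights + ArchConfig (+ optional metadata) into one .npz file."""
    path = Path(path)
    meta = {"cfg": asdict(model.cfg), "seed": model.seed, "trained": model.trained}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_arrays())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[SynthesisModel, dict]:
    """Rebuild a model (and its metadata) from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    model = SynthesisModel(ArchConfig(**meta["cfg"]), seed=meta.get("seed", 0))
    model.load_state_arrays(arrays)
    model.trained = bool(meta.get("trained", True))
    if "norm_stats" in meta:
        from .preprocess import NormStats

        model.norm_stats = NormStats(**meta["norm_stats"])
    return model, meta
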