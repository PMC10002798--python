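"""The McEUN segmentation network.

A U-Net variant with one multi-channel-input encoder and an assembly of six
decoders, one per tissue class.  Skip connections between encoder levels and
every decoder pass through additive attention gates; dropout is applied at
the bottleneck.  Each decoder ends in a single-channel score map; voxelwise
class probabilities are obtained by softmax normalization across the six
heads.  Kernel weights use the Glorot-normal initializer and all biases
start at the constant 0.03.

Runs in 2-D slice mode: volumes are segmented as stacks of transaxial
slices, which keeps training tractable on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag

__all__ = ["McEUNConfig", "McEUN", "build_mceun", "predict_segmentation", "Adam"]

N_CLASSES = 6
BIAS_INIT = 0.03


@dataclass
class McEUNConfig:
    """Architecture hyperparameters.

    ``depth`` counts resolution levels (``depth - 1`` poolings); input
    spatial size must be divisible by ``2**(depth-1)``.
    """

    in_channels: int = 2
    depth: int = 3
    base_filters: int = 8
    dropout_rate: float = 0.15
    attention_channels: int = 4
    class_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")


def _glorot_normal(rng, shape):
    f, c, kh, kw = shape
    fan_in, fan_out = c * kh * kw, f * kh * kw
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class McEUN:
    """Multi-channel-input, six-decoder, attention-gated U-Net (2-D)."""

    def __init__(self, config: McEUNConfig, seed: int = 0) -> None:
        self.config = config
        self.params: dict[str, ag.Tensor] = {}
        rng = np.random.default_rng(seed)
        ch = [config.base_filters * 2**lvl for lvl in range(config.depth)]
        self.channels = ch

        def conv(name, cin, cout, k=3):
            self.params[f"{name}.w"] = ag.Tensor(
                _glorot_normal(rng, (cout, cin, k, k)), requires_grad=True,
                name=f"{name}.w",
            )
            self.params[f"{name}.b"] = ag.Tensor(
                np.full(cout, BIAS_INIT, dtype=np.float32), requires_grad=True,
                name=f"{name}.b",
            )

        # encoder: a conv pair per level
        cin = config.in_channels
        for lvl in range(config.depth):
            conv(f"enc{lvl}.0", cin, ch[lvl])
            conv(f"enc{lvl}.1", ch[lvl], ch[lvl])
            cin = ch[lvl]
        # six decoders with attention-gated skips
        ci = config.attention_channels
        for d in range(N_CLASSES):
            for lvl in range(config.depth - 2, -1, -1):
                up_c = ch[lvl + 1]
                conv(f"dec{d}.ag{lvl}.g", up_c, ci, k=1)
                conv(f"dec{d}.ag{lvl}.x", ch[lvl], ci, k=1)
                conv(f"dec{d}.ag{lvl}.psi", ci, 1, k=1)
                conv(f"dec{d}.lvl{lvl}.0", up_c + ch[lvl], ch[lvl])
                conv(f"dec{d}.lvl{lvl}.1", ch[lvl], ch[lvl])
            conv(f"dec{d}.head", ch[0], 1, k=1)

    # -- building blocks ---------------------------------------------------
    def _conv_block(self, name, x):
        x = ag.relu(ag.conv2d(x, self.params[f"{name}.0.w"],
                              self.params[f"{name}.0.b"]))
        return ag.relu(ag.conv2d(x, self.params[f"{name}.1.w"],
                                 self.params[f"{name}.1.b"]))

    def _attention_gate(self, name, skip, gate_coarse):
        """Additive attention: the coarser-level gating signal selects
        salient regions of the skip features."""
        g = ag.conv2d(ag.upsample2(gate_coarse), self.params[f"{name}.g.w"],
                      self.params[f"{name}.g.b"])
        xg = ag.conv2d(skip, self.params[f"{name}.x.w"],
                       self.params[f"{name}.x.b"])
        q = ag.relu(ag.add(g, xg))
        alpha = ag.sigmoid(ag.conv2d(q, self.params[f"{name}.psi.w"],
                                     self.params[f"{name}.psi.b"]))
        return ag.mul(skip, alpha)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> ag.Tensor:
        """Logits tensor (N, 6, H, W) for a batch of 2-D slices."""
        cfg = self.config
        n, c, h, w = x.shape
        div = 2 ** (cfg.depth - 1)
        if h % div or w % div:
            raise ValueError(f"spatial size must be divisible by {div}")
        t = ag.Tensor(x)
        skips = []
        for lvl in range(cfg.depth):
            t = self._conv_block(f"enc{lvl}", t)
            if lvl < cfg.depth - 1:
                skips.append(t)
                t = ag.maxpool2(t)
        if train and cfg.dropout_rate > 0:
            t = ag.dropout(t, cfg.dropout_rate,
                           rng or np.random.default_rng(0), train=True)
        heads = []
        for d in range(N_CLASSES):
            dec = t
            for lvl in range(cfg.depth - 2, -1, -1):
                gated = self._attention_gate(f"dec{d}.ag{lvl}", skips[lvl], dec)
                dec = ag.concat([ag.upsample2(dec), gated], axis=1)
                dec = self._conv_block(f"dec{d}.lvl{lvl}", dec)
            heads.append(ag.conv2d(dec, self.params[f"dec{d}.head.w"],
                                   self.params[f"dec{d}.head.b"]))
        return ag.concat(heads, axis=1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (N, 6, H, W); deterministic."""
        return ag.softmax_channels(self.forward(x, train=False).data)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)


def build_mceun(config: McEUNConfig | None = None, seed: int = 0) -> McEUN:
    """Construct and initialize a McEUN (Glorot-normal kernels, 0.03 biases)."""
    return McEUN(config or McEUNConfig(), seed=seed)


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, ag.Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )


def predict_segmentation(
    network: McEUN,
    scatter_recon: np.ndarray,
    photopeak_recon: np.ndarray,
    batch_slices: int = 16,
) -> np.ndarray:
    """Voxelwise arg-max six-class label volume from the two initial
    estimates (scatter-window and photopeak NAC reconstructions)."""
    import warnings

    for name, vol in (("scatter", scatter_recon), ("photopeak", photopeak_recon)):
        sup = vol > 0
        if sup.any() and abs(float(vol[sup].mean()) - 1.0) > 0.5:
            warnings.warn(
                f"{name} reconstruction does not look unit-mean normalized",
                stacklevel=2,
            )
    x = np.stack([scatter_recon, photopeak_recon], axis=0).astype(np.float32)
    nz = x.shape[3]
    labels = np.empty(scatter_recon.shape, dtype=np.uint8)
    for z0 in range(0, nz, batch_slices):
        zs = range(z0, min(z0 + batch_slices, nz))
        batch = np.stack([x[:, :, :, z] for z in zs], axis=0)
        proba = network.predict_proba(batch)
        lab = np.argmax(proba, axis=1).astype(np.uint8)
        for i, z in enumerate(zs):
            labels[:, :, z] = lab[i]
    return labels
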