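"""Densely connected constant-resolution denoising network.

Seven layers, each a composite of batch normalisation, ReLU and a 3x3
convolution, wired densely: layer ``l`` consumes the channel-wise
concatenation of 1x1-remapped outputs of layers ``0..l-2`` plus the raw
output of layer ``l-1``.  The 1x1 maps unify older feature maps to
``C(x_{l-1}) // (L-1)`` channels (floored at 1) so the concatenated input
cannot grow without bound.  Spatial dimensions are preserved everywhere —
no pooling, striding or resampling — and the final layer emits a single
channel: the rib-suppressed image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ribsuppress.sadxnet.autodiff import (
    Tensor, batchnorm2d, concat, conv1x1, conv2d, relu,
)

__all__ = ["NetConfig", "SADXNet", "channel_plan"]


@dataclass(frozen=True)
class NetConfig:
    """Channel schedule of the dense network.

    ``channels[l-1]`` is the output-channel count of layer ``l``; the
    schedule rises then falls and the last layer must emit one channel.
    """

    channels: tuple = (16, 32, 64, 128, 64, 32, 1)

    def __post_init__(self):
        if len(self.channels) < 2:
            raise ValueError("need at least two layers")
        if self.channels[-1] != 1:
            raise ValueError("the final layer must output one channel")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel counts must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.channels)


def channel_plan(cfg: NetConfig, in_channels: int = 1) -> list[dict]:
    """Symbolic channel bookkeeping of the dense wiring.

    For each layer ``l`` (1-based) reports the unified width of the 1x1 maps
    ``unify = max(1, C(x_{l-1}) // (L-1))``, the number of remapped older
    inputs ``l - 1``, the concatenated input width
    ``(l-1) * unify + C(x_{l-1})``, and the output width.
    """
    L = cfg.n_layers
    outs = [in_channels] + list(cfg.channels)
    plan = []
    for l in range(1, L + 1):
        prev = outs[l - 1]
        unify = max(1, prev // (L - 1))
        n_old = l - 1
        plan.append({
            "layer": l,
            "unify_channels": unify,
            "n_unified_inputs": n_old,
            "in_channels": n_old * unify + prev,
            "out_channels": outs[l],
        })
    return plan


class SADXNet:
    """The dense denoising network with its parameters.

    Parameters are float64 numpy arrays wrapped in autodiff Tensors; the
    initialisation is He-style and fully determined by ``seed``.
    """

    def __init__(self, config: NetConfig = NetConfig(), seed: int = 0,
                 in_channels: int = 1):
        self.config = config
        self.in_channels = in_channels
        self.plan = channel_plan(config, in_channels)
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self.running: dict[str, dict] = {}
        outs = [in_channels] + list(config.channels)
        for entry in self.plan:
            l = entry["layer"]
            cin = entry["in_channels"]
            cout = entry["out_channels"]
            unify = entry["unify_channels"]
            for j in range(entry["n_unified_inputs"]):
                src = outs[j]     # 1x1 map applied to x_j, j = 0..l-2
                w = rng.standard_normal((unify, src)) * np.sqrt(2.0 / src)
                self.params[f"l{l}_u{j}_w"] = Tensor(w, requires_grad=True)
            self.params[f"l{l}_bn_gamma"] = Tensor(np.ones(cin), requires_grad=True)
            self.params[f"l{l}_bn_beta"] = Tensor(np.zeros(cin), requires_grad=True)
            self.running[f"l{l}"] = {"mean": np.zeros(cin), "var": np.ones(cin)}
            w = rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / (cin * 9))
            self.params[f"l{l}_conv_w"] = Tensor(w, requires_grad=True)
            self.params[f"l{l}_conv_b"] = Tensor(np.zeros(cout), requires_grad=True)

    # ------------------------------------------------------------------
    def forward(self, x, training: bool = True, return_intermediates: bool = False):
        """Run the network on an (N, 1, H, W) batch; output is (N, 1, H, W)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.data.shape}")
        xs = [x]
        for entry in self.plan:
            l = entry["layer"]
            pieces = [conv1x1(xs[j], self.params[f"l{l}_u{j}_w"])
                      for j in range(entry["n_unified_inputs"])]
            pieces.append(xs[l - 1])
            z = pieces[0] if len(pieces) == 1 else concat(pieces, axis=1)
            z = batchnorm2d(z, self.params[f"l{l}_bn_gamma"],
                            self.params[f"l{l}_bn_beta"],
                            running=self.running[f"l{l}"], training=training)
            z = relu(z)
            z = conv2d(z, self.params[f"l{l}_conv_w"], self.params[f"l{l}_conv_b"])
            xs.append(z)
        if return_intermediates:
            return xs[-1], xs
        return xs[-1]

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single forward pass in eval mode on one 2-D image."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("predict expects a single 2-D grayscale image")
        out = self.forward(image[None, None], training=False)
        return out.data[0, 0]

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.params.items()}
        for k, r in self.running.items():
            state[f"running_{k}_mean"] = r["mean"].copy()
            state[f"running_{k}_var"] = r["var"].copy()
        return state

    def load_state_dict(self, state: dict):
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64)
        for k, r in self.running.items():
            r["mean"] = np.asarray(state[f"running_{k}_mean"], dtype=np.float64)
            r["var"] = np.asarray(state[f"running_{k}_var"], dtype=np.float64)

    def save(self, path):
        """Single-file checkpoint with the net config embedded."""
        meta = json.dumps({"channels": list(self.config.channels),
                           "in_channels": self.in_channels})
        np.savez_compressed(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **self.state_dict())

    @classmethod
    def load(cls, path) -> "SADXNet":
        with np.load(Path(path)) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            net = cls(NetConfig(channels=tuple(meta["channels"])),
                      in_channels=meta["in_channels"])
            net.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
        return net
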