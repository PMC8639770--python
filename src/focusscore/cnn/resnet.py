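"""18-layer residual network with a single-logit head for binary output.

The standard basic-block residual architecture: a 7x7 stride-2 stem, 3x3
stride-2 max pool, four stages of two basic blocks with channel widths
(w, 2w, 4w, 8w), global average pooling and a linear head.  ``base_width``
w = 64 gives the canonical 18-layer network; smaller widths keep the same
depth and topology for CPU-scale experiments.
"""

from __future__ import annotations

import numpy as np

from .nn import (Adam, BasicBlock, BatchNorm2d, Conv2d, GlobalAvgPool, Layer,
                 Linear, MaxPool2d, ReLU, Sequential)

__all__ = ["ResNet18", "build_model"]


class ResNet18(Sequential):
    def __init__(self, base_width: int = 64, seed: int = 0, in_channels: int = 3):
        rng = np.random.default_rng(seed)
        w = base_width
        layers: list[Layer] = [
            Conv2d(in_channels, w, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(w),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        widths = [w, 2 * w, 4 * w, 8 * w]
        cin = w
        for i, cout in enumerate(widths):
            stride = 1 if i == 0 else 2
            layers.append(BasicBlock(cin, cout, stride, rng))
            layers.append(BasicBlock(cout, cout, 1, rng))
            cin = cout
        layers.append(GlobalAvgPool())
        layers.append(Linear(8 * w, 1, rng))
        super().__init__(*layers)
        self.base_width = base_width
        self.seed = seed

    # -- state ------------------------------------------------------------
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict:
        return {
            "base_width": self.base_width,
            "seed": self.seed,
            "params": [p.value.copy() for p in self.params()],
            "buffers": [b.copy() for b in self.buffers()],
        }

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"], strict=True):
            p.value[...] = v
        for b, v in zip(self.buffers(), state["buffers"], strict=True):
            b[...] = v

    @classmethod
    def from_state(cls, state: dict) -> "ResNet18":
        model = cls(base_width=state["base_width"], seed=state["seed"])
        model.load_state_dict(state)
        return model


def build_model(pretrained: bool = False, base_width: int = 64, seed: int = 0) -> ResNet18:
    """Construct the 18-layer residual network with seeded random init.

    Pretraining is not part of the protocol (and no pretrained weights exist
    for this engine), so ``pretrained=True`` raises.
    """
    if pretrained:
        raise NotImplementedError(
            "pretrained weights are not available; the training protocol uses "
            "random initialization")
    return ResNet18(base_width=base_width, seed=seed)
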