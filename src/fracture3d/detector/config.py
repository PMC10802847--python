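"""Detector configuration and the backbone shape contract.

The training hyperparameters default to the study setup: initial learning
rate 0.001 dropped by a factor 0.5 every 20 epochs, at most 50 epochs,
minibatch 4, Adam.  The network input defaults to 512x512 (the size
implied by the first CSP block's 256x256 output); any input side divisible
by 32 is accepted and all feature maps scale proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# (block_id, csp_units, out_rows, out_cols, out_channels) for a 512x512x3 input
CSP_UNITS = (1, 2, 8, 8, 4)
CSP_CHANNELS = (128, 128, 256, 512, 1024)

# standard 9-anchor layout (w, h) in input pixels, three per detection scale
DEFAULT_ANCHORS = (
    ((12, 16), (19, 36), (40, 28)),       # stride 8
    ((36, 75), (76, 55), (72, 146)),      # stride 16
    ((142, 110), (192, 243), (459, 401)), # stride 32
)


@dataclass(frozen=True)
class BackboneShapeSpec:
    """Expected (block_id, units, rows, cols, channels) of each CSP block."""

    input_size: int = 512
    blocks: tuple[tuple[int, int, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.blocks:
            object.__setattr__(self, "blocks", self.for_input(self.input_size))
        for (b0, u0, r0, c0, _), (b1, u1, r1, c1, _) in zip(self.blocks, self.blocks[1:]):
            if r1 * 2 != r0 or c1 * 2 != c0:
                raise ValueError("spatial size must halve between consecutive CSP blocks")

    @staticmethod
    def for_input(input_size: int) -> tuple[tuple[int, int, int, int, int], ...]:
        if input_size % 32:
            raise ValueError(f"input size {input_size} not divisible by 32")
        return tuple(
            (i + 1, CSP_UNITS[i], input_size >> (i + 1), input_size >> (i + 1), CSP_CHANNELS[i])
            for i in range(5)
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration shared by the rule and network detectors."""

    kind: str = "rule"  # "rule" | "yolov4"
    score_threshold: float = 0.25
    input_size: int = 512
    # rule-detector parameters
    hu_band: tuple[float, float] = (1150.0, 1250.0)
    min_gap_px: float = 5.0
    angular_bins: int = 0  # 0 = adaptive from the shell radius
    # network training schedule
    initial_lr: float = 0.001
    drop_period: int = 20
    drop_factor: float = 0.5
    max_epochs: int = 50
    minibatch: int = 4
    optimizer: str = "adam"
    # network inference
    nms_iou: float = 0.5
    num_classes: int = 1
    anchors: tuple = DEFAULT_ANCHORS
    png_window: tuple[float, float] = (-200.0, 1800.0)

    def __post_init__(self) -> None:
        if self.kind not in ("rule", "yolov4"):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")
        if not (0.0 <= self.nms_iou <= 1.0):
            raise ValueError("nms_iou must be in [0, 1]")
        for v, name in (
            (self.initial_lr, "initial_lr"),
            (self.drop_period, "drop_period"),
            (self.drop_factor, "drop_factor"),
            (self.max_epochs, "max_epochs"),
            (self.minibatch, "minibatch"),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def learning_rate(epoch: int, config: DetectorConfig = DetectorConfig()) -> float:
    """Step schedule: lr(e) = initial_lr * drop_factor ** floor(e / drop_period).

    With the defaults this is 0.001 for epochs 0-19, 0.0005 for 20-39 and
    0.00025 for 40-49.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * config.drop_factor ** math.floor(epoch / config.drop_period)
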