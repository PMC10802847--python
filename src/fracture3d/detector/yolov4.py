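"""CSPDarknet-53 / SPP / PAN one-stage detector scaffold in NumPy.

The backbone is built from five cross-stage-partial (CSP) blocks with
(1, 2, 8, 8, 4) residual units; for a 512x512x3 input the block outputs
are 256x256x128, 128x128x128, 64x64x256, 32x32x512 and 16x16x1024, each
halving the spatial size.  Inside every block, convolution is followed by
batch normalization and the mish activation.  The neck applies spatial
pyramid pooling (stride-1 max pools of size 5/9/13) to the last feature
map, then a path-aggregation network: a top-down pass that upsamples
semantically strong maps, and a bottom-up pass that returns localization
detail.  Three one-stage heads emit, per grid cell and anchor, the
bounding-box offsets, an objectness score and a classification score.

This is a desk-scale scaffold: it trains end-to-end on toy phantom sets
and honours the published hyperparameter schedule, but makes no attempt
at GPU-class throughput.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from fracture3d.annotation import BoxRecord
from fracture3d.detector import nn
from fracture3d.detector.config import (
    CSP_CHANNELS,
    CSP_UNITS,
    BackboneShapeSpec,
    DetectorConfig,
    learning_rate,
)
from fracture3d.dicom_io import VolumeGrid

logger = logging.getLogger(__name__)

LAMBDA_COORD = 5.0
LAMBDA_NOOBJ = 0.5


class ConvBNMish:
    """Convolution -> batch normalization -> mish, the CSP building brick."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1, name: str = ""):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = nn.Tensor(w, requires_grad=True, name=f"{name}.w")
        self.gamma = nn.Tensor(np.ones(out_ch), requires_grad=True, name=f"{name}.gamma")
        self.beta = nn.Tensor(np.zeros(out_ch), requires_grad=True, name=f"{name}.beta")
        self.running_mean = np.zeros(out_ch, dtype=np.float32)
        self.running_var = np.ones(out_ch, dtype=np.float32)
        self.stride = stride
        self.pad = kernel // 2
        self.name = name

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        y = nn.conv2d(x, self.w, None, stride=self.stride, pad=self.pad)
        y = nn.batchnorm2d(
            y, self.gamma, self.beta, self.running_mean, self.running_var, train
        )
        return nn.mish(y)

    @property
    def params(self):
        return [self.w, self.gamma, self.beta]

    def state(self):
        return {
            f"{self.name}.w": self.w.data,
            f"{self.name}.gamma": self.gamma.data,
            f"{self.name}.beta": self.beta.data,
            f"{self.name}.running_mean": self.running_mean,
            f"{self.name}.running_var": self.running_var,
        }

    def load_state(self, state):
        self.w.data = state[f"{self.name}.w"]
        self.gamma.data = state[f"{self.name}.gamma"]
        self.beta.data = state[f"{self.name}.beta"]
        self.running_mean = state[f"{self.name}.running_mean"].copy()
        self.running_var = state[f"{self.name}.running_var"].copy()


class CSPUnit:
    """Residual unit: 1x1 then 3x3 convolution with a skip connection."""

    def __init__(self, rng, ch: int, name: str):
        self.conv1 = ConvBNMish(rng, ch, ch, 1, name=f"{name}.conv1")
        self.conv2 = ConvBNMish(rng, ch, ch, 3, name=f"{name}.conv2")

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        return nn.add(x, self.conv2(self.conv1(x, train), train))

    @property
    def params(self):
        return self.conv1.params + self.conv2.params

    def state(self):
        return {**self.conv1.state(), **self.conv2.state()}

    def load_state(self, state):
        self.conv1.load_state(state)
        self.conv2.load_state(state)


class CSPBlock:
    """Downsample, split the feature map, process one part, merge.

    The split-and-merge routing keeps half the channels on an identity
    path, which shortens gradient paths and cuts computation.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, units: int, name: str):
        hidden = out_ch // 2
        self.down = ConvBNMish(rng, in_ch, out_ch, 3, stride=2, name=f"{name}.down")
        self.split_a = ConvBNMish(rng, out_ch, hidden, 1, name=f"{name}.split_a")
        self.split_b = ConvBNMish(rng, out_ch, hidden, 1, name=f"{name}.split_b")
        self.units = [CSPUnit(rng, hidden, f"{name}.unit{u}") for u in range(units)]
        self.post = ConvBNMish(rng, hidden, hidden, 1, name=f"{name}.post")
        self.transition = ConvBNMish(rng, 2 * hidden, out_ch, 1, name=f"{name}.transition")

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        y = self.down(x, train)
        a = self.split_a(y, train)
        b = self.split_b(y, train)
        for unit in self.units:
            b = unit(b, train)
        b = self.post(b, train)
        return self.transition(nn.concat([a, b], axis=1), train)

    @property
    def params(self):
        out = self.down.params + self.split_a.params + self.split_b.params
        for u in self.units:
            out += u.params
        return out + self.post.params + self.transition.params

    def _modules(self):
        return [self.down, self.split_a, self.split_b, *self.units, self.post, self.transition]

    def state(self):
        out = {}
        for m in self._modules():
            out.update(m.state())
        return out

    def load_state(self, state):
        for m in self._modules():
            m.load_state(state)


class Head:
    """One detection head: 3x3 feature conv then a plain 1x1 projection."""

    def __init__(self, rng, in_ch: int, out_ch: int, name: str):
        self.conv = ConvBNMish(rng, in_ch, 2 * in_ch, 3, name=f"{name}.conv")
        fan_in = 2 * in_ch
        self.proj_w = nn.Tensor(
            rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, 2 * in_ch, 1, 1)),
            requires_grad=True,
            name=f"{name}.proj_w",
        )
        self.proj_b = nn.Tensor(np.zeros(out_ch), requires_grad=True, name=f"{name}.proj_b")
        self.name = name

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        return nn.conv2d(self.conv(x, train), self.proj_w, self.proj_b)

    @property
    def params(self):
        return self.conv.params + [self.proj_w, self.proj_b]

    def state(self):
        return {
            **self.conv.state(),
            f"{self.name}.proj_w": self.proj_w.data,
            f"{self.name}.proj_b": self.proj_b.data,
        }

    def load_state(self, state):
        self.conv.load_state(state)
        self.proj_w.data = state[f"{self.name}.proj_w"]
        self.proj_b.data = state[f"{self.name}.proj_b"]


class YoloV4Network:
    """Backbone + SPP/PAN neck + three one-stage heads."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        if config.input_size % 32:
            raise ValueError(f"input size {config.input_size} not divisible by 32")
        self.config = config
        rng = np.random.default_rng(seed)
        nc = config.num_classes
        self.head_channels = 3 * (5 + nc)

        self.stem = ConvBNMish(rng, 3, 32, 3, name="stem")
        self.blocks = []
        in_ch = 32
        for i, (units, out_ch) in enumerate(zip(CSP_UNITS, CSP_CHANNELS)):
            self.blocks.append(CSPBlock(rng, in_ch, out_ch, units, name=f"csp{i + 1}"))
            in_ch = out_ch

        # SPP on the deepest map
        self.spp_pre = ConvBNMish(rng, 1024, 512, 1, name="spp_pre")
        self.spp_post = ConvBNMish(rng, 4 * 512, 512, 1, name="spp_post")
        # PAN top-down
        self.p5_red = ConvBNMish(rng, 512, 256, 1, name="p5_red")
        self.c4_red = ConvBNMish(rng, 512, 256, 1, name="c4_red")
        self.p4_conv = ConvBNMish(rng, 512, 256, 3, name="p4_conv")
        self.p4_red = ConvBNMish(rng, 256, 128, 1, name="p4_red")
        self.c3_red = ConvBNMish(rng, 256, 128, 1, name="c3_red")
        self.p3_conv = ConvBNMish(rng, 256, 128, 3, name="p3_conv")
        # PAN bottom-up
        self.d3 = ConvBNMish(rng, 128, 256, 3, stride=2, name="d3")
        self.n4_conv = ConvBNMish(rng, 512, 256, 3, name="n4_conv")
        self.d4 = ConvBNMish(rng, 256, 512, 3, stride=2, name="d4")
        self.n5_conv = ConvBNMish(rng, 1024, 512, 3, name="n5_conv")
        # heads at strides 8 / 16 / 32
        self.heads = [
            Head(rng, 128, self.head_channels, name="head8"),
            Head(rng, 256, self.head_channels, name="head16"),
            Head(rng, 512, self.head_channels, name="head32"),
        ]

    # -- forward ---------------------------------------------------------

    def backbone_forward(self, x: nn.Tensor, train: bool = False) -> list[nn.Tensor]:
        """Return the five CSP block outputs for input (N, 3, S, S)."""
        y = self.stem(x, train)
        feats = []
        for block in self.blocks:
            y = block(y, train)
            feats.append(y)
        return feats

    def forward(self, x: nn.Tensor, train: bool = False) -> dict:
        feats = self.backbone_forward(x, train)
        c3, c4, c5 = feats[2], feats[3], feats[4]

        y = self.spp_pre(c5, train)
        spp = nn.concat(
            [y, nn.maxpool2d_same(y, 5), nn.maxpool2d_same(y, 9), nn.maxpool2d_same(y, 13)],
            axis=1,
        )
        p5 = self.spp_post(spp, train)

        up5 = nn.upsample2(self.p5_red(p5, train))
        p4 = self.p4_conv(nn.concat([self.c4_red(c4, train), up5], axis=1), train)
        up4 = nn.upsample2(self.p4_red(p4, train))
        p3 = self.p3_conv(nn.concat([self.c3_red(c3, train), up4], axis=1), train)

        n4 = self.n4_conv(nn.concat([self.d3(p3, train), p4], axis=1), train)
        n5 = self.n5_conv(nn.concat([self.d4(n4, train), p5], axis=1), train)

        heads = [
            self.heads[0](p3, train),
            self.heads[1](n4, train),
            self.heads[2](n5, train),
        ]
        return {"backbone": feats, "neck": [p3, n4, n5], "heads": heads}

    # -- plumbing --------------------------------------------------------

    def _modules(self):
        mods = [self.stem, *self.blocks, self.spp_pre, self.spp_post, self.p5_red,
                self.c4_red, self.p4_conv, self.p4_red, self.c3_red, self.p3_conv,
                self.d3, self.n4_conv, self.d4, self.n5_conv, *self.heads]
        return mods

    @property
    def params(self) -> list[nn.Tensor]:
        out = []
        for m in self._modules():
            out += m.params
        return out

    def shape_spec(self) -> BackboneShapeSpec:
        return BackboneShapeSpec(input_size=self.config.input_size)

    def describe(self) -> dict:
        return {
            "architecture": "CSPDarknet-53 backbone, SPP + PAN neck, 3 one-stage heads",
            "input_size": self.config.input_size,
            "csp_units": list(CSP_UNITS),
            "csp_channels": list(CSP_CHANNELS),
            "num_classes": self.config.num_classes,
            "anchors": [list(map(list, scale)) for scale in self.config.anchors],
            "head_channels": self.head_channels,
        }

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar describing the architecture."""
        path = Path(path)
        state = {}
        for m in self._modules():
            state.update(m.state())
        np.savez_compressed(path.with_suffix(".npz"), **state)
        path.with_suffix(".json").write_text(json.dumps(self.describe(), indent=2))

    def load(self, path: str | Path) -> None:
        data = np.load(Path(path).with_suffix(".npz"))
        state = {k: data[k] for k in data.files}
        for m in self._modules():
            m.load_state(state)


def build_yolov4(config: DetectorConfig | None = None, seed: int = 0) -> YoloV4Network:
    """Construct the network with seeded random weights."""
    return YoloV4Network(config or DetectorConfig(kind="yolov4"), seed=seed)


# -- data preparation ----------------------------------------------------


def prepare_image(image: np.ndarray, input_size: int) -> np.ndarray:
    """Resize a 2D greyscale slice to (3, S, S) float32 in [0, 1]."""
    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape != (input_size, input_size):
        img = resize(img, (input_size, input_size), order=1, preserve_range=True,
                     anti_aliasing=True).astype(np.float32)
    return np.repeat(img[None, :, :], 3, axis=0)


def _scale_boxes(boxes: list[BoxRecord], shape, input_size: int) -> np.ndarray:
    """Boxes as (cx, cy, w, h) in network-input pixel coordinates."""
    h, w = shape[:2]
    rx = input_size / w
    ry = input_size / h
    out = np.zeros((len(boxes), 4), dtype=np.float32)
    for i, b in enumerate(boxes):
        out[i] = (
            (b.x_start + b.x_extent / 2.0) * rx,
            (b.y_start + b.y_extent / 2.0) * ry,
            b.x_extent * rx,
            b.y_extent * ry,
        )
    return out


def _wh_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    inter = np.minimum(wh[0], anchors[:, 0]) * np.minimum(wh[1], anchors[:, 1])
    union = wh[0] * wh[1] + anchors[:, 0] * anchors[:, 1] - inter
    return inter / union


def _build_targets(batch_boxes, shapes, config: DetectorConfig):
    """Per-scale target arrays for the one-stage loss."""
    nc = config.num_classes
    anchors = np.array([a for scale in config.anchors for a in scale], dtype=np.float32)
    targets = []
    for (hs, ws), _scale_anchors in zip(shapes, config.anchors):
        n = len(batch_boxes)
        targets.append(
            {
                "obj": np.zeros((n, 3, 1, hs, ws), dtype=np.float32),
                "xy": np.zeros((n, 3, 2, hs, ws), dtype=np.float32),
                "wh": np.zeros((n, 3, 2, hs, ws), dtype=np.float32),
                "cls": np.zeros((n, 3, nc, hs, ws), dtype=np.float32),
            }
        )
    for bi, boxes in enumerate(batch_boxes):
        for cx, cy, w, h in boxes:
            best = int(np.argmax(_wh_iou(np.array([w, h]), anchors)))
            si, ai = divmod(best, 3)
            hs, ws = shapes[si]
            stride = config.input_size / ws
            gx, gy = cx / stride, cy / stride
            ci = min(int(gx), ws - 1)
            cj = min(int(gy), hs - 1)
            t = targets[si]
            t["obj"][bi, ai, 0, cj, ci] = 1.0
            t["xy"][bi, ai, :, cj, ci] = (gx - ci, gy - cj)
            aw, ah = config.anchors[si][ai]
            t["wh"][bi, ai, :, cj, ci] = (math.log(max(w, 1e-3) / aw), math.log(max(h, 1e-3) / ah))
            t["cls"][bi, ai, 0, cj, ci] = 1.0  # single "fracture" class
    return targets


def detection_loss(outputs: dict, batch_boxes, config: DetectorConfig) -> nn.Tensor:
    """Standard one-stage loss: box regression + objectness + class BCE."""
    heads = outputs["heads"]
    nc = config.num_classes
    shapes = [h.data.shape[2:] for h in heads]
    targets = _build_targets(batch_boxes, shapes, config)
    total: nn.Tensor | None = None
    for head, t in zip(heads, targets):
        n, _, hs, ws = head.data.shape
        o = nn.reshape(head, (n, 3, 5 + nc, hs, ws))
        obj_mask = t["obj"]
        xy = nn.sigmoid(nn.slice_axis(o, 2, 0, 2))
        loss_xy = nn.mse_weighted(xy, t["xy"], LAMBDA_COORD * obj_mask)
        wh = nn.slice_axis(o, 2, 2, 4)
        loss_wh = nn.mse_weighted(wh, t["wh"], LAMBDA_COORD * obj_mask)
        obj = nn.slice_axis(o, 2, 4, 5)
        obj_weight = obj_mask + LAMBDA_NOOBJ * (1.0 - obj_mask)
        loss_obj = nn.bce_with_logits(obj, obj_mask, obj_weight)
        cls = nn.slice_axis(o, 2, 5, 5 + nc)
        loss_cls = nn.bce_with_logits(cls, t["cls"], obj_mask)
        scale_loss = nn.add(nn.add(loss_xy, loss_wh), nn.add(loss_obj, loss_cls))
        total = scale_loss if total is None else nn.add(total, scale_loss)
    return total


@dataclass
class LossTrace:
    """Per-iteration training losses and per-epoch validation losses."""

    train: list[float]
    validation: list[float]
    epochs: int
    iterations_per_epoch: int


def train_yolov4(
    network: YoloV4Network,
    dataset: list[tuple[np.ndarray, list[BoxRecord]]],
    config: DetectorConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    validation: list[tuple[np.ndarray, list[BoxRecord]]] | None = None,
) -> tuple[YoloV4Network, LossTrace]:
    """Run the configured Adam schedule and record the loss trace.

    The learning rate starts at ``initial_lr`` and is multiplied by
    ``drop_factor`` every ``drop_period`` epochs; training runs for
    ``epochs`` (default ``max_epochs``) with minibatches of
    ``config.minibatch`` images.
    """
    if not dataset:
        raise ValueError("empty dataset")
    config = config or network.config
    epochs = config.max_epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    optimizer = nn.Adam(network.params, lr=config.initial_lr)

    prepared = [
        (prepare_image(img, config.input_size), _scale_boxes(boxes, img.shape, config.input_size))
        for img, boxes in dataset
    ]
    prepared_val = None
    if validation:
        prepared_val = [
            (prepare_image(img, config.input_size), _scale_boxes(boxes, img.shape, config.input_size))
            for img, boxes in validation
        ]

    mb = config.minibatch
    iters_per_epoch = math.ceil(len(prepared) / mb)
    train_trace: list[float] = []
    val_trace: list[float] = []
    for epoch in range(epochs):
        optimizer.lr = learning_rate(epoch, config)
        order = rng.permutation(len(prepared))
        for start in range(0, len(prepared), mb):
            batch = [prepared[i] for i in order[start : start + mb]]
            x = nn.Tensor(np.stack([b[0] for b in batch]))
            out = network.forward(x, train=True)
            loss = detection_loss(out, [b[1] for b in batch], config)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            train_trace.append(loss.item())
        if prepared_val:
            x = nn.Tensor(np.stack([b[0] for b in prepared_val]))
            out = network.forward(x, train=False)
            val_trace.append(detection_loss(out, [b[1] for b in prepared_val], config).item())
        logger.info("epoch %d: lr=%.6f last train loss=%.4f", epoch, optimizer.lr, train_trace[-1])
    return network, LossTrace(
        train=train_trace,
        validation=val_trace,
        epochs=epochs,
        iterations_per_epoch=iters_per_epoch,
    )


# -- inference -----------------------------------------------------------


def _nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy non-maximum suppression on (x0, y0, x1, y1) corner boxes."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        xx0 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy0 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx1 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy1 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(0.0, xx1 - xx0) * np.maximum(0.0, yy1 - yy0)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / (area_i + area_r - inter)
        order = rest[iou <= iou_thr]
    return keep


def decode_head(
    head_data: np.ndarray,
    scale_anchors,
    input_size: int,
    num_classes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode one head's raw output into input-pixel corner boxes + scores."""
    n, _, hs, ws = head_data.shape
    assert n == 1
    o = head_data.reshape(3, 5 + num_classes, hs, ws)
    stride = input_size / ws
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    gy, gx = np.mgrid[0:hs, 0:ws]
    boxes = []
    scores = []
    for ai, (aw, ah) in enumerate(scale_anchors):
        bx = (sig(o[ai, 0]) + gx) * stride
        by = (sig(o[ai, 1]) + gy) * stride
        bw = aw * np.exp(np.clip(o[ai, 2], -8, 8))
        bh = ah * np.exp(np.clip(o[ai, 3], -8, 8))
        score = sig(o[ai, 4]) * sig(o[ai, 5:]).max(axis=0)
        boxes.append(
            np.stack([bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=-1).reshape(-1, 4)
        )
        scores.append(score.reshape(-1))
    return np.concatenate(boxes), np.concatenate(scores)


def detect_yolo(
    network: YoloV4Network,
    volume: VolumeGrid,
    config: DetectorConfig | None = None,
) -> list[BoxRecord]:
    """Per-slice forward pass, decode, threshold, NMS, rescale to pixels."""
    config = config or network.config
    rows, cols, n_slices = volume.shape
    lo, hi = config.png_window
    results: list[BoxRecord] = []
    for k in range(n_slices):
        hu = volume.voxels[:, :, k]
        img = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
        x = nn.Tensor(prepare_image(img, config.input_size)[None])
        out = network.forward(x, train=False)
        all_boxes = []
        all_scores = []
        for head, scale_anchors in zip(out["heads"], config.anchors):
            b, s = decode_head(
                head.data, scale_anchors, config.input_size, config.num_classes
            )
            all_boxes.append(b)
            all_scores.append(s)
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        mask = scores >= config.score_threshold
        boxes, scores = boxes[mask], scores[mask]
        if not len(boxes):
            continue
        keep = _nms(boxes, scores, config.nms_iou)
        rx = cols / config.input_size
        ry = rows / config.input_size
        for i in keep:
            x0 = int(np.clip(math.floor(boxes[i, 0] * rx), 0, cols - 1))
            y0 = int(np.clip(math.floor(boxes[i, 1] * ry), 0, rows - 1))
            x1 = int(np.clip(math.ceil(boxes[i, 2] * rx), x0 + 1, cols))
            y1 = int(np.clip(math.ceil(boxes[i, 3] * ry), y0 + 1, rows))
            results.append(
                BoxRecord(
                    x_start=x0,
                    y_start=y0,
                    x_extent=x1 - x0,
                    y_extent=y1 - y0,
                    slice_index=volume.meta[k].slice_index,
                    score=float(np.clip(scores[i], 0.0, 1.0)),
                )
            )
    return results
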