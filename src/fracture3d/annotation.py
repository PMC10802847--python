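"""Bounding-box data model, 4-by-N matrix storage and training augmentations.

A fracture annotation is an axis-aligned box on one axial slice, stored as
the 4-tuple (x_start, y_start, x_extent, y_extent) in pixels.  Boxes are
half-open in pixel index space: the covered columns are
``[x_start, x_start + x_extent)`` and likewise for rows, so the covered
area is exactly ``x_extent * y_extent`` pixels.  Coordinates are 0-based
throughout, including the on-disk TSV format.

Augmentations mirror detector-training practice on medical CT: horizontal
(X-axis) flips and mild random up-scaling (1.0–1.3×), but never vertical
flips, plus an independent random-shift augmentation that replicates each
slice several times with small X/Y translations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

logger = logging.getLogger(__name__)

SCALE_RANGE = (1.0, 1.3)


@dataclass(frozen=True)
class BoxRecord:
    """One axis-aligned 2D box on one slice.

    ``score`` is absent (None) for ground truth and a confidence in [0, 1]
    for detections.
    """

    x_start: int
    y_start: int
    x_extent: int
    y_extent: int
    slice_index: int = 0
    label: str = "fracture"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.x_extent < 1 or self.y_extent < 1:
            raise ValueError(f"box extents must be >= 1, got {self.x_extent}x{self.y_extent}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    @property
    def x_end(self) -> int:
        """Exclusive end column."""
        return self.x_start + self.x_extent

    @property
    def y_end(self) -> int:
        """Exclusive end row."""
        return self.y_start + self.y_extent

    @property
    def area(self) -> int:
        return self.x_extent * self.y_extent


@dataclass
class BoxMatrix:
    """The 4-by-N storage convention: one column per box.

    Rows are (x_start, y_start, x_extent, y_extent); slice indices, labels
    and optional scores ride along as parallel lists so the conversion to
    and from a list of :class:`BoxRecord` is lossless.
    """

    data: np.ndarray  # int array, shape (4, N)
    slice_indices: list[int]
    labels: list[str]
    scores: list[float | None]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != 4:
            raise ValueError(f"expected a 4xN matrix, got shape {self.data.shape}")
        n = self.data.shape[1]
        if not (len(self.slice_indices) == len(self.labels) == len(self.scores) == n):
            raise ValueError("parallel lists must match the matrix column count")

    @property
    def n_boxes(self) -> int:
        return self.data.shape[1]


def to_matrix(boxes: list[BoxRecord]) -> BoxMatrix:
    """Pack a list of boxes into the 4-by-N matrix convention."""
    if not boxes:
        return BoxMatrix(np.zeros((4, 0), dtype=int), [], [], [])
    data = np.array(
        [[b.x_start, b.y_start, b.x_extent, b.y_extent] for b in boxes], dtype=int
    ).T
    return BoxMatrix(
        data,
        [b.slice_index for b in boxes],
        [b.label for b in boxes],
        [b.score for b in boxes],
    )


def from_matrix(matrix: BoxMatrix) -> list[BoxRecord]:
    """Inverse of :func:`to_matrix`."""
    return [
        BoxRecord(
            x_start=int(matrix.data[0, i]),
            y_start=int(matrix.data[1, i]),
            x_extent=int(matrix.data[2, i]),
            y_extent=int(matrix.data[3, i]),
            slice_index=matrix.slice_indices[i],
            label=matrix.labels[i],
            score=matrix.scores[i],
        )
        for i in range(matrix.n_boxes)
    ]


def _clamp_box(
    x0: float, y0: float, x1: float, y1: float, box: BoxRecord, width: int, height: int
) -> BoxRecord | None:
    """Round a transformed box to pixels and clamp to image bounds.

    Returns None when the box falls fully outside the image.
    """
    xi0 = int(np.floor(x0 + 0.5))
    yi0 = int(np.floor(y0 + 0.5))
    xi1 = int(np.floor(x1 + 0.5))
    yi1 = int(np.floor(y1 + 0.5))
    xi0c, xi1c = max(xi0, 0), min(xi1, width)
    yi0c, yi1c = max(yi0, 0), min(yi1, height)
    if xi1c - xi0c < 1 or yi1c - yi0c < 1:
        return None
    return replace(
        box, x_start=xi0c, y_start=yi0c, x_extent=xi1c - xi0c, y_extent=yi1c - yi0c
    )


def _fill_value(image: np.ndarray) -> float:
    """Background fill: 0 for 8-bit PNG slices, air (−1000 HU) otherwise."""
    return 0.0 if image.dtype == np.uint8 else -1000.0


def augment(
    image: np.ndarray,
    boxes: list[BoxRecord],
    seed: int | None = None,
    *,
    flip: bool | None = None,
    scale: float | None = None,
) -> tuple[np.ndarray, list[BoxRecord]]:
    """Random horizontal flip and/or random 1–1.3× scaling about the center.

    The affine transform is drawn from {identity, horizontal flip} ×
    {scale s ~ Uniform(1, 1.3)} unless ``flip``/``scale`` pin it down
    explicitly.  Scaling is anchored at the image center; the output is
    re-cropped to the original size with background fill.  Boxes are
    transformed with the pixels, re-clamped to bounds, and dropped (with a
    log line) only when pushed fully outside the image.  Vertical flips are
    deliberately never drawn.
    """
    rng = np.random.default_rng(seed)
    if flip is None:
        flip = bool(rng.integers(0, 2))
    if scale is None:
        scale = float(rng.uniform(*SCALE_RANGE))
    if scale <= 0:
        raise ValueError("scale must be positive")

    height, width = image.shape[:2]
    cx = width / 2.0
    cy = height / 2.0

    if not flip and scale == 1.0:
        return image.copy(), list(boxes)

    out = image
    if scale != 1.0:
        # forward map: p' = c + s*(p - c); warp takes the inverse map
        inv = AffineTransform(scale=(1 / scale, 1 / scale)) + AffineTransform(
            translation=(cx - cx / scale, cy - cy / scale)
        )
        out = warp(
            out.astype(float),
            inv,
            output_shape=(height, width),
            order=1,
            cval=_fill_value(image),
            preserve_range=True,
        ).astype(image.dtype)
    if flip:
        out = out[:, ::-1].copy()

    new_boxes: list[BoxRecord] = []
    for b in boxes:
        x0 = cx + scale * (b.x_start - cx)
        x1 = cx + scale * (b.x_end - cx)
        y0 = cy + scale * (b.y_start - cy)
        y1 = cy + scale * (b.y_end - cy)
        clamped = _clamp_box(x0, y0, x1, y1, b, width, height)
        if clamped is None:
            logger.info("augment: box %s scaled fully outside the image, dropped", b)
            continue
        if flip:
            clamped = replace(clamped, x_start=width - clamped.x_start - clamped.x_extent)
        new_boxes.append(clamped)
    return out, new_boxes


def shift_augment(
    image: np.ndarray,
    boxes: list[BoxRecord],
    n_copies: int = 10,
    max_shift: int = 20,
    seed: int | None = None,
) -> list[tuple[np.ndarray, list[BoxRecord]]]:
    """Replicate a slice ``n_copies`` times with random X/Y pixel shifts.

    Shifts are drawn uniformly from [−max_shift, max_shift] per axis;
    vacated pixels are filled with background, and boxes are translated and
    clamped (dropped only when fully outside).  ``max_shift = 0`` returns
    identical copies.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    height, width = image.shape[:2]
    if max_shift >= width or max_shift >= height:
        raise ValueError(f"max_shift {max_shift} exceeds image size {width}x{height}")
    rng = np.random.default_rng(seed)
    fill = _fill_value(image)
    out: list[tuple[np.ndarray, list[BoxRecord]]] = []
    for _ in range(n_copies):
        dx = int(rng.integers(-max_shift, max_shift + 1))
        dy = int(rng.integers(-max_shift, max_shift + 1))
        shifted = np.full_like(image, fill)
        src_x = slice(max(0, -dx), min(width, width - dx))
        dst_x = slice(max(0, dx), min(width, width + dx))
        src_y = slice(max(0, -dy), min(height, height - dy))
        dst_y = slice(max(0, dy), min(height, height + dy))
        shifted[dst_y, dst_x] = image[src_y, src_x]
        shifted_boxes: list[BoxRecord] = []
        for b in boxes:
            clamped = _clamp_box(
                b.x_start + dx, b.y_start + dy, b.x_end + dx, b.y_end + dy, b, width, height
            )
            if clamped is None:
                logger.info("shift_augment: box %s shifted fully outside, dropped", b)
                continue
            shifted_boxes.append(clamped)
        out.append((shifted, shifted_boxes))
    return out


_HEADER = "# slice_index\tx_start\ty_start\tx_extent\ty_extent\tlabel\tscore (0-based pixel coordinates)"


def write_boxes(boxes: list[BoxRecord], path: str | Path) -> None:
    """Write boxes as a TSV table, one box per line, 0-based coordinates."""
    path = Path(path)
    lines = [_HEADER]
    for b in boxes:
        score = "" if b.score is None else f"{b.score:.6f}"
        lines.append(
            f"{b.slice_index}\t{b.x_start}\t{b.y_start}\t{b.x_extent}\t{b.y_extent}\t{b.label}\t{score}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_boxes(path: str | Path) -> list[BoxRecord]:
    """Read a TSV box table written by :func:`write_boxes`.

    A malformed line raises ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    boxes: list[BoxRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) not in (6, 7):
            raise ValueError(
                f"{path.name}:{lineno}: expected 6 or 7 tab-separated fields, got {len(fields)}"
            )
        try:
            slice_index = int(fields[0])
            x_start, y_start, x_extent, y_extent = (int(f) for f in fields[1:5])
            label = fields[5]
            score = None
            if len(fields) == 7 and fields[6] != "":
                score = float(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
        boxes.append(
            BoxRecord(
                x_start=x_start,
                y_start=y_start,
                x_extent=x_extent,
                y_extent=y_extent,
                slice_index=slice_index,
                label=label,
                score=score,
            )
        )
    return boxes
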