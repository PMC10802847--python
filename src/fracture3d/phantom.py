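"""Synthetic CT phantom: tubular bone with known fracture ground truth.

Patient CT data for fracture studies are privacy-protected, so the
pipeline is exercised on a generated stand-in: a hollow tube whose
cortical shell sits at a configurable HU level inside the 1150–1250 HU
cortical-bone band, embedded in soft tissue (−50 HU) surrounded by air
(−1000 HU).  Fractures are carved in as angular gaps in the shell or as
in-plane displacements of the distal fragment, over known slice ranges,
and the generator emits the matching ground-truth bounding boxes.

The ground-truth box on a slice is the tight axis-aligned bounding box of
the voxels where the fractured shell differs from the unfractured shell
(hand-drawn clinical boxes have no reproducible definition, so the
symmetric difference is used as the surrogate).  A fixed seed fully
determines the output, noise included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fracture3d.annotation import BoxRecord
from fracture3d.dicom_io import SliceMeta, VolumeGrid

CORTICAL_BAND = (1150.0, 1250.0)


@dataclass(frozen=True)
class FractureSpec:
    """One fracture: either a cortical gap or a fragment displacement.

    ``slice_start``/``slice_stop`` bound the affected slices (half-open).
    For ``kind="gap"`` the shell arc centred at ``angle_center`` (radians)
    with angular width ``angle_width`` is replaced by background HU.  For
    ``kind="displacement"`` every affected slice has the whole bone
    cross-section shifted by ``shift`` pixels (x, y).
    """

    slice_start: int
    slice_stop: int
    kind: str = "gap"
    angle_center: float = 0.0
    angle_width: float = math.pi / 3
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.kind not in ("gap", "displacement"):
            raise ValueError(f"unknown fracture kind {self.kind!r}")
        if self.slice_stop <= self.slice_start:
            raise ValueError("fracture slice range is empty")
        if self.kind == "gap" and not (0 < self.angle_width <= 2 * math.pi):
            raise ValueError("angle_width must be in (0, 2*pi]")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic CT series.

    Defaults follow a desk-scale long-bone study setup: a 512×512 in-plane
    grid (the detector's default input size), 0.8 mm pixels, 1 mm slices,
    and a cortical shell at 1200 HU — the middle of the 1150–1250 band the
    reconstruction thresholds on.
    """

    rows: int = 512
    cols: int = 512
    n_slices: int = 40
    pixel_spacing: tuple[float, float] = (0.8, 0.8)  # (x, y) mm/px
    slice_thickness: float = 1.0  # mm
    center: tuple[float, float] | None = None  # (col, row); default grid center
    radius_outer: float = 60.0  # px
    radius_inner: float = 42.0  # px
    cortical_hu: float = 1200.0
    soft_tissue_hu: float = -50.0
    air_hu: float = -1000.0
    soft_tissue_radius: float | None = None  # px; default 1.6 * radius_outer
    fractures: tuple[FractureSpec, ...] = ()
    noise_sd: float = 0.0  # HU; truncated at 3 sd
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.radius_inner < self.radius_outer):
            raise ValueError("need 0 < radius_inner < radius_outer")
        if not (CORTICAL_BAND[0] <= self.cortical_hu <= CORTICAL_BAND[1]):
            raise ValueError(
                f"cortical_hu {self.cortical_hu} outside the cortical band {CORTICAL_BAND}"
            )
        for f in self.fractures:
            if f.slice_start < 0 or f.slice_stop > self.n_slices:
                raise ValueError(f"fracture {f} outside the slice range [0, {self.n_slices})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomResult:
    """Generated series plus the ground truth needed by tests and oracles."""

    volume: VolumeGrid
    boxes: list[BoxRecord]  # tight boxes of the disrupted region, per slice
    shell_mask: np.ndarray  # bool (row, col, slice): fractured cortical shell
    pristine_shell_mask: np.ndarray  # bool: shell with no fracture applied
    disrupted_mask: np.ndarray  # bool: symmetric difference of the two shells

    def boxes_on_slice(self, k: int) -> list[BoxRecord]:
        return [b for b in self.boxes if b.slice_index == k]


def _ring_mask(rows: int, cols: int, center: tuple[float, float], r_in: float, r_out: float):
    cy = center[1]
    cx = center[0]
    yy, xx = np.mgrid[0:rows, 0:cols]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    ring = (r2 <= r_out**2) & (r2 > r_in**2)
    disk = r2 <= r_out**2
    angle = np.arctan2(yy - cy, xx - cx)
    return ring, disk, angle


def generate(spec: PhantomSpec) -> PhantomResult:
    """Build the phantom volume and its ground-truth boxes.

    The voxel array is integer HU (as real CT is); identical specs give
    bit-identical output.
    """
    rows, cols, n = spec.rows, spec.cols, spec.n_slices
    center = spec.center if spec.center is not None else ((cols - 1) / 2.0, (rows - 1) / 2.0)
    soft_r = spec.soft_tissue_radius or 1.6 * spec.radius_outer

    ring, disk, angle = _ring_mask(rows, cols, center, spec.radius_inner, spec.radius_outer)
    yy, xx = np.mgrid[0:rows, 0:cols]
    soft = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= soft_r**2

    pristine_shell = np.repeat(ring[:, :, None], n, axis=2)
    shell = pristine_shell.copy()

    for f in spec.fractures:
        sl = slice(f.slice_start, f.slice_stop)
        if f.kind == "gap":
            # wrap-aware angular wedge
            d = np.angle(np.exp(1j * (angle - f.angle_center)))
            wedge = np.abs(d) <= f.angle_width / 2.0
            shell[:, :, sl] &= ~wedge[:, :, None]
        else:
            dx, dy = f.shift
            shifted = np.zeros_like(ring)
            src_y = slice(max(0, -dy), min(rows, rows - dy))
            dst_y = slice(max(0, dy), min(rows, rows + dy))
            src_x = slice(max(0, -dx), min(cols, cols - dx))
            dst_x = slice(max(0, dx), min(cols, cols + dx))
            shifted[dst_y, dst_x] = ring[src_y, src_x]
            shell[:, :, sl] = shifted[:, :, None]

    disrupted = shell ^ pristine_shell

    hu = np.full((rows, cols, n), spec.air_hu, dtype=np.float64)
    hu[soft] = spec.soft_tissue_hu
    hu[shell] = spec.cortical_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=hu.shape)
        np.clip(noise, -3 * spec.noise_sd, 3 * spec.noise_sd, out=noise)
        hu += noise
    hu = np.round(hu)

    boxes: list[BoxRecord] = []
    for k in range(n):
        diff = disrupted[:, :, k]
        if not diff.any():
            continue
        rows_any = np.flatnonzero(diff.any(axis=1))
        cols_any = np.flatnonzero(diff.any(axis=0))
        boxes.append(
            BoxRecord(
                x_start=int(cols_any[0]),
                y_start=int(rows_any[0]),
                x_extent=int(cols_any[-1] - cols_any[0] + 1),
                y_extent=int(rows_any[-1] - rows_any[0] + 1),
                slice_index=k,
            )
        )

    meta = [
        SliceMeta(
            rows=rows,
            cols=cols,
            pixel_spacing_x=spec.pixel_spacing[0],
            pixel_spacing_y=spec.pixel_spacing[1],
            slice_thickness=spec.slice_thickness,
            slice_index=k,
        )
        for k in range(n)
    ]
    volume = VolumeGrid(voxels=hu, meta=meta, series_id=f"phantom-seed{spec.seed}")
    return PhantomResult(
        volume=volume,
        boxes=boxes,
        shell_mask=shell,
        pristine_shell_mask=pristine_shell,
        disrupted_mask=disrupted,
    )


def sample_specs(
    n_cases: int,
    seed: int = 0,
    *,
    rows: int = 512,
    cols: int = 512,
    n_slices: int = 40,
    pixel_spacing: tuple[float, float] = (0.8, 0.8),
    slice_thickness: float = 1.0,
    radius_outer: float = 60.0,
    radius_inner: float = 42.0,
    cortical_hu: float = 1200.0,
    noise_sd: float = 0.0,
    fractures_per_case: int = 1,
) -> list[PhantomSpec]:
    """Draw a seeded cohort of one-or-more-fracture phantom cases.

    Each case gets fractures with a random angular position, an angular
    width of 40-80 degrees and a span of 4-8 slices, placed away from the
    volume ends — a plain stand-in for the variety of cortical
    disruptions seen across a fracture cohort.  The base seed fully
    determines every case.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        case_rng = np.random.default_rng(case_seed)
        fractures = []
        for _ in range(fractures_per_case):
            length = min(int(case_rng.integers(4, 9)), max(1, n_slices - 4))
            start_lo = min(2, n_slices - length)
            start_hi = max(start_lo + 1, n_slices - length - 1)
            start = int(case_rng.integers(start_lo, start_hi))
            fractures.append(
                FractureSpec(
                    slice_start=start,
                    slice_stop=start + length,
                    kind="gap",
                    angle_center=float(case_rng.uniform(-math.pi, math.pi)),
                    angle_width=float(case_rng.uniform(math.radians(40), math.radians(80))),
                )
            )
        specs.append(
            PhantomSpec(
                rows=rows,
                cols=cols,
                n_slices=n_slices,
                pixel_spacing=pixel_spacing,
                slice_thickness=slice_thickness,
                radius_outer=radius_outer,
                radius_inner=radius_inner,
                cortical_hu=cortical_hu,
                fractures=tuple(fractures),
                noise_sd=noise_sd,
                seed=case_seed,
            )
        )
    return specs


def split_dataset(
    cases: list, fractions: tuple[float, float, float] = (0.6, 0.1, 0.3), seed: int = 0
) -> tuple[list, list, list]:
    """Shuffle and partition cases into train/validation/test splits.

    Split sizes follow largest-remainder rounding of ``len(cases) *
    fraction``, so a 10-case set under (0.6, 0.1, 0.3) yields 6/1/3.  The
    partition is disjoint and exhaustive, with a seeded shuffle.
    """
    if not cases:
        raise ValueError("empty case list")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(cases)
    exact = [f * n for f in fractions]
    sizes = [int(math.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    short = n - sum(sizes)
    # hand the leftover slots to the largest remainders (ties: earlier split)
    for idx in sorted(range(3), key=lambda i: (-remainders[i], i))[:short]:
        sizes[idx] += 1
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [cases[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return train, val, test
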