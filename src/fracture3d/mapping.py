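"""Lift per-slice pixel boxes into millimetre cuboids and stack the 3D mask.

The coordinate frame is the scanner grid: origin at the corner of voxel
(0, 0, 0), axes along image X, image Y and the slice direction.  A 2D box
(x_start, y_start, x_extent, y_extent) on slice k becomes the cuboid with
origin (x_start*sx, y_start*sy, k*t) and extents (x_extent*sx,
y_extent*sy, t), where (sx, sy) is the pixel spacing and t the slice
thickness — the mapping is exactly invertible given the metadata.  A
slice's z-slab is the half-open [k*t, (k+1)*t), matching the half-open
pixel convention, so boxes on adjacent slices tile without overlap.

Stacking cuboids across slices produces the 3D fracture mask (the "red
mask") rendered over the reconstructed bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from fracture3d.annotation import BoxRecord
from fracture3d.dicom_io import SliceMeta
from fracture3d.reconstruction import BoneMesh

logger = logging.getLogger(__name__)

MERGE_GAP_DEFAULT = 1  # detector misses on one slice should not split a fracture


@dataclass(frozen=True)
class Cuboid3D:
    """Axis-aligned box in millimetre coordinates."""

    origin: tuple[float, float, float]
    extents: tuple[float, float, float]
    slice_index: int
    score: float | None = None

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"cuboid extents must be positive, got {self.extents}")

    @property
    def volume(self) -> float:
        return self.extents[0] * self.extents[1] * self.extents[2]

    def xy_interval(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the in-plane footprint."""
        return (
            self.origin[0],
            self.origin[0] + self.extents[0],
            self.origin[1],
            self.origin[1] + self.extents[1],
        )


@dataclass
class FractureMask3D:
    """Union of lifted box cuboids, grouped into connected components."""

    cuboids: list[Cuboid3D]
    groups: list[list[int]]  # indices into cuboids, one list per component
    source_id: str = ""

    @property
    def n_components(self) -> int:
        return len(self.groups)

    def voxelize(
        self, shape: tuple[int, int, int], meta: SliceMeta
    ) -> np.ndarray:
        """Boolean union of the cuboids on the source voxel grid."""
        out = np.zeros(shape, dtype=bool)
        sx, sy, t = meta.pixel_spacing_x, meta.pixel_spacing_y, meta.slice_thickness
        for c in self.cuboids:
            x0 = int(round(c.origin[0] / sx))
            y0 = int(round(c.origin[1] / sy))
            z0 = int(round(c.origin[2] / t))
            x1 = x0 + int(round(c.extents[0] / sx))
            y1 = y0 + int(round(c.extents[1] / sy))
            z1 = z0 + int(round(c.extents[2] / t))
            out[
                max(y0, 0) : min(y1, shape[0]),
                max(x0, 0) : min(x1, shape[1]),
                max(z0, 0) : min(z1, shape[2]),
            ] = True
        return out


def box_to_cuboid(box: BoxRecord, meta: SliceMeta) -> Cuboid3D:
    """Translate a pixel box on one slice into a millimetre cuboid."""
    sx, sy, t = meta.pixel_spacing_x, meta.pixel_spacing_y, meta.slice_thickness
    return Cuboid3D(
        origin=(box.x_start * sx, box.y_start * sy, box.slice_index * t),
        extents=(box.x_extent * sx, box.y_extent * sy, t),
        slice_index=box.slice_index,
        score=box.score,
    )


def cuboid_to_box(cuboid: Cuboid3D, meta: SliceMeta) -> BoxRecord:
    """Exact inverse of :func:`box_to_cuboid` for the same metadata."""
    sx, sy, t = meta.pixel_spacing_x, meta.pixel_spacing_y, meta.slice_thickness
    return BoxRecord(
        x_start=int(round(cuboid.origin[0] / sx)),
        y_start=int(round(cuboid.origin[1] / sy)),
        x_extent=int(round(cuboid.extents[0] / sx)),
        y_extent=int(round(cuboid.extents[1] / sy)),
        slice_index=cuboid.slice_index,
        score=cuboid.score,
    )


def _xy_overlap(a: Cuboid3D, b: Cuboid3D) -> bool:
    ax0, ax1, ay0, ay1 = a.xy_interval()
    bx0, bx1, by0, by1 = b.xy_interval()
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def stack_mask(
    cuboids: list[Cuboid3D],
    merge_gap: int = MERGE_GAP_DEFAULT,
    source_id: str = "",
) -> FractureMask3D:
    """Group lifted boxes into connected fracture components.

    Two cuboids join one component when their in-plane footprints overlap
    with positive area and at most ``merge_gap`` empty slices separate
    them (adjacent slices have zero empty slices between).  With
    ``merge_gap = 0`` every box is rendered on its own unless slabs
    actually touch, which reproduces render-every-box behaviour.
    """
    n = len(cuboids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(cuboids[i].slice_index - cuboids[j].slice_index) - 1
            if gap <= merge_gap and _xy_overlap(cuboids[i], cuboids[j]):
                union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    groups = sorted(components.values(), key=lambda g: min(g))
    logger.info("stack_mask: %d cuboids -> %d components", n, len(groups))
    return FractureMask3D(cuboids=list(cuboids), groups=groups, source_id=source_id)


BONE_COLOR = (226, 223, 210, 255)
MASK_COLOR = (255, 0, 0, 110)  # semi-transparent red


def overlay(
    mesh: BoneMesh,
    mask: FractureMask3D,
    out: str | Path,
    snapshot: str | Path | None = None,
    camera_elev: float = 20.0,
    camera_azim: float = -60.0,
) -> Path:
    """Write a 3D scene of the bone mesh with the red fracture mask.

    The scene is exported as glTF; if ``snapshot`` is given, a static PNG
    is rendered with a fixed camera (deterministic for fixed inputs).
    Inputs are not mutated.  A coordinate-frame mismatch (both objects
    carry source ids and they differ) is an error.
    """
    if mesh.provenance and mask.source_id and mesh.provenance != mask.source_id:
        raise ValueError(
            f"coordinate-frame mismatch: mesh from {mesh.provenance!r}, "
            f"mask from {mask.source_id!r}"
        )
    out = Path(out)
    scene = trimesh.Scene()
    bone = mesh.as_trimesh()
    bone.visual.face_colors = BONE_COLOR
    scene.add_geometry(bone, node_name="bone")
    for gi, group in enumerate(mask.groups):
        for ci in group:
            c = mask.cuboids[ci]
            box = trimesh.creation.box(extents=c.extents)
            box.apply_translation(np.asarray(c.origin) + np.asarray(c.extents) / 2.0)
            box.visual.face_colors = MASK_COLOR
            scene.add_geometry(box, node_name=f"fracture_{gi}_{ci}")
    scene.export(str(out))

    if snapshot is not None:
        _render_snapshot(mesh, mask, Path(snapshot), camera_elev, camera_azim)
    return out


def _render_snapshot(
    mesh: BoneMesh, mask: FractureMask3D, path: Path, elev: float, azim: float
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="3d")
    ax.plot_trisurf(
        mesh.vertices[:, 0],
        mesh.vertices[:, 1],
        mesh.faces,
        mesh.vertices[:, 2],
        color=(0.85, 0.83, 0.78),
        alpha=0.6,
        linewidth=0,
    )
    for group in mask.groups:
        for ci in group:
            c = mask.cuboids[ci]
            box = trimesh.creation.box(extents=c.extents)
            box.apply_translation(np.asarray(c.origin) + np.asarray(c.extents) / 2.0)
            ax.plot_trisurf(
                box.vertices[:, 0],
                box.vertices[:, 1],
                box.faces,
                box.vertices[:, 2],
                color=(1.0, 0.0, 0.0),
                alpha=0.35,
                linewidth=0,
            )
    ax.view_init(elev=elev, azim=azim)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
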