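"""Bone segmentation by HU thresholding and capped surface reconstruction.

Cortical bone occupies a narrow attenuation band on CT; thresholding the
volume at 1150–1250 HU (both bounds inclusive, both configurable) gives a
binary bone matrix.  A marching-cubes isosurface at level 0.5 of that
binary field, scaled by the voxel spacing, yields the bone surface in
millimetres.  The volume is zero-padded one layer in-plane only, so
structures touching the lateral borders still close, while a tube running
the full slice range stays open at the top and bottom slice planes; those
openings are then closed with planar caps to fashion a watertight bone
model whose enclosed volume is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from fracture3d.dicom_io import VolumeGrid

logger = logging.getLogger(__name__)

HU_BAND_DEFAULT = (1150.0, 1250.0)
MIN_COMPONENT_VOXELS = 20


@dataclass
class BoneMask:
    """Binary bone matrix aligned with the source volume's voxels."""

    mask: np.ndarray  # bool, (row, col, slice)
    hu_band: tuple[float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (row, col, slice)")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class BoneMesh:
    """Triangulated bone surface in millimetre coordinates.

    Vertices are (x, y, z) mm with x = col * pixel_spacing_x,
    y = row * pixel_spacing_y, z = slice * slice_thickness.
    """

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices exceed vertex count")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    def enclosed_volume(self) -> float:
        """Enclosed volume in mm^3; requires a watertight mesh."""
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise ValueError("mesh is not watertight; volume is undefined")
        return float(abs(tm.volume))

    def export(self, path) -> None:
        """Write the mesh; format from the extension (.ply/.stl and variants)."""
        self.as_trimesh().export(path)


def threshold_bone(
    volume: VolumeGrid,
    hu_low: float = HU_BAND_DEFAULT[0],
    hu_high: float = HU_BAND_DEFAULT[1],
) -> BoneMask:
    """Binary bone matrix: 1 exactly where ``hu_low <= HU <= hu_high``."""
    if not hu_low < hu_high:
        raise ValueError(f"reversed HU bounds: ({hu_low}, {hu_high})")
    mask = (volume.voxels >= hu_low) & (volume.voxels <= hu_high)
    logger.info(
        "threshold_bone: band [%s, %s] HU -> %d voxels", hu_low, hu_high, int(mask.sum())
    )
    return BoneMask(mask=mask, hu_band=(hu_low, hu_high), source_id=volume.series_id)


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    dropped = int((~keep[1:]).sum())
    if dropped:
        logger.info(
            "extract_surface: dropped %d components under %d voxels", dropped, min_voxels
        )
    return keep[labels]


def extract_surface(
    mask: BoneMask,
    spacing: tuple[float, float, float],
    min_component_voxels: int = MIN_COMPONENT_VOXELS,
) -> BoneMesh:
    """Marching-cubes isosurface of the binary mask at level 0.5.

    ``spacing`` is (dx, dy, dz) mm.  The mask is zero-padded one layer
    along rows and columns only, so the surface closes laterally but stays
    open where bone meets the first/last slice plane (see
    :func:`cap_mesh`).  Connected components smaller than
    ``min_component_voxels`` are dropped as thresholding specks.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("no bone found: the mask has no foreground voxels")
    if min_component_voxels > 0:
        m = _drop_small_components(m, min_component_voxels)
        if not m.any():
            raise ValueError("no bone found: all components below the size floor")
    padded = np.pad(m, ((1, 1), (1, 1), (0, 0)))
    dx, dy, dz = spacing
    # array axes are (row, col, slice) -> spacing (dy, dx, dz)
    verts, faces, _, _ = measure.marching_cubes(
        padded.astype(np.float32), level=0.5, spacing=(dy, dx, dz)
    )
    verts[:, 0] -= dy  # undo the padding offset
    verts[:, 1] -= dx
    # reorder (row, col, slice) -> (x, y, z)
    xyz = verts[:, [1, 0, 2]]
    return BoneMesh(vertices=xyz, faces=faces, provenance=mask.source_id)


def _boundary_loops(tm: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary (edges on exactly one face)."""
    edges = tm.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return []
    # walk the boundary edges into closed loops
    adjacency: dict[int, list[int]] = {}
    for a, b in boundary:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    unvisited = {tuple(e) for e in boundary}
    loops: list[np.ndarray] = []
    while unvisited:
        a, b = next(iter(unvisited))
        loop = [a, b]
        unvisited.discard((a, b))
        while True:
            nxt = [v for v in adjacency[loop[-1]] if v != loop[-2]]
            candidates = [
                v for v in nxt if tuple(sorted((loop[-1], v))) in unvisited
            ]
            if not candidates:
                break
            v = candidates[0]
            unvisited.discard(tuple(sorted((loop[-1], v))))
            if v == loop[0]:
                break
            loop.append(v)
        loops.append(np.array(loop))
    return loops


def cap_mesh(
    mesh: BoneMesh,
    mask: BoneMask,
    slice_thickness: float | None = None,
    plane_tol: float = 1e-6,
) -> BoneMesh:
    """Close the open top/bottom slice-plane boundaries with planar caps.

    Boundary loops lying in a constant-z plane are extruded half a slice
    outward (the isosurface passes through voxel centers, so the outermost
    half-slab of bone lies beyond the first/last slice plane) and closed
    with a triangle fan to the loop centroid, oriented consistently with
    the adjacent faces; the result is watertight.  When
    ``slice_thickness`` is None the extrusion is skipped and the cap sits
    on the slice plane itself.  An already-closed mesh is returned
    unchanged.  Boundary loops that are *not* planar in z (holes elsewhere
    in the surface) are reported as an error rather than silently capped.
    """
    tm = mesh.as_trimesh()
    if tm.is_watertight:
        return mesh

    loops = _boundary_loops(tm)
    bad = []
    vertices = mesh.vertices.copy()
    faces = list(mesh.faces)
    z_mid = vertices[:, 2].mean()

    # orientation lookup: boundary edge -> the single face that uses it
    edge_dir: dict[tuple[int, int], bool] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_dir[(int(a), int(b))] = True

    new_faces = []
    new_vertices: list[np.ndarray] = []
    n0 = len(vertices)

    def add_vertex(v) -> int:
        new_vertices.append(np.asarray(v, dtype=float))
        return n0 + len(new_vertices) - 1

    for loop in loops:
        z = vertices[loop, 2]
        if z.max() - z.min() > plane_tol:
            bad.append(loop)
            continue
        if slice_thickness is not None:
            offset = -slice_thickness / 2.0 if z[0] <= z_mid else slice_thickness / 2.0
        else:
            offset = 0.0
        shifted = {}
        if offset != 0.0:
            for v in loop:
                p = vertices[int(v)].copy()
                p[2] += offset
                shifted[int(v)] = add_vertex(p)
        centroid = vertices[loop].mean(axis=0)
        centroid[2] += offset
        c_idx = add_vertex(centroid)
        for i in range(len(loop)):
            a = int(loop[i])
            b = int(loop[(i + 1) % len(loop)])
            if (a, b) not in edge_dir:
                a, b = b, a  # owner face traverses the edge the other way
            if offset != 0.0:
                # side wall of the half-slice extrusion, then the fan cap
                ap, bp = shifted[a], shifted[b]
                new_faces.append((b, a, ap))
                new_faces.append((b, ap, bp))
                new_faces.append((bp, ap, c_idx))
            else:
                new_faces.append((b, a, c_idx))

    if bad:
        raise ValueError(
            f"mesh has {len(bad)} non-planar boundary holes that are not "
            "top/bottom slice openings; refusing to cap them"
        )
    if new_vertices:
        vertices = np.vstack([vertices, np.array(new_vertices)])
    capped = BoneMesh(
        vertices=vertices,
        faces=np.array(faces + new_faces, dtype=int),
        provenance=mesh.provenance,
    )
    tm2 = capped.as_trimesh()
    if not tm2.is_watertight:
        logger.warning("cap_mesh: result is still not watertight")
    return capped


def save_mask(mask: BoneMask, path) -> None:
    """Persist the binary matrix as a compressed array file (.npz)."""
    np.savez_compressed(
        path, mask=mask.mask, hu_band=np.array(mask.hu_band), source_id=mask.source_id
    )


def load_mask(path) -> BoneMask:
    data = np.load(path, allow_pickle=False)
    return BoneMask(
        mask=data["mask"],
        hu_band=tuple(data["hu_band"]),
        source_id=str(data["source_id"]),
    )
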