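"""Pixel-to-millimetre lifting, mask stacking and the overlay scene."""

import numpy as np
import pytest

from fracture3d import (
    BoxRecord,
    Cuboid3D,
    SliceMeta,
    box_to_cuboid,
    cap_mesh,
    extract_surface,
    overlay,
    stack_mask,
    threshold_bone,
)
from fracture3d.mapping import cuboid_to_box


def meta(sx=0.5, sy=0.5, t=2.0, k=0):
    return SliceMeta(rows=512, cols=512, pixel_spacing_x=sx, pixel_spacing_y=sy,
                     slice_thickness=t, slice_index=k)


class TestBoxToCuboid:
    def test_linear_scaling(self):
        c = box_to_cuboid(BoxRecord(10, 20, 30, 40, slice_index=7), meta())
        assert c.origin == (5.0, 10.0, 14.0)
        assert c.extents == (15.0, 20.0, 2.0)

    def test_unit_spacing_is_identity(self):
        c = box_to_cuboid(BoxRecord(10, 20, 30, 40, slice_index=3), meta(1.0, 1.0, 1.0))
        assert c.origin == (10.0, 20.0, 3.0)
        assert c.extents == (30.0, 40.0, 1.0)

    @pytest.mark.parametrize("sx,sy,t", [(0.5, 0.5, 2.0), (0.8, 0.6, 1.25), (1.0, 1.0, 3.0)])
    def test_inverse_round_trip_exact(self, rng, sx, sy, t):
        m = meta(sx, sy, t)
        for _ in range(50):
            box = BoxRecord(
                x_start=int(rng.integers(0, 400)),
                y_start=int(rng.integers(0, 400)),
                x_extent=int(rng.integers(1, 100)),
                y_extent=int(rng.integers(1, 100)),
                slice_index=int(rng.integers(0, 40)),
            )
            back = cuboid_to_box(box_to_cuboid(box, m), m)
            assert (back.x_start, back.y_start, back.x_extent, back.y_extent,
                    back.slice_index) == (
                box.x_start, box.y_start, box.x_extent, box.y_extent, box.slice_index,
            )

    def test_z_extent_is_slice_thickness(self):
        c = box_to_cuboid(BoxRecord(0, 0, 1, 1, slice_index=5), meta(t=1.25))
        assert c.extents[2] == 1.25


class TestStackMask:
    def test_single_cuboid_single_component(self):
        c = Cuboid3D((0, 0, 0), (5, 5, 1), slice_index=0)
        mask = stack_mask([c])
        assert mask.n_components == 1

    def test_adjacent_identical_boxes_fuse_with_double_volume(self):
        m = meta(1.0, 1.0, 2.0)
        cuboids = [
            box_to_cuboid(BoxRecord(10, 10, 20, 10, slice_index=k), m) for k in (3, 4)
        ]
        mask = stack_mask(cuboids)
        assert mask.n_components == 1
        vox = mask.voxelize((64, 64, 12), m)
        assert vox.sum() == 2 * 20 * 10  # voxel count; x2 slabs of thickness t
        zs = np.flatnonzero(vox.any(axis=(0, 1)))
        assert list(zs) == [3, 4]

    def test_far_apart_cuboids_stay_separate(self):
        a = Cuboid3D((0, 0, 0), (5, 5, 1), slice_index=0)
        b = Cuboid3D((50, 50, 30), (5, 5, 1), slice_index=30)
        assert stack_mask([a, b], merge_gap=0).n_components == 2

    def test_merge_gap_bridges_missed_slices(self):
        m = meta(1.0, 1.0, 1.0)
        cuboids = [
            box_to_cuboid(BoxRecord(10, 10, 10, 10, slice_index=k), m) for k in (2, 4)
        ]
        assert stack_mask(cuboids, merge_gap=0).n_components == 2
        assert stack_mask(cuboids, merge_gap=1).n_components == 1

    def test_disjoint_volume_is_conserved(self, rng):
        """Voxelized volume equals the cuboid volume sum for disjoint boxes."""
        m = meta(0.5, 0.5, 2.0)
        boxes = [
            BoxRecord(10 + 30 * i, 20, 12, 15, slice_index=2 * i) for i in range(4)
        ]
        cuboids = [box_to_cuboid(b, m) for b in boxes]
        mask = stack_mask(cuboids, merge_gap=0)
        vox = mask.voxelize((128, 256, 12), m)
        voxel_volume = 0.5 * 0.5 * 2.0
        assert vox.sum() * voxel_volume == pytest.approx(
            sum(c.volume for c in cuboids), abs=1e-9
        )


@pytest.fixture(scope="module")
def bone_mesh(fractured_phantom):
    mask = threshold_bone(fractured_phantom.volume)
    return cap_mesh(extract_surface(mask, fractured_phantom.volume.spacing), mask, 1.0)


class TestOverlay:
    def test_scene_written_with_empty_mask(self, bone_mesh, tmp_path):
        mask = stack_mask([], source_id=bone_mesh.provenance)
        out = overlay(bone_mesh, mask, tmp_path / "scene.gltf")
        assert out.exists()
        assert "fracture_" not in out.read_text()

    def test_red_mask_contains_disruption_centroid(
        self, bone_mesh, fractured_phantom, tmp_path
    ):
        from fracture3d.detector import detect_rule

        volume = fractured_phantom.volume
        dets = detect_rule(volume)
        cuboids = [box_to_cuboid(b, volume.meta[0]) for b in dets]
        mask = stack_mask(cuboids, source_id=volume.series_id)
        overlay(bone_mesh, mask, tmp_path / "scene.gltf", snapshot=tmp_path / "snap.png")
        assert (tmp_path / "snap.png").exists()
        ys, xs, zs = np.nonzero(fractured_phantom.disrupted_mask)
        sx, sy, t = volume.spacing
        centroid = (xs.mean() * sx, ys.mean() * sy, zs.mean() * t)
        lo = np.min([c.origin for c in cuboids], axis=0)
        hi = np.max([np.add(c.origin, c.extents) for c in cuboids], axis=0)
        assert (lo <= centroid).all() and (centroid <= hi).all()

    def test_frame_mismatch_rejected(self, bone_mesh, tmp_path):
        mask = stack_mask(
            [Cuboid3D((0, 0, 0), (1, 1, 1), 0)], source_id="other-series"
        )
        with pytest.raises(ValueError, match="mismatch"):
            overlay(bone_mesh, mask, tmp_path / "scene.gltf")

    def test_inputs_not_mutated(self, bone_mesh, tmp_path):
        vertices_before = bone_mesh.vertices.copy()
        c = Cuboid3D((1, 1, 1), (2, 2, 1), 1)
        mask = stack_mask([c], source_id=bone_mesh.provenance)
        overlay(bone_mesh, mask, tmp_path / "scene.gltf")
        np.testing.assert_array_equal(bone_mesh.vertices, vertices_before)
        assert mask.cuboids == [c]
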