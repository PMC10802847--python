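"""Box matrix round trips, augmentation geometry and the TSV format."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fracture3d import (
    BoxRecord,
    augment,
    from_matrix,
    read_boxes,
    shift_augment,
    to_matrix,
    write_boxes,
)

boxes_strategy = st.lists(
    st.builds(
        BoxRecord,
        x_start=st.integers(0, 400),
        y_start=st.integers(0, 400),
        x_extent=st.integers(1, 100),
        y_extent=st.integers(1, 100),
        slice_index=st.integers(0, 50),
        label=st.sampled_from(["fracture", "comminuted"]),
        score=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    ),
    max_size=8,
)


class TestBoxMatrix:
    def test_empty_list_gives_4x0(self):
        m = to_matrix([])
        assert m.data.shape == (4, 0)
        assert from_matrix(m) == []

    def test_single_box_column_order(self):
        m = to_matrix([BoxRecord(10, 20, 30, 40)])
        np.testing.assert_array_equal(m.data[:, 0], [10, 20, 30, 40])

    @given(boxes_strategy)
    def test_round_trip_is_identity(self, boxes):
        assert from_matrix(to_matrix(boxes)) == boxes

    def test_shape_validation(self):
        from fracture3d.annotation import BoxMatrix

        with pytest.raises(ValueError, match="4xN"):
            BoxMatrix(np.zeros((3, 2)), [0, 0], ["a", "a"], [None, None])


class TestAugment:
    def test_identity_element(self, rng):
        image = rng.normal(size=(64, 64)).astype(np.float32)
        boxes = [BoxRecord(10, 20, 30, 20)]
        out, out_boxes = augment(image, boxes, flip=False, scale=1.0)
        np.testing.assert_array_equal(out, image)
        assert out_boxes == boxes

    def test_horizontal_flip_is_involution(self, rng):
        image = rng.normal(size=(64, 64)).astype(np.float32)
        boxes = [BoxRecord(10, 20, 30, 20)]
        once = augment(image, boxes, flip=True, scale=1.0)
        twice = augment(once[0], once[1], flip=True, scale=1.0)
        np.testing.assert_array_equal(twice[0], image)
        assert twice[1] == boxes

    def test_flip_formula_on_512_image(self, rng):
        """x_start' = W - x_start - x_extent under a pure horizontal flip."""
        image = rng.normal(size=(512, 512)).astype(np.float32)
        _, out_boxes = augment(image, [BoxRecord(10, 20, 30, 40)], flip=True, scale=1.0)
        b = out_boxes[0]
        assert (b.x_start, b.y_start, b.x_extent, b.y_extent) == (472, 20, 30, 40)

    @pytest.mark.parametrize("scale", [1.1, 1.2, 1.3])
    def test_scaling_multiplies_extents_within_one_pixel(self, rng, scale):
        image = rng.normal(size=(256, 256)).astype(np.float32)
        boxes = [BoxRecord(100, 110, 40, 30)]
        _, out_boxes = augment(image, boxes, flip=False, scale=scale)
        b = out_boxes[0]
        assert abs(b.x_extent - 40 * scale) <= 1.0
        assert abs(b.y_extent - 30 * scale) <= 1.0

    def test_never_flips_vertically(self, rng):
        """Row content order is preserved for every drawn transform."""
        image = np.zeros((64, 64), dtype=np.float32)
        image[5, :] = 1.0  # marker near the top
        for seed in range(10):
            out, _ = augment(image, [], seed=seed)
            top = out[:32].sum()
            bottom = out[32:].sum()
            assert top >= bottom

    def test_box_dropped_only_when_pushed_outside(self, rng):
        image = rng.normal(size=(64, 64)).astype(np.float32)
        # center box survives any 1-1.3x scale; corner sliver may not
        center = BoxRecord(30, 30, 4, 4)
        for seed in range(5):
            _, out = augment(image, [center], seed=seed)
            assert len(out) == 1


class TestShiftAugment:
    def test_copy_count(self, rng):
        image = rng.normal(size=(64, 64)).astype(np.float32)
        out = shift_augment(image, [BoxRecord(10, 20, 10, 10)], n_copies=10, max_shift=5, seed=0)
        assert len(out) == 10

    def test_zero_shift_returns_identical_copies(self, rng):
        image = rng.normal(size=(32, 32)).astype(np.float32)
        boxes = [BoxRecord(4, 5, 6, 7)]
        for img, bxs in shift_augment(image, boxes, n_copies=3, max_shift=0, seed=0):
            np.testing.assert_array_equal(img, image)
            assert bxs == boxes

    def test_boxes_translate_with_pixels(self):
        """The box moves by exactly the shift applied to the image."""
        image = np.zeros((64, 64), dtype=np.float32)
        image[22, 21] = 1.0  # marker inside the box
        boxes = [BoxRecord(15, 16, 20, 20)]
        for img, bxs in shift_augment(image, boxes, n_copies=8, max_shift=6, seed=3):
            my, mx = np.unravel_index(np.argmax(img), img.shape)
            dx, dy = mx - 21, my - 22
            assert bxs[0].x_start == 15 + dx
            assert bxs[0].y_start == 16 + dy
            assert (bxs[0].x_extent, bxs[0].y_extent) == (20, 20)

    def test_oversized_shift_rejected(self, rng):
        image = rng.normal(size=(16, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="max_shift"):
            shift_augment(image, [], n_copies=1, max_shift=16)


class TestBoxFile:
    def test_empty_file_reads_empty(self, tmp_path):
        path = tmp_path / "boxes.tsv"
        path.write_text("")
        assert read_boxes(path) == []

    @given(boxes_strategy)
    def test_write_read_round_trip(self, boxes):
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "boxes.tsv"
            write_boxes(boxes, path)
            back = read_boxes(path)
        assert len(back) == len(boxes)
        for a, b in zip(back, boxes):
            assert (a.x_start, a.y_start, a.x_extent, a.y_extent) == (
                b.x_start, b.y_start, b.x_extent, b.y_extent,
            )
            assert a.slice_index == b.slice_index and a.label == b.label
            if b.score is None:
                assert a.score is None
            else:
                assert a.score == pytest.approx(b.score, abs=1e-6)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "boxes.tsv"
        path.write_text("0\t1\t2\t3\t4\tfracture\t\nbad\tline\there\n")
        with pytest.raises(ValueError, match=":2"):
            read_boxes(path)
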