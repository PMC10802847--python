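"""Network scaffold: backbone shapes, schedule, toy training, decoding."""

import numpy as np
import pytest

from fracture3d import BoxRecord, FractureSpec, PhantomSpec, generate
from fracture3d.detector import (
    BackboneShapeSpec,
    DetectorConfig,
    build_yolov4,
    detect_yolo,
    learning_rate,
    train_yolov4,
)
from fracture3d.detector import nn
from fracture3d.detector.config import CSP_CHANNELS


@pytest.fixture(scope="module")
def tiny_config():
    return DetectorConfig(kind="yolov4", input_size=32, score_threshold=0.25)


@pytest.fixture(scope="module")
def toy_dataset():
    """Phantom slices with a through-going cortical gap, plus the boxes."""
    spec = PhantomSpec(
        rows=64, cols=64, n_slices=20, radius_outer=20, radius_inner=14,
        fractures=(FractureSpec(0, 20, angle_center=0.5, angle_width=1.2),),
    )
    result = generate(spec)
    lo, hi = -200.0, 1800.0
    images = [
        np.clip((result.volume.voxels[:, :, k] - lo) / (hi - lo), 0, 1).astype(np.float32)
        for k in range(20)
    ]
    return result, [(images[k], result.boxes_on_slice(k)) for k in range(20)]


class TestBackboneShapes:
    def test_five_blocks_halve_spatially_at_64(self, tiny_config):
        net = build_yolov4(DetectorConfig(kind="yolov4", input_size=64), seed=0)
        x = nn.Tensor(np.zeros((1, 3, 64, 64), np.float32))
        feats = net.backbone_forward(x)
        sides = [f.shape[2] for f in feats]
        channels = [f.shape[1] for f in feats]
        assert sides == [32, 16, 8, 4, 2]
        assert channels == list(CSP_CHANNELS)

    def test_shape_spec_scales_with_input(self):
        spec = BackboneShapeSpec(input_size=256)
        assert [b[2] for b in spec.blocks] == [128, 64, 32, 16, 8]
        assert [b[4] for b in spec.blocks] == list(CSP_CHANNELS)

    def test_input_not_divisible_by_32_rejected(self):
        with pytest.raises(ValueError, match="divisible by 32"):
            build_yolov4(DetectorConfig(kind="yolov4", input_size=100))

    def test_head_channel_count(self, tiny_config):
        net = build_yolov4(tiny_config, seed=0)
        out = net.forward(nn.Tensor(np.zeros((1, 3, 32, 32), np.float32)))
        # 3 anchors x (4 box + 1 objectness + 1 class)
        assert all(h.shape[1] == 18 for h in out["heads"])
        assert [h.shape[2] for h in out["heads"]] == [4, 2, 1]


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 0.001), (19, 0.001), (20, 0.0005), (39, 0.0005), (40, 0.00025), (49, 0.00025)],
    )
    def test_halving_every_20_epochs(self, epoch, expected):
        assert learning_rate(epoch) == pytest.approx(expected)

    def test_step_function_closed_form(self):
        config = DetectorConfig(kind="yolov4")
        for epoch in range(0, 100, 7):
            assert learning_rate(epoch, config) == pytest.approx(
                0.001 * 0.5 ** (epoch // 20)
            )


class TestTraining:
    def test_iteration_count_follows_minibatch_arithmetic(self, tiny_config, toy_dataset):
        _, dataset = toy_dataset
        net = build_yolov4(tiny_config, seed=0)
        _, trace = train_yolov4(net, dataset[:8], tiny_config, seed=0, epochs=2)
        assert trace.iterations_per_epoch == 2  # ceil(8 / 4)
        assert len(trace.train) == 4

    def test_loss_decreases_on_toy_set(self, tiny_config, toy_dataset):
        _, dataset = toy_dataset
        net = build_yolov4(tiny_config, seed=1)
        _, trace = train_yolov4(net, dataset[:12], tiny_config, seed=0, epochs=5)
        first = np.mean(trace.train[:3])
        last = np.mean(trace.train[-3:])
        assert last < first

    def test_empty_dataset_rejected(self, tiny_config):
        net = build_yolov4(tiny_config, seed=0)
        with pytest.raises(ValueError, match="empty dataset"):
            train_yolov4(net, [], tiny_config)

    def test_validation_trace_one_entry_per_epoch(self, tiny_config, toy_dataset):
        _, dataset = toy_dataset
        net = build_yolov4(tiny_config, seed=0)
        _, trace = train_yolov4(
            net, dataset[:4], tiny_config, seed=0, epochs=2, validation=dataset[4:6]
        )
        assert len(trace.validation) == 2


class TestDetect:
    def test_threshold_one_gives_no_boxes(self, toy_dataset):
        result, _ = toy_dataset
        config = DetectorConfig(kind="yolov4", input_size=32, score_threshold=1.0)
        net = build_yolov4(config, seed=2)
        assert detect_yolo(net, result.volume, config) == []

    def test_untrained_output_is_valid(self, tiny_config, toy_dataset):
        result, _ = toy_dataset
        net = build_yolov4(tiny_config, seed=2)
        dets = detect_yolo(net, result.volume, tiny_config)
        rows, cols, _ = result.volume.shape
        for d in dets:
            assert 0.0 <= d.score <= 1.0
            assert 0 <= d.x_start < cols and d.x_start + d.x_extent <= cols
            assert 0 <= d.y_start < rows and d.y_start + d.y_extent <= rows

    def test_rescale_commutes_with_physical_mapping(self):
        """Scaling a pixel box by r then lifting with spacing s equals
        lifting the original with spacing r*s."""
        from fracture3d import SliceMeta, box_to_cuboid

        box = BoxRecord(10, 20, 30, 40, slice_index=2)
        scaled = BoxRecord(20, 40, 60, 80, slice_index=2)
        meta_fine = SliceMeta(rows=512, cols=512, pixel_spacing_x=0.5,
                              pixel_spacing_y=0.5, slice_thickness=1.0, slice_index=2)
        meta_coarse = SliceMeta(rows=256, cols=256, pixel_spacing_x=1.0,
                                pixel_spacing_y=1.0, slice_thickness=1.0, slice_index=2)
        assert box_to_cuboid(scaled, meta_fine) == box_to_cuboid(box, meta_coarse)


def test_save_load_round_trip(tmp_path, tiny_config, toy_dataset):
    result, _ = toy_dataset
    net = build_yolov4(tiny_config, seed=3)
    net.save(tmp_path / "weights")
    net2 = build_yolov4(tiny_config, seed=99)
    net2.load(tmp_path / "weights")
    assert detect_yolo(net2, result.volume, tiny_config) == detect_yolo(
        net, result.volume, tiny_config
    )
    assert (tmp_path / "weights.json").exists()


def test_gradients_match_finite_differences(rng):
    """Spot-check the autodiff engine on a small conv + bn + mish stack."""
    x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32), requires_grad=True)
    w = nn.Tensor(rng.normal(size=(4, 3, 3, 3)).astype(np.float32) * 0.1, requires_grad=True)
    gamma = nn.Tensor(np.ones(4), requires_grad=True)
    beta = nn.Tensor(np.zeros(4), requires_grad=True)
    rm = np.zeros(4, np.float32)
    rv = np.ones(4, np.float32)

    def forward():
        y = nn.conv2d(x, w, None, stride=1, pad=1)
        y = nn.batchnorm2d(y, gamma, beta, rm.copy(), rv.copy(), train=False)
        y = nn.mish(y)
        return nn.mse_weighted(y, np.zeros_like(y.data), 1.0)

    loss = forward()
    loss.backward()
    eps = 1e-3
    for tensor in (w, beta):
        flat = tensor.data.ravel()
        grad = tensor.grad.ravel()
        for idx in rng.choice(flat.size, size=3, replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = forward().item()
            flat[idx] = orig - eps
            down = forward().item()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=0.05, abs=1e-3)
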