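"""Workflow orchestration: phantom generation, preprocess, detect,
reconstruct, map, evaluate.

Each stage operates on a case-directory layout under the output
directory::

    out/
      manifest.json            # cases, train/val/test split, provenance
      cases/case_000/
        dicom/slice_*.dcm      # the CT series
        gt_boxes.tsv           # ground-truth fracture boxes
        png/slice_*.png        # windowed 8-bit slices (preprocess)
        detections.tsv         # detector output (detect)
        mesh.ply               # capped bone surface (reconstruct)
        scene.gltf, snapshot.png  # bone + red mask overlay (map)
      metrics.json, pr_curve.png  # aggregate evaluation

Stages are independently invokable (mirroring the workflow's panels) and
deterministic for a fixed config and seed when the rule detector is used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from fracture3d import __version__, annotation, dicom_io, evaluation, mapping, phantom, reconstruction
from fracture3d.detector import DetectorConfig, detect_rule
from fracture3d.detector.yolov4 import build_yolov4, detect_yolo

logger = logging.getLogger(__name__)


class PhantomParams(BaseModel):
    """Study conditions for the synthetic dataset."""

    n_cases: int = 10
    rows: int = 512
    cols: int = 512
    n_slices: int = 40
    pixel_spacing: tuple[float, float] = (0.8, 0.8)
    slice_thickness: float = 1.0
    radius_outer: float = 60.0
    radius_inner: float = 42.0
    cortical_hu: float = 1200.0
    noise_sd: float = 0.0
    fractures_per_case: int = 1


class DetectorParams(BaseModel):
    kind: str = "rule"
    score_threshold: float = 0.25
    input_size: int = 512
    min_gap_px: float = 5.0
    nms_iou: float = 0.5
    weights: str | None = None  # path stem for yolov4 weights (.npz/.json)

    @field_validator("kind")
    @classmethod
    def _kind_ok(cls, v):
        if v not in ("rule", "yolov4"):
            raise ValueError(f"detector kind must be 'rule' or 'yolov4', got {v!r}")
        return v


class PipelineConfig(BaseModel):
    """Validated configuration for every pipeline stage."""

    out_dir: str = "fracture3d_out"
    seed: int = 0
    hu_band: tuple[float, float] = (1150.0, 1250.0)
    png_window: tuple[float, float] = (-200.0, 1800.0)
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    iou_min: float = 0.5
    ap_interpolation: str = "all_points"
    merge_gap: int = 1
    phantom: PhantomParams = Field(default_factory=PhantomParams)
    detector: DetectorParams = Field(default_factory=DetectorParams)

    @field_validator("split_fractions")
    @classmethod
    def _fractions_sum(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            kind=self.detector.kind,
            score_threshold=self.detector.score_threshold,
            input_size=self.detector.input_size,
            hu_band=self.hu_band,
            min_gap_px=self.detector.min_gap_px,
            nms_iou=self.detector.nms_iou,
            png_window=self.png_window,
        )


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }


def _case_dirs(out_dir: Path) -> list[Path]:
    return sorted((out_dir / "cases").glob("case_*"))


def run_phantom(config: PipelineConfig, force: bool = False) -> Path:
    """Generate the seeded phantom dataset: DICOM series, ground-truth
    box TSVs and a split manifest."""
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force to overwrite")
    (out / "cases").mkdir(parents=True, exist_ok=True)

    p = config.phantom
    specs = phantom.sample_specs(
        p.n_cases,
        config.seed,
        rows=p.rows,
        cols=p.cols,
        n_slices=p.n_slices,
        pixel_spacing=p.pixel_spacing,
        slice_thickness=p.slice_thickness,
        radius_outer=p.radius_outer,
        radius_inner=p.radius_inner,
        cortical_hu=p.cortical_hu,
        noise_sd=p.noise_sd,
        fractures_per_case=p.fractures_per_case,
    )
    case_names = []
    for i, spec in enumerate(specs):
        result = phantom.generate(spec)
        name = f"case_{i:03d}"
        case_dir = out / "cases" / name
        dicom_io.write_series(result.volume, case_dir / "dicom")
        annotation.write_boxes(result.boxes, case_dir / "gt_boxes.tsv")
        case_names.append(name)
        logger.info("run_phantom: wrote %s (%d gt boxes)", name, len(result.boxes))

    train, val, test = phantom.split_dataset(
        case_names, config.split_fractions, seed=config.seed
    )
    manifest = {
        "cases": case_names,
        "splits": {"train": train, "val": val, "test": test},
        "provenance": _provenance(config),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def preprocess_case(case_dir: Path, config: PipelineConfig) -> None:
    volume = dicom_io.read_series(case_dir / "dicom")
    dicom_io.to_png(volume, case_dir / "png", window=config.png_window)


def detect_case(case_dir: Path, config: PipelineConfig, network=None) -> list:
    volume = dicom_io.read_series(case_dir / "dicom")
    det_config = config.detector_config()
    if config.detector.kind == "rule":
        detections = detect_rule(volume, det_config)
    else:
        if network is None:
            network = build_yolov4(det_config, seed=config.seed)
            if config.detector.weights:
                network.load(config.detector.weights)
        detections = detect_yolo(network, volume, det_config)
    annotation.write_boxes(detections, case_dir / "detections.tsv")
    return detections


def reconstruct_case(case_dir: Path, config: PipelineConfig) -> reconstruction.BoneMesh:
    volume = dicom_io.read_series(case_dir / "dicom")
    mask = reconstruction.threshold_bone(volume, *config.hu_band)
    mesh = reconstruction.extract_surface(mask, volume.spacing)
    mesh = reconstruction.cap_mesh(mesh, mask, volume.spacing[2])
    mesh.export(case_dir / "mesh.ply")
    return mesh


def map_case(case_dir: Path, config: PipelineConfig) -> mapping.FractureMask3D:
    volume = dicom_io.read_series(case_dir / "dicom")
    detections = annotation.read_boxes(case_dir / "detections.tsv")
    cuboids = [mapping.box_to_cuboid(b, volume.meta[0]) for b in detections]
    mask3d = mapping.stack_mask(cuboids, merge_gap=config.merge_gap, source_id=volume.series_id)
    mask = reconstruction.threshold_bone(volume, *config.hu_band)
    mesh = reconstruction.cap_mesh(
        reconstruction.extract_surface(mask, volume.spacing), mask, volume.spacing[2]
    )
    mapping.overlay(
        mesh, mask3d, case_dir / "scene.gltf", snapshot=case_dir / "snapshot.png"
    )
    return mask3d


def evaluate_dataset(out_dir: Path, config: PipelineConfig, cases: list[str]) -> dict:
    """Aggregate metrics across cases: one PR curve, one IoU stats block."""
    gt_all = []
    pred_all = []
    for offset, name in enumerate(cases):
        case_dir = out_dir / "cases" / name
        # keep slices from different cases distinct during matching
        shift = offset * 100000
        for b in annotation.read_boxes(case_dir / "gt_boxes.tsv"):
            gt_all.append(
                annotation.BoxRecord(
                    b.x_start, b.y_start, b.x_extent, b.y_extent,
                    slice_index=b.slice_index + shift, label=b.label,
                )
            )
        for b in annotation.read_boxes(case_dir / "detections.tsv"):
            pred_all.append(
                annotation.BoxRecord(
                    b.x_start, b.y_start, b.x_extent, b.y_extent,
                    slice_index=b.slice_index + shift, label=b.label, score=b.score,
                )
            )
    counts, matched = evaluation.match(gt_all, pred_all, iou_min=config.iou_min)
    curve = evaluation.pr_curve(
        gt_all, pred_all, iou_min=config.iou_min, interpolation=config.ap_interpolation
    )
    stats = evaluation.iou_stats(matched) if matched else None
    report = evaluation.metrics_report(counts, curve, stats)
    report["provenance"] = _provenance(config)
    (out_dir / "metrics.json").write_text(json.dumps(report, indent=2))
    evaluation.plot_pr_curve(curve, out_dir / "pr_curve.png")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Reconstruct, detect, map and evaluate every test-split case.

    A stage failure aborts that case (logged) and the remaining cases
    continue; if every case fails, a RuntimeError is raised.
    """
    out = Path(config.out_dir)
    manifest = read_manifest(out)
    test_cases = manifest["splits"]["test"]
    succeeded = []
    for name in test_cases:
        case_dir = out / "cases" / name
        try:
            preprocess_case(case_dir, config)
            detect_case(case_dir, config)
            reconstruct_case(case_dir, config)
            map_case(case_dir, config)
            succeeded.append(name)
        except Exception:
            logger.exception("case %s failed; continuing", name)
    if not succeeded:
        raise RuntimeError("all cases failed")
    report = evaluate_dataset(out, config, succeeded)
    logger.info(
        "run_pipeline: %d/%d cases, AP=%.3f",
        len(succeeded), len(test_cases), report["average_precision"],
    )
    return report
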