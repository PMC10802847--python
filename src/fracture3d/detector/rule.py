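"""Deterministic rule-based cortical-gap detector.

A fracture of a tubular bone interrupts the cortical shell, which on an
axial slice is a bright ring in the 1150-1250 HU band.  The detector
thresholds each slice into that band, walks the ring in polar order
around its centroid and looks for angular runs with no shell pixels.  A
run whose arc length (at the mean shell radius) reaches ``min_gap_px``
is reported as one detection: the tight box around the missing arc, with
a score equal to the normalized gap size (gap arc / half circumference,
clipped to 1).

Because the decision depends only on the thresholded mask, the detector
is exactly invariant to HU perturbations that stay inside or outside the
band, and two identical volumes always give identical detections.
"""

from __future__ import annotations

import logging

import numpy as np

from fracture3d.annotation import BoxRecord
from fracture3d.detector.config import DetectorConfig
from fracture3d.dicom_io import VolumeGrid
from fracture3d.reconstruction import threshold_bone

logger = logging.getLogger(__name__)


def _angular_runs(occupied: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of empty bins as (start_bin, length)."""
    n = len(occupied)
    if occupied.all():
        return []
    if not occupied.any():
        return [(0, n)]
    runs = []
    # rotate so the scan starts on an occupied bin, making runs non-wrapping
    start = int(np.argmax(occupied))
    rolled = np.roll(occupied, -start)
    in_run = False
    run_start = 0
    for i in range(n):
        if not rolled[i] and not in_run:
            in_run, run_start = True, i
        elif rolled[i] and in_run:
            runs.append(((run_start + start) % n, i - run_start))
            in_run = False
    if in_run:
        runs.append(((run_start + start) % n, n - run_start))
    return runs


def detect_rule(volume: VolumeGrid, config: DetectorConfig | None = None) -> list[BoxRecord]:
    """Find cortical-shell interruptions on every slice of *volume*.

    Returns scored :class:`BoxRecord` detections; an unbroken (or absent)
    shell on a slice contributes none.  Deterministic: no randomness
    anywhere in the scan.
    """
    config = config or DetectorConfig(kind="rule")
    mask3d = threshold_bone(volume, *config.hu_band).mask
    results: list[BoxRecord] = []
    for k in range(volume.shape[2]):
        mask = mask3d[:, :, k]
        ys, xs = np.nonzero(mask)
        if len(ys) < 8:  # too few shell pixels to define a ring
            continue
        cy, cx = ys.mean(), xs.mean()
        dx = xs - cx
        dy = ys - cy
        radii = np.hypot(dx, dy)
        r_mean = float(radii.mean())
        if r_mean < 2.0:
            continue
        r_in = float(np.percentile(radii, 2))
        r_out = float(np.percentile(radii, 98))
        n_bins = config.angular_bins or int(np.clip(2 * np.pi * r_mean / 2.0, 36, 720))
        angles = np.arctan2(dy, dx)
        bins = ((angles + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        occupied = np.zeros(n_bins, dtype=bool)
        occupied[bins] = True

        bin_width = 2 * np.pi / n_bins
        for run_start, run_len in _angular_runs(occupied):
            arc_px = run_len * bin_width * r_mean
            if arc_px < config.min_gap_px:
                continue
            if run_len >= n_bins:  # no shell at all on this slice
                continue
            # reconstruct the missing arc at the shell's radial extent
            theta0 = run_start * bin_width - np.pi
            thetas = theta0 + bin_width * (np.arange(run_len * 4 + 1) / 4.0)
            rr = np.linspace(r_in, r_out, 5)
            px = cx + np.outer(np.cos(thetas), rr)
            py = cy + np.outer(np.sin(thetas), rr)
            x0 = int(np.clip(np.floor(px.min()), 0, volume.shape[1] - 1))
            x1 = int(np.clip(np.ceil(px.max()) + 1, x0 + 1, volume.shape[1]))
            y0 = int(np.clip(np.floor(py.min()), 0, volume.shape[0] - 1))
            y1 = int(np.clip(np.ceil(py.max()) + 1, y0 + 1, volume.shape[0]))
            score = float(np.clip(arc_px / (np.pi * r_mean), 0.0, 1.0))
            results.append(
                BoxRecord(
                    x_start=x0,
                    y_start=y0,
                    x_extent=x1 - x0,
                    y_extent=y1 - y0,
                    slice_index=volume.meta[k].slice_index,
                    score=score,
                )
            )
    logger.info("detect_rule: %d detections over %d slices", len(results), volume.shape[2])
    return results
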