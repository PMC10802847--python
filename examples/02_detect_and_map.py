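"""Detect cortical gaps per slice and lift the boxes into a 3D red mask.

Runs the deterministic rule detector on a fractured phantom, converts
each 2D detection into a millimetre cuboid via the DICOM geometry, stacks
the cuboids into connected fracture components, and writes a glTF scene
of the bone with the semi-transparent red mask plus a PNG snapshot.
"""

from pathlib import Path

from fracture3d import (
    FractureSpec,
    PhantomSpec,
    box_to_cuboid,
    cap_mesh,
    extract_surface,
    generate,
    overlay,
    stack_mask,
    threshold_bone,
)
from fracture3d.detector import detect_rule

result = generate(
    PhantomSpec(
        rows=128, cols=128, n_slices=16, radius_outer=36, radius_inner=26,
        fractures=(FractureSpec(5, 10, angle_center=0.7, angle_width=1.0),),
    )
)
volume = result.volume

detections = detect_rule(volume)
print(f"detections: {len(detections)} (one per fractured slice)")
for d in detections[:2]:
    print(f"  slice {d.slice_index}: box ({d.x_start}, {d.y_start}, "
          f"{d.x_extent}, {d.y_extent}), score {d.score:.2f}")

meta = volume.meta[0]
cuboids = [box_to_cuboid(d, meta) for d in detections]
mask3d = stack_mask(cuboids, merge_gap=1, source_id=volume.series_id)
print(f"fracture components after stacking: {mask3d.n_components}")

bone = threshold_bone(volume)
mesh = cap_mesh(extract_surface(bone, volume.spacing), bone, volume.spacing[2])
out = Path("scratch_example_scene")
out.mkdir(exist_ok=True)
overlay(mesh, mask3d, out / "scene.gltf", snapshot=out / "snapshot.png")
print(f"scene written to {out}/scene.gltf, snapshot to {out}/snapshot.png")
# One component means the per-slice boxes fused into a single 3D fracture
# region; its cuboids span exactly the fractured slice range.
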