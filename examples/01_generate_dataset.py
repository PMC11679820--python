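"""Generate a labeled synthetic pose dataset and inspect its structure.

Builds clips for the seven posture classes (falling, lie, lie_down,
sit_down, sleeping, standing, stand_up), each a sequence of 33-landmark
pose frames with observation noise and occasional occlusions, and writes
them in the flat keypoint-table CSV layout.
"""

from posefall import GeneratorConfig, generate_dataset, standard_frame_count, write_keypoint_table

cfg = GeneratorConfig(clips_per_class=5, seed=42)
ds = generate_dataset(cfg)

print(f"clips: {len(ds)}  ({cfg.clips_per_class} per class x 7 classes)")
lengths = sorted({len(c) for c in ds.clips})
print(f"clip lengths range {lengths[0]}..{lengths[-1]} frames (falls are shortest)")
print(f"standard frame count (dataset minimum): {standard_frame_count(ds)}")

write_keypoint_table(ds, "scratch_dataset.csv", dialect="csv")
print("wrote scratch_dataset.csv in the 33-landmark keypoint-table layout")
# Each row is one frame: clip index, frame number, 33 x (x, y, z) landmark
# coordinates in image-normalized units (y grows downward), and the label.
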