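"""Import pose-estimation output: DeepLabCut CSV -> confidence filter ->
fixed windows -> dataset directory.

Writes a miniature DeepLabCut-style CSV (three header rows with x, y,
likelihood per bodypart), drops low-confidence frames, cuts the recording
into 10-frame clips and saves the resulting dataset.  With real data,
point ``read_keypoint_csv`` at the CSV your pose-estimation run produced.
"""

import tempfile
from pathlib import Path

import numpy as np

import ethoclust as ec

tmp = Path(tempfile.mkdtemp())
csv = tmp / "session1.csv"

rng = np.random.default_rng(0)
bodyparts = ["snout", "forelimb", "tail"]
lines = [
    "scorer," + ",".join(["net"] * 9),
    "bodyparts," + ",".join(bp for bp in bodyparts for _ in range(3)),
    "coords," + ",".join(["x", "y", "likelihood"] * 3),
]
for r in range(45):
    vals = []
    for _ in bodyparts:
        # a likelihood dip around frames 30-34 simulates occlusion
        lik = 0.55 if 30 <= r < 35 else 0.98
        vals += [f"{rng.uniform(0, 100):.2f}", f"{rng.uniform(0, 100):.2f}", str(lik)]
    lines.append(f"{r}," + ",".join(vals))
csv.write_text("\n".join(lines) + "\n")

table = ec.read_keypoint_csv(csv, dialect="deeplabcut")
print(f"parsed {table.n_frames} frames x {len(table.keypoint_names)} keypoints")

coords, frame_ok = ec.filter_by_confidence(table, threshold=0.9)
print(f"{int(frame_ok.sum())}/{len(frame_ok)} frames pass the 0.9 "
      "confidence threshold")

segments = ec.fixed_window_segment(coords, window=10, stride=10,
                                   pass_mask=frame_ok, source_video="session1")
for s in segments:
    print(f"  {s.segment_id}: frames [{s.start_frame}, {s.end_frame}], "
          f"confidence_ok={s.confidence_ok}")

dataset = ec.SegmentDataset(segments, ["walk", "rest", "groom"], "train")
ec.save_dataset(dataset, tmp / "dataset" / "train")
back = ec.load_dataset(tmp / "dataset" / "train")
print(f"round-trip: {len(back)} segments, bit-exact "
      f"{all(np.array_equal(a.frames, b.frames) for a, b in zip(back.segments, dataset.segments))}")
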