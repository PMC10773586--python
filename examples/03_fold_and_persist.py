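"""Fold a 2-s EEG window into point clouds and compare their barcodes.

Each fold doubles the number of points (19 -> 38 -> 76 -> 152 for a
19-channel window) while halving their dimension; more points expose more
topological structure, especially 1-dimensional loops.
"""

from topoeeg import (
    FiltrationConfig,
    PreprocessConfig,
    SynthesisConfig,
    cut_segments,
    fold_segment,
    generate_recording,
    preprocess_recording,
    vr_persistence,
)

syn = SynthesisConfig(duration=60.0, seizure_intervals=[(20.0, 30.0)], seed=1)
pp = PreprocessConfig(interictal_buffer_s=5.0, seed=1)
rec = preprocess_recording(generate_recording(syn), pp)
segment = cut_segments(rec, pp)[0]
print(f"segment: {segment.n_channels} x {segment.window_samples} samples, "
      f"label = {segment.label}")

for n_folds in range(3):
    cloud = fold_segment(segment, n_folds)
    barcode = vr_persistence(cloud, FiltrationConfig(n_folds=n_folds))
    n_loops = len(barcode.by_dim(1))
    print(f"folds = {n_folds}: {cloud.n_points:>3} points of dim "
          f"{cloud.dimension:>3}  ->  {len(barcode.by_dim(0))} component bars, "
          f"{n_loops} loop bars")
# point count x dimension is conserved (19 x 512 = 9728 samples) and the
# number of loop bars grows with the fold count.
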