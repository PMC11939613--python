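"""Render a synthetic image stack and extract per-cell ROI traces.

One well of 10 cells is rendered as disks on a dark background whose
per-frame intensity follows each cell's ground-truth trace; circular-ROI
mean extraction then reproduces those traces, and a seeded random sample
of cells mimics the manual pick-10-cells-per-well analysis step.
"""

import numpy as np

from cawave import roi, synth

stack = synth.generate_image_stack(
    synth.CohortGenParams(n_wells=1, cells_per_well=10, p_peaking=0.7, seed=5),
    synth.StackGeometry(frame_shape=(128, 128), pixel_noise_sd=1.0),
)
print(f"stack: {stack.frames.shape[0]} frames of {stack.frames.shape[1:]} pixels, "
      f"{len(stack.roi_truth)} cells")

picked = roi.sample_cells(stack.roi_truth, k=5, seed=2, frame_shape=stack.frames.shape[1:])
for r in picked:
    truth = next(t for t in stack.per_cell_truth if t.cell_id == r.roi_id)
    got = roi.extract_roi_trace(stack.frames, r, fps=truth.fps)
    err = float(np.max(np.abs(got.values - truth.values)))
    print(f"  {r.roi_id}: radius {r.radius:.1f} px, max |extracted - truth| = {err:.3f} a.u.")
print("Extraction error stays near pixel_noise_sd / sqrt(ROI area): the ROI")
print("mean is an unbiased, noise-averaging readout of the rendered cell.")
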