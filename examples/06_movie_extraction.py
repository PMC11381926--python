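"""End-to-end pixel pipeline: movie rendering, donut extraction, PV match.

Renders traces into a synthetic widefield movie with a drifting smooth
background, recovers them via ROI-minus-donut extraction, preprocesses to
dF/F, and matches PV labels between two channels by mask overlap.
"""

import numpy as np

from usprf import (
    MovieLayout, ROISet, SessionConfig, extract_trace, generate_movie,
    generate_session, match_pv, preprocess,
)

cfg = SessionConfig(protocol="single_prf", prf_set=(40.0,), pre_s=10.0,
                    post_s=10.0, n_trials_or_blocks=3, n_neurons=4, seed=2)
traces, trials, _ = generate_session(cfg)

layout = MovieLayout(height=128, width=128, radius_px=4,
                     background_amp=20.0, pixel_noise_sd=0.05, seed=2)
movie, rois = generate_movie(traces, layout)
print(f"movie: {movie.shape[0]} frames of {movie.shape[1]}x{movie.shape[2]} px, "
      f"{rois.n_rois} ROIs")

raw = extract_trace(movie, rois)
for k in range(raw.n_neurons):
    r = np.corrcoef(raw.values[k], traces.values[k])[0, 1]
    print(f"  neuron {k}: extracted-vs-true Pearson r = {r:.4f}")

dff = preprocess(raw, trials)
fs = int(trials.fs)
pre_means = [abs(dff.values[:, int(o * fs) - 10 * fs : int(o * fs)].mean())
             for o in trials.us_onsets]
print(f"max |pre-US baseline mean| after dF/F referencing: {max(pre_means):.2e}")

# a tdTomato channel marking neurons 0 and 2 as PV
tdt = np.where(np.isin(rois.label_mask, [1, 3]), rois.label_mask, 0)
pv = match_pv(rois, ROISet(label_mask=tdt))
print(f"PV labels from channel overlap: {pv.tolist()}")
print("# donut subtraction removes the shared background drift, so the")
print("# extracted traces correlate with the planted ones at r ~ 1")
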