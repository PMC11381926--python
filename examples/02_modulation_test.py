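"""Shuffled-baseline modulation test on an alternating-PRF session.

Simulates a session in which distinct neuron subsets prefer 10, 40 or
140 Hz pulse repetition frequency (PRF), runs the full detection +
shuffle pipeline, and prints per-PRF responder proportions and the
specific / non-specific classification against ground truth.
"""

import numpy as np

from usprf import SessionConfig, analyze_session, generate_session, proportion_report

cfg = SessionConfig(n_neurons=40, frac_modulated=0.2, p_evoked=0.6, seed=3)
traces, trials, truth = generate_session(cfg)
res = analyze_session(traces, trials, seed=3)

print(proportion_report(res.modulation).to_string(index=False))
print("\nresponder classes:")
print(res.responders["class"].value_counts().to_string())

# agreement with ground truth preference
hits = []
classes = res.responders.set_index("neuron")
for nid in res.kept:
    pref = truth.preferred_prf[nid]
    if np.isfinite(pref):
        row = classes.loc[nid]
        hits.append(row["class"] == "specific" and row["prfs_modulated"] == [pref])
print(f"\n{np.mean(hits):.0%} of truly PRF-preferring neurons recovered as "
      f"'specific' at their preferred PRF (n={len(hits)})")
print("# each percentage is n_modulated / n_total for that PRF; the generator")
print("# plants 20% preferring neurons per PRF, the excess is the ~5% false-")
print("# positive rate of the 95th-percentile shuffle test")
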