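"""Transient network synchrony around the stimulation window.

Computes the pairwise asymmetric correlation coefficient (ACC) of
binarised event trains in 1 s bins aligned to trial onset, grouped by
whether the pair contains US-modulated neurons.  The co-activation rises
sharply in the US bin for Mod:Mod and Mod:Non pairs and stays flat for
Non:Non pairs.
"""

from usprf import SessionConfig, analyze_session, generate_session, transient_acc
from usprf.synchrony import baseline_bins_mean

cfg = SessionConfig(
    protocol="single_prf", prf_set=(140.0,), n_trials_or_blocks=20,
    post_s=39.0, n_neurons=30, frac_modulated=0.3, p_evoked=0.5, seed=5,
)
traces, trials, _ = generate_session(cfg)
res = analyze_session(traces, trials, seed=5)
course = transient_acc(res.masks(), trials, res.modulated_flags(140.0))

bl = baseline_bins_mean(course)
us = course[course["bin"] == 10].set_index("group")["value"]
post = course[course["bin"] == 12].set_index("group")["value"]
print(f"{'pair group':>10} {'BL (0-8 s)':>12} {'US bin':>8} {'+2 s bin':>9}")
for g in ("Mod:Mod", "Mod:Non", "Non:Non", "All"):
    print(f"{g:>10} {bl[g]:12.3f} {us[g]:8.3f} {post[g]:9.3f}")
print("# BL = mean ACC over the first 8 s of the trial; the US-bin increase")
print("# is confined to pairs containing a modulated neuron and returns to")
print("# baseline within ~1 s of US offset")
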