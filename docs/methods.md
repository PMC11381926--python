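# Methods

This note documents the models and numerical choices behind `usprf`: what
the synthetic generator emulates, how each analysis stage is defined, the
parameters that matter, and the known limitations.

## Synthetic sessions

`generate_session` emulates widefield GCaMP7f recordings of mouse motor
cortex during transcranial ultrasound (US) stimulation, under two trial
protocols: *single-PRF* (long trials, default 10 s pre / 1 s US / 39 s
recovery, one pulse repetition frequency throughout) and *alternating*
(blocks of short 10/1/10 s trials in which 10, 40 and 140 Hz each occur
once per block in random order). Trials are separated by 0.5 s pauses; the
generator produces a continuous trace across them, which is what the
preprocessing of real recordings reconstructs by interpolation.

Per neuron the model is:

- **Baseline events.** A homogeneous Poisson process at `baseline_rate`
  (default 3.10 events/min, the event rate typical of GCaMP7f recordings
  in this preparation). Inter-event intervals are exactly exponential;
  the generator does not enforce separation between events (see
  *Limitations*).
- **Event waveform.** Linear rise over a duration drawn from
  Normal(`rise_mean_s` = 1.11 s, `rise_sd_s` = 0.67 s) truncated (by
  resampling) above 0.15 s, followed by exponential decay with
  `decay_tau_s` = 0.7 s — GCaMP7f-like kinetics; the truncation raises the
  realised mean rise to ≈ 1.20 s. Peak amplitudes are
  Normal(1.0, 0.2) ΔF/F truncated above 5× the noise SD, so events are
  well separated from noise, as in curated recordings.
- **Evoked events.** A disjoint `frac_modulated` of neurons per PRF is
  assigned that PRF as preferred; on each of its trials the neuron fires
  an extra event with probability `p_evoked`, with rise start uniform in
  `evoked_latency_s` = (0, 0.3) s after onset — fast enough that the
  rising phase covers most of the 1 s US window.
- **Noise.** Additive white Gaussian, `noise_sd` = 0.05 ΔF/F.

`generate_sham_session` keeps the trial structure and sets the evoked
component to zero (the acoustic-coupling-omitted control). PV labels are
Bernoulli(`frac_pv` = 0.12), matching the observed PV fraction in
dual-channel recordings. Identical seeds give bit-identical sessions.

What the generator does **not** emulate: motion artefacts, neuropil
contamination beyond a spatially smooth background (movies only), photon
shot noise, bleaching curvature beyond a linear trend, correlated
baseline activity between neurons, trial-to-trial drift of evoked
amplitude, or any dependence of event kinetics on the evoking PRF.
Passing recovery tests therefore demonstrates correctness of the
statistics under the assumed model, not robustness to every pathology of
real recordings.

`generate_movie` renders traces into circular ROIs on a constant
baseline plus an optional spatially smooth drifting background and white
pixel noise, with matching label masks — enough structure to make donut
subtraction non-trivial while keeping the round trip exactly checkable.

`generate_umi_matrix` plants per-gene, per-population expression as
Bernoulli(nonzero fraction) × zero-truncated negative binomial
(mean/dispersion per population), so the planted fraction-expressing is
exact in expectation and the planted Cliff's δ between expressing cells
has a closed form (`planted_cliffs_delta`, computed from the truncated
pmfs) that recovery tests use as an independent oracle. Background genes
shared across populations guarantee positive library sizes.

## Trace extraction and ΔF/F

Raw traces are mean ROI pixel intensity minus the mean of a surrounding
donut (annulus 15–50 px from the ROI centroid, excluding pixels of *any*
ROI). The ΔF/F pipeline is fixed-order: shape-preserving piecewise-cubic
(PCHIP) interpolation onto a uniform 20 Hz grid spanning inter-trial
gaps; linear detrend; min–max normalisation to [0, 1]; per-trial
subtraction of the 10 s pre-US mean. After the last step every trial's
baseline is exactly zero and values lie in [−1, 1]. Constant traces
cannot be normalised and are dropped; dropped neurons are absent from all
downstream tables rather than carried as NaN rows. The "ΔF/F" label for
the min-max-then-baseline pipeline is unconventional but is the package's
operational definition.

PV matching: a GCaMP ROI is PV-positive iff strictly more than 50% of its
pixels are covered by tdTomato ROIs after warping the tdT mask by the
supplied (landmark-derived) homogeneous transform; the denominator is the
GCaMP ROI area, ties at exactly 50% are non-PV.

## Event detection

The detector finds sharp fluorescence rises using their spectral
signature, then measures each event's timing on a lightly smoothed copy
of the trace. Stages, with defaults in `DetectionParams`:

1. **Smoothing.** Detection trace `s1` = 1 s moving mean; measurement
   trace `s_meas` = 0.25 s moving mean. The raw-trace noise SD σ is
   estimated robustly from first differences (median/0.6745/√2).
2. **Spectral gate.** Sliding multitaper spectrum of `s1` (1 s window,
   step 1 sample, NW = 2, K = 3 Slepian tapers, zero-padded FFT). Band
   power in 0.2–2 Hz is normalised per frequency by that frequency's
   median over the recording (events are sparse, so the median tracks the
   noise floor) and averaged over the band; timepoints above the median
   of this score pass the gate. Normalising by *total* power instead was
   tested and rejected: within a 1 s window a ~1 s transient is nearly a
   ramp whose energy sits below the band, so that ratio is lower at event
   peaks than in smoothed noise and inverts the gate.
3. **Candidates.** Local maxima of `s_meas` with prominence ≥ 3 σ_meas
   (σ_meas = σ/√5) that pass the gate, nudged to the raw-trace maximum
   within ±2 samples so fast rises are not smeared late.
4. **Rise start.** Walking backwards from the peak on `s_meas`, track the
   running minimum and stop once the trace climbs 4 σ_meas above it (the
   decay of an earlier event); the search never crosses the preceding
   candidate peak. The onset is the latest raw sample within 3 σ of the
   raw minimum of that stretch. A literal global argmin over the 3 s
   lookback would land wherever baseline noise happens to dip — or on an
   earlier event's baseline — and destroys both rise-time recovery and
   event counts; the locality rule keeps the printed definition's intent
   (pre-peak minimum) while being noise-aware. Measured biases on the
   default generator: −0.02 s for 0.5 s rises, ≈ −0.1 s for long rises
   (session-level mean detected rise ≈ 1.10 s).
5. **Criteria.** Keep candidates with rise time > 0.1 s and amplitude
   > 2.5× the pre-event SD. Amplitude is `s_meas[peak]` minus a baseline
   reference: the larger of the rise-start value and the median of the
   clean pre-event window (this stops noise dips at the rise start from
   inflating noise amplitudes). The pre-event SD is the raw-trace SD over
   the 2 s before onset, excluding samples inside any other event (its
   rise plus a 3 s decay window); if under 0.5 s of clean data remains it
   falls back to — and is always floored at — the whole-trace robust
   (MAD) SD, because a short window badly underestimates noise.
6. **Merging.** Overlapping rise intervals are merged keeping the higher
   peak; the rising-phase mask is 1 on [rise start, peak], inclusive.

Neurons with no event anywhere are flagged and removed from further
analysis. Detections are invariant to positive rescaling of the trace
(every criterion is relative to an estimated SD). On pure white noise the
detector produces no events in 60 × 1000 s of simulation; on the default
generator it detects every *distinguishable* transient (miss rate ≈ the
6% probability that an event starts inside the previous event's rise,
with zero false positives).

## Modulation testing

Event density is the mean of the rising-phase mask over a window. The
null for each neuron is built once per session: each of 1000 iterations
draws *k* grid-aligned 1 s windows (with replacement; a flag switches to
without-replacement) wholly inside the baseline mask — the recording
minus [onset, onset + 5 s) for *every* onset — and records their mean
density; *k* defaults to the number of trials per PRF condition (20 in
the single-PRF protocol, 25 in the alternating one). A neuron is
modulated by a PRF iff its observed mean US-window density exceeds the
null's empirical 95th percentile and its 1 s pre-US density does not
(pre-US exclusion, which removes events already rising at onset). The
same null is reused across PRFs within a session. Shuffle seeds are
session seed + neuron index, so flags are reproducible. No correction for
multiple comparisons across neurons is applied — deliberately, to match
the analysis convention this pipeline reproduces; at the 95th percentile
the sham/null flag rate is ≈ 3–5%.

Responder classes: *specific* (exactly one PRF modulated), *non-specific*
(two or more), *non-responder*. Percentages in reports are rounded
half-away-from-zero to two decimals.

## Network synchrony

ACC(A,B) = ½(|A∧B|/|A| + |A∧B|/|B|) on binary rising-phase trains; pairs
(or bins) where either train has no events leave a denominator undefined
and are excluded rather than scored zero, which would bias group means
downward. Sustained ACC uses the full recording. Transient ACC uses 1 s
bins anchored at trial start; by default a bin's samples are concatenated
across trials before the ratio. The per-trial-then-average alternative is
available (`per_trial=True`) but noisy by construction — a single-trial
bin holds at most 20 samples, so the either-empty exclusion conditions on
both neurons being active in the same second and largely erases the
Mod:Non contrast; pooling across trials preserves it. The baseline value
"BL" is the mean over the trial's first eight 1 s bins; bins are compared
across sessions with Friedman + Nemenyi (critical difference
q_α/√2 · √(k(k+1)/6n), studentized-range quantile at infinite df).

On the default modulated generator the US-bin transient ACC rises
severalfold above BL for Mod:Mod and Mod:Non pairs, is unchanged for
Non:Non pairs, and is flat on sham sessions. Because generated rising
phases last ~1.1 s, elevated co-activation spills into the first
post-offset second; from 2 s after onset the time-course is back at
baseline. (Property tests for "no change" therefore examine bins from
2 s onward.)

## Evoked-response profiles

Profiles are computed on trial-averaged traces aligned to onset: peak =
maximum in (0, 5] s (a later global post-onset maximum invalidates the
neuron for profile statistics); amplitude = peak minus the minimum
between onset and peak; FWHM = total (possibly non-contiguous) time above
the pre-peak minimum plus half the amplitude, measured on the
piecewise-linear trace with interpolated crossings; AUC = trapezoidal
integral over [0, 5] s. Referencing the half-max to the pre-peak minimum
keeps FWHM consistent with the amplitude definition. Population latency
is the first post-onset time the population-average trace exceeds its
10 s-baseline mean by two baseline SDs.

The GLM `Y ~ 1 + PRF + CellType + PRF×CellType` uses a Gaussian family
with identity link (configurable); the deviance test against the
intercept-only model is the exact F-test for the Gaussian family and a
χ² likelihood-ratio test otherwise. By the reporting convention adopted
here, coefficients are *analysed* only when the omnibus deviance test is
significant (the table is always returned, with a flag).

## Inferential layer

Fisher's exact (two-sided, hypergeometric; p = 1 with a warning for
zero-margin tables), Wilcoxon rank-sum/signed-rank and Kruskal–Wallis
with tie-corrected normal approximations, Dunn's pairwise z-tests with
Šidák adjustment after a significant omnibus, and Friedman + Nemenyi as
above. α = 0.05 throughout. Post-hoc tables are attached only when the
omnibus test is significant.

## Expression statistics

Normalisation is log2(count / cell total × 100 000 + 1). Cliff's δ is
computed in O((n+m) log m) by sorting and rank-searching; property tests
verify exact agreement with the O(nm) pairwise count. By default δ and
the accompanying rank-sum test use expressing (nonzero) cells only —
matching the convention that distribution overlap is assessed among
cells with detectable expression — with a flag to include zeros. The
report also carries (δ+1)/2 as the exceedance probability P(X > Y)
interpretation.

## Acoustic intensity

I_SPPA = p²/(2Z), converted to W/cm²; I_SPTA = I_SPPA × duty cycle. With
p = 522 kPa and water impedance Z = 1.5 × 10⁶ Rayl the closed form gives
9.08 W/cm²; published figures sometimes print 9.11 for the same inputs,
which would require an unrounded pressure or slightly different Z — the
utility implements the closed form and does not adjust constants.

## Problem sizes and determinism

Recovery tests use 12 sessions × 20 neurons and the acceptance script
12 sessions × 40 neurons (single-PRF, ~17 min each) for rate and
rise-duration recovery, ≥ 2000
null neurons for the type-I audit, 12 + 12 sessions × 30 neurons for the
synchrony pattern, and 10 sessions × 50 neurons for specificity recovery
— sizes at which the Monte-Carlo standard errors are several times
smaller than the tolerances being checked. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give identical outputs.

## Known limitations

- **Overlapping events.** Because baseline events are exactly Poisson,
  ~6% start inside the previous event's rise and render as one transient;
  the detected event rate is therefore ≈ rate × exp(−λ·E[rise]) ≈ 2.92
  events/min for a planted 3.10 — an inherent property of the generative
  model, not a detector deficiency (the misses are monotone compound
  rises that no peak-based detector can split).
- The detector's spectral parameters (window, tapers, band) are declared
  defaults validated by recovery, not a claimed bit-for-bit match to any
  particular spectral toolbox configuration.
- Manual quality control of real recordings is replaced by the
  deterministic zero-event removal rule.
- The expression module covers two-population comparisons per gene;
  multi-way designs and clustering/visualisation are out of scope.
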