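"""Calcium event detection from dF/F traces.

Events are detected from the spectral profile of their sharp fluorescence
rise: the trace is smoothed with a 1 s sliding mean, a sliding multitaper
spectrum is computed, and candidate peaks are local trace maxima whose
normalised low-frequency band power exceeds the median over the
recording.  Candidates are kept when the rise lasts more than 100 ms and
the amplitude exceeds 2.5x the pre-event standard deviation.
The rising phase (rise start to peak) of each event is binarised into a
20 Hz mask used by all downstream density and synchrony statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.signal.windows import dpss

from .session import TrialStructure

__all__ = [
    "DetectionParams",
    "CalciumEvent",
    "EventTrain",
    "detect_events",
    "event_rate",
    "event_density",
    "non_us_windows",
]


@dataclass
class DetectionParams:
    """Tunable detector parameters.

    The spectral stage uses a sliding multitaper estimate (window
    ``spec_window_s``, time-bandwidth ``nw``, ``k_tapers`` Slepian tapers)
    and gates candidates on the band power in ``band`` Hz, normalised per
    frequency by its median over the recording and thresholded at the
    median of the resulting score.  Rise
    timing is refined on a lightly smoothed copy of the trace
    (``meas_smooth_s``); the rise start is the nearest preceding minimum
    within ``lookback_s`` of the peak, tie-broken to the latest sample
    within ``onset_tol_sd`` noise SDs of that minimum.
    """

    fs: float = 20.0
    smooth_s: float = 1.0
    meas_smooth_s: float = 0.25
    spec_window_s: float = 1.0
    nw: float = 2.0
    k_tapers: int = 3
    band: tuple = (0.2, 2.0)
    rise_min_s: float = 0.1
    amp_factor: float = 2.5
    lookback_s: float = 3.0
    pre_sd_window_s: float = 2.0
    min_clean_pre_s: float = 0.5
    event_exclusion_post_s: float = 3.0  # decay window excluded from "clean" baseline
    onset_tol_sd: float = 3.0
    stop_sd: float = 4.0
    peak_prominence_sd: float = 3.0  # find_peaks floor, in measurement-trace noise SDs


@dataclass(frozen=True)
class CalciumEvent:
    """One detected calcium event.

    ``rise_start_s``/``peak_s`` bound the rising phase; ``amplitude`` is
    the peak-minus-rise-start fluorescence difference on the detection
    trace and ``pre_event_sd`` the raw-trace SD of the pre-event window
    the amplitude criterion was evaluated against.
    """

    rise_start_s: float
    peak_s: float
    amplitude: float
    pre_event_sd: float

    @property
    def rise_time_s(self) -> float:
        return self.peak_s - self.rise_start_s


@dataclass
class EventTrain:
    """Detected events plus the binary rising-phase mask at the trace rate."""

    events: list
    rising_mask: np.ndarray
    fs: float = 20.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def empty(self) -> bool:
        """True when no event was found; such neurons are removed from
        further analysis."""
        return not self.events

    def peak_times(self) -> np.ndarray:
        return np.asarray([e.peak_s for e in self.events])

    def rise_times(self) -> np.ndarray:
        return np.asarray([e.rise_time_s for e in self.events])


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from first differences, insensitive to sparse transients."""
    d = np.abs(np.diff(x))
    return float(np.median(d) / (0.6745 * np.sqrt(2.0))) or 1e-12


def _band_power_score(smoothed: np.ndarray, p: DetectionParams) -> np.ndarray:
    """Sliding multitaper normalised band power per timepoint.

    The multitaper power at each frequency is normalised by that
    frequency's median over the recording (events are sparse, so the
    median tracks the noise floor), then averaged over the analysis band.
    Timepoints inside calcium transients score far above the median of
    this series, which is the candidate gate.
    """
    win = int(round(p.spec_window_s * p.fs))
    n = smoothed.size
    if n < win:
        raise ValueError("trace shorter than the spectrogram window")
    tapers = dpss(win, p.nw, Kmax=p.k_tapers)
    nfft = 1
    while nfft < 4 * win:
        nfft *= 2
    segs = np.lib.stride_tricks.sliding_window_view(smoothed, win)
    segs = segs - segs.mean(axis=1, keepdims=True)
    psd = np.zeros((segs.shape[0], nfft // 2 + 1))
    for tap in tapers:
        psd += np.abs(np.fft.rfft(segs * tap, n=nfft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / p.fs)
    in_band = (freqs >= p.band[0]) & (freqs <= p.band[1])
    band = psd[:, in_band]
    floor = np.median(band, axis=0)
    floor[floor <= 0] = np.inf
    score_valid = (band / floor).mean(axis=1)
    # window centers; replicate to the trace edges
    score = np.empty(n)
    lo = (win - 1) // 2
    score[lo : lo + score_valid.size] = score_valid
    score[:lo] = score_valid[0]
    score[lo + score_valid.size :] = score_valid[-1]
    return score


def _find_onset(
    x: np.ndarray,
    s_meas: np.ndarray,
    peak: int,
    sigma_meas: float,
    sigma_raw: float,
    p: DetectionParams,
    lo_bound: int = 0,
) -> int:
    """Rise start: nearest preceding minimum within the lookback window.

    Walk backwards from the peak on the smoothed trace tracking the
    running minimum; stop once the trace climbs ``stop_sd`` noise SDs
    above it (the decay of an earlier event).  The onset is then the
    latest raw sample at most ``onset_tol_sd`` raw SDs above the raw
    minimum of that stretch — the raw trace is used here because
    smoothing smears the rise onset earlier, and flat pre-event baseline
    must not drag the onset arbitrarily early.  ``lo_bound`` caps the
    search: a rise cannot start before the preceding candidate peak.
    """
    lo = max(lo_bound, peak - int(round(p.lookback_s * p.fs)))
    m = s_meas[peak - 1] if peak > 0 else s_meas[peak]
    im = max(peak - 1, 0)
    j = peak - 2
    while j >= lo:
        v = s_meas[j]
        if v < m:
            m, im = v, j
        elif v > m + p.stop_sd * sigma_meas:
            break
        j -= 1
    m_raw = float(np.min(x[im : peak + 1]))
    thr = m_raw + p.onset_tol_sd * sigma_raw
    onset = im
    for k in range(peak - 1, im - 1, -1):
        if x[k] <= thr:
            onset = k
            break
    return onset


def detect_events(dff: np.ndarray, params: DetectionParams | None = None) -> EventTrain:
    """Detect calcium events in a uniform 20 Hz dF/F trace.

    Returns an :class:`EventTrain`; ``train.empty`` flags neurons with no
    event anywhere in the recording (removed from further analysis by the
    pipeline).  Raises ``ValueError`` for traces shorter than the
    spectrogram window or under 10 s.
    """
    p = params or DetectionParams()
    x = np.asarray(dff, dtype=float).ravel()
    if x.size < 10 * p.fs:
        raise ValueError("trace must cover at least 10 s")
    fs = p.fs
    s1 = uniform_filter1d(x, max(1, int(round(p.smooth_s * fs))), mode="nearest")
    s_meas = uniform_filter1d(x, max(1, int(round(p.meas_smooth_s * fs))), mode="nearest")
    sigma_raw = _robust_noise_sd(x)
    sigma_meas = sigma_raw / np.sqrt(max(1, int(round(p.meas_smooth_s * fs))))

    score = _band_power_score(s1, p)
    gate = score > np.median(score)
    # candidate peaks on the lightly smoothed trace (resolves events closer
    # than the 1 s detection smoothing); a small prominence floor prunes
    # bare noise ripples cheaply before the amplitude criterion runs
    peaks, _ = find_peaks(s_meas, prominence=p.peak_prominence_sd * sigma_meas)
    peaks = peaks[gate[peaks]]
    if peaks.size == 0:
        return EventTrain(events=[], rising_mask=np.zeros(x.size, dtype=np.uint8), fs=fs)
    # nudge each peak onto the raw-trace maximum nearby: smoothing smears
    # fast rises late, which would inflate their measured rise times
    for k in range(peaks.size):
        a, b = max(0, peaks[k] - 2), min(x.size, peaks[k] + 3)
        peaks[k] = a + int(np.argmax(x[a:b]))
    peaks = np.unique(peaks)

    provisional = []
    prev_pk = 0
    for pk in peaks:
        if pk == 0:
            continue
        onset = _find_onset(
            x, s_meas, pk, sigma_meas, sigma_raw, p,
            lo_bound=prev_pk + 1 if prev_pk else 0,
        )
        provisional.append((onset, pk))
        prev_pk = pk

    # pre-event SD excludes samples inside any provisional event, i.e. its
    # rise interval plus the decay window after the peak
    in_event = np.zeros(x.size, dtype=bool)
    n_post = int(round(p.event_exclusion_post_s * fs))
    for onset, pk in provisional:
        in_event[onset : pk + 1 + n_post] = True
    n_pre = int(round(p.pre_sd_window_s * fs))
    min_clean = int(round(p.min_clean_pre_s * fs))
    trace_median = float(np.median(x))
    fallback_sd = 1.4826 * float(np.median(np.abs(x - trace_median)))

    accepted = []
    for onset, pk in provisional:
        rise_time = (pk - onset) / fs
        if rise_time <= p.rise_min_s:
            continue
        a = max(0, onset - n_pre)
        clean = x[a:onset][~in_event[a:onset]]
        if clean.size >= min_clean:
            # floored at the whole-trace robust SD: a short clean window
            # can badly underestimate the noise
            pre_sd = max(float(np.std(clean)), fallback_sd)
            # reference the amplitude to the pre-event baseline when the
            # rise-start sample sits in a noise dip below it
            ref = max(float(s_meas[onset]), float(np.median(clean)))
        else:
            pre_sd = fallback_sd
            ref = max(float(s_meas[onset]), trace_median)
        if pre_sd <= 0:
            pre_sd = fallback_sd or 1e-12
        amp = float(s_meas[pk]) - ref
        if amp > p.amp_factor * pre_sd:
            accepted.append((onset, pk, amp, pre_sd))

    # merge overlapping rise intervals, keeping the higher peak
    accepted.sort(key=lambda t: (t[0], t[1]))
    merged: list[tuple] = []
    for ev in accepted:
        if merged and ev[0] <= merged[-1][1]:
            if s_meas[ev[1]] > s_meas[merged[-1][1]]:
                merged[-1] = ev
        else:
            merged.append(ev)

    events = [
        CalciumEvent(
            rise_start_s=onset / fs, peak_s=pk / fs,
            amplitude=float(amp), pre_event_sd=pre_sd,
        )
        for onset, pk, amp, pre_sd in merged
    ]
    mask = np.zeros(x.size, dtype=np.uint8)
    for onset, pk, _, _ in merged:
        mask[onset : pk + 1] = 1  # rising phase inclusive of both endpoints
    return EventTrain(events=events, rising_mask=mask, fs=fs)


def event_rate(train: EventTrain, windows) -> float:
    """Events per minute: peaks falling in ``windows`` over total duration.

    ``windows`` is an iterable of half-open ``(start_s, end_s)`` intervals.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("window set must be non-empty")
    total = sum(e - s for s, e in windows)
    if total <= 0:
        raise ValueError("windows must have positive total duration")
    peaks = train.peak_times()
    count = sum(int(np.sum((peaks >= s) & (peaks < e))) for s, e in windows)
    return count / total * 60.0


def event_density(train: EventTrain, window) -> float:
    """Fraction of samples occupied by rising phases within ``window``."""
    s, e = window
    i0 = int(round(s * train.fs))
    i1 = int(round(e * train.fs))
    if i0 < 0 or i1 > train.rising_mask.size or i1 <= i0:
        raise ValueError("window outside recording")
    return float(train.rising_mask[i0:i1].mean())


def non_us_windows(trials: TrialStructure, post_exclusion_s: float = 5.0):
    """Non-US periods: the recording minus US seconds and the following
    ``post_exclusion_s`` seconds."""
    out = []
    t = 0.0
    for onset in trials.us_onsets:
        if onset > t:
            out.append((t, float(onset)))
        t = float(onset) + trials.us_s + post_exclusion_s
    if t < trials.session_duration_s:
        out.append((t, trials.session_duration_s))
    return out
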