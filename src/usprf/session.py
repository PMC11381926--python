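"""Trial-structure and session-configuration types.

A recording session is a sequence of trials, each containing a pre-stimulus
baseline, a 1 s ultrasound (US) stimulation period, and a recovery period,
separated by short inter-trial pauses.  Two protocols are supported:

``single_prf``
    Long trials (default 10 s pre / 1 s US / 39 s post) with the same pulse
    repetition frequency (PRF) on every trial.

``alternating``
    Short trials (10 s pre / 1 s US / 10 s post) organised in blocks; each
    block presents every PRF in the set once, in random order, so a session
    of ``n`` blocks yields ``n`` trials per PRF.

All times are in seconds, frames are 0-based, and windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


@dataclass(frozen=True)
class TrialStructure:
    """US onset times and per-trial PRF labels for one session.

    Parameters
    ----------
    us_onsets
        US onset times in seconds, strictly increasing.
    prf_per_trial
        PRF label (Hz) of each trial; same length as ``us_onsets``.
    us_s
        Duration of each US stimulation period (s).
    pre_s
        Pre-US baseline duration within each trial (s).
    post_s
        Post-US recovery duration within each trial (s).
    session_duration_s
        Total session duration (s).
    fs
        Sampling rate of the aligned fluorescence traces (samples/s).
    """

    us_onsets: np.ndarray
    prf_per_trial: np.ndarray
    us_s: float
    pre_s: float
    post_s: float
    session_duration_s: float
    fs: float = 20.0
    pause_s: float = 0.5

    def __post_init__(self) -> None:
        onsets = np.asarray(self.us_onsets, dtype=float)
        prfs = np.asarray(self.prf_per_trial, dtype=float)
        object.__setattr__(self, "us_onsets", onsets)
        object.__setattr__(self, "prf_per_trial", prfs)
        if onsets.ndim != 1 or prfs.shape != onsets.shape:
            raise ConfigurationError("prf_per_trial must match us_onsets")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ConfigurationError("US onsets must be strictly increasing")
        if onsets.size and onsets[-1] + self.us_s > self.session_duration_s:
            raise ConfigurationError("last US period exceeds session duration")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return int(self.us_onsets.size)

    @property
    def prf_set(self) -> np.ndarray:
        """Unique PRF labels present in the session, sorted."""
        return np.unique(self.prf_per_trial)

    @property
    def n_samples(self) -> int:
        return int(round(self.session_duration_s * self.fs))

    def onsets_for(self, prf: float) -> np.ndarray:
        """Onset times of the trials delivered at ``prf`` Hz."""
        sel = self.us_onsets[np.isclose(self.prf_per_trial, prf)]
        if sel.size == 0:
            raise ValueError(f"no trials with PRF {prf} Hz")
        return sel

    def trial_starts(self) -> np.ndarray:
        """Start time of each trial (onset minus the pre-US baseline)."""
        return self.us_onsets - self.pre_s


@dataclass
class SessionConfig:
    """Parameters of the synthetic session generator.

    The defaults emulate the study conditions of the imaging experiments:
    20 Hz GCaMP7f imaging, baseline calcium events at 3.10 events/min,
    rising phases of 1.11 +/- 0.67 s, and US-evoked events placed within
    0-0.3 s of the onsets of a neuron's preferred PRF.

    Parameters
    ----------
    protocol
        ``"single_prf"`` or ``"alternating"``.
    n_trials_or_blocks
        Number of trials (single PRF) or blocks (alternating).
    prf_set
        PRF labels in Hz; exactly one for ``single_prf``.
    pre_s, us_s, post_s, pause_s
        Trial segment durations in seconds.
    fs
        Imaging rate (samples/s).
    n_neurons
        Neurons per session.
    frac_modulated
        Fraction of neurons assigned to each PRF as their preferred PRF
        (non-overlapping across PRFs).
    p_evoked
        Per-trial probability that US at the preferred PRF elicits an event.
    baseline_rate
        Homogeneous baseline event rate (events/min).
    rise_mean_s, rise_sd_s
        Normal parameters of event rise durations, truncated above
        ``rise_min_s``.
    decay_tau_s
        Exponential decay time constant after the peak (s); GCaMP7f-like.
    amp_mean, amp_sd
        Event peak amplitude distribution (dF/F), truncated above
        ``5 * noise_sd`` so events are well separated from noise.
    noise_sd
        Additive white Gaussian noise SD (dF/F units).
    evoked_latency_s
        ``(lo, hi)`` window after US onset in which evoked events start.
    frac_pv
        Fraction of neurons labelled parvalbumin-positive.
    seed
        Generator seed; identical seeds give bit-identical sessions.
    """

    protocol: str = "alternating"
    n_trials_or_blocks: int = 25
    prf_set: tuple = (10.0, 40.0, 140.0)
    pre_s: float = 10.0
    us_s: float = 1.0
    post_s: float = 10.0
    pause_s: float = 0.5
    fs: float = 20.0
    n_neurons: int = 50
    frac_modulated: float = 0.13
    p_evoked: float = 0.5
    baseline_rate: float = 3.10
    rise_mean_s: float = 1.11
    rise_sd_s: float = 0.67
    rise_min_s: float = 0.15
    decay_tau_s: float = 0.7
    amp_mean: float = 1.0
    amp_sd: float = 0.2
    noise_sd: float = 0.05
    evoked_latency_s: tuple = (0.0, 0.3)
    frac_pv: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("single_prf", "alternating"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if not self.prf_set:
            raise ConfigurationError("prf_set must be non-empty")
        if self.protocol == "single_prf" and len(self.prf_set) != 1:
            raise ConfigurationError("single_prf protocol needs exactly one PRF")
        if self.protocol == "alternating" and len(self.prf_set) < 2:
            raise ConfigurationError("alternating protocol needs >= 2 PRFs")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if min(self.pre_s, self.us_s, self.post_s) <= 0 or self.pause_s < 0:
            raise ConfigurationError("trial segment durations must be positive")
        for name in ("frac_modulated", "p_evoked", "frac_pv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.frac_modulated * len(self.prf_set) > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_modulated * len(prf_set) may not exceed 1"
            )
        lo, hi = self.evoked_latency_s
        if lo < 0 or hi < lo:
            raise ConfigurationError("evoked_latency_s must satisfy 0 <= lo <= hi")

    @property
    def trial_period_s(self) -> float:
        """Trial duration including the inter-trial pause."""
        return self.pre_s + self.us_s + self.post_s + self.pause_s

    @property
    def n_trials(self) -> int:
        n = self.n_trials_or_blocks
        return n if self.protocol == "single_prf" else n * len(self.prf_set)

    @property
    def session_duration_s(self) -> float:
        return self.n_trials * self.trial_period_s


@dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests.

    Attributes
    ----------
    preferred_prf
        Preferred PRF (Hz) per neuron; NaN for non-modulated neurons.
    event_times
        Per neuron, array of true event rise-start times (s), sorted.
    rise_durations
        Per neuron, array of true rise durations (s), aligned with
        ``event_times``.
    evoked
        Per neuron, boolean array marking which events are US-evoked.
    modulated
        Mapping PRF -> boolean array over neurons (true preference flags).
    pv_label
        Boolean array, parvalbumin-positive per neuron.
    """

    preferred_prf: np.ndarray
    event_times: list = field(default_factory=list)
    rise_durations: list = field(default_factory=list)
    evoked: list = field(default_factory=list)
    modulated: dict = field(default_factory=dict)
    pv_label: np.ndarray | None = None
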