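"""Ground-truthed synthetic data generators.

Emulates the statistical structure the analysis assumes: 20 Hz GCaMP7f
dF/F traces with baseline calcium events as a homogeneous point process,
linear-ramp rises and exponential decays, US-evoked events in a
PRF-preferring subset of neurons under the single-PRF and alternating
trial protocols, sham sessions with no evoked component, pixel movies for
end-to-end extraction tests, and UMI count matrices with planted
between-population expression shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import ROISet, TraceMatrix
from .session import ConfigurationError, GroundTruth, SessionConfig, TrialStructure

__all__ = [
    "generate_session",
    "generate_sham_session",
    "generate_movie",
    "generate_umi_matrix",
    "MovieLayout",
    "LayoutError",
    "GeneSpec",
    "PopulationExpression",
    "truncated_nb_pmf",
    "planted_cliffs_delta",
]


# ---------------------------------------------------------------------------
# sessions


def _build_trial_structure(config: SessionConfig, rng: np.random.Generator) -> TrialStructure:
    period = config.trial_period_s
    n_trials = config.n_trials
    starts = np.arange(n_trials) * period
    onsets = starts + config.pre_s
    if config.protocol == "single_prf":
        prfs = np.full(n_trials, config.prf_set[0], dtype=float)
    else:
        prfs = np.concatenate([
            rng.permutation(np.asarray(config.prf_set, dtype=float))
            for _ in range(config.n_trials_or_blocks)
        ])
    return TrialStructure(
        us_onsets=onsets,
        prf_per_trial=prfs,
        us_s=config.us_s,
        pre_s=config.pre_s,
        post_s=config.post_s,
        session_duration_s=config.session_duration_s,
        fs=config.fs,
        pause_s=config.pause_s,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on being > lower, by resampling."""
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def _render_events(
    trace: np.ndarray,
    times: np.ndarray,
    rises: np.ndarray,
    amps: np.ndarray,
    decay_tau: float,
    fs: float,
) -> None:
    """Add linear-rise / exponential-decay transients in place."""
    n = trace.size
    for t0, r, a in zip(times, rises, amps):
        i0 = int(round(t0 * fs))
        n_rise = max(1, int(round(r * fs)))
        n_decay = int(round(6 * decay_tau * fs))
        kernel = np.concatenate([
            np.linspace(0.0, a, n_rise + 1)[1:],
            a * np.exp(-np.arange(1, n_decay + 1) / (decay_tau * fs)),
        ])
        hi = min(n, i0 + kernel.size)
        if hi <= i0:
            continue
        trace[i0:hi] += kernel[: hi - i0]


def generate_session(
    config: SessionConfig, *, _sham: bool = False
) -> tuple[TraceMatrix, TrialStructure, GroundTruth]:
    """Simulate one imaging session.

    Baseline events are a homogeneous point process at ``baseline_rate``;
    each event is a linear ramp over a truncated-normal rise duration
    followed by an exponential decay.  Modulated neurons additionally fire
    an event with probability ``p_evoked`` within the evoked-latency window
    after each onset of their preferred PRF.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    trials = _build_trial_structure(config, rng)
    n_samples = trials.n_samples
    duration = config.session_duration_s
    fs = config.fs
    n = config.n_neurons

    # preferred-PRF assignment: disjoint subsets of size frac_modulated * n
    preferred = np.full(n, np.nan)
    if not _sham and config.frac_modulated > 0:
        per_prf = int(round(config.frac_modulated * n))
        order = rng.permutation(n)
        for k, prf in enumerate(config.prf_set):
            preferred[order[k * per_prf : (k + 1) * per_prf]] = prf
    pv = rng.random(n) < config.frac_pv

    amp_floor = 5.0 * config.noise_sd if config.noise_sd > 0 else 1e-6
    values = np.zeros((n, n_samples))
    event_times, rise_durs, evoked_flags = [], [], []
    for i in range(n):
        n_base = rng.poisson(config.baseline_rate / 60.0 * duration)
        t_base = np.sort(rng.uniform(0.0, duration, n_base))
        t_evk = np.empty(0)
        if not _sham and np.isfinite(preferred[i]):
            onsets = trials.onsets_for(preferred[i])
            hit = rng.random(onsets.size) < config.p_evoked
            lo, hi = config.evoked_latency_s
            t_evk = onsets[hit] + rng.uniform(lo, hi, int(hit.sum()))
        t_all = np.concatenate([t_base, t_evk])
        is_evk = np.concatenate([
            np.zeros(t_base.size, bool), np.ones(t_evk.size, bool)
        ])
        order_ = np.argsort(t_all, kind="stable")
        t_all, is_evk = t_all[order_], is_evk[order_]
        rises = _truncated_normal(
            rng, config.rise_mean_s, config.rise_sd_s, config.rise_min_s, t_all.size
        )
        amps = _truncated_normal(rng, config.amp_mean, config.amp_sd, amp_floor, t_all.size)
        _render_events(values[i], t_all, rises, amps, config.decay_tau_s, fs)
        event_times.append(t_all)
        rise_durs.append(rises)
        evoked_flags.append(is_evk)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, values.shape)

    modulated = {
        float(prf): (np.isfinite(preferred) & np.isclose(preferred, prf))
        if not _sham
        else np.zeros(n, bool)
        for prf in config.prf_set
    }
    truth = GroundTruth(
        preferred_prf=preferred,
        event_times=event_times,
        rise_durations=rise_durs,
        evoked=evoked_flags,
        modulated=modulated,
        pv_label=pv,
    )
    traces = TraceMatrix(values=values, fs=fs, stage="dff")
    return traces, trials, truth


def generate_sham_session(
    config: SessionConfig,
) -> tuple[TraceMatrix, TrialStructure, GroundTruth]:
    """Sham session: identical trial structure, no evoked component.

    Emulates pulsing without acoustic coupling; every ground-truth
    modulation flag is false.
    """
    return generate_session(config, _sham=True)


# ---------------------------------------------------------------------------
# movies


class LayoutError(ValueError):
    """Raised when an imaging-geometry layout is invalid."""


@dataclass
class MovieLayout:
    """Imaging geometry for synthetic movies.

    Circular, non-overlapping ROIs of ``radius_px`` placed at ``centroids``
    (auto grid if omitted) in a ``height x width`` frame.  ``background_amp``
    adds a spatially smooth, slowly drifting background (uniform per frame
    plus an optional linear gradient scaled by ``background_gradient``)
    that donut subtraction must remove; ``pixel_noise_sd`` adds white pixel
    noise.
    """

    height: int = 128
    width: int = 128
    radius_px: int = 4
    centroids: np.ndarray | None = None
    baseline: float = 100.0
    background_amp: float = 0.0
    background_gradient: float = 0.0
    pixel_noise_sd: float = 0.0
    seed: int = 0


def _auto_centroids(layout: MovieLayout, n: int) -> np.ndarray:
    gap = 4 * layout.radius_px + 2
    per_row = max(1, (layout.width - gap) // gap)
    cents = []
    for i in range(n):
        r, c = divmod(i, per_row)
        cents.append((gap // 2 + layout.radius_px + r * gap,
                      gap // 2 + layout.radius_px + c * gap))
    cents = np.asarray(cents, float)
    if cents[:, 0].max() + layout.radius_px >= layout.height:
        raise LayoutError("frame too small for requested number of ROIs")
    return cents


def generate_movie(
    traces: TraceMatrix, layout: MovieLayout
) -> tuple[np.ndarray, ROISet]:
    """Render traces into a pixel movie with matching label masks.

    Each ROI's pixels carry its neuron's trace on top of a constant
    baseline, the smooth background process, and pixel noise.
    """
    rng = np.random.default_rng(layout.seed)
    n, t = traces.n_neurons, traces.n_samples
    cents = (np.asarray(layout.centroids, float)
             if layout.centroids is not None else _auto_centroids(layout, n))
    if cents.shape != (n, 2):
        raise LayoutError("need one centroid per neuron")
    d = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if np.any(d <= 2 * layout.radius_px):
        raise LayoutError("ROIs overlap")
    yy, xx = np.mgrid[: layout.height, : layout.width]
    labels = np.zeros((layout.height, layout.width), dtype=np.uint16)
    for i, (cy, cx) in enumerate(cents):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= layout.radius_px**2
        labels[disk] = i + 1
    movie = np.full((t, layout.height, layout.width), layout.baseline, dtype=float)
    if layout.background_amp > 0:
        tt = np.arange(t) / max(traces.fs, 1.0)
        drift = np.sin(2 * np.pi * tt / max(tt[-1], 1.0)) + 0.3 * tt / max(tt[-1], 1.0)
        spatial = 1.0 + layout.background_gradient * (xx / layout.width - 0.5)
        movie += layout.background_amp * drift[:, None, None] * spatial[None, :, :]
    for i in range(n):
        disk = labels == i + 1
        movie[:, disk] += traces.values[i][:, None]
    if layout.pixel_noise_sd > 0:
        movie += rng.normal(0.0, layout.pixel_noise_sd, movie.shape)
    return movie, ROISet(label_mask=labels)


# ---------------------------------------------------------------------------
# UMI count matrices


@dataclass
class PopulationExpression:
    """Per-population expression parameters of one gene.

    ``nonzero_frac`` is the fraction of cells with any expression; cells
    that express draw counts from a zero-truncated negative binomial with
    mean ``nb_mean`` and dispersion ``nb_disp`` (variance
    ``mu + mu^2 / disp``).
    """

    nonzero_frac: float
    nb_mean: float = 3.0
    nb_disp: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonzero_frac <= 1.0:
            raise ConfigurationError("nonzero_frac must lie in [0, 1]")
        if self.nb_mean <= 0 or self.nb_disp <= 0:
            raise ConfigurationError("nb_mean and nb_disp must be positive")


@dataclass
class GeneSpec:
    """A gene with population-specific expression parameters."""

    name: str
    populations: dict = field(default_factory=dict)


def _sample_ztnb(
    rng: np.random.Generator, mu: float, disp: float, size: int
) -> np.ndarray:
    """Zero-truncated negative binomial via inverse-CDF above P(0)."""
    p = disp / (disp + mu)
    p0 = stats.nbinom.pmf(0, disp, p)
    u = rng.uniform(p0, 1.0, size)
    return stats.nbinom.ppf(u, disp, p).astype(np.int64)


def truncated_nb_pmf(mu: float, disp: float, kmax: int | None = None) -> np.ndarray:
    """PMF of the zero-truncated NB on 1..kmax (tail mass folded into kmax)."""
    p = disp / (disp + mu)
    if kmax is None:
        kmax = int(stats.nbinom.ppf(1.0 - 1e-12, disp, p)) + 1
    ks = np.arange(1, kmax + 1)
    pmf = stats.nbinom.pmf(ks, disp, p)
    pmf[-1] += stats.nbinom.sf(kmax, disp, p)
    return pmf / (1.0 - stats.nbinom.pmf(0, disp, p))


def planted_cliffs_delta(a: PopulationExpression, b: PopulationExpression) -> float:
    """Analytic Cliff's delta between the two nonzero count distributions.

    Independent oracle for recovery tests: delta = sum_ij p_i q_j sign(i-j)
    over the truncated-NB pmfs (normalisation makes it invariant to the
    monotone log-normalisation applied downstream).
    """
    kmax = int(
        max(
            stats.nbinom.ppf(1 - 1e-10, a.nb_disp, a.nb_disp / (a.nb_disp + a.nb_mean)),
            stats.nbinom.ppf(1 - 1e-10, b.nb_disp, b.nb_disp / (b.nb_disp + b.nb_mean)),
        )
    ) + 2
    pa = truncated_nb_pmf(a.nb_mean, a.nb_disp, kmax)
    pb = truncated_nb_pmf(b.nb_mean, b.nb_disp, kmax)
    cdf_b = np.cumsum(pb)
    less = np.concatenate([[0.0], cdf_b[:-1]])     # P(B < k)
    greater = 1.0 - cdf_b                           # P(B > k)
    return float(np.sum(pa * (less - greater)))


def generate_umi_matrix(
    n_cells_per_pop: dict,
    genes: list,
    seed: int = 0,
    n_background_genes: int = 20,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic cell x gene UMI matrix with population labels.

    Returns ``(counts, labels)``: an integer DataFrame (cells x genes) and
    a Series of population labels indexed like the rows.  Background genes
    are shared across populations so every cell has a positive library
    size (the first background gene is zero-truncated).
    """
    rng = np.random.default_rng(seed)
    pops = list(n_cells_per_pop)
    cells = []
    labels = []
    for pop in pops:
        n = int(n_cells_per_pop[pop])
        cols = {}
        for g in genes:
            if pop not in g.populations:
                raise ConfigurationError(f"gene {g.name} lacks parameters for {pop!r}")
            pe = g.populations[pop]
            expressed = rng.random(n) < pe.nonzero_frac
            counts = np.zeros(n, dtype=np.int64)
            counts[expressed] = _sample_ztnb(
                rng, pe.nb_mean, pe.nb_disp, int(expressed.sum())
            )
            cols[g.name] = counts
        for j in range(n_background_genes):
            if j == 0:
                cols[f"bg{j}"] = _sample_ztnb(rng, 5.0, 2.0, n)
            else:
                cols[f"bg{j}"] = rng.negative_binomial(2.0, 2.0 / 7.0, n)
        cells.append(pd.DataFrame(cols))
        labels.extend([pop] * n)
    counts = pd.concat(cells, ignore_index=True)
    return counts, pd.Series(labels, name="population")
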