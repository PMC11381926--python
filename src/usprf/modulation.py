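"""Shuffled-baseline test for US-evoked modulation.

For each neuron, a null distribution of event density is built by
averaging the binary rising-phase mask over randomly placed 1 s windows
during baseline (the recording excluding 5 s after every US onset),
repeated 1000 times.  A neuron is modulated by a PRF when its mean event
density during that PRF's 1 s US windows exceeds the 95th percentile of
the null, unless its density in the 1 s immediately before US is itself
above that percentile (pre-US exclusion, which guards against events
already rising when US arrives).  Neurons responding to exactly one PRF
are "specific" responders; to two or more, "non-specific".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .events import EventTrain
from .session import TrialStructure

__all__ = [
    "ShuffleDistribution",
    "ModulationResult",
    "ResponderClass",
    "baseline_mask",
    "shuffle_baseline",
    "classify_modulation",
    "response_significance",
    "classify_specificity",
    "modulation_table",
    "proportion_report",
    "percentage",
]


@dataclass
class ShuffleDistribution:
    """Null distribution of window-averaged event density."""

    samples: np.ndarray
    p95: float
    n_windows: int
    baseline_mask: np.ndarray


@dataclass(frozen=True)
class ModulationResult:
    """Per neuron x PRF outcome of the shuffled-baseline test."""

    neuron: int
    prf: float
    observed_us_density: float
    observed_pre_density: float
    p95: float
    modulated: bool
    excluded_preus: bool
    significance: float


@dataclass(frozen=True)
class ResponderClass:
    """PRF-specificity class of one neuron across the tested PRFs."""

    neuron: int
    cls: str  # specific | non_specific | non_responder
    prfs_modulated: frozenset


def baseline_mask(trials: TrialStructure, exclusion_s: float = 5.0) -> np.ndarray:
    """Boolean sample mask of baseline periods.

    Excludes ``[onset, onset + exclusion_s)`` for every US onset.
    """
    fs = trials.fs
    mask = np.ones(trials.n_samples, dtype=bool)
    for onset in trials.us_onsets:
        i0 = int(round(onset * fs))
        i1 = min(mask.size, int(round((onset + exclusion_s) * fs)))
        mask[i0:i1] = False
    return mask


def shuffle_baseline(
    train: EventTrain,
    trials: TrialStructure,
    n_windows: int | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    window_s: float = 1.0,
    with_replacement: bool = True,
) -> ShuffleDistribution:
    """Build the shuffled-baseline null for one neuron.

    Each iteration draws ``n_windows`` 1 s windows whose full extent lies in
    the baseline mask (grid-aligned, any valid start sample) and records the
    mean event density over them; ``n_iter`` iterations give the null whose
    empirical 95th percentile is the modulation threshold.  ``n_windows``
    defaults to the number of trials per PRF condition.  Windows are drawn
    with replacement within an iteration by default; ``with_replacement=
    False`` draws them without replacement instead.
    """
    fs = trials.fs
    w = int(round(window_s * fs))
    mask = baseline_mask(trials)
    if n_windows is None:
        n_windows = int(round(trials.n_trials / len(trials.prf_set)))
    # valid starts: full window inside baseline
    ok = np.ones(mask.size - w + 1, dtype=bool)
    bad = ~mask
    csum = np.concatenate([[0], np.cumsum(bad)])
    ok = (csum[w:] - csum[:-w]) == 0
    starts = np.nonzero(ok)[0]
    if starts.size == 0:
        raise ValueError("baseline mask shorter than one window")
    m = train.rising_mask.astype(float)
    mcsum = np.concatenate([[0.0], np.cumsum(m)])
    dens = (mcsum[starts + w] - mcsum[starts]) / w
    rng = np.random.default_rng(seed)
    if with_replacement:
        idx = rng.integers(0, starts.size, size=(n_iter, n_windows))
        samples = dens[idx].mean(axis=1)
    else:
        if n_windows > starts.size:
            raise ValueError("not enough valid windows to draw without replacement")
        samples = np.array([
            dens[rng.choice(starts.size, n_windows, replace=False)].mean()
            for _ in range(n_iter)
        ])
    return ShuffleDistribution(
        samples=samples,
        p95=float(np.percentile(samples, 95)),
        n_windows=int(n_windows),
        baseline_mask=mask,
    )


def response_significance(observed: float, p95: float) -> float:
    """(observed - P95) / P95; +inf sentinel when P95 is zero but the
    observed density is not, 0 when both are zero."""
    if observed < 0 or p95 < 0:
        raise ValueError("inputs must be non-negative")
    if p95 == 0:
        return np.inf if observed > 0 else 0.0
    return (observed - p95) / p95


def classify_modulation(
    train: EventTrain,
    trials: TrialStructure,
    prf: float,
    dist: ShuffleDistribution,
    neuron: int = 0,
    window_s: float = 1.0,
) -> ModulationResult:
    """Apply the shuffled-baseline test to one neuron at one PRF."""
    fs = trials.fs
    w = int(round(window_s * fs))
    onsets = trials.onsets_for(prf)
    m = train.rising_mask.astype(float)
    us_d, pre_d = [], []
    for onset in onsets:
        i = int(round(onset * fs))
        us_d.append(m[i : i + w].mean())
        pre_d.append(m[max(0, i - w) : i].mean())
    obs_us = float(np.mean(us_d))
    obs_pre = float(np.mean(pre_d))
    excluded = obs_pre > dist.p95
    modulated = (obs_us > dist.p95) and not excluded
    return ModulationResult(
        neuron=neuron,
        prf=float(prf),
        observed_us_density=obs_us,
        observed_pre_density=obs_pre,
        p95=dist.p95,
        modulated=modulated,
        excluded_preus=excluded,
        significance=response_significance(obs_us, dist.p95),
    )


def classify_specificity(results) -> ResponderClass:
    """Responder class from one neuron's results across PRFs."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("specificity needs results for at least two PRFs")
    neurons = {r.neuron for r in results}
    if len(neurons) != 1:
        raise ValueError("results must belong to a single neuron")
    mod = frozenset(r.prf for r in results if r.modulated)
    cls = (
        "non_responder" if len(mod) == 0
        else "specific" if len(mod) == 1
        else "non_specific"
    )
    return ResponderClass(neuron=results[0].neuron, cls=cls, prfs_modulated=mod)


def modulation_table(results) -> pd.DataFrame:
    """Flatten ModulationResults into a tidy DataFrame."""
    return pd.DataFrame([
        {
            "neuron": r.neuron,
            "prf": r.prf,
            "observed_us_density": r.observed_us_density,
            "observed_pre_density": r.observed_pre_density,
            "p95": r.p95,
            "modulated": r.modulated,
            "excluded_preus": r.excluded_preus,
            "significance": r.significance,
        }
        for r in results
    ])


def percentage(count: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) / Decimal(total) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def proportion_report(table: pd.DataFrame, by=("prf",)) -> pd.DataFrame:
    """Counts and percentages of modulated neurons per condition.

    ``table`` needs a boolean ``modulated`` column plus the grouping
    columns in ``by`` (e.g. prf, cell type, stim/sham).
    """
    if table.empty:
        raise ValueError("results table is empty")
    rows = []
    for key, grp in table.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        n_mod = int(grp["modulated"].sum())
        n_tot = int(len(grp))
        rows.append(
            dict(zip(by, key))
            | {"n_modulated": n_mod, "n_total": n_tot,
               "percentage": percentage(n_mod, n_tot)}
        )
    return pd.DataFrame(rows)
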