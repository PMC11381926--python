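"""End-to-end per-session analysis.

Glues the stages together: event detection on every neuron, removal of
neurons with no events, one shuffled-baseline null per neuron (shared
across PRFs, with the baseline excluding 5 s after all onsets), the
modulation test per PRF, and responder-specificity classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import DetectionParams, EventTrain, detect_events
from .extraction import TraceMatrix
from .modulation import (
    classify_modulation,
    classify_specificity,
    modulation_table,
    shuffle_baseline,
)
from .session import TrialStructure

__all__ = ["SessionAnalysis", "analyze_session"]


@dataclass
class SessionAnalysis:
    """Results of one session.

    ``kept`` indexes neurons with at least one detected event; neurons
    without events are removed from all downstream tables (never NaN rows).
    """

    trains: dict               # neuron id -> EventTrain (kept neurons only)
    kept: np.ndarray           # neuron ids retained
    removed: np.ndarray        # neuron ids dropped (no events)
    modulation: pd.DataFrame   # one row per kept neuron x PRF
    responders: pd.DataFrame   # one row per kept neuron (multi-PRF sessions)

    def masks(self) -> np.ndarray:
        """Rising-phase masks of kept neurons, stacked in ``kept`` order."""
        return np.stack([self.trains[i].rising_mask for i in self.kept])

    def modulated_flags(self, prf: float) -> np.ndarray:
        """Boolean modulated flag per kept neuron for one PRF."""
        sub = self.modulation[np.isclose(self.modulation["prf"], prf)]
        sub = sub.set_index("neuron").loc[self.kept]
        return sub["modulated"].to_numpy(dtype=bool)


def analyze_session(
    traces: TraceMatrix,
    trials: TrialStructure,
    params: DetectionParams | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> SessionAnalysis:
    """Run detection + modulation testing for every neuron of a session.

    Shuffle seeds are derived as ``seed + neuron_index`` so per-neuron
    flags are reproducible regardless of which neurons are analysed.
    """
    params = params or DetectionParams(fs=trials.fs)
    trains: dict[int, EventTrain] = {}
    kept, removed = [], []
    for idx in range(traces.n_neurons):
        nid = int(traces.neuron_ids[idx])
        train = detect_events(traces.values[idx], params)
        if train.empty:
            removed.append(nid)
            continue
        trains[nid] = train
        kept.append(nid)
    results = []
    responders = []
    prfs = trials.prf_set
    for idx, nid in enumerate(kept):
        dist = shuffle_baseline(
            trains[nid], trials, n_iter=n_iter, seed=seed + idx
        )
        per_prf = [
            classify_modulation(trains[nid], trials, prf, dist, neuron=nid)
            for prf in prfs
        ]
        results.extend(per_prf)
        if len(prfs) >= 2:
            rc = classify_specificity(per_prf)
            responders.append({
                "neuron": nid, "class": rc.cls,
                "n_prfs_modulated": len(rc.prfs_modulated),
                "prfs_modulated": sorted(rc.prfs_modulated),
            })
    return SessionAnalysis(
        trains=trains,
        kept=np.asarray(kept, dtype=int),
        removed=np.asarray(removed, dtype=int),
        modulation=modulation_table(results),
        responders=pd.DataFrame(responders),
    )
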