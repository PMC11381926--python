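"""Pairwise asymmetric correlation coefficient (ACC) of event trains.

For binary rising-phase trains A and B,

    ACC(A, B) = 1/2 * ( |A & B| / |A|  +  |A & B| / |B| )

the mean of the two conditional co-occurrence fractions: symmetric,
bounded in [0, 1], and 1 for identical nonzero trains.  Pairs (or bins)
where either train has no events leave a denominator undefined and are
excluded rather than scored zero, which would bias group means downward.

Sustained ACC uses the full recording; transient ACC is computed in 1 s
bins aligned to trial onsets, pooling each bin's samples across trials by
default (``per_trial=True`` instead averages single-trial ACCs, which is
far noisier because single-trial bins hold at most ~20 samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import TrialStructure

__all__ = [
    "acc",
    "acc_matrix",
    "pair_group_labels",
    "sustained_acc",
    "transient_acc",
    "baseline_bins_mean",
]


def acc(a: np.ndarray, b: np.ndarray) -> float:
    """ACC of two equal-length binary trains; NaN if either is all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("trains must have equal length")
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        return np.nan
    inter = np.count_nonzero(a & b)
    return 0.5 * (inter / sa + inter / sb)


def acc_matrix(masks: np.ndarray) -> np.ndarray:
    """All-pairs ACC for a stack of binary trains ``(n_neurons, n_samples)``.

    Entries involving an all-zero train are NaN; the diagonal of nonzero
    trains is 1.
    """
    m = np.asarray(masks, dtype=float)
    inter = m @ m.T
    s = m.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * (inter / s[:, None] + inter / s[None, :])
    out[(s == 0), :] = np.nan
    out[:, (s == 0)] = np.nan
    return out


def pair_group_labels(flags: np.ndarray, kind: str = "mod") -> np.ndarray:
    """Group label per unordered pair (i < j) from a boolean neuron flag.

    ``kind="mod"`` labels Mod:Mod / Mod:Non / Non:Non; ``kind="pv"`` labels
    PV:PV / PV:nonPV / nonPV:nonPV.
    """
    pos, neg = {"mod": ("Mod", "Non"), "pv": ("PV", "nonPV")}[kind]
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    iu, ju = np.triu_indices(n, k=1)
    both = flags[iu] & flags[ju]
    neither = ~flags[iu] & ~flags[ju]
    labels = np.where(
        both, f"{pos}:{pos}", np.where(neither, f"{neg}:{neg}", f"{pos}:{neg}")
    )
    return labels


def _pair_frame(mat: np.ndarray, flags, kind) -> pd.DataFrame:
    n = mat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    df = pd.DataFrame({"i": iu, "j": ju, "acc": mat[iu, ju], "group": "All"})
    if flags is not None:
        df["group"] = pair_group_labels(flags, kind)
    return df


def sustained_acc(
    masks: np.ndarray, flags: np.ndarray | None = None, kind: str = "mod"
) -> pd.DataFrame:
    """Full-recording ACC for every unordered pair, with group labels.

    Session-level statistics should average the ``acc`` column per group
    (undefined pairs are NaN and excluded by ``mean``).
    """
    masks = np.atleast_2d(masks)
    if masks.shape[0] < 2:
        raise ValueError("need at least two neurons")
    return _pair_frame(acc_matrix(masks), flags, kind)


def _bin_sample_indices(trials: TrialStructure, bin_idx: int, w: int) -> np.ndarray:
    starts = np.round(trials.trial_starts() * trials.fs).astype(int)
    idx = (starts[:, None] + bin_idx * w + np.arange(w)[None, :]).ravel()
    return idx[(idx >= 0) & (idx < trials.n_samples)]


def transient_acc(
    masks: np.ndarray,
    trials: TrialStructure,
    flags: np.ndarray | None = None,
    kind: str = "mod",
    bin_s: float = 1.0,
    per_trial: bool = False,
) -> pd.DataFrame:
    """Trial-aligned ACC time course in ``bin_s`` bins.

    Returns a long DataFrame (group, bin, t_rel, value) where ``t_rel`` is
    the bin start relative to trial start and ``value`` the mean ACC over
    the group's defined pairs.  With the default pooling, each bin's
    samples are concatenated across trials before the ACC ratio; with
    ``per_trial=True`` single-trial ACCs are averaged instead.
    """
    masks = np.atleast_2d(masks)
    fs = trials.fs
    w = int(round(bin_s * fs))
    trial_len = trials.pre_s + trials.us_s + trials.post_s
    n_bins = int(trial_len // bin_s)
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    n = masks.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    groups = pair_group_labels(flags, kind) if flags is not None else np.full(iu.size, "All")
    rows = []
    for b in range(n_bins):
        if per_trial:
            starts = np.round(trials.trial_starts() * fs).astype(int)
            per = []
            for s0 in starts:
                sub = masks[:, s0 + b * w : s0 + (b + 1) * w]
                if sub.shape[1] == w:
                    per.append(acc_matrix(sub)[iu, ju])
            vals = np.nanmean(np.stack(per), axis=0) if per else np.full(iu.size, np.nan)
        else:
            idx = _bin_sample_indices(trials, b, w)
            vals = acc_matrix(masks[:, idx])[iu, ju]
        group_sets = [("All", np.ones(iu.size, bool))] + [
            (g, groups == g) for g in np.unique(groups) if g != "All"
        ]
        for g, sel_mask in group_sets:
            sel = vals[sel_mask]
            rows.append({
                "group": g, "bin": b, "t_rel": b * bin_s,
                "value": float(np.nanmean(sel)) if np.isfinite(sel).any() else np.nan,
                "n_pairs": int(np.isfinite(sel).sum()),
            })
    return pd.DataFrame(rows)


def baseline_bins_mean(course: pd.DataFrame, n_bl_bins: int = 8) -> pd.Series:
    """Per-group "BL" value: mean over the first ``n_bl_bins`` trial bins."""
    bl = course[course["bin"] < n_bl_bins]
    return bl.groupby("group")["value"].mean()
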