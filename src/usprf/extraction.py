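"""Fluorescence trace extraction and preprocessing.

Turns widefield movies plus ROI label masks into per-neuron dF/F traces:
mean ROI intensity minus the mean of a surrounding "donut" (annulus)
background mask, followed by interpolation onto a uniform 20 Hz grid,
linear detrending, min-max normalisation, and per-trial referencing to the
10 s pre-US baseline.  Also matches parvalbumin (PV) labels between a
GCaMP channel and a tdTomato channel via mask overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import detrend as _linear_detrend
from skimage.transform import warp as _warp

from .session import TrialStructure

logger = logging.getLogger(__name__)

DONUT_INNER_PX = 15
DONUT_OUTER_PX = 50


@dataclass
class ROISet:
    """Labelled ROIs with per-ROI background annuli.

    The donut of each ROI is the annulus between ``inner_px`` and
    ``outer_px`` pixels from the ROI centroid, excluding pixels belonging
    to *any* ROI so neighbouring somata never contaminate the background
    estimate.
    """

    label_mask: np.ndarray
    inner_px: int = DONUT_INNER_PX
    outer_px: int = DONUT_OUTER_PX
    pv_label: np.ndarray | None = None
    centroids: np.ndarray = field(init=False)
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.label_mask)
        if mask.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if np.any(mask < 0):
            raise ValueError("ROI labels must be non-negative")
        labels = np.unique(mask)
        self.labels = labels[labels > 0]
        cents = np.zeros((self.labels.size, 2))
        for i, lab in enumerate(self.labels):
            ys, xs = np.nonzero(mask == lab)
            cents[i] = (ys.mean(), xs.mean())
        self.centroids = cents

    @property
    def n_rois(self) -> int:
        return int(self.labels.size)

    def roi_mask(self, label: int) -> np.ndarray:
        return np.asarray(self.label_mask) == label

    def donut_mask(self, label: int) -> np.ndarray:
        """Annulus around the ROI centroid, excluding all ROI pixels."""
        idx = int(np.nonzero(self.labels == label)[0][0])
        cy, cx = self.centroids[idx]
        h, w = self.label_mask.shape
        yy, xx = np.ogrid[:h, :w]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring = (r2 >= self.inner_px**2) & (r2 <= self.outer_px**2)
        return ring & (np.asarray(self.label_mask) == 0)


@dataclass
class TraceMatrix:
    """Per-neuron fluorescence traces.

    ``values`` is ``(n_neurons, n_samples)``; ``stage`` is ``"raw"``
    (background-subtracted pixel means) or ``"dff"`` (fully preprocessed).
    """

    values: np.ndarray
    fs: float = 20.0
    timestamps: np.ndarray | None = None
    stage: str = "raw"
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.timestamps is None:
            self.timestamps = np.arange(self.values.shape[1]) / self.fs
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])


def extract_trace(
    movie: np.ndarray,
    rois: ROISet,
    fs: float = 20.0,
    timestamps: np.ndarray | None = None,
) -> TraceMatrix:
    """Raw trace per ROI: mean ROI pixel value minus mean donut pixel value.

    ROIs whose donut is empty after excluding ROI pixels are skipped with a
    warning and are absent from the output.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, height, width)")
    if movie.shape[1:] != np.asarray(rois.label_mask).shape:
        raise ValueError("mask dimensions do not match movie frames")
    flat = movie.reshape(movie.shape[0], -1)
    traces, kept = [], []
    for lab in rois.labels:
        roi = rois.roi_mask(lab).ravel()
        donut = rois.donut_mask(lab).ravel()
        if not donut.any():
            logger.warning("ROI %d has an empty donut; skipped", lab)
            continue
        traces.append(flat[:, roi].mean(axis=1) - flat[:, donut].mean(axis=1))
        kept.append(lab)
    if not traces:
        raise ValueError("no ROI with a valid donut mask")
    return TraceMatrix(
        values=np.stack(traces), fs=fs, timestamps=timestamps, stage="raw",
        neuron_ids=np.asarray(kept),
    )


def preprocess(
    raw: TraceMatrix,
    trials: TrialStructure,
    baseline_s: float = 10.0,
) -> TraceMatrix:
    """Raw traces -> dF/F on a uniform 20 Hz grid.

    Fixed pipeline order: (1) shape-preserving piecewise-cubic (PCHIP)
    interpolation onto a uniform grid at ``trials.fs``, spanning any
    inter-trial gaps in the timestamps; (2) linear detrend (removes
    photobleaching); (3) min-max normalisation to [0, 1]; (4) per trial,
    subtraction of the mean over the ``baseline_s`` pre-US window, so every
    trial's baseline sits at zero.

    Neurons with a constant trace (zero range) cannot be normalised; they
    are dropped with a log entry and are absent from the output.
    """
    if trials.pre_s < baseline_s:
        raise ValueError(f"trial structure must provide a {baseline_s} s pre-US baseline")
    fs = trials.fs
    grid = np.arange(int(round(trials.session_duration_s * fs))) / fs
    ts = raw.timestamps
    out, kept = [], []
    for i in range(raw.n_neurons):
        y = raw.values[i]
        if ts.shape == grid.shape and np.allclose(ts, grid):
            v = y.astype(float).copy()
        else:
            v = PchipInterpolator(ts, y, extrapolate=True)(grid)
        v = _linear_detrend(v, type="linear")
        rng_ = v.max() - v.min()
        if rng_ <= 1e-12:
            logger.info("neuron %s dropped: constant trace", raw.neuron_ids[i])
            continue
        v = (v - v.min()) / rng_
        v = _subtract_trial_baselines(v, trials, baseline_s)
        out.append(v)
        kept.append(raw.neuron_ids[i])
    if not out:
        raise ValueError("all neurons dropped during preprocessing")
    return TraceMatrix(
        values=np.stack(out), fs=fs, timestamps=grid, stage="dff",
        neuron_ids=np.asarray(kept),
    )


def _subtract_trial_baselines(
    v: np.ndarray, trials: TrialStructure, baseline_s: float
) -> np.ndarray:
    """Subtract the mean of the pre-US window from each trial's span."""
    fs = trials.fs
    n = v.size
    onsets = np.round(trials.us_onsets * fs).astype(int)
    starts = np.round(trials.trial_starts() * fs).astype(int)
    # trial spans tile the session: each span runs to the next trial's start
    bounds = np.concatenate([[0], starts[1:], [n]])
    out = v.copy()
    nb = int(round(baseline_s * fs))
    for k, onset in enumerate(onsets):
        lo, hi = bounds[k], bounds[k + 1]
        base = v[onset - nb : onset].mean()
        out[lo:hi] -= base
    return out


def match_pv(
    gcamp_rois: ROISet,
    tdt_rois: ROISet,
    transform: np.ndarray | None = None,
) -> np.ndarray:
    """PV labels for GCaMP ROIs by overlap with tdTomato ROIs.

    A GCaMP ROI is PV-positive iff strictly more than 50% of its pixels are
    covered by tdT ROIs after warping the tdT mask into the GCaMP frame.

    Parameters
    ----------
    transform
        Optional 3x3 homogeneous matrix mapping tdT coordinates to GCaMP
        coordinates (e.g. a landmark-derived affine); identity if omitted.
    """
    tdt_mask = np.asarray(tdt_rois.label_mask) > 0
    if transform is not None:
        transform = np.asarray(transform, dtype=float)
        if transform.shape != (3, 3) or abs(np.linalg.det(transform)) < 1e-12:
            raise ValueError("degenerate or invalid transform")
        tdt_mask = _warp(
            tdt_mask.astype(float), np.linalg.inv(transform), order=0,
            output_shape=np.asarray(gcamp_rois.label_mask).shape,
            preserve_range=True,
        ) > 0.5
    pv = np.zeros(gcamp_rois.n_rois, dtype=bool)
    for i, lab in enumerate(gcamp_rois.labels):
        roi = gcamp_rois.roi_mask(lab)
        overlap = np.count_nonzero(roi & tdt_mask) / np.count_nonzero(roi)
        pv[i] = overlap > 0.5
    return pv
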