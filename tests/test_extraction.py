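"""Donut background subtraction, dF/F preprocessing, and PV matching."""

import numpy as np
import pytest

from usprf import ROISet, TraceMatrix, extract_trace, match_pv, preprocess
from usprf.session import TrialStructure


def _disk_mask(h, w, cy, cx, r, label, base=None):
    m = np.zeros((h, w), dtype=int) if base is None else base
    yy, xx = np.ogrid[:h, :w]
    m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = label
    return m


def _trials(n_trials=2, pre=10.0, us=1.0, post=10.0, pause=0.5, fs=20.0):
    period = pre + us + post + pause
    return TrialStructure(
        us_onsets=np.arange(n_trials) * period + pre,
        prf_per_trial=np.full(n_trials, 40.0),
        us_s=us, pre_s=pre, post_s=post, pause_s=pause,
        session_duration_s=n_trials * period, fs=fs,
    )


class TestExtractTrace:
    def test_roi_minus_donut_arithmetic(self):
        mask = _disk_mask(120, 120, 60, 60, 4, 1)
        rois = ROISet(label_mask=mask)
        frame = np.full((120, 120), 4.0)
        frame[mask == 1] = 10.0
        got = extract_trace(frame[None, :, :], rois)
        assert got.values[0, 0] == pytest.approx(6.0)

    def test_uniform_frame_cancels(self):
        mask = _disk_mask(120, 120, 60, 60, 4, 1)
        movie = np.full((3, 120, 120), 7.5)
        got = extract_trace(movie, ROISet(label_mask=mask))
        np.testing.assert_allclose(got.values, 0.0, atol=1e-12)

    def test_neighbor_excluded_from_donut(self):
        """A neighbouring ROI's brightness never leaks into the donut."""
        mask = _disk_mask(160, 160, 80, 80, 4, 1)
        mask = _disk_mask(160, 160, 80, 100, 4, 2, base=mask)
        rois = ROISet(label_mask=mask)
        outs = []
        for neighbor_value in (0.0, 50.0, 500.0):
            frame = np.zeros((160, 160))
            frame[mask == 1] = 10.0
            frame[mask == 2] = neighbor_value
            outs.append(extract_trace(frame[None], rois).values[0, 0])
        assert outs[0] == outs[1] == outs[2]

    def test_uniform_offset_invariance(self, rng):
        mask = _disk_mask(120, 120, 60, 60, 4, 1)
        rois = ROISet(label_mask=mask)
        movie = rng.normal(10, 1, (20, 120, 120))
        base = extract_trace(movie, rois).values
        shifted = extract_trace(movie + 123.4, rois).values
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_empty_donut_skipped(self):
        # ROI pixels fill the frame, so the annulus has nothing left:
        # the ROI is skipped, and with no ROI remaining extraction errors
        mask = np.ones((40, 40), dtype=int)
        with pytest.raises(ValueError):
            extract_trace(np.zeros((2, 40, 40)), ROISet(label_mask=mask))


class TestPreprocess:
    def test_pre_us_mean_zero_per_trial(self, rng):
        trials = _trials()
        n = trials.n_samples
        raw = TraceMatrix(values=rng.normal(5, 1, (3, n)).cumsum(axis=1) / 50,
                          fs=20.0, stage="raw")
        out = preprocess(raw, trials)
        fs = int(trials.fs)
        for onset in trials.us_onsets:
            i = int(round(onset * fs))
            pre = out.values[:, i - 10 * fs : i]
            np.testing.assert_allclose(pre.mean(axis=1), 0.0, atol=1e-9)
        assert out.values.min() >= -1.0 and out.values.max() <= 1.0
        assert not np.isnan(out.values).any()

    def test_linear_ramp_dropped(self, rng):
        trials = _trials()
        n = trials.n_samples
        ramp = np.linspace(0, 1, n)[None, :]
        noisy = rng.normal(0, 0.1, (1, n))
        raw = TraceMatrix(values=np.vstack([ramp, noisy]), fs=20.0, stage="raw")
        out = preprocess(raw, trials)
        # the pure-ramp neuron detrends to a constant and is dropped
        assert out.n_neurons == 1
        assert out.neuron_ids[0] == 1

    def test_on_grid_interpolation_is_identity(self):
        trials = _trials(n_trials=1)
        n = trials.n_samples
        y = np.sin(np.arange(n) / 40.0)
        raw = TraceMatrix(values=y[None], fs=20.0, stage="raw")
        out = preprocess(raw, trials)
        # invert the affine steps: interpolation must not have moved values
        v = out.values[0]
        recon_affine = np.polyfit(np.arange(n), y, 1)
        detr = y - np.polyval(recon_affine, np.arange(n))
        expect = (detr - detr.min()) / (detr.max() - detr.min())
        i = int(round(trials.us_onsets[0] * 20))
        expect = expect - expect[i - 200 : i].mean()
        np.testing.assert_allclose(v, expect, atol=1e-9)

    def test_gap_interpolation(self, rng):
        """Timestamps with a gap are interpolated onto the uniform grid."""
        trials = _trials(n_trials=2)
        grid = np.arange(trials.n_samples) / 20.0
        keep = (grid < 21.0) | (grid >= 21.5)  # drop the inter-trial pause
        y = np.cos(grid / 7.0) + 0.1 * rng.normal(size=grid.size)
        raw = TraceMatrix(values=y[keep][None], fs=20.0,
                          timestamps=grid[keep], stage="raw")
        out = preprocess(raw, trials)
        assert out.n_samples == trials.n_samples
        assert not np.isnan(out.values).any()


class TestMatchPV:
    def test_overlap_rules(self):
        h = w = 64
        g = _disk_mask(h, w, 32, 32, 5, 1)
        # identical
        assert match_pv(ROISet(g), ROISet(g.copy()))[0]
        # disjoint
        t = _disk_mask(h, w, 10, 10, 5, 1)
        assert not match_pv(ROISet(g), ROISet(t))[0]

    def test_strict_threshold_at_50_percent(self):
        h = w = 32
        g = np.zeros((h, w), dtype=int)
        g[10:20, 10:20] = 1  # 100 px ROI
        t60 = np.zeros((h, w), dtype=int)
        t60[10:20, 10:16] = 1  # covers 60 px
        t50 = np.zeros((h, w), dtype=int)
        t50[10:20, 10:15] = 1  # covers exactly 50 px
        assert match_pv(ROISet(g), ROISet(t60))[0]
        assert not match_pv(ROISet(g), ROISet(t50))[0]

    def test_affine_transform_applied(self):
        h = w = 64
        g = _disk_mask(h, w, 32, 32, 5, 1)
        t = _disk_mask(h, w, 22, 27, 5, 1)  # shifted by (dy=-10, dx=-5)
        # transform maps tdT (x, y) -> GCaMP (x, y): translation (+5, +10)
        m = np.array([[1, 0, 5], [0, 1, 10], [0, 0, 1]], dtype=float)
        assert match_pv(ROISet(g), ROISet(t), transform=m)[0]
        with pytest.raises(ValueError):
            match_pv(ROISet(g), ROISet(t), transform=np.zeros((3, 3)))
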