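"""Shuffled-baseline test: oracle equivalence, flag logic, reporting."""

import numpy as np
import pandas as pd
import pytest

from usprf import (
    classify_modulation,
    classify_specificity,
    modulation_table,
    percentage,
    proportion_report,
    response_significance,
    shuffle_baseline,
)
from usprf.events import EventTrain
from usprf.modulation import ModulationResult, baseline_mask
from usprf.session import TrialStructure

FS = 20.0


def _trials(n_trials=3, pre=10.0, us=1.0, post=10.0, pause=0.5, prfs=None):
    period = pre + us + post + pause
    onsets = np.arange(n_trials) * period + pre
    return TrialStructure(
        us_onsets=onsets,
        prf_per_trial=np.full(n_trials, 40.0) if prfs is None else np.asarray(prfs),
        us_s=us, pre_s=pre, post_s=post, pause_s=pause,
        session_duration_s=n_trials * period, fs=FS,
    )


def _train(mask):
    return EventTrain(events=[], rising_mask=np.asarray(mask, dtype=np.uint8), fs=FS)


class TestShuffleBaseline:
    def test_constant_masks(self):
        trials = _trials()
        n = trials.n_samples
        zero = shuffle_baseline(_train(np.zeros(n)), trials, seed=0)
        assert zero.p95 == 0.0 and np.all(zero.samples == 0)
        one = shuffle_baseline(_train(np.ones(n)), trials, seed=0)
        assert one.p95 == 1.0 and np.all(one.samples == 1.0)

    def test_baseline_mask_excludes_5s_post_onset(self):
        trials = _trials()
        mask = baseline_mask(trials)
        for onset in trials.us_onsets:
            i = int(onset * FS)
            assert not mask[i : i + int(5 * FS)].any()
        assert mask[: int(trials.us_onsets[0] * FS)].all()

    def test_p95_matches_exhaustive_enumeration(self, rng):
        """Oracle: exact distribution of the mean of k window densities by
        k-fold convolution of the enumerated window-value pmf."""
        trials = TrialStructure(
            us_onsets=np.array([20.0]), prf_per_trial=np.array([40.0]),
            us_s=1.0, pre_s=10.0, post_s=39.0, pause_s=0.0,
            session_duration_s=60.0, fs=FS,
        )
        mask = (rng.random(trials.n_samples) < 0.15).astype(np.uint8)
        train = _train(mask)
        k = 5
        dist = shuffle_baseline(train, trials, n_windows=k, n_iter=4000, seed=3)
        # enumerate every valid grid-aligned window's density
        bmask = baseline_mask(trials)
        w = int(FS)
        dens = []
        for s in range(trials.n_samples - w + 1):
            if bmask[s : s + w].all():
                dens.append(mask[s : s + w].sum())  # integer counts 0..20
        dens = np.asarray(dens)
        # pmf of one window's count, then k-fold convolution = sum of counts
        pmf = np.bincount(dens, minlength=w + 1) / dens.size
        total = pmf.copy()
        for _ in range(k - 1):
            total = np.convolve(total, pmf)
        cdf = np.cumsum(total)
        q95_count = np.searchsorted(cdf, 0.95)
        exact_p95 = q95_count / (k * w)
        assert dist.p95 == pytest.approx(exact_p95, abs=0.02)

    def test_seed_determinism_and_replacement_flag(self):
        trials = _trials()
        m = np.zeros(trials.n_samples)
        m[:: 7] = 1
        a = shuffle_baseline(_train(m), trials, seed=5)
        b = shuffle_baseline(_train(m), trials, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = shuffle_baseline(_train(m), trials, seed=5, with_replacement=False)
        assert c.samples.shape == a.samples.shape


class TestClassification:
    def test_events_only_during_us_modulated(self):
        trials = _trials()
        m = np.zeros(trials.n_samples)
        for onset in trials.us_onsets:
            i = int(onset * FS)
            m[i : i + 10] = 1
        train = _train(m)
        dist = shuffle_baseline(train, trials, seed=1)
        res = classify_modulation(train, trials, 40.0, dist)
        assert res.modulated and not res.excluded_preus
        assert res.p95 == 0.0 and res.observed_us_density == 0.5

    def test_events_only_pre_us_excluded(self):
        trials = _trials()
        m = np.zeros(trials.n_samples)
        for onset in trials.us_onsets:
            i = int(onset * FS)
            m[i - 20 : i] = 1
        train = _train(m)
        dist = shuffle_baseline(train, trials, seed=1)
        res = classify_modulation(train, trials, 40.0, dist)
        assert res.excluded_preus and not res.modulated

    def test_no_trials_of_prf_errors(self):
        trials = _trials()
        train = _train(np.zeros(trials.n_samples))
        dist = shuffle_baseline(train, trials, seed=1)
        with pytest.raises(ValueError):
            classify_modulation(train, trials, 999.0, dist)


class TestResponseSignificance:
    @pytest.mark.parametrize("obs,p95,expected", [
        (0.2, 0.2, 0.0),
        (0.4, 0.2, 1.0),
        (0.3, 0.2, pytest.approx(0.5)),
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, obs, p95, expected):
        assert response_significance(obs, p95) == expected

    def test_infinite_sentinel_and_errors(self):
        assert np.isinf(response_significance(0.3, 0.0))
        with pytest.raises(ValueError):
            response_significance(-0.1, 0.2)


class TestSpecificity:
    def _res(self, prf, mod):
        return ModulationResult(
            neuron=0, prf=prf, observed_us_density=0.1,
            observed_pre_density=0.0, p95=0.05, modulated=mod,
            excluded_preus=False, significance=1.0,
        )

    @pytest.mark.parametrize("flags,cls", [
        ((True, False, False), "specific"),
        ((True, True, False), "non_specific"),
        ((False, False, False), "non_responder"),
    ])
    def test_classes(self, flags, cls):
        results = [self._res(prf, f) for prf, f in zip((10.0, 40.0, 140.0), flags)]
        assert classify_specificity(results).cls == cls

    def test_needs_two_prfs(self):
        with pytest.raises(ValueError):
            classify_specificity([self._res(10.0, True)])


class TestProportionReport:
    def test_printed_percentage_arithmetic(self):
        assert percentage(162, 861) == 18.82
        assert percentage(0, 100) == 0.00
        assert percentage(87, 1915) == 4.54

    def test_report_groups(self):
        table = pd.DataFrame({
            "prf": [10.0] * 861,
            "modulated": [True] * 162 + [False] * (861 - 162),
        })
        rep = proportion_report(table)
        assert rep.loc[0, "n_modulated"] == 162
        assert rep.loc[0, "percentage"] == 18.82

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            proportion_report(pd.DataFrame(columns=["prf", "modulated"]))

    def test_modulation_table_roundtrip(self):
        res = ModulationResult(3, 40.0, 0.2, 0.0, 0.1, True, False, 1.0)
        df = modulation_table([res])
        assert df.loc[0, "neuron"] == 3 and bool(df.loc[0, "modulated"])
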