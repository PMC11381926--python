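"""Generator correctness: determinism, point-process statistics, protocol
structure, movie round trips, UMI matrices, and the intensity formulas."""

import numpy as np
import pytest
from scipy import stats

import usprf
from usprf import (
    MovieLayout,
    SessionConfig,
    extract_trace,
    generate_movie,
    generate_session,
    generate_sham_session,
    generate_umi_matrix,
    isppa,
    ispta,
)
from usprf.session import ConfigurationError
from usprf.simulate import (
    GeneSpec,
    LayoutError,
    PopulationExpression,
    planted_cliffs_delta,
)


class TestSessionGeneration:
    def test_seed_determinism(self):
        cfg = SessionConfig(n_neurons=4, n_trials_or_blocks=3, seed=7)
        a, _, _ = generate_session(cfg)
        b, _, _ = generate_session(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_trial_structure_alternating(self):
        cfg = SessionConfig(n_trials_or_blocks=5, seed=3, n_neurons=2)
        _, trials, _ = generate_session(cfg)
        assert trials.n_trials == 15
        # every block holds each PRF exactly once
        prfs = trials.prf_per_trial.reshape(5, 3)
        for block in prfs:
            assert sorted(block) == [10.0, 40.0, 140.0]
        assert np.all(np.diff(trials.us_onsets) > 0)
        np.testing.assert_allclose(trials.us_onsets[0], cfg.pre_s)

    def test_no_evoked_events_without_modulation(self):
        """With p_evoked=0 the event process near onsets is pure baseline."""
        cfg = SessionConfig(
            protocol="single_prf", prf_set=(40.0,), n_trials_or_blocks=10,
            post_s=19.0, n_neurons=200, frac_modulated=0.0, p_evoked=0.0,
            noise_sd=0.0, seed=5,
        )
        _, trials, truth = generate_session(cfg)
        assert np.all(~np.isfinite(truth.preferred_prf))
        n_near = 0
        n_total = 0
        for times in truth.event_times:
            n_total += times.size
            for onset in trials.us_onsets:
                n_near += int(np.sum((times >= onset) & (times < onset + 0.3)))
        # Poisson expectation for the 0.3 s windows
        frac_window = trials.n_trials * 0.3 / trials.session_duration_s
        expected = n_total * frac_window
        assert abs(n_near - expected) < 4 * np.sqrt(expected) + 5
        # empirical rate matches baseline_rate
        rate = n_total / cfg.n_neurons / trials.session_duration_s * 60
        assert rate == pytest.approx(cfg.baseline_rate, abs=0.1)

    def test_interevent_intervals_exponential(self):
        """KS test of ground-truth inter-event intervals vs Exp(rate)."""
        cfg = SessionConfig(
            protocol="single_prf", prf_set=(40.0,), n_trials_or_blocks=20,
            post_s=39.0, n_neurons=60, frac_modulated=0.0, seed=9,
        )
        _, _, truth = generate_session(cfg)
        iei = np.concatenate([np.diff(t) for t in truth.event_times if t.size > 1])
        assert iei.size >= 1000
        scale = 60.0 / cfg.baseline_rate
        _, p = stats.kstest(iei, "expon", args=(0, scale))
        assert p > 0.01

    def test_sham_flags_false_and_no_population_transient(self):
        cfg = SessionConfig(n_neurons=120, n_trials_or_blocks=8, seed=21)
        traces, trials, truth = generate_sham_session(cfg)
        assert all(not f.any() for f in truth.modulated.values())
        # population mean aligned to onset shows no transient above 2 SD of
        # its own pre-US baseline
        more = [generate_sham_session(
            SessionConfig(n_neurons=120, n_trials_or_blocks=8, seed=22 + k))[0]
            for k in range(4)]
        fs = int(trials.fs)
        segs = []
        for tm in [traces] + more:
            # skip the first trial: the session starts with no event tails,
            # which biases that trial's baseline low
            for onset in trials.us_onsets[1:]:
                i = int(round(onset * fs))
                segs.append(tm.values[:, i - 10 * fs : i + 5 * fs])
        pop = np.concatenate(segs, axis=0).mean(axis=0)
        base = pop[: 10 * fs]
        # 1 s bin averages post-onset: an evoked transient would lift the
        # US bin by ~10x this band, pure noise wiggle stays inside it
        post_bins = pop[10 * fs :].reshape(5, fs).mean(axis=1)
        assert np.all(post_bins < base.mean() + 2 * base.std())

    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(protocol="single_prf", prf_set=(10.0, 40.0))
        with pytest.raises(ConfigurationError):
            SessionConfig(prf_set=())
        with pytest.raises(ConfigurationError):
            SessionConfig(frac_modulated=1.2)
        with pytest.raises(ConfigurationError):
            SessionConfig(pre_s=-1.0)
        with pytest.raises(ConfigurationError):
            SessionConfig(frac_modulated=0.5)  # 3 PRFs x 0.5 > 1


class TestMovies:
    def test_single_roi_roundtrip_identity(self, small_session):
        _, traces, _, _ = small_session
        one = usprf.TraceMatrix(values=traces.values[:1, :400], fs=20.0, stage="dff")
        movie, rois = generate_movie(one, MovieLayout(height=64, width=64, radius_px=3))
        got = extract_trace(movie, rois)
        # identical up to a constant offset
        diff = got.values[0] - one.values[0]
        np.testing.assert_allclose(diff, diff[0] * np.ones_like(diff), atol=1e-9)

    def test_uniform_background_drift_removed(self):
        flat = usprf.TraceMatrix(values=np.zeros((1, 300)), fs=20.0, stage="dff")
        layout = MovieLayout(height=64, width=64, radius_px=3, background_amp=25.0)
        movie, rois = generate_movie(flat, layout)
        got = extract_trace(movie, rois)
        np.testing.assert_allclose(got.values[0], 0.0, atol=1e-9)

    def test_two_rois_recovered(self, small_session):
        _, traces, _, _ = small_session
        two = usprf.TraceMatrix(values=traces.values[:2, :600], fs=20.0, stage="dff")
        layout = MovieLayout(height=96, width=96, radius_px=3,
                             background_amp=10.0, pixel_noise_sd=0.02, seed=4)
        movie, rois = generate_movie(two, layout)
        got = extract_trace(movie, rois)
        for k in range(2):
            r = np.corrcoef(got.values[k], two.values[k])[0, 1]
            assert r > 0.99

    def test_overlapping_rois_raise(self):
        tm = usprf.TraceMatrix(values=np.zeros((2, 50)), fs=20.0)
        layout = MovieLayout(height=64, width=64, radius_px=5,
                             centroids=np.array([[20.0, 20.0], [20.0, 26.0]]))
        with pytest.raises(LayoutError):
            generate_movie(tm, layout)


class TestUMIMatrix:
    GENES = [GeneSpec("gA", {
        "pv": PopulationExpression(0.34, nb_mean=4.0, nb_disp=2.0),
        "glut": PopulationExpression(0.15, nb_mean=4.0, nb_disp=2.0),
    })]

    def test_identical_populations_delta_near_zero(self):
        genes = [GeneSpec("g", {
            "a": PopulationExpression(0.5, 3.0, 2.0),
            "b": PopulationExpression(0.5, 3.0, 2.0),
        })]
        counts, labels = generate_umi_matrix({"a": 3000, "b": 3000}, genes, seed=1)
        xa = counts.loc[labels == "a", "g"]
        xb = counts.loc[labels == "b", "g"]
        d = usprf.cliffs_delta(xa[xa > 0], xb[xb > 0])
        assert abs(d) < 0.03

    def test_planted_delta_recovered_vs_analytic_oracle(self):
        a = PopulationExpression(0.5, nb_mean=6.0, nb_disp=3.0)
        b = PopulationExpression(0.5, nb_mean=4.0, nb_disp=3.0)
        target = planted_cliffs_delta(a, b)
        assert 0.1 < target < 0.4  # a genuine planted shift
        genes = [GeneSpec("g", {"a": a, "b": b})]
        counts, labels = generate_umi_matrix({"a": 5000, "b": 5000}, genes, seed=2)
        xa = counts.loc[labels == "a", "g"]
        xb = counts.loc[labels == "b", "g"]
        d = usprf.cliffs_delta(xa[xa > 0], xb[xb > 0])
        assert d == pytest.approx(target, abs=0.03)

    def test_nonzero_fractions_recovered(self):
        counts, labels = generate_umi_matrix(
            {"pv": 4000, "glut": 4000}, self.GENES, seed=3)
        f_pv = float((counts.loc[labels == "pv", "gA"] > 0).mean())
        f_gl = float((counts.loc[labels == "glut", "gA"] > 0).mean())
        assert f_pv == pytest.approx(0.34, abs=3 * np.sqrt(0.34 * 0.66 / 4000))
        assert f_gl == pytest.approx(0.15, abs=3 * np.sqrt(0.15 * 0.85 / 4000))

    def test_cell_totals_positive_and_deterministic(self):
        c1, _ = generate_umi_matrix({"a": 50, "b": 50}, self.GENES_AB, seed=5)
        c2, _ = generate_umi_matrix({"a": 50, "b": 50}, self.GENES_AB, seed=5)
        assert (c1.sum(axis=1) > 0).all()
        assert c1.equals(c2)

    GENES_AB = [GeneSpec("gA", {
        "a": PopulationExpression(0.3), "b": PopulationExpression(0.3)})]


class TestAcousticIntensity:
    def test_zero_pressure(self):
        assert isppa(0.0) == 0.0

    def test_hand_evaluated_closed_form(self):
        # 522 kPa in water: (522e3)^2 / (2 * 1.5e6) = 90828 W/m^2 = 9.08 W/cm^2
        assert isppa(522e3) == pytest.approx(9.0828, abs=1e-4)

    def test_duty_cycle_scaling(self):
        assert ispta(10.0, 0.20) == pytest.approx(2.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            isppa(1.0, 0.0)
        with pytest.raises(ValueError):
            isppa(-1.0)
        with pytest.raises(ValueError):
            ispta(1.0, 1.5)
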