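"""Step fitting, melting-event detection, on-rate estimation, alignment."""

import numpy as np
import pytest

import procswitch as ps
from procswitch.steps import InsufficientDataError, Step

from conftest import make_trace


def _step(time, size, before=0.0):
    return Step(time=time, size=size, plateau_before=before,
                plateau_after=before + size, fit_quality=2.0)


class TestDetectSteps:
    def test_clean_staircase_exact(self):
        y = np.zeros(300)
        y[100:] += 1
        y[200:] += 1
        steps = ps.detect_steps(make_trace(y))
        assert len(steps) == 2
        assert [s.size for s in steps] == pytest.approx([1.0, 1.0])
        assert [s.time for s in steps] == pytest.approx(
            [100 / 89.0, 200 / 89.0])

    def test_noisy_staircase_recovery(self):
        """>= 90% of injected 1 bp steps found within +-2 samples at
        0.3 bp r.m.s. noise."""
        rng = np.random.default_rng(1)
        n = 1800
        t = np.arange(n) / 89.0
        true_times = np.arange(1.0, 19.0)
        y = np.searchsorted(true_times, t, side="right") \
            + rng.normal(0, 0.3, n)
        steps = ps.detect_steps(make_trace(y))
        det = np.array([s.time for s in steps if s.size > 0])
        recovered = sum(np.any(np.abs(det - q) <= 2 / 89.0)
                        for q in true_times)
        assert recovered >= 0.9 * len(true_times)

    def test_flat_noise_yields_no_steps(self):
        rng = np.random.default_rng(0)
        assert ps.detect_steps(make_trace(rng.normal(0, 0.3, 500))) == []

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        y = np.searchsorted([1.0, 2.0, 3.0], np.arange(600) / 89.0,
                            side="right") + rng.normal(0, 0.2, 600)
        a = ps.detect_steps(make_trace(y))
        b = ps.detect_steps(make_trace(y + 7.5))
        assert [s.time for s in a] == [s.time for s in b]
        assert [s.size for s in a] == pytest.approx([s.size for s in b])
        assert [s.plateau_before + 7.5 for s in a] == pytest.approx(
            [s.plateau_before for s in b], abs=1e-9)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            ps.detect_steps(make_trace([0.0, 1.0]))


class TestMeltPairing:
    def test_pair_within_window(self):
        steps = [_step(1.0, 5.0), _step(1.03, -5.0, before=5.0)]
        events, rest = ps.detect_melt_events_during_unwinding(steps, 89.0)
        assert len(events) == 1 and rest == []
        assert events[0].t_melt == 1.0
        assert events[0].amplitude == 5.0

    def test_separation_beyond_window(self):
        steps = [_step(1.0, 5.0), _step(1.2, -5.0)]
        events, rest = ps.detect_melt_events_during_unwinding(steps, 89.0)
        assert events == [] and len(rest) == 2

    def test_amplitude_boundary(self):
        steps = [_step(1.0, 1.0), _step(1.02, -1.0)]
        events, rest = ps.detect_melt_events_during_unwinding(steps, 89.0)
        assert events == [] and len(rest) == 2

    def test_first_match_tie_break(self):
        steps = [_step(1.0, 3.0), _step(1.02, 3.0), _step(1.04, -3.0)]
        events, rest = ps.detect_melt_events_during_unwinding(steps, 89.0)
        # chain resolves by pairing the earliest qualifying forward step:
        # here step 2 (+3) pairs with step 3 (-3); step 1 has no partner
        assert len(events) == 1 and len(rest) == 1
        assert rest[0].time == 1.0


class TestBareMeltDetection:
    def test_flat_trace(self):
        assert ps.detect_melt_events_bare(make_trace(np.zeros(500))) == []

    def test_injected_pulse_recovery(self):
        """>= 90% of resolvable injected 5 bp pulses recovered at
        0.3 bp noise (pulses shorter than one sample leave no trace)."""
        melt = ps.MeltingParams(concentration=10e-9)
        trace, log = ps.simulate_bare_hairpin(melt, duration=300.0,
                                              noise_sd=0.3, seed=4)
        events = ps.detect_melt_events_bare(trace)
        resolvable = log.melt_events[log.melt_events["resolvable"]]
        det_times = np.array([e.t_melt for e in events])
        dt = trace.dt
        hit = sum(np.any(np.abs(det_times - t0) <= 2 * dt)
                  for t0 in resolvable["t_start_s"])
        assert hit >= 0.9 * len(resolvable)

    def test_small_amplitude_rejected(self):
        y = np.zeros(500)
        y[200:203] = 3.0          # below the 4 bp criterion
        assert ps.detect_melt_events_bare(make_trace(y)) == []

    def test_long_lived_excursion_rejected(self):
        y = np.zeros(500)
        y[100:200] = 6.0          # 1.1 s >> max lifetime
        assert ps.detect_melt_events_bare(make_trace(y)) == []


class TestKonEstimate:
    def test_exact_arithmetic(self):
        events = [ps.MeltEvent(t_melt=float(i), t_anneal=i + 0.02,
                               amplitude=5.0, baseline_position=0.0)
                  for i in range(10)]
        est = ps.estimate_kon(events, 10e-9)
        assert est.k_on == pytest.approx(1e8)

    def test_insufficient_events(self):
        with pytest.raises(InsufficientDataError) as err:
            ps.estimate_kon([], 10e-9)
        assert err.value.n_events == 0

    def test_concentration_invariance(self):
        """Doubling concentration halves the mean gap: same k_on."""
        rng = np.random.default_rng(0)
        for conc, lam in ((10e-9, 1.2), (20e-9, 2.4)):
            gaps = rng.exponential(1 / lam, 2000)
            times = np.cumsum(gaps)
            events = [ps.MeltEvent(t_melt=t, t_anneal=t + 0.02,
                                   amplitude=5.0, baseline_position=0.0)
                      for t in times]
            est = ps.estimate_kon(events, conc)
            assert est.k_on == pytest.approx(1.2e8, rel=0.1)

    def test_recovery_from_simulation(self):
        """Corrected estimate within 2 s.e. of the generating on-rate."""
        melt = ps.MeltingParams(concentration=10e-9)
        trace, _ = ps.simulate_bare_hairpin(melt, duration=500.0,
                                            noise_sd=0.3, seed=1)
        events = ps.detect_melt_events_bare(trace)
        est = ps.estimate_kon(events, 10e-9, sampling_interval=trace.dt)
        assert abs(est.k_on - 1.2e8) < 2 * est.se


class TestClassifySteps:
    def test_all_forward(self):
        cls = ps.classify_steps([_step(i * 0.1, 1.0) for i in range(5)])
        assert cls.fractions["forward"] == 1.0

    def test_constructed_fractions(self):
        sizes = [1.0, 1.0, -1.0, -3.0]
        cls = ps.classify_steps(
            [_step(i * 0.1, s) for i, s in enumerate(sizes)])
        assert cls.fractions == {"forward": 0.5, "backstep": 0.25,
                                 "backslide": 0.25}

    def test_release_recapture_pairs_flagged(self):
        steps = [_step(0.0, 1.0), _step(0.1, -5.0), _step(0.15, 5.0)]
        cls = ps.classify_steps(steps)
        assert cls.n_release_recapture_pairs == 1

    def test_generator_step_mix_recovered(self):
        """Injected step-type fractions match the configured mix."""
        rates = ps.KineticRates(k1=0.02, k_minus1=0.18, k2=0.17, k_off=0.037)
        all_steps = []
        for seed in range(40):
            _, log = ps.simulate_trace(
                rates, melting=ps.MeltingParams(concentration=0.0),
                duration=120.0, noise_sd=0.0, seed=seed)
            sub = log.steps[~log.steps["kind"].isin(
                ["release", "recapture"])]
            all_steps.extend(_step(r.time_s, r.size_bp)
                             for r in sub.itertuples())
        cls = ps.classify_steps(all_steps)
        assert cls.fractions["backstep"] == pytest.approx(0.20, abs=0.04)
        assert cls.fractions["backslide"] == pytest.approx(0.18, abs=0.05)

    def test_empty(self):
        cls = ps.classify_steps([])
        assert cls.n_steps == 0


class TestMeltFrequencyVsConcentration:
    def test_linear_in_concentration(self):
        """Detected melt frequency on bare traces rises linearly with
        concentration (R^2 > 0.9 over four concentrations)."""
        concs = np.array([2.0, 5.0, 10.0, 20.0])   # nM
        freqs = []
        for conc in concs:
            trace, _ = ps.simulate_bare_hairpin(
                ps.MeltingParams(concentration=conc * 1e-9),
                duration=300.0, noise_sd=0.3, seed=int(conc))
            freqs.append(len(ps.detect_melt_events_bare(trace)) / 300.0)
        slope, intercept = np.polyfit(concs, freqs, 1)
        fitted = slope * concs + intercept
        ss_res = np.sum((freqs - fitted) ** 2)
        ss_tot = np.sum((freqs - np.mean(freqs)) ** 2)
        assert slope > 0
        assert 1 - ss_res / ss_tot > 0.9

    def test_no_false_positives_without_protein(self):
        trace, _ = ps.simulate_bare_hairpin(
            ps.MeltingParams(concentration=0.0), duration=300.0,
            noise_sd=0.3, seed=9)
        zero = len(ps.detect_melt_events_bare(trace))
        trace10, _ = ps.simulate_bare_hairpin(
            ps.MeltingParams(concentration=10e-9), duration=300.0,
            noise_sd=0.3, seed=9)
        assert zero < len(ps.detect_melt_events_bare(trace10))


class TestAlignment:
    def test_single_event_at_origin(self):
        y = np.zeros(200)
        y[100:102] = 5.0
        trace = make_trace(y)
        ev = ps.MeltEvent(t_melt=100 / 89.0, t_anneal=102 / 89.0,
                          amplitude=5.0, baseline_position=0.0)
        before, after = ps.align_events(trace, [ev], window=0.1)
        # the melting transition sits at (t=0, x=0) by construction
        i = np.argmin(np.abs(before[:, 0] - (-trace.dt)))
        assert before[i, 1] == pytest.approx(0.0)

    def test_identical_events_coincide(self):
        y = np.zeros(2000)
        centers = [300, 800, 1300]
        for c in centers:
            y[c:c + 2] = 5.0
        trace = make_trace(y)
        events = [ps.MeltEvent(t_melt=c / 89.0, t_anneal=(c + 2) / 89.0,
                               amplitude=5.0, baseline_position=0.0)
                  for c in centers]
        before, _ = ps.align_events(trace, events, window=0.1)
        # noiseless identical events: clouds overlap exactly
        for tau in np.unique(np.round(before[:, 0], 9)):
            vals = before[np.isclose(before[:, 0], tau), 1]
            assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_stationary_motor_returns_to_baseline(self):
        """With no enzyme motion, the post-anneal modal position equals the
        pre-melt position."""
        trace, log = ps.simulate_bare_hairpin(
            ps.MeltingParams(concentration=10e-9), duration=200.0,
            noise_sd=0.2, seed=6)
        events = ps.detect_melt_events_bare(trace)[:50]
        before, after = ps.align_events(trace, events, window=0.1)
        post = after[after[:, 0] > 0, 1]
        hist, edges = np.histogram(post, bins=np.arange(-3, 8.5, 0.5))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(mode) < 1.0

    def test_random_control_runs(self):
        trace, _ = ps.simulate_bare_hairpin(
            ps.MeltingParams(concentration=10e-9), duration=100.0,
            noise_sd=0.2, seed=6)
        before, after = ps.align_random_control(trace, 20, seed=0)
        assert before.shape[1] == 2 and len(before) > 0


class TestKde2d:
    def test_normalisation_and_positivity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 2))
        t_ax, x_ax, dens = ps.kde2d(pts)
        cell = (t_ax[1] - t_ax[0]) * (x_ax[1] - x_ax[0])
        assert dens.min() >= 0
        assert dens.sum() * cell == pytest.approx(1.0, abs=1e-3)

    def test_single_point_peak(self):
        t_ax, x_ax, dens = ps.kde2d(np.array([[0.5, 2.0]]),
                                    bandwidth=(0.1, 0.5))
        ix, it = np.unravel_index(np.argmax(dens), dens.shape)
        assert t_ax[it] == pytest.approx(0.5, abs=0.05)
        assert x_ax[ix] == pytest.approx(2.0, abs=0.25)

    def test_two_points_symmetric_bimodal(self):
        pts = np.array([[-1.0, 0.0], [1.0, 0.0]])
        t_ax, x_ax, dens = ps.kde2d(pts, bandwidth=(0.3, 0.3),
                                    extent=(-2, 2, -1, 1))
        marg = dens.sum(axis=0)
        assert np.allclose(marg, marg[::-1], rtol=1e-8)
        mid = len(marg) // 2
        assert marg[mid] < marg[np.argmax(marg)]

    def test_matches_histogram(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10000, 2))
        t_ax, x_ax, dens = ps.kde2d(pts, bandwidth=(0.15, 0.15),
                                    grid_shape=(120, 120),
                                    extent=(-4, 4, -4, 4))
        # coarse-bin comparison against the empirical histogram
        hist, ex, ey = np.histogram2d(pts[:, 0], pts[:, 1],
                                      bins=8, range=[[-4, 4], [-4, 4]],
                                      density=True)
        cell_t = t_ax[1] - t_ax[0]
        for i in range(8):
            for j in range(8):
                sel_t = (t_ax >= ex[i]) & (t_ax < ex[i + 1])
                sel_x = (x_ax >= ey[j]) & (x_ax < ey[j + 1])
                approx = dens[np.ix_(sel_x, sel_t)].mean()
                assert approx == pytest.approx(hist[i, j], abs=0.02)
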