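import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somsnn import snn
from somsnn.snn import (ClassifierConfig, KernelParams, TempotronNeuron,
                        Trace, classify, evaluate_early_decision, find_t_max,
                        init_neurons, make_kernel, membrane_trace, psp_kernel,
                        tempotron_update, train_one_vs_all, truncate_pattern)
from somsnn.som import SpikePattern
from somsnn.synthetic_data import default_spike_specs, generate_spike_dataset

from conftest import random_spike_pattern

RWCP_KERNEL = make_kernel(750.0, 187.5)


def neuron(weights, kernel=RWCP_KERNEL, **kw):
    return TempotronNeuron(weights=np.asarray(weights, dtype=float),
                           kernel=kernel, **kw)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_trace(weights, kernel, pattern, dt, v_rest=0.0):
    """Double loop over grid points and events; the reference for V(t)."""
    t_end = pattern.duration_ms + 3.0 * kernel.tau_m
    grid = np.arange(int(math.floor(t_end / dt)) + 1) * dt
    v = np.full(grid.size, v_rest)
    for i, t in enumerate(grid):
        for u, tj in pattern.events:
            if tj < t:
                v[i] += weights[u] * kernel.k0 * (
                    math.exp(-(t - tj) / kernel.tau_m)
                    - math.exp(-(t - tj) / kernel.tau_s))
    return grid, v


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

class TestKernel:
    def test_normalization_at_peak(self):
        k = RWCP_KERNEL
        assert psp_kernel(k, k.t_peak) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_t_peak(self):
        k = make_kernel(2.0, 1.0)
        assert k.t_peak == pytest.approx(2.0 * math.log(2.0), rel=1e-14)

    def test_grid_search_matches_closed_form(self):
        k = RWCP_KERNEL
        grid = np.arange(0.0, 5000.0, 0.01)
        vals = psp_kernel(k, grid)
        i = int(np.argmax(vals))
        assert vals[i] == pytest.approx(1.0, abs=1e-6)
        assert grid[i] == pytest.approx(k.t_peak, abs=0.01)

    def test_frozen_high_precision_value(self):
        # K(100 ms) for tau_m=750, tau_s=187.5, from a 30-digit
        # arbitrary-precision evaluation of the closed form
        assert psp_kernel(RWCP_KERNEL, 100.0) == pytest.approx(
            0.610677628426511651547070646336, abs=1e-12)

    def test_causality_and_zero_at_origin(self):
        assert psp_kernel(RWCP_KERNEL, -5.0) == 0.0
        assert psp_kernel(RWCP_KERNEL, 0.0) == 0.0

    def test_bounds_and_unique_maximum(self):
        grid = np.arange(-100.0, 6000.0, 0.5)
        vals = psp_kernel(RWCP_KERNEL, grid)
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)
        peak_region = np.nonzero(vals > 1.0 - 1e-9)[0]
        assert np.all(np.diff(peak_region) == 1)  # single contiguous peak

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            make_kernel(1.0, 2.0)
        with pytest.raises(ValueError):
            make_kernel(2.0, 2.0)


# ---------------------------------------------------------------------------
# Membrane dynamics
# ---------------------------------------------------------------------------

class TestMembraneTrace:
    def test_zero_weights_stay_at_rest(self, rng):
        p = random_spike_pattern(rng)
        trace = membrane_trace(neuron(np.zeros(p.n_units)), p,
                               effective_thr=1.0)
        assert np.all(trace.v == 0.0)
        assert not trace.fired

    def test_single_event_peak_is_linear_in_weight(self):
        p = SpikePattern(events=[(0, 0.0)], duration_ms=100.0, n_units=1)
        trace = membrane_trace(neuron([0.5]), p, dt=0.5, effective_thr=None)
        t_max, v_max = find_t_max(trace)
        assert v_max == pytest.approx(0.5, abs=1e-4)
        assert t_max == pytest.approx(RWCP_KERNEL.t_peak, abs=0.5)
        trace2 = membrane_trace(neuron([1.0]), p, dt=0.5, effective_thr=None)
        np.testing.assert_allclose(trace2.v, 2.0 * trace.v, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_matches_naive_double_loop(self, seed):
        r = np.random.default_rng(seed)
        p = random_spike_pattern(r, n_units=r.integers(1, 10),
                                 n_events=r.integers(0, 50),
                                 duration_ms=float(r.uniform(50, 400)))
        w = r.standard_normal(p.n_units)
        trace = membrane_trace(neuron(w), p, dt=1.0, effective_thr=None)
        grid, v_ref = naive_trace(w, RWCP_KERNEL, p, dt=1.0)
        np.testing.assert_allclose(trace.v, v_ref, atol=1e-9)
        np.testing.assert_array_equal(trace.times, grid)

    def test_linearity_of_event_union(self, rng):
        p1 = random_spike_pattern(rng, n_units=6, n_events=10, duration_ms=300.0)
        p2 = random_spike_pattern(rng, n_units=6, n_events=8, duration_ms=300.0)
        union_events = sorted(p1.events + p2.events, key=lambda e: e[1])
        union = SpikePattern(events=union_events, duration_ms=300.0, n_units=6)
        w = rng.standard_normal(6)
        t_u = membrane_trace(neuron(w), union, effective_thr=None)
        t_1 = membrane_trace(neuron(w), p1, effective_thr=None)
        t_2 = membrane_trace(neuron(w), p2, effective_thr=None)
        np.testing.assert_allclose(t_u.v, t_1.v + t_2.v, atol=1e-9)

    def test_shunting_drops_post_spike_events(self):
        # strong early drive guarantees a spike; the late event must not
        # appear in the shunted trace
        p = SpikePattern(events=[(0, 0.0), (1, 400.0)], duration_ms=500.0,
                         n_units=2)
        n = neuron([5.0, 5.0])
        shunted = membrane_trace(n, p, effective_thr=1.0, shunt_after_spike=True)
        assert shunted.fired and shunted.spike_time < 400.0
        early_only = SpikePattern(events=[(0, 0.0)], duration_ms=500.0, n_units=2)
        reference = membrane_trace(n, early_only, effective_thr=None)
        np.testing.assert_allclose(shunted.v, reference.v, atol=1e-12)

    def test_unit_out_of_range_rejected(self):
        p = SpikePattern(events=[(3, 1.0)], duration_ms=10.0, n_units=4)
        with pytest.raises(ValueError):
            membrane_trace(neuron([1.0, 1.0]), p)

    def test_dt_convergence(self, rng):
        p = random_spike_pattern(rng, n_units=5, n_events=15, duration_ms=400.0)
        w = rng.standard_normal(5)
        peak1 = np.max(membrane_trace(neuron(w), p, dt=1.0,
                                      effective_thr=None).v)
        peak2 = np.max(membrane_trace(neuron(w), p, dt=0.5,
                                      effective_thr=None).v)
        assert abs(peak2 - peak1) / max(abs(peak2), 1e-12) < 0.01

    def test_translation_covariance(self, rng):
        p = random_spike_pattern(rng, n_units=4, n_events=12, duration_ms=300.0)
        w = np.abs(rng.standard_normal(4))
        shift = 50.0
        shifted = SpikePattern(events=[(u, t + shift) for u, t in p.events],
                               duration_ms=p.duration_ms + shift, n_units=4)
        t1, _ = find_t_max(membrane_trace(neuron(w), p, effective_thr=None))
        t2, _ = find_t_max(membrane_trace(neuron(w), shifted,
                                          effective_thr=None))
        assert t2 == pytest.approx(t1 + shift, abs=1e-9)


class TestFindTMax:
    def test_rising_trace_last_point(self):
        tr = Trace(times=np.arange(5.0), v=np.array([0., 1., 2., 3., 4.]),
                   spike_time=None)
        assert find_t_max(tr) == (4.0, 4.0)

    def test_flat_trace_earliest_tie(self):
        tr = Trace(times=np.arange(5.0), v=np.zeros(5), spike_time=None)
        assert find_t_max(tr) == (0.0, 0.0)

    def test_matches_linear_scan(self, rng):
        v = rng.standard_normal(100)
        tr = Trace(times=np.arange(100.0), v=v, spike_time=None)
        best, t_best = max(v), None
        for t, val in zip(tr.times, v):
            if val == best:
                t_best = t
                break
        assert find_t_max(tr) == (t_best, best)

    def test_spike_time_overrides_argmax(self):
        tr = Trace(times=np.arange(5.0), v=np.array([0., 3., 2., 9., 1.]),
                   spike_time=1.0)
        assert find_t_max(tr) == (1.0, 3.0)


# ---------------------------------------------------------------------------
# Maximum-Margin Tempotron updates
# ---------------------------------------------------------------------------

class TestTempotronUpdate:
    def test_confident_target_gets_zero_delta(self):
        p = SpikePattern(events=[(0, 0.0)], duration_ms=200.0, n_units=2)
        n = neuron([10.0, 0.0], margin=0.5)
        delta, err = tempotron_update(n, p, is_target=True, learning_rate=0.01)
        assert not err and np.all(delta == 0.0)

    def test_failed_target_potentiates_active_units_only(self, rng):
        p = SpikePattern(events=[(0, 10.0), (2, 50.0)], duration_ms=300.0,
                         n_units=4)
        # small sub-threshold weights so the potential peaks after the events
        n = neuron(np.full(4, 0.05), margin=0.5)
        delta, err = tempotron_update(n, p, is_target=True, learning_rate=0.01)
        assert err
        assert delta[0] > 0 and delta[2] > 0
        assert delta[1] == 0.0 and delta[3] == 0.0

    def test_deltas_match_brute_force_sum(self):
        p = SpikePattern(events=[(0, 10.0), (1, 40.0), (0, 80.0), (2, 120.0)],
                         duration_ms=300.0, n_units=3)
        n = neuron(np.full(3, 0.05), margin=0.5)
        lr = 0.01
        delta, err = tempotron_update(n, p, is_target=True, learning_rate=lr)
        assert err
        trace = membrane_trace(n, p, effective_thr=n.v_thr + n.margin)
        t_max, _ = find_t_max(trace)
        expected = np.zeros(3)
        for u, tj in p.events:
            if tj < t_max:
                expected[u] += lr * float(psp_kernel(RWCP_KERNEL, t_max - tj))
        np.testing.assert_allclose(delta, expected, atol=1e-15)

    def test_firing_nontarget_depressed_at_spike_time(self):
        p = SpikePattern(events=[(0, 0.0), (1, 300.0)], duration_ms=400.0,
                         n_units=2)
        n = neuron([5.0, 5.0], margin=0.5)
        delta, err = tempotron_update(n, p, is_target=False, learning_rate=0.01)
        assert err
        assert delta[0] < 0
        # the late event falls after the (early) erroneous spike: untouched
        assert delta[1] == 0.0


# ---------------------------------------------------------------------------
# One-vs-all training and the margin-zero reduction
# ---------------------------------------------------------------------------

def disjoint_two_class_patterns():
    """Two classes driving disjoint unit subsets: linearly separable."""
    patterns = []
    for rep in range(3):
        ev_a = [(u, 50.0 * i) for i, u in enumerate([0, 1, 0, 1, 2])]
        ev_b = [(u, 50.0 * i) for i, u in enumerate([5, 6, 5, 7, 6])]
        patterns.append(SpikePattern(events=ev_a, duration_ms=250.0,
                                     n_units=8, label=0))
        patterns.append(SpikePattern(events=ev_b, duration_ms=250.0,
                                     n_units=8, label=1))
    return patterns


class TestTraining:
    def test_separable_classes_reach_zero_errors(self):
        patterns = disjoint_two_class_patterns()
        # few samples, so a larger step than the full-corpus default
        cfg = ClassifierConfig(epochs=10, learning_rate=0.1, seed=0)
        _, errors = train_one_vs_all(patterns, 2, cfg)
        assert errors[-1] == 0

    def test_single_sample_fires_above_margin(self):
        p = SpikePattern(events=[(0, 0.0), (1, 50.0)], duration_ms=100.0,
                         n_units=2, label=0)
        cfg = ClassifierConfig(epochs=60, learning_rate=0.05, seed=1)
        neurons, _ = train_one_vs_all([p], 1, cfg)
        trace = membrane_trace(neurons[0], p,
                               effective_thr=neurons[0].v_thr + neurons[0].margin)
        assert trace.fired

    def test_deterministic_given_seed(self):
        patterns = disjoint_two_class_patterns()
        cfg = ClassifierConfig(epochs=3, seed=5)
        n1, e1 = train_one_vs_all(patterns, 2, cfg)
        n2, e2 = train_one_vs_all(patterns, 2, cfg)
        assert e1 == e2
        for a, b in zip(n1, n2):
            assert np.array_equal(a.weights, b.weights)

    def test_empty_or_mislabeled_rejected(self):
        with pytest.raises(ValueError):
            train_one_vs_all([], 2, ClassifierConfig())
        bad = SpikePattern(events=[], duration_ms=10.0, n_units=2, label=5)
        with pytest.raises(ValueError):
            train_one_vs_all([bad], 2, ClassifierConfig())


def reference_standard_tempotron(patterns, n_classes, cfg, kernel, v_thr=1.0):
    """Plain Tempotron (no margin), written as explicit per-event loops."""
    rng = np.random.default_rng(cfg.seed)
    weights = [rng.normal(0.0, cfg.weight_init_sigma, patterns[0].n_units)
               for _ in range(n_classes)]
    order_rng = np.random.default_rng(cfg.seed + 1)
    epoch_errors = []
    for _ in range(cfg.epochs):
        errors = 0
        for i in order_rng.permutation(len(patterns)):
            p = patterns[i]
            for c in range(n_classes):
                n = TempotronNeuron(weights=weights[c], kernel=kernel,
                                    v_thr=v_thr, margin=0.0)
                trace = membrane_trace(n, p, dt=cfg.dt, shunt_after_spike=True,
                                       effective_thr=v_thr)
                is_target = (c == p.label)
                if is_target and not trace.fired:
                    sign = 1.0
                    t_max = float(trace.times[int(np.argmax(trace.v))])
                    ev_times = [tj for _, tj in p.events]
                    if ev_times and not any(tj < t_max for tj in ev_times):
                        sel = trace.times > min(ev_times)
                        t_max = float(
                            trace.times[sel][int(np.argmax(trace.v[sel]))])
                elif (not is_target) and trace.fired:
                    sign = -1.0
                    t_max = trace.spike_time
                else:
                    continue
                delta = np.zeros_like(weights[c])
                for u, tj in p.events:
                    if tj < t_max:
                        x = t_max - tj
                        k_val = kernel.k0 * (np.exp(-x / kernel.tau_m)
                                             - np.exp(-x / kernel.tau_s))
                        delta[u] += (sign * cfg.learning_rate) * k_val
                weights[c] = weights[c] + delta
                errors += 1
        epoch_errors.append(errors)
    return weights, epoch_errors


class TestMarginZeroReduction:
    def test_collapses_to_standard_tempotron(self):
        specs = default_spike_specs(n_classes=2, n_units=8, length=10,
                                    substitution_prob=0.1,
                                    warp_range=(0.8, 1.2))
        patterns = generate_spike_dataset(specs, n_per_class=5, seed=3)
        cfg = ClassifierConfig(epochs=5, seed=11)
        ours, our_errors = train_one_vs_all(patterns, 2, cfg,
                                            kernel=RWCP_KERNEL, margin=0.0)
        ref_w, ref_errors = reference_standard_tempotron(patterns, 2, cfg,
                                                         RWCP_KERNEL)
        assert our_errors == ref_errors
        for n, w in zip(ours, ref_w):
            assert np.array_equal(n.weights, w)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

class TestClassify:
    def test_all_zero_weights_pick_class_zero(self, rng):
        p = random_spike_pattern(rng, n_units=4)
        neurons = [neuron(np.zeros(4)) for _ in range(3)]
        d = classify(neurons, p)
        assert d.label == 0
        assert not any(d.fired)
        assert d.decision_time_ms == p.duration_ms

    def test_earliest_spike_wins(self):
        p = SpikePattern(events=[(0, 100.0), (1, 160.0)], duration_ms=300.0,
                         n_units=2)
        early = neuron([5.0, 0.0])
        late = neuron([0.0, 5.0])
        d = classify([late, early], p)
        assert d.label == 1           # 'early' sits at index 1 here
        assert d.fired == [True, True]
        assert d.decision_time_ms < 160.0 + RWCP_KERNEL.t_peak

    def test_single_firing_neuron_wins_regardless_of_peaks(self):
        p = SpikePattern(events=[(0, 0.0)], duration_ms=200.0, n_units=1)
        neurons = [neuron([0.9]), neuron([2.0])]
        d = classify(neurons, p)
        assert d.fired == [False, True]
        assert d.label == 1

    def test_no_spike_argmax_peak(self):
        p = SpikePattern(events=[(0, 0.0)], duration_ms=200.0, n_units=1)
        neurons = [neuron([0.3]), neuron([0.7]), neuron([0.5])]
        d = classify(neurons, p)
        assert not any(d.fired)
        assert d.label == 1
        assert d.peak_potentials == pytest.approx([0.3, 0.7, 0.5], abs=1e-3)


class TestEarlyDecision:
    def test_full_fraction_is_identity(self, rng):
        patterns = [random_spike_pattern(rng, n_units=4, label=0)
                    for _ in range(5)]
        neurons = [neuron(rng.standard_normal(4)) for _ in range(2)]
        accs, ratios = evaluate_early_decision(neurons, patterns, [1.0])
        plain = [classify(neurons, p).label for p in patterns]
        expected = 100.0 * sum(l == 0 for l in plain) / 5
        assert accs[1.0] == expected
        assert len(ratios) == 5
        assert all(0.0 < r <= 1.0 + 1e-12 for r in ratios)

    def test_tiny_fraction_falls_back_to_flat_trace_rule(self):
        p = SpikePattern(events=[(0, 100.0)], duration_ms=200.0, n_units=1,
                         label=0)
        truncated = truncate_pattern(p, 0.1)
        assert truncated.n_events == 0
        d = classify([neuron([5.0]), neuron([5.0])], truncated)
        assert d.label == 0 and not any(d.fired)

    def test_invalid_fraction_rejected(self, rng):
        p = random_spike_pattern(rng)
        with pytest.raises(ValueError):
            truncate_pattern(p, 0.0)


# ---------------------------------------------------------------------------
# ReSuMe variant
# ---------------------------------------------------------------------------

class TestResume:
    def test_desired_time_is_mean_of_t_max(self, rng):
        patterns = [random_spike_pattern(rng, n_units=6, n_events=12,
                                         duration_ms=400.0) for _ in range(5)]
        n = neuron(rng.standard_normal(6))
        expected = np.mean([
            find_t_max(membrane_trace(n, p, effective_thr=None))[0]
            for p in patterns])
        assert snn.resume_desired_time(n, patterns) == pytest.approx(expected)
        assert snn.resume_desired_time(n, patterns[:1]) == pytest.approx(
            find_t_max(membrane_trace(n, patterns[0], effective_thr=None))[0])

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError):
            snn.resume_desired_time(neuron(np.zeros(2)), [])

    def test_matched_spike_gives_zero_net_update(self):
        p = SpikePattern(events=[(0, 0.0)], duration_ms=200.0, n_units=1,
                         label=0)
        cfg = ClassifierConfig(epochs=1, seed=4)
        strong = neuron([5.0], margin=0.0)
        trace = membrane_trace(strong, p, effective_thr=strong.v_thr)
        assert trace.fired
        before = strong.weights.copy()
        neurons, errors = snn.resume_train([p], 1, [trace.spike_time], cfg,
                                           neurons=[strong])
        assert errors == [0]
        assert np.array_equal(neurons[0].weights, before)

    def test_silent_neuron_pure_potentiation(self):
        p = SpikePattern(events=[(0, 10.0), (1, 150.0)], duration_ms=200.0,
                         n_units=2, label=0)
        cfg = ClassifierConfig(epochs=1, seed=6)
        init_w = init_neurons(1, 2, RWCP_KERNEL, cfg, margin=0.0)[0].weights.copy()
        neurons, _ = snn.resume_train([p], 1, [100.0], cfg)
        # only unit 0 spikes before the desired time 100 ms
        assert neurons[0].weights[0] > init_w[0]
        assert neurons[0].weights[1] == init_w[1]

    def test_separable_toy_set_learns(self):
        specs = default_spike_specs(n_classes=2, n_units=12, length=12,
                                    substitution_prob=0.05,
                                    warp_range=(0.9, 1.1))
        train = generate_spike_dataset(specs, n_per_class=8, seed=5)
        # short patterns (600 ms), so the sharper speech-profile kernel
        kernel = make_kernel(225.0, 56.25)
        cfg = ClassifierConfig(epochs=20, learning_rate=0.05, seed=7)
        probe = init_neurons(2, 12, kernel, cfg)
        desired = [snn.resume_desired_time(probe[c],
                                           [p for p in train if p.label == c])
                   for c in range(2)]
        neurons, _ = snn.resume_train(train, 2, desired, cfg, kernel=kernel)
        assert snn.accuracy(neurons, train) >= 90.0


class TestSerialization:
    def test_classifier_roundtrip(self, tmp_path, rng):
        neurons = [neuron(rng.standard_normal(6)) for _ in range(3)]
        path = tmp_path / "clf.json"
        snn.save_classifier(path, neurons)
        back = snn.load_classifier(path)
        assert len(back) == 3
        for a, b in zip(neurons, back):
            assert np.array_equal(a.weights, b.weights)
            assert a.kernel == b.kernel
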