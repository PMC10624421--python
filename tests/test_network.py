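"""Circuit construction, membrane/synapse integration, decision readout,
and parameter-scheme sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cbgt.config import ConnectivitySpec, default_config
from cbgt.network import (
    INSTANCE_KEYS,
    NetworkState,
    build_network,
    categorize_rt,
    detect_decision,
    lhs_samples,
    nmda_mg_factor,
    sample_parameter_schemes,
    sliding_rate,
    step_neurons,
    step_synapses,
    synaptic_current,
    trial_firing_features,
)
from cbgt.sim import SimulatedSubject


def small_config(**kw):
    cfg = default_config()
    for p in cfg.populations:
        p.n_neurons = max(p.n_neurons // 4, 6)
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def quiet_state(net):
    return NetworkState(
        V=net.VL.copy(), h=np.full(net.n_neurons, 0.3),
        s_ampa=np.zeros(net.n_neurons), s_nmda=np.zeros(net.n_neurons),
        s_gaba=np.zeros(net.n_neurons), refractory=np.zeros(net.n_neurons),
    )


class TestBuild:
    def test_full_connectivity_yields_complete_bipartite(self):
        cfg = small_config(normalize_in_degree=False)
        for c in cfg.connections:
            if (c.source, c.target, c.receptor) == ("GPe", "STN", "GABA"):
                c.connection_probability = 1.0
        net = build_network(cfg, seed=0)
        s, d = net.slices["GPe_left"], net.slices["STN_left"]
        block = net.W["GABA"][d, s]
        assert np.count_nonzero(block) == (s.stop - s.start) * (d.stop - d.start)

    def test_zero_probability_yields_no_synapses(self):
        cfg = small_config(normalize_in_degree=False)
        for c in cfg.connections:
            if (c.source, c.target) == ("GPe", "STN"):
                c.connection_probability = 0.0
        net = build_network(cfg, seed=0)
        s, d = net.slices["GPe_left"], net.slices["STN_left"]
        assert np.count_nonzero(net.W["GABA"][d, s]) == 0

    def test_synapse_counts_follow_binomial_law(self):
        """p=0.3 Bernoulli draws: mean realized count over seeds inside the
        binomial 99% CI for the mean."""
        cfg = small_config(normalize_in_degree=False)
        for p in cfg.populations:
            if p.name in ("GPe", "STN"):
                p.n_neurons = 40
        for c in cfg.connections:
            if (c.source, c.target) == ("GPe", "STN"):
                c.connection_probability = 0.3
        n_seeds = 60
        counts = []
        for seed in range(n_seeds):
            net = build_network(cfg, seed=seed)
            s, d = net.slices["GPe_left"], net.slices["STN_left"]
            counts.append(np.count_nonzero(net.W["GABA"][d, s]))
        n_pairs = 40 * 40
        total = np.sum(counts)
        lo, hi = stats.binom.interval(0.99, n_seeds * n_pairs, 0.3)
        assert lo <= total <= hi

    def test_same_seed_same_network(self):
        cfg = small_config()
        a, b = build_network(cfg, seed=7), build_network(cfg, seed=7)
        for r in ("AMPA", "NMDA", "GABA"):
            assert np.array_equal(a.W[r], b.W[r])
        assert np.array_equal(a.I_offset, b.I_offset)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ConnectivitySpec("Cx", "Th", "AMPA", 1.2, 0.1)

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            ConnectivitySpec("Cx", "Hippocampus", "AMPA", 0.5, 0.1)


class TestMembraneIntegration:
    def test_resting_potential_is_a_fixed_point(self):
        net = build_network(small_config(), seed=0)
        state = quiet_state(net)
        for _ in range(100):
            state, spikes = step_neurons(state, net, 0.1, np.zeros(net.n_neurons))
            assert not spikes.any()
        assert np.allclose(state.V, net.VL, atol=1e-12)

    def test_subthreshold_charging_matches_closed_form(self):
        """With gT = 0 and constant current the exponential-Euler step solves
        the linear membrane equation exactly."""
        net = build_network(small_config(), seed=0)
        state = quiet_state(net)
        i = net.slices["Cx_left"].start  # a gT = 0 neuron
        I = np.zeros(net.n_neurons)
        I[i] = 400.0  # subthreshold: V_inf = -70 + 16 mV
        dt, n = 0.1, 500
        for _ in range(n):
            state, _ = step_neurons(state, net, dt, I)
        t = n * dt
        tau = net.C[i] / net.gL[i]
        expected = net.VL[i] + (I[i] / net.gL[i]) * (1 - np.exp(-t / tau))
        assert state.V[i] == pytest.approx(expected, abs=1e-9)

    def test_synaptic_transient_accurate_against_fine_step_oracle(self):
        """With a decaying synaptic conductance (the only case where the
        per-step conductance freeze is approximate) the default-step
        trajectory stays within 0.05 mV of a 10x-finer reference."""
        net = build_network(small_config(), seed=0)
        i = net.slices["Cx_left"].start

        def run(dt, T=3.0):
            state = quiet_state(net)
            state.s_ampa[i] = 5.0  # subthreshold excitatory transient
            for _ in range(int(round(T / dt))):
                state = step_synapses(state, net, dt, np.zeros(net.n_neurons, dtype=bool))
                state, _ = step_neurons(state, net, dt, np.zeros(net.n_neurons))
            return state.V[i]

        assert abs(run(0.1) - run(0.01)) < 0.05

    def test_post_inhibitory_rebound_burst(self):
        """A bursty neuron held hyperpolarized accumulates h; on release it
        fires more spikes than without the hold."""
        net = build_network(small_config(), seed=0)
        i = net.slices["GPe_left"].start  # gT > 0
        assert net.gT[i] > 0

        def spikes_after(hold_pA, drive_pA=300.0):
            state = quiet_state(net)
            state.h[:] = 0.05
            I = np.zeros(net.n_neurons)
            I[i] = hold_pA
            for _ in range(4000):  # 400 ms conditioning phase
                state, _ = step_neurons(state, net, 0.1, I)
            count = 0
            I[i] = drive_pA  # tonic drive lifting V above the burst gate
            for _ in range(1500):  # 150 ms test window
                state, spk = step_neurons(state, net, 0.1, I)
                count += int(spk[i])
            return count

        # hyperpolarizing hold de-inactivates the T-current (h -> 1), so the
        # released neuron fires a rebound burst on top of its tonic rate
        assert spikes_after(-300.0) > spikes_after(300.0)

    def test_gating_variable_stays_in_unit_interval(self):
        net = build_network(small_config(), seed=0)
        state = quiet_state(net)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            I = rng.normal(0, 400, net.n_neurons)
            state, _ = step_neurons(state, net, 0.1, I)
            assert np.all((state.h >= 0) & (state.h <= 1))

    def test_nonfinite_state_aborts(self):
        net = build_network(small_config(), seed=0)
        state = quiet_state(net)
        state.V[0] = np.nan
        with pytest.raises(FloatingPointError):
            step_neurons(state, net, 0.1, np.zeros(net.n_neurons))


class TestSynapses:
    def test_gating_decay_is_exponential(self):
        net = build_network(small_config(), seed=0)
        state = quiet_state(net)
        state.s_ampa[:] = 0.5
        for _ in range(100):
            state = step_synapses(state, net, 0.1, np.zeros(net.n_neurons, dtype=bool))
        assert np.allclose(state.s_ampa, 0.5 * np.exp(-10.0 / net.tau_ampa), atol=1e-12)

    def test_nmda_saturates_below_one_under_kilohertz_drive(self):
        net = build_network(small_config(normalize_in_degree=False), seed=0)
        state = quiet_state(net)
        rng = np.random.default_rng(1)
        # drive every neuron's NMDA gate directly at ~1 kHz for 500 ms
        for _ in range(5000):
            spikes = rng.random(net.n_neurons) < 0.1  # 1 kHz at dt=0.1 ms
            state.s_nmda *= np.exp(-0.1 / net.tau_nmda)
            state.s_nmda += net.nmda_alpha * (1 - state.s_nmda) * spikes
            assert np.all(state.s_nmda < 1.0)

    def test_zero_gating_zero_current(self):
        net = build_network(small_config(), seed=0)
        I = synaptic_current(net.VL, np.zeros(net.n_neurons), np.zeros(net.n_neurons),
                             np.zeros(net.n_neurons), net)
        assert np.all(I == 0)

    def test_excitatory_current_vanishes_at_reversal(self):
        net = build_network(small_config(), seed=0)
        V = np.full(net.n_neurons, net.V_E[0])
        I = synaptic_current(V, np.ones(net.n_neurons), np.ones(net.n_neurons),
                             np.zeros(net.n_neurons), net)
        assert np.allclose(I, 0.0)

    def test_magnesium_block_value_at_zero_mv(self):
        assert nmda_mg_factor(0.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57))


class TestKernelEquivalence:
    def test_fused_kernel_matches_reference_steps_exactly(self):
        """With all stochastic drive disabled, the numba session kernel and
        the pure-numpy reference integration produce identical spike counts
        and membrane trajectories."""
        cfg = small_config()
        for p in cfg.populations:
            p.background.noise_sd = 0.0
            p.background.neuron_noise_sd = 0.0
            if p.name == "Cx":  # ensure cortical spikes exercise the
                p.background.mean_level = 540.0  # plastic fan-out too
        subj = SimulatedSubject(cfg, seed=3, warmup_ms=0)
        net = subj.net
        state = NetworkState(
            V=subj.V.copy(), h=subj.h.copy(), s_ampa=subj.sA.copy(),
            s_nmda=subj.sN.copy(), s_gaba=subj.sG.copy(),
            refractory=subj.refr.copy(),
        )
        counts = np.zeros((16, 101), dtype=np.int64)
        subj._run(100, stim=False, readout=False, plast=False, counts=counts)
        kernel_counts = counts.sum(axis=1)

        I = net.bg_mean[net.nuc_of] + net.I_offset
        spk = np.zeros(net.n_neurons, dtype=bool)
        ref_counts = np.zeros(16, dtype=int)
        for _ in range(1000):
            state = step_synapses(state, net, cfg.dt, spk)
            state, spk = step_neurons(state, net, cfg.dt, I)
            np.add.at(ref_counts, net.pop_of[spk], 1)
        assert np.array_equal(kernel_counts, ref_counts)
        assert np.abs(state.V - subj.V).max() < 1e-9

    def test_identical_seed_identical_session(self):
        from cbgt.task import BanditConfig, BanditEnv

        cfg = small_config()
        outs = []
        for _ in range(2):
            subj = SimulatedSubject(cfg, seed=5, warmup_ms=50)
            env = BanditEnv(BanditConfig(n_trials=3, k=10, seed=9))
            res = subj.run_session(env)
            outs.append(res)
        a, b = outs
        assert a.trials.choice.tolist() == b.trials.choice.tolist()
        assert a.trials.rt.tolist() == b.trials.rt.tolist()
        assert np.array_equal(a.features, b.features)


class TestDecisionReadout:
    def _poisson_spikes(self, rate_hz, n_neurons, t0, t1, rng):
        n = rng.poisson(rate_hz * n_neurons * (t1 - t0) / 1000.0)
        return np.sort(rng.uniform(t0, t1, n))

    def test_left_crossing_wins_with_correct_rt(self):
        rng = np.random.default_rng(0)
        left = self._poisson_spikes(80.0, 10, 250.0, 600.0, rng)  # strong from +250
        right = self._poisson_spikes(5.0, 10, 0.0, 1000.0, rng)
        out = detect_decision(left, right, 0.0, 10, 10, rng=rng)
        assert out.choice == "left" and out.valid
        assert 250.0 <= out.reaction_time <= 300.0

    def test_no_crossing_drops_trial(self):
        rng = np.random.default_rng(1)
        left = self._poisson_spikes(5.0, 10, 0.0, 1000.0, rng)
        right = self._poisson_spikes(5.0, 10, 0.0, 1000.0, rng)
        out = detect_decision(left, right, 0.0, 10, 10, rng=rng)
        assert out.choice == "none" and not out.valid and out.reaction_time is None

    def test_crossing_time_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(2)
        left = self._poisson_spikes(40.0, 10, 100.0, 1000.0, rng)
        right = np.array([])
        out = detect_decision(left, right, 0.0, 10, 10, rng=rng)
        # brute force: first 1-ms-stepped 20-ms window with >= 30 Hz
        expected = None
        for t in np.arange(1.0, 1001.0):
            c = np.sum((left > t - 20.0) & (left <= t))
            if c / (10 * 0.02) >= 30.0:
                expected = t
                break
        assert out.reaction_time == pytest.approx(expected, abs=1.0)


class TestRTCategories:
    def test_small_set_quartile_labels(self):
        labels = categorize_rt(np.array([100.0, 200.0, 300.0, 400.0]))
        assert labels.tolist() == ["fast", "fast", "intermediate", "slow"]

    def test_degenerate_identical_rts_all_slow(self):
        labels = categorize_rt(np.full(10, 250.0))
        assert set(labels) == {"slow"}

    def test_labels_match_sort_oracle(self):
        rng = np.random.default_rng(3)
        rts = rng.gamma(3.0, 80.0, 1000)
        labels = categorize_rt(rts)
        p50, p75 = np.percentile(rts, [50, 75])
        oracle = np.where(rts >= p75, "slow", np.where(rts < p50, "fast", "intermediate"))
        assert np.array_equal(labels, oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            categorize_rt(np.array([]))


class TestFiringFeatures:
    def test_rate_definition(self):
        counts = np.zeros((16, 200), dtype=int)
        counts[0, :200] = 0
        counts[3, ::20] = 1  # 10 spikes over 200 ms in population 3
        n_per_pop = np.full(16, 5)
        feats = trial_firing_features(counts, n_per_pop, 0.0, 200.0)
        assert feats[3] == pytest.approx(10 / (5 * 0.2))
        assert feats[0] == 0.0

    def test_matches_per_spike_counting_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(0.3, size=(16, 500))
        n_per_pop = rng.integers(5, 40, 16)
        feats = trial_firing_features(counts, n_per_pop, 0.0, 350.0)
        oracle = np.array(
            [counts[i, :350].sum() / (n_per_pop[i] * 0.350) for i in range(16)]
        )
        assert np.allclose(feats, oracle)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            trial_firing_features(np.zeros((16, 10)), np.ones(16), 5.0, 5.0)


class TestParameterSampling:
    def test_one_dimensional_lhs_occupies_every_decile(self):
        samples = lhs_samples({"stim_amplitude": (0.0, 1.0)}, 10, seed=0)
        deciles = sorted(int(s["stim_amplitude"] * 10) for s in samples)
        assert deciles == list(range(10))

    def test_marginals_uniform_by_ks(self):
        ranges = {"bg:Cx": (100.0, 300.0), "stim_amplitude": (20.0, 90.0),
                  "w:dSPN->GPi:GABA": (1.0, 4.0)}
        samples = lhs_samples(ranges, 300, seed=1)
        for name, (lo, hi) in ranges.items():
            u = (np.array([s[name] for s in samples]) - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_impossible_rate_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_parameter_schemes({"stim_amplitude": (40, 80)}, 2,
                                     {"Cx": (50.0, 10.0)}, seed=0)

    def test_screen_accepts_and_rejects_with_reasons(self):
        cfg = small_config()
        accepted, rejected = sample_parameter_schemes(
            {"bg:Cx": (120.0, 220.0)}, 3,
            {"GPi": (5.0, 500.0)},  # broad: accept
            seed=0, base_config=cfg, baseline_ms=120.0,
        )
        assert len(accepted) == 3 and not rejected
        accepted, rejected = sample_parameter_schemes(
            {"bg:Cx": (120.0, 220.0)}, 2,
            {"GPi": (0.0, 0.001)},  # impossible-to-satisfy band
            seed=0, base_config=cfg, baseline_ms=120.0,
        )
        assert not accepted and all(r["reasons"] for r in rejected)
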