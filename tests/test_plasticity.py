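"""Dopamine-modulated STDP: traces, eligibility, Q-learning, dopamine
dynamics, transfer functions, and soft-bounded weight updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt.config import PlasticityParams
from cbgt.plasticity import (
    DopamineState,
    QState,
    TraceState,
    dopamine_step,
    q_update,
    transfer_f,
    update_eligibility,
    update_traces,
    weight_update,
)

P = PlasticityParams()


class TestTraces:
    def test_pure_decay(self):
        tr = TraceState.zeros(3, 2)
        tr.a_pre[:] = 1.0
        for _ in range(50):
            update_traces(tr, np.zeros(3), np.zeros(2), 1.0, P)
        assert np.allclose(tr.a_pre, np.exp(-50.0 / P.tau_pre))

    def test_impulse_response_is_analytic(self):
        tr = TraceState.zeros(1, 1)
        update_traces(tr, np.array([1.0]), np.zeros(1), 1.0, P)
        t_rec = [tr.a_pre[0]]
        for _ in range(30):
            update_traces(tr, np.zeros(1), np.zeros(1), 1.0, P)
            t_rec.append(tr.a_pre[0])
        expected = (P.delta_pre / P.tau_pre) * np.exp(-np.arange(31) / P.tau_pre)
        assert np.allclose(t_rec, expected)

    def test_linearity_in_spike_impact(self):
        import dataclasses

        p2 = dataclasses.replace(P, delta_pre=2 * P.delta_pre)
        a, b = TraceState.zeros(1, 1), TraceState.zeros(1, 1)
        spikes = (np.random.default_rng(0).random(40) < 0.2).astype(float)
        for s in spikes:
            update_traces(a, np.array([s]), np.zeros(1), 1.0, P)
            update_traces(b, np.array([s]), np.zeros(1), 1.0, p2)
        assert b.a_pre[0] == pytest.approx(2 * a.a_pre[0])


class TestEligibility:
    def test_post_after_pre_raises_e(self):
        tr = TraceState.zeros(1, 1)
        update_eligibility(tr, np.array([1.0]), np.zeros(1), 1.0, P)
        update_traces(tr, np.array([1.0]), np.zeros(1), 1.0, P)
        for _ in range(9):
            update_eligibility(tr, np.zeros(1), np.zeros(1), 1.0, P)
            update_traces(tr, np.zeros(1), np.zeros(1), 1.0, P)
        update_eligibility(tr, np.zeros(1), np.array([1.0]), 1.0, P)
        assert tr.e[0, 0] > 0

    def test_pre_after_post_lowers_e(self):
        tr = TraceState.zeros(1, 1)
        update_eligibility(tr, np.zeros(1), np.array([1.0]), 1.0, P)
        update_traces(tr, np.zeros(1), np.array([1.0]), 1.0, P)
        for _ in range(9):
            update_eligibility(tr, np.zeros(1), np.zeros(1), 1.0, P)
            update_traces(tr, np.zeros(1), np.zeros(1), 1.0, P)
        update_eligibility(tr, np.array([1.0]), np.zeros(1), 1.0, P)
        assert tr.e[0, 0] < 0

    def test_silent_synapse_decays_to_zero(self):
        tr = TraceState.zeros(2, 2)
        tr.e[:] = 0.7
        for _ in range(2000):
            update_eligibility(tr, np.zeros(2), np.zeros(2), 1.0, P)
        assert np.all(np.abs(tr.e) < 1e-4)

    def test_five_spike_pattern_matches_closed_form_oracle(self):
        """E for an arbitrary pre/post pattern equals the closed-form sum
        over spike pairs (independent event-based evaluation of the same
        ODEs)."""
        pre_times = [2.0, 9.0, 23.0]
        post_times = [11.0, 30.0]
        T = 40

        def a_pre_at(t):
            return sum(
                (P.delta_pre / P.tau_pre) * np.exp(-(t - s) / P.tau_pre)
                for s in pre_times if s < t
            )

        def a_post_at(t):
            return sum(
                (P.delta_post / P.tau_post) * np.exp(-(t - s) / P.tau_post)
                for s in post_times if s < t
            )

        e_expected = 0.0
        events = sorted([(t, "pre") for t in pre_times] + [(t, "post") for t in post_times])
        t_last = 0.0
        for t, kind in events:
            e_expected *= np.exp(-(t - t_last) / P.tau_e)
            if kind == "post":
                e_expected += a_pre_at(t) / P.tau_e
            else:
                e_expected -= a_post_at(t) / P.tau_e
            t_last = t
        e_expected *= np.exp(-(T - t_last) / P.tau_e)

        tr = TraceState.zeros(1, 1)
        for step in range(T):
            t = float(step + 1)  # spike times fall on integer-ms boundaries
            pre = np.array([1.0 if t in pre_times else 0.0])
            post = np.array([1.0 if t in post_times else 0.0])
            update_eligibility(tr, pre, post, 1.0, P)
            update_traces(tr, pre, post, 1.0, P)
        # iterate decay convention differs by at most one step's decay
        assert tr.e[0, 0] == pytest.approx(e_expected, rel=0.08)


class TestQLearning:
    def test_reward_equal_to_expectation_is_fixed_point(self):
        q = QState(q={"left": 0.6, "right": 0.5})
        q, rpe = q_update(q, "left", 0.6, P)
        assert rpe == pytest.approx(0.0)
        assert q.q["left"] == pytest.approx(0.6)

    def test_repeated_reward_converges_geometrically(self):
        q = QState(q={"left": 0.0, "right": 0.0})
        n = 12
        for _ in range(n):
            q, _ = q_update(q, "left", 1.0, P)
        assert q.q["left"] == pytest.approx(1.0 - (1.0 - P.alpha_q) ** n)
        assert q.q["right"] == 0.0  # only the chosen action updates

    def test_prediction_error_is_pre_update(self):
        q = QState(q={"left": 0.6, "right": 0.5})
        _, rpe = q_update(q, "left", 1.0, P)
        assert rpe == pytest.approx(0.4)

    def test_no_choice_no_update(self):
        q = QState()
        q2, rpe = q_update(q, "none", 1.0, P)
        assert rpe is None and q2.q == {"left": 0.5, "right": 0.5}


class TestDopamine:
    def test_decay_without_events(self):
        d = DopamineState(k_da=0.8)
        for _ in range(40):
            dopamine_step(d, 1.0, P)
        assert d.k_da == pytest.approx(0.8 * np.exp(-40.0 / P.tau_dop))

    def test_phasic_jump_amplitude(self):
        d = DopamineState(k_da=0.0)
        dopamine_step(d, 1.0, P, rpe_event=0.5)
        assert d.k_da == pytest.approx(P.c_scale * 0.5 / P.tau_dop)

    def test_zero_rpe_event_adds_nothing_beyond_decay(self):
        d = DopamineState(k_da=0.0)
        dopamine_step(d, 1.0, P, rpe_event=0.0)
        assert d.k_da == pytest.approx(0.0)

    def test_negative_rpe_gives_dopamine_dip(self):
        d = DopamineState(k_da=0.0)
        dopamine_step(d, 1.0, P, rpe_event=-0.7)
        assert d.k_da < 0


class TestTransfer:
    def test_ispn_half_maximum_at_c(self):
        assert transfer_f(P.half_max_c, "iSPN", P) == pytest.approx(0.5)

    def test_zero_dopamine_zero_impact(self):
        assert transfer_f(0.0, "dSPN", P) == 0.0
        assert transfer_f(0.0, "iSPN", P) == 0.0

    def test_dspn_branch_is_identity(self):
        ks = np.linspace(-3, 3, 13)
        assert np.allclose(transfer_f(ks, "dSPN", P), ks)

    def test_ispn_branch_saturates_and_preserves_sign(self):
        out = transfer_f(np.array([-50.0, -0.1, 0.1, 50.0]), "iSPN", P)
        assert np.all(np.abs(out) < 1.0)
        assert np.all(np.sign(out) == [-1, -1, 1, 1])


class TestWeightUpdate:
    def test_zero_eligibility_freezes_weights(self):
        w = np.full((3, 3), 0.3)
        out = weight_update(w, np.zeros((3, 3)), 1.0, 1.0, "dSPN", P)
        assert np.array_equal(out, w)

    def test_soft_bounds_hold_at_rails(self):
        w_hi = np.full(4, P.w_max_dspn)
        out = weight_update(w_hi, np.full(4, 0.5), 1.0, 1.0, "dSPN", P)
        assert np.all(out <= P.w_max_dspn + 1e-12)
        w_lo = np.full(4, P.w_min)
        out = weight_update(w_lo, np.full(4, 0.5), -1.0, 1.0, "dSPN", P)
        assert np.all(out >= P.w_min - 1e-12)

    def test_constant_drive_relaxation_matches_closed_form(self):
        """dw/dt = D (Wmax - w) with constant positive drive D: the iterated
        update tracks Wmax - (Wmax - w0) exp(-D t)."""
        e, k = 0.01, 0.5
        D = P.alpha_w_dspn * e * k
        w0, dt, n = 0.2, 0.01, 4000
        w = np.array([w0])
        for _ in range(n):
            w = weight_update(w, np.array([e]), k, dt, "dSPN", P)
        expected = P.w_max_dspn - (P.w_max_dspn - w0) * np.exp(-D * n * dt)
        assert w[0] == pytest.approx(expected, rel=1e-3)

    def test_out_of_bounds_input_rejected(self):
        with pytest.raises(ValueError):
            weight_update(np.array([2.0]), np.array([0.1]), 1.0, 1.0, "dSPN", P)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_never_violated_under_random_drive(self, seed):
        """Property fuzz: arbitrary eligibility and dopamine sequences keep
        every weight inside [W_min, W_max] for both SPN classes."""
        rng = np.random.default_rng(seed)
        w_d = rng.uniform(P.w_min, P.w_max_dspn, (4, 4))
        w_i = rng.uniform(P.w_min, P.w_max_ispn, (4, 4))
        for _ in range(100):
            e = rng.normal(0.0, 0.05, (4, 4))
            k = rng.normal(0.0, 1.5)
            w_d = weight_update(w_d, e, k, 1.0, "dSPN", P)
            w_i = weight_update(w_i, e, k, 1.0, "iSPN", P)
            assert np.all((w_d >= P.w_min) & (w_d <= P.w_max_dspn))
            assert np.all((w_i >= P.w_min) & (w_i <= P.w_max_ispn))


class TestSignDissociation:
    def _run_channel(self, rate_pre, rate_post, rpes, seed=0):
        """Poisson pre/post activity at 1 ms resolution; one RPE per 200 ms
        'trial'. Returns (mean dSPN weight, mean iSPN weight) after learning."""
        rng = np.random.default_rng(seed)
        n_pre, n_post = 20, 10
        tr_d = TraceState.zeros(n_pre, n_post)
        tr_i = TraceState.zeros(n_pre, n_post)
        w_d = np.full((n_pre, n_post), 0.3)
        w_i = np.full((n_pre, n_post), 0.3)
        dop = DopamineState()
        for trial, rpe in enumerate(rpes):
            for ms in range(200):
                pre = (rng.random(n_pre) < rate_pre / 1000.0).astype(float)
                post = (rng.random(n_post) < rate_post / 1000.0).astype(float)
                for tr in (tr_d, tr_i):
                    update_eligibility(tr, pre, post, 1.0, P)
                    update_traces(tr, pre, post, 1.0, P)
                dopamine_step(dop, 1.0, P, rpe_event=rpe if ms == 0 else None)
                w_d = weight_update(w_d, tr_d.e, dop.k_da, 1.0, "dSPN", P)
                w_i = weight_update(w_i, tr_i.e, dop.k_da, 1.0, "iSPN", P)
        return w_d.mean(), w_i.mean()

    def test_sustained_positive_rpe_potentiates_dspn_depresses_ispn(self):
        wd, wi = self._run_channel(20.0, 15.0, [0.5] * 10, seed=1)
        assert wd > 0.32
        assert wi < 0.30

    def test_sustained_negative_rpe_flips_the_signs(self):
        wd, wi = self._run_channel(20.0, 15.0, [-0.5] * 10, seed=2)
        assert wd < 0.30
        assert wi > 0.32
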