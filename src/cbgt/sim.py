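"""Closed-loop CBGT bandit sessions.

:class:`SimulatedSubject` wraps one realized network instance (one seed =
one "simulated participant") and runs it through a change-point bandit:
on each trial the cortex of both channels receives the stimulus drive, the
first thalamic channel to reach the 30 Hz readout threshold determines the
choice and reaction time, the environment returns a reward, the Q-learned
prediction error releases phasic dopamine, and the corticostriatal weights
consolidate during the 600 ms inter-trial interval.

Per trial the subject logs choice, RT, reward, block, dropped flag, the
16-element vector of population firing rates during the reaction time
(decoding features), and mean corticostriatal weights per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .config import NetworkConfig, default_config
from .network import INSTANCE_KEYS, Network, build_network, trial_firing_features
from .plasticity import QState, q_update
from .task import BanditConfig, BanditEnv

_PLASTIC_BLOCKS = (("dSPN", "left"), ("iSPN", "left"), ("dSPN", "right"), ("iSPN", "right"))


@dataclass
class SessionResult:
    trials: pd.DataFrame
    features: np.ndarray           # n_trials x 16 mean rates (Hz)
    feature_names: tuple = INSTANCE_KEYS
    boundaries: np.ndarray | None = None
    weights: pd.DataFrame | None = None


def _csr_by_source(W: np.ndarray):
    """CSR of the transposed matrix: fan-out lists per presynaptic neuron."""
    src_ptr = [0]
    idx, wt = [], []
    Wt = W.T
    for j in range(W.shape[1]):
        nz = np.nonzero(Wt[j])[0]
        idx.append(nz)
        wt.append(Wt[j, nz].astype(np.float64))
        src_ptr.append(src_ptr[-1] + len(nz))
    return (
        np.asarray(src_ptr, dtype=np.int64),
        np.concatenate(idx).astype(np.int64) if idx else np.empty(0, np.int64),
        np.concatenate(wt) if wt else np.empty(0),
    )


class SimulatedSubject:
    """One network instance driven through bandit trials via the fused kernel."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0,
                 warmup_ms: float = 300.0):
        self.config = config or default_config()
        self.seed = seed
        self.net = build_network(self.config, seed)
        net = self.net
        self._rng = np.random.default_rng(seed + 7919)

        self.a_csr = _csr_by_source(net.W["AMPA"])
        self.n_csr = _csr_by_source(net.W["NMDA"])
        self.g_csr = _csr_by_source(net.W["GABA"])

        # plastic blocks: dSPN_l, iSPN_l, dSPN_r, iSPN_r
        n_cx = np.array([net.slices["Cx_left"].stop - net.slices["Cx_left"].start,
                         net.slices["Cx_right"].stop - net.slices["Cx_right"].start],
                        dtype=np.int64)
        if n_cx[0] != n_cx[1]:
            raise ValueError("action channels must have equal cortex sizes")
        spn_keys = [f"{spn}_{ch}" for spn, ch in _PLASTIC_BLOCKS]
        n_spn = np.array([net.slices[k].stop - net.slices[k].start for k in spn_keys],
                         dtype=np.int64)
        if len(set(n_spn)) != 1:
            raise ValueError("SPN populations must have equal sizes")
        self.cx_start = np.array([net.slices["Cx_left"].start, net.slices["Cx_right"].start],
                                 dtype=np.int64)
        self.spn_start = np.array([net.slices[k].start for k in spn_keys], dtype=np.int64)
        self.n_cx, self.n_spn = n_cx, n_spn
        self.Mp = np.zeros((4, n_cx[0], n_spn[0]), dtype=np.uint8)
        self.Wp = np.zeros((4, n_cx[0], n_spn[0]))
        for b, (spn, ch) in enumerate(_PLASTIC_BLOCKS):
            entry = net.plastic.get((spn, ch))
            if entry is None:
                raise ValueError("config lacks plastic corticostriatal projections")
            self.Mp[b] = entry["mask"].T.astype(np.uint8)  # stored (pre, post)
            self.Wp[b] = entry["w"].T
        self.Ep = np.zeros_like(self.Wp)
        self.A_pre = np.zeros((2, n_cx[0]))
        self.A_post = np.zeros((4, n_spn[0]))
        self.k_da = np.zeros(1)
        self.q = QState(q={"left": self.config.plasticity.q_init,
                           "right": self.config.plasticity.q_init})

        # state
        st = net.initial_state(self._rng)
        self.V, self.h = st.V, st.h
        self.sA, self.sN, self.sG = st.s_ampa, st.s_nmda, st.s_gaba
        self.refr = st.refractory
        self.spk_prev = np.zeros(net.n_neurons, dtype=np.uint8)
        self.ou_x = net.bg_mean.copy()
        self.I_noise = np.zeros(net.n_neurons)
        self._dec_hm = np.exp(-self.config.dt / net.tau_h_minus)
        self._dec_hp = np.exp(-self.config.dt / net.tau_h_plus)
        self._dec_a = np.exp(-self.config.dt / net.tau_ampa)
        self._dec_n = np.exp(-self.config.dt / net.tau_nmda)
        self._dec_g = np.exp(-self.config.dt / net.tau_gaba)
        self._stim_on = np.zeros(net.n_neurons)
        for key in ("Cx_left", "Cx_right"):
            self._stim_on[net.slices[key]] = self.config.timing.stim_amplitude
        self._stim_off = np.zeros(net.n_neurons)
        self.tie_count = 0
        if warmup_ms > 0:
            self._run(int(warmup_ms), stim=False, readout=False, plast=False)

    # -- kernel dispatch ----------------------------------------------------
    def _run(self, n_ms: int, stim: bool, readout: bool, plast: bool,
             counts: np.ndarray | None = None, ms_offset: int = 0,
             da_event_ms: int = -1, da_inc: float = 0.0,
             spike_capacity: int = 0):
        cfg = self.config
        net = self.net
        steps_per_ms = int(round(1.0 / cfg.dt))
        if counts is None:
            counts = np.zeros((len(INSTANCE_KEYS), n_ms + 1), dtype=np.int64)
        ro = cfg.readout
        win_s = ro.window_ms * 1e-3
        thr_l = ro.threshold_hz * (net.slices["Th_left"].stop - net.slices["Th_left"].start) * win_s
        thr_r = ro.threshold_hz * (net.slices["Th_right"].stop - net.slices["Th_right"].start) * win_s
        pl = cfg.plasticity
        alpha_w = np.array([pl.alpha_w_dspn, pl.alpha_w_ispn, pl.alpha_w_dspn, pl.alpha_w_ispn])
        w_max = np.array([pl.w_max_dspn, pl.w_max_ispn, pl.w_max_dspn, pl.w_max_ispn])
        spike_ids = np.empty(spike_capacity, dtype=np.int64)
        spike_times = np.empty(spike_capacity, dtype=np.float64)
        n_spikes = np.zeros(1, dtype=np.int64)
        dec_ms, channel, tie = _kernel.run_phase(
            int(self._rng.integers(2**31)),
            n_ms * steps_per_ms, cfg.dt, steps_per_ms,
            self.V, self.h, self.sA, self.sN, self.sG, self.refr, self.spk_prev,
            net.C, net.gL, net.VL, net.gT, net.Vh, net.VT,
            self._dec_hm, self._dec_hp, net.Vth, net.Vreset, net.t_ref,
            net.g_ampa, net.g_nmda, net.g_gaba, net.V_E, net.V_I,
            self._dec_a, self._dec_n, self._dec_g, net.nmda_alpha,
            *self.a_csr, *self.n_csr, *self.g_csr,
            net.pop_of, net.nuc_of, self.ou_x, net.bg_mean, net.bg_theta, net.bg_sigma,
            net.neuron_sigma, net.I_offset, self.I_noise,
            self._stim_on if stim else self._stim_off,
            cfg.timing.stim_ramp_ms if stim else 0.0,
            counts, ms_offset,
            1 if readout else 0, thr_l, thr_r, ro.window_ms,
            1 if plast else 0,
            self.cx_start, self.n_cx, self.spn_start, self.n_spn,
            self.Wp, self.Mp, self.Ep, self.A_pre, self.A_post,
            pl.tau_pre, pl.tau_post, pl.delta_pre, pl.delta_post, pl.tau_e,
            self.k_da, pl.tau_dop, pl.c_scale, pl.half_max_c,
            alpha_w, w_max, pl.w_min,
            da_event_ms, da_inc,
            spike_ids, spike_times, n_spikes,
        )
        self._last_spikes = (spike_ids[: n_spikes[0]], spike_times[: n_spikes[0]])
        return counts, dec_ms, channel, tie

    # -- public API ---------------------------------------------------------
    def baseline_rates(self, duration_ms: float = 300.0) -> dict[str, float]:
        """Mean firing rate (Hz) per population instance at rest."""
        n_ms = int(duration_ms)
        counts, *_ = self._run(n_ms, stim=False, readout=False, plast=False)
        totals = counts.sum(axis=1)
        return {
            k: totals[i] / (self.net.n_per_pop[i] * n_ms * 1e-3)
            for i, k in enumerate(INSTANCE_KEYS)
        }

    def record_spikes(self, duration_ms: float, stim: bool = False) -> pd.DataFrame:
        """Record a raster (neuron_id, population, channel, time_ms) for
        ``duration_ms`` of free-running (or stimulated) activity."""
        cap = int(self.net.n_neurons * duration_ms)  # generous: 1 kHz/neuron
        self._run(int(duration_ms), stim=stim, readout=False, plast=False,
                  spike_capacity=cap)
        ids, times = self._last_spikes
        keys = np.array(INSTANCE_KEYS, dtype=object)[self.net.pop_of[ids]]
        pop = [k.split("_")[0] for k in keys]
        chan = [k.split("_")[1] if "_" in k else "shared" for k in keys]
        return pd.DataFrame(
            dict(neuron_id=ids, population=pop, channel=chan, time_ms=times)
        )

    def run_trial(self, plast: bool = True):
        """One decision phase (stimulus on, readout armed, max 1000 ms).

        Returns (choice, rt_ms, dropped, features, counts).
        """
        cfg = self.config
        max_ms = int(cfg.readout.max_rt_ms)
        counts = np.zeros((len(INSTANCE_KEYS), max_ms + 1), dtype=np.int64)
        counts, dec_ms, channel, tie = self._run(
            max_ms, stim=True, readout=True, plast=plast, counts=counts
        )
        self.tie_count += tie
        if dec_ms < 0:
            choice, rt, dropped = "none", None, True
            window_end = float(max_ms)
        else:
            choice = "left" if channel == 0 else "right"
            rt, dropped = float(dec_ms), False
            window_end = float(dec_ms)
        if cfg.readout.feature_window == "fixed":
            window_end = min(cfg.readout.fixed_window_ms, window_end)
        feats = trial_firing_features(counts, self.net.n_per_pop, 0.0, max(window_end, 1.0))
        return choice, rt, dropped, feats, counts

    def deliver_outcome(self, choice: str, reward: float | None, plast: bool = True):
        """Inter-trial interval with reward-locked phasic dopamine."""
        rpe = None
        if choice in ("left", "right") and reward is not None:
            self.q, rpe = q_update(self.q, choice, reward, self.config.plasticity)
        self._run(
            int(self.config.timing.inter_trial_ms),
            stim=False, readout=False, plast=plast,
            da_event_ms=0 if rpe is not None else -1,
            da_inc=rpe if rpe is not None else 0.0,
        )
        return rpe

    def probe_rts(self, n_trials: int) -> np.ndarray:
        """RTs of plasticity-frozen probe trials (for regime labeling)."""
        rts = []
        for _ in range(n_trials):
            _, rt, dropped, _, _ = self.run_trial(plast=False)
            if not dropped:
                rts.append(rt)
            self._run(int(self.config.timing.inter_trial_ms),
                      stim=False, readout=False, plast=False)
        return np.asarray(rts)

    def mean_weights(self) -> dict[str, float]:
        out = {}
        for b, (spn, ch) in enumerate(_PLASTIC_BLOCKS):
            m = self.Mp[b].astype(bool)
            out[f"w_{spn}_{ch}"] = float(self.Wp[b][m].mean())
        return out

    def run_session(self, env: BanditEnv, plast: bool = True) -> SessionResult:
        """Play out a full bandit session against ``env``."""
        feats_rows, weight_rows = [], []
        while not env.done:
            choice, rt, dropped, feats, _ = self.run_trial(plast=plast)
            rec = env.step(choice, rt=rt, dropped=dropped)
            self.deliver_outcome(choice, None if dropped else rec.reward, plast=plast)
            feats_rows.append(feats)
            weight_rows.append(self.mean_weights())
        trials = env.to_frame()
        return SessionResult(
            trials=trials,
            features=np.vstack(feats_rows),
            boundaries=env.boundaries,
            weights=pd.DataFrame(weight_rows),
        )


def run_bandit_experiment(
    n_trials: int = 120,
    seed: int = 0,
    config: NetworkConfig | None = None,
    bandit: BanditConfig | None = None,
) -> SessionResult:
    """Convenience entry point: one simulated subject, one network protocol
    session (deterministic switches every 10 trials, 75/25 rewards)."""
    bandit = bandit or BanditConfig(n_trials=n_trials, k=10, p_optimal=0.75, seed=seed + 1)
    subj = SimulatedSubject(config, seed=seed)
    env = BanditEnv(bandit)
    return subj.run_session(env)
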