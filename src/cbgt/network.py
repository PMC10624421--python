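"""Two-channel spiking CBGT circuit: construction, integration, and readout.

The circuit's sixteen population instances (seven channelized populations x
left/right plus the shared CxI and FSI pools) are flattened into per-neuron
parameter vectors and a per-receptor sparse adjacency realized by
independent Bernoulli draws at the configured connection probabilities.
Membrane dynamics follow the integrate-and-fire-or-burst model with
conductance-based AMPA/NMDA/GABA synapses; integration is fixed-step
exponential-Euler (the total conductance is frozen within a step and the
membrane relaxed exactly toward its instantaneous equilibrium).

The functions in this module are the reference semantics used by the unit
tests; the fused numba kernel in :mod:`cbgt._kernel` replicates them for
closed-loop session speed and is cross-checked against them.

A decision is read out when either thalamic subpopulation's rate — a 20 ms
sliding boxcar stepped at 1 ms — reaches 30 Hz after stimulus onset; trials
that never cross within 1000 ms are dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .config import (
    CHANNELS,
    POPULATIONS,
    NetworkConfig,
    PopulationSpec,
    ReadoutConfig,
    default_config,
)

#: fixed order of the sixteen population instances; also the order of the
#: per-trial firing-rate feature vector
INSTANCE_KEYS = (
    "Cx_left", "Cx_right", "CxI",
    "dSPN_left", "dSPN_right", "iSPN_left", "iSPN_right", "FSI",
    "GPe_left", "GPe_right", "STN_left", "STN_right",
    "GPi_left", "GPi_right", "Th_left", "Th_right",
)


@dataclass
class NetworkState:
    """Per-neuron integrator state."""

    V: np.ndarray
    h: np.ndarray
    s_ampa: np.ndarray
    s_nmda: np.ndarray
    s_gaba: np.ndarray
    refractory: np.ndarray
    t: float = 0.0


@dataclass
class DecisionOutcome:
    choice: str               # 'left' | 'right' | 'none'
    reaction_time: float | None  # ms from onset, None when dropped
    valid: bool
    tie: bool = False


class Network:
    """A realized network instance: parameter vectors plus fixed adjacency."""

    def __init__(self, config: NetworkConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        spec_by_key = {p.key: p for p in config.populations}
        missing = set(INSTANCE_KEYS) - set(spec_by_key)
        if missing:
            raise ValueError(f"population specs missing: {sorted(missing)}")
        self.slices: dict[str, slice] = {}
        start = 0
        for key in INSTANCE_KEYS:
            n = spec_by_key[key].n_neurons
            self.slices[key] = slice(start, start + n)
            start += n
        self.n_neurons = start
        self.pop_of = np.empty(self.n_neurons, dtype=np.int64)
        for i, key in enumerate(INSTANCE_KEYS):
            self.pop_of[self.slices[key]] = i

        def vec(attr_path):
            out = np.empty(self.n_neurons)
            for key in INSTANCE_KEYS:
                obj = spec_by_key[key]
                val = obj
                for part in attr_path.split("."):
                    val = getattr(val, part)
                out[self.slices[key]] = val
            return out

        np_ = "neuron_params."
        sp = "synapse_params."
        self.C = vec(np_ + "C"); self.gL = vec(np_ + "gL"); self.VL = vec(np_ + "VL")
        self.gT = vec(np_ + "gT"); self.Vh = vec(np_ + "Vh"); self.VT = vec(np_ + "VT")
        self.tau_h_minus = vec(np_ + "tau_h_minus")
        self.tau_h_plus = vec(np_ + "tau_h_plus")
        self.Vth = vec(np_ + "spike_threshold")
        self.Vreset = vec(np_ + "reset_potential")
        self.t_ref = vec(np_ + "refractory_period")
        self.g_ampa = vec(sp + "g_ampa"); self.g_nmda = vec(sp + "g_nmda")
        self.g_gaba = vec(sp + "g_gaba")
        self.V_E = vec(sp + "V_E"); self.V_I = vec(sp + "V_I")
        self.tau_ampa = vec(sp + "tau_ampa"); self.tau_nmda = vec(sp + "tau_nmda")
        self.tau_gaba = vec(sp + "tau_gaba"); self.nmda_alpha = vec(sp + "nmda_alpha")

        # the mean-reverting background walk is shared per nucleus: the two
        # channels of a population receive the same fluctuating drive, so
        # drive fluctuations vary decision speed without deciding the race
        self.nucleus_names = list(POPULATIONS)
        self.nuc_of = np.empty(self.n_neurons, dtype=np.int64)
        for key in INSTANCE_KEYS:
            name = key.split("_")[0]
            self.nuc_of[self.slices[key]] = self.nucleus_names.index(name)
        by_name = {p.name: p for p in config.populations}
        self.bg_mean = np.array([by_name[n].background.mean_level for n in self.nucleus_names])
        self.bg_theta = np.array([by_name[n].background.reversion_rate for n in self.nucleus_names])
        self.bg_sigma = np.array([by_name[n].background.noise_sd for n in self.nucleus_names])
        self.neuron_sigma = np.array(
            [spec_by_key[k].background.neuron_noise_sd for k in INSTANCE_KEYS]
        )
        # frozen per-neuron drive offsets (part of the realized instance)
        self.I_offset = np.zeros(self.n_neurons)
        for i, key in enumerate(INSTANCE_KEYS):
            sd = spec_by_key[key].background.hetero_sd
            if sd > 0:
                sl = self.slices[key]
                off = rng.normal(0.0, sd, sl.stop - sl.start)
                # demean within the instance: heterogeneity desynchronizes
                # without introducing a net drive bias between channels
                self.I_offset[sl] = off - off.mean()
        self.n_per_pop = np.array([spec_by_key[k].n_neurons for k in INSTANCE_KEYS])

        # --- adjacency -----------------------------------------------------
        # static synapses in dense per-receptor matrices W[target, source];
        # plastic corticostriatal synapses kept separately
        self.W = {r: np.zeros((self.n_neurons, self.n_neurons), dtype=np.float32)
                  for r in ("AMPA", "NMDA", "GABA")}
        self.plastic: dict[tuple[str, str], dict] = {}
        for conn in config.connections:
            pairs = self._instance_pairs(conn.source, conn.target, conn.within_channel)
            for src_key, dst_key in pairs:
                s, d = self.slices[src_key], self.slices[dst_key]
                mask = rng.random((d.stop - d.start, s.stop - s.start)) < conn.connection_probability
                if conn.source == conn.target and src_key == dst_key:
                    np.fill_diagonal(mask, False)  # no autapses
                if conn.plastic:
                    ch = dst_key.rsplit("_", 1)[1]
                    spn = conn.target
                    entry = self.plastic.setdefault(
                        (spn, ch),
                        dict(pre=s, post=d,
                             mask=mask,
                             w=np.zeros(mask.shape)),
                    )
                    entry["mask"] |= mask
                    entry["w"] = np.where(entry["mask"], conn.synaptic_weight, 0.0)
                else:
                    block = mask * conn.synaptic_weight
                    if config.normalize_in_degree:
                        # scale each target's summed weight to its expectation:
                        # removes realized-adjacency gain asymmetries between
                        # channels while keeping Bernoulli connectivity
                        expected = conn.connection_probability * mask.shape[1] * conn.synaptic_weight
                        if expected > 0:
                            row_sum = block.sum(axis=1, keepdims=True)
                            scale = np.where(row_sum > 0, expected / np.maximum(row_sum, 1e-12), 0.0)
                            block = block * scale
                    self.W[conn.receptor][d, s] += block
        # realized synapse counts per projection are fixed by the seed
        self.rng = rng

    @staticmethod
    def _instance_pairs(source: str, target: str, within: bool):
        def instances(name):
            return [name] if name in ("CxI", "FSI") else [f"{name}_{c}" for c in CHANNELS]
        pairs = []
        for s in instances(source):
            for d in instances(target):
                if within and "_" in s and "_" in d:
                    if s.rsplit("_", 1)[1] != d.rsplit("_", 1)[1]:
                        continue
                pairs.append((s, d))
        return pairs

    def initial_state(self, rng: np.random.Generator | None = None) -> NetworkState:
        rng = rng or self.rng
        V = self.VL + rng.uniform(0.0, 5.0, self.n_neurons)
        return NetworkState(
            V=V,
            h=np.full(self.n_neurons, 0.3),
            s_ampa=np.zeros(self.n_neurons),
            s_nmda=np.zeros(self.n_neurons),
            s_gaba=np.zeros(self.n_neurons),
            refractory=np.zeros(self.n_neurons),
        )


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> Network:
    """Realize a network instance: identical seed implies identical adjacency."""
    return Network(config or default_config(), seed)


# ---------------------------------------------------------------------------
# reference integration steps (mirrored by the numba kernel)
# ---------------------------------------------------------------------------

def nmda_mg_factor(V: np.ndarray) -> np.ndarray:
    """Voltage-dependent magnesium-block factor of the NMDA current."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(V)) / 3.57)


def synaptic_current(V, s_ampa, s_nmda, s_gaba, net: Network) -> np.ndarray:
    """Total receptor current (pA), positive = hyperpolarizing (outward)."""
    I = net.g_ampa * s_ampa * (V - net.V_E)
    I += net.g_nmda * s_nmda * (V - net.V_E) * nmda_mg_factor(V)
    I += net.g_gaba * s_gaba * (V - net.V_I)
    return I


def step_synapses(state: NetworkState, net: Network, dt: float, spikes: np.ndarray) -> NetworkState:
    """Decay gating variables and apply incoming spikes (``spikes`` is the
    boolean emission vector of the previous step). AMPA/GABA integrate the
    summed synaptic weights; NMDA saturates via alpha (1 - s) per impulse."""
    state.s_ampa *= np.exp(-dt / net.tau_ampa)
    state.s_nmda *= np.exp(-dt / net.tau_nmda)
    state.s_gaba *= np.exp(-dt / net.tau_gaba)
    if np.any(spikes):
        spk = np.asarray(spikes, dtype=np.float64)
        inc_a = net.W["AMPA"] @ spk
        inc_g = net.W["GABA"] @ spk
        for (spn, ch), entry in net.plastic.items():
            pre_spk = spk[entry["pre"]]
            drive = (entry["w"] * entry["mask"]) @ pre_spk
            inc_a[entry["post"]] += drive
        state.s_ampa += inc_a
        state.s_gaba += inc_g
        # NMDA saturates per impulse: apply each presynaptic spike in turn so
        # that s never exceeds 1 even under synchronous volleys
        plastic_by_pre: dict[int, list] = {}
        for entry in net.plastic.values():
            for local_j, j in enumerate(range(entry["pre"].start, entry["pre"].stop)):
                plastic_by_pre.setdefault(j, []).append((entry, local_j))
        for j in np.nonzero(spikes)[0]:
            w_col = net.W["NMDA"][:, j]
            state.s_nmda += net.nmda_alpha * (1.0 - state.s_nmda) * w_col
            for entry, local_j in plastic_by_pre.get(j, []):
                w_pl = entry["w"][:, local_j] * entry["mask"][:, local_j]
                post = entry["post"]
                state.s_nmda[post] += (
                    net.nmda_alpha[post] * (1.0 - state.s_nmda[post]) * w_pl
                )
    if np.any(state.s_ampa < 0) or np.any(state.s_gaba < 0) or np.any(state.s_nmda < 0):
        raise FloatingPointError("negative gating value")
    return state


def step_neurons(
    state: NetworkState, net: Network, dt: float, I_ext: np.ndarray
) -> tuple[NetworkState, np.ndarray]:
    """One exponential-Euler membrane step; returns the spike vector.

    The burst gate h decays with tau_h_minus while V >= Vh and recovers
    toward 1 with tau_h_plus below it; the T-current activates only above
    Vh. ``I_ext`` is depolarizing-positive (pA).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError("non-finite membrane potential")
    V = state.V
    burst_open = (V >= net.Vh) & (net.gT > 0)
    g_T = np.where(burst_open, net.gT * state.h, 0.0)
    mg = nmda_mg_factor(V)
    gA = net.g_ampa * state.s_ampa
    gN = net.g_nmda * state.s_nmda * mg
    gG = net.g_gaba * state.s_gaba
    g_tot = net.gL + g_T + gA + gN + gG
    V_inf = (net.gL * net.VL + g_T * net.VT + (gA + gN) * net.V_E + gG * net.V_I + I_ext) / g_tot
    V_new = V_inf + (V - V_inf) * np.exp(-g_tot * dt / net.C)

    refr = state.refractory > 0
    V_new = np.where(refr, net.Vreset, V_new)
    state.refractory = np.maximum(state.refractory - dt, 0.0)

    spikes = (V_new >= net.Vth) & ~refr
    state.V = np.where(spikes, net.Vreset, V_new)
    state.refractory = np.where(spikes, net.t_ref, state.refractory)

    above = state.V >= net.Vh
    h = state.h
    h_dec = h * np.exp(-dt / net.tau_h_minus)
    h_ris = 1.0 + (h - 1.0) * np.exp(-dt / net.tau_h_plus)
    state.h = np.where(above, h_dec, h_ris)
    state.t += dt
    return state, spikes


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

def sliding_rate(
    spike_times: np.ndarray, n_neurons: int, t_grid: np.ndarray, window_ms: float
) -> np.ndarray:
    """Population rate (Hz) in a boxcar (t - window, t] at each grid time."""
    spike_times = np.asarray(spike_times, dtype=float)
    counts = np.array(
        [np.sum((spike_times > t - window_ms) & (spike_times <= t)) for t in t_grid]
    )
    return counts / (n_neurons * window_ms * 1e-3)


def detect_decision(
    th_left_spikes: np.ndarray,
    th_right_spikes: np.ndarray,
    t_onset: float,
    n_left: int,
    n_right: int,
    readout: ReadoutConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecisionOutcome:
    """First thalamic channel whose windowed rate reaches threshold wins.

    Rates are estimated in a ``window_ms`` boxcar stepped at ``step_ms``
    starting at onset. Ties within the same estimation step go to the
    higher rate, or to a fair coin when exactly equal. If neither channel
    crosses within ``max_rt_ms`` the trial is dropped.
    """
    ro = readout or ReadoutConfig()
    grid = np.arange(t_onset + ro.step_ms, t_onset + ro.max_rt_ms + ro.step_ms / 2, ro.step_ms)
    rate_l = sliding_rate(th_left_spikes, n_left, grid, ro.window_ms)
    rate_r = sliding_rate(th_right_spikes, n_right, grid, ro.window_ms)
    for t, rl, rr in zip(grid, rate_l, rate_r):
        hit_l, hit_r = rl >= ro.threshold_hz, rr >= ro.threshold_hz
        if hit_l and hit_r:
            if rl > rr:
                ch = "left"
            elif rr > rl:
                ch = "right"
            else:
                ch = ("left", "right")[int((rng or np.random.default_rng()).integers(2))]
            return DecisionOutcome(ch, t - t_onset, True, tie=True)
        if hit_l or hit_r:
            return DecisionOutcome("left" if hit_l else "right", t - t_onset, True)
    return DecisionOutcome("none", None, False)


def categorize_rt(rts: np.ndarray) -> np.ndarray:
    """Label reaction times: slow (>= 75th percentile), fast (< 50th), else
    intermediate; percentiles are taken from the empirical distribution."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT set")
    if rts.size < 4:
        raise ValueError("need at least 4 RTs for quartile labels")
    p50, p75 = np.percentile(rts, [50, 75])
    labels = np.full(rts.shape, "intermediate", dtype=object)
    labels[rts >= p75] = "slow"
    labels[rts < p50] = "fast"
    return labels


def trial_firing_features(
    counts_ms: np.ndarray, n_per_pop: np.ndarray, t0_ms: float, t1_ms: float
) -> np.ndarray:
    """Mean firing rate (Hz) per population instance over [t0, t1).

    ``counts_ms`` is the (16 populations x milliseconds) spike-count matrix
    logged by the simulator; rates are spikes / (neurons x window length).
    """
    if t1_ms <= t0_ms:
        raise ValueError("zero-length feature window")
    a, b = int(np.floor(t0_ms)), int(np.ceil(t1_ms))
    window_s = (b - a) * 1e-3
    return counts_ms[:, a:b].sum(axis=1) / (n_per_pop * window_s)


# ---------------------------------------------------------------------------
# parameter-scheme sampling
# ---------------------------------------------------------------------------

def apply_overrides(config: NetworkConfig, overrides: dict[str, float]) -> NetworkConfig:
    """Return a copy of ``config`` with named scalar knobs replaced.

    Supported keys: ``bg:<Pop>`` (background mean of every instance of the
    population), ``w:<Src>-><Dst>:<receptor>`` (synaptic weight),
    ``stim_amplitude``, and ``plasticity.<field>``.
    """
    cfg = dataclasses.replace(
        config,
        populations=[dataclasses.replace(
            p,
            neuron_params=dataclasses.replace(p.neuron_params),
            synapse_params=dataclasses.replace(p.synapse_params),
            background=dataclasses.replace(p.background),
        ) for p in config.populations],
        connections=[dataclasses.replace(c) for c in config.connections],
        plasticity=dataclasses.replace(config.plasticity),
        timing=dataclasses.replace(config.timing),
        readout=dataclasses.replace(config.readout),
    )
    for key, val in overrides.items():
        if key == "stim_amplitude":
            cfg.timing.stim_amplitude = val
        elif key.startswith("bg:"):
            name = key[3:]
            hit = False
            for p in cfg.populations:
                if p.name == name:
                    p.background.mean_level = val
                    hit = True
            if not hit:
                raise KeyError(key)
        elif key.startswith("w:"):
            spec, receptor = key[2:].split(":")
            src, dst = spec.split("->")
            hit = False
            for c in cfg.connections:
                if c.source == src and c.target == dst and c.receptor == receptor:
                    c.synaptic_weight = val
                    hit = True
            if not hit:
                raise KeyError(key)
        elif key.startswith("plasticity."):
            setattr(cfg.plasticity, key.split(".", 1)[1], val)
        else:
            raise KeyError(f"unknown override {key!r}")
    return cfg


def lhs_samples(ranges: dict[str, tuple[float, float]], n_samples: int, seed: int) -> list[dict]:
    """Latin-hypercube samples over named scalar ranges (one stratum per
    sample and dimension)."""
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_samples)
    out = []
    for row in unit:
        d = {}
        for name, u in zip(names, row):
            lo, hi = ranges[name]
            d[name] = lo + u * (hi - lo)
        out.append(d)
    return out


def sample_parameter_schemes(
    ranges: dict[str, tuple[float, float]],
    n_samples: int,
    rate_bounds: dict[str, tuple[float, float]],
    seed: int = 0,
    base_config: NetworkConfig | None = None,
    baseline_ms: float = 300.0,
    rt_trials: int = 0,
):
    """Latin-hypercube screen of network parameter schemes.

    Each sampled configuration is simulated briefly at baseline (no
    stimulus); schemes whose population rates violate ``rate_bounds``
    (Hz, keyed by population name) are rejected with the reason recorded.
    If ``rt_trials`` > 0, accepted schemes additionally run that many
    decision trials and are labeled fast / intermediate / slow by the
    quartiles of their mean RTs.

    Returns (accepted records, rejected records).
    """
    from .sim import SimulatedSubject  # deferred: sim imports this module

    for name, (lo, hi) in rate_bounds.items():
        if hi < lo:
            raise ValueError(f"impossible rate bounds for {name}")
    base = base_config or default_config()
    accepted, rejected = [], []
    for i, overrides in enumerate(lhs_samples(ranges, n_samples, seed)):
        cfg = apply_overrides(base, overrides)
        subj = SimulatedSubject(cfg, seed=seed + 1000 + i)
        rates = subj.baseline_rates(baseline_ms)
        reasons = []
        for name, (lo, hi) in rate_bounds.items():
            keys = [k for k in INSTANCE_KEYS if k == name or k.startswith(name + "_")]
            mean_rate = float(np.mean([rates[k] for k in keys]))
            if not (lo <= mean_rate <= hi):
                reasons.append(f"{name}: {mean_rate:.1f} Hz outside [{lo}, {hi}]")
        rec = dict(overrides=overrides, config=cfg, rates=rates)
        if reasons:
            rec["reasons"] = reasons
            rejected.append(rec)
        else:
            if rt_trials > 0:
                rts = subj.probe_rts(rt_trials)
                rec["mean_rt"] = float(np.mean(rts)) if len(rts) else np.nan
            accepted.append(rec)
    if rt_trials > 0 and accepted:
        rts = np.array([r.get("mean_rt", np.nan) for r in accepted])
        lo_q, hi_q = np.nanpercentile(rts, [25, 75])
        for r in accepted:
            m = r.get("mean_rt", np.nan)
            r["regime"] = (
                "fast" if m <= lo_q else "slow" if m >= hi_q else "intermediate"
            )
    if not accepted:
        return accepted, rejected
    return accepted, rejected
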