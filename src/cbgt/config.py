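"""Configuration of the spiking CBGT circuit.

All neuron, synapse, connectivity, plasticity and task constants route
through :class:`NetworkConfig`. The circuit has nine populations — cortex
(Cx), cortical interneurons (CxI), direct- and indirect-pathway striatal
projection neurons (dSPN, iSPN), striatal fast-spiking interneurons (FSI),
external and internal globus pallidus (GPe, GPi), subthalamic nucleus (STN)
and thalamus (Th) — organized into left and right action channels except for
the shared CxI and FSI pools. GPe and STN use the burst-capable neuron
(gT > 0); all others are leaky integrate-and-fire (gT = 0).

Units: capacitance nF, conductance nS, voltage mV, time ms, current pA
(nS*mV = pA; pA/nF = mV/ms). External/background currents are
depolarizing-positive.

The shipped defaults are implementation defaults (standard conductance-LIF
values calibrated to plausible baseline rates and to the target
reaction-time distribution); they are not taken from any published
parameter table. See ``data/default_network.yaml`` for the versioned,
unit-annotated copy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

POPULATIONS = ("Cx", "CxI", "dSPN", "iSPN", "FSI", "GPe", "STN", "GPi", "Th")
SHARED = ("CxI", "FSI")
CHANNELED = tuple(p for p in POPULATIONS if p not in SHARED)
CHANNELS = ("left", "right")
RECEPTORS = ("AMPA", "NMDA", "GABA")


@dataclass
class NeuronParams:
    """Integrate-and-fire-or-burst membrane parameters.

    With ``gT = 0`` the model reduces exactly to a leaky integrate-and-fire
    unit; ``gT > 0`` adds a low-threshold Ca2+ current gated by the slow
    variable h, producing post-inhibitory rebound bursts.
    """

    C: float = 0.5             # nF
    gL: float = 25.0           # nS (tau_m = 20 ms)
    VL: float = -70.0          # mV
    gT: float = 0.0            # nS; > 0 only for bursty populations
    Vh: float = -60.0          # mV, burst gating threshold
    VT: float = 120.0          # mV, Ca2+ reversal
    tau_h_minus: float = 20.0  # ms, h decay when V >= Vh
    tau_h_plus: float = 100.0  # ms, h recovery when V < Vh
    spike_threshold: float = -50.0  # mV  (default, not printed)
    reset_potential: float = -70.0  # mV  (default, not printed)
    refractory_period: float = 2.0  # ms  (default, not printed)

    def __post_init__(self) -> None:
        if min(self.C, self.gL) <= 0 or self.gT < 0:
            raise ValueError("capacitance and conductances must be positive")
        if self.tau_h_minus <= 0 or self.tau_h_plus <= 0:
            raise ValueError("gating time constants must be positive")


@dataclass
class SynapseParams:
    """Receptor conductances and kinetics of one target population."""

    g_ampa: float = 1.0        # nS per unit gating
    g_nmda: float = 1.0
    g_gaba: float = 1.0
    V_E: float = 0.0           # mV
    V_I: float = -80.0         # mV
    tau_ampa: float = 2.0      # ms
    tau_nmda: float = 100.0    # ms
    tau_gaba: float = 5.0      # ms
    nmda_alpha: float = 0.63   # 1/ms, saturation rate of s_NMDA


@dataclass
class BackgroundDrive:
    """Mean-reverting (Ornstein-Uhlenbeck) background current to a population.

    x <- x + theta (mu - x) dt + sigma sqrt(dt) N(0,1), shared by all neurons
    of the population instance; ``neuron_noise_sd`` adds independent
    per-neuron current noise (held constant within 1 ms).
    """

    mean_level: float = 0.0     # pA
    reversion_rate: float = 0.05  # 1/ms (tau = 20 ms)
    noise_sd: float = 0.0       # pA / sqrt(ms)
    neuron_noise_sd: float = 0.0  # pA
    hetero_sd: float = 0.0      # pA, frozen per-neuron offset (desynchronizes)


@dataclass
class PopulationSpec:
    name: str
    channel: str                  # 'left' | 'right' | 'shared'
    n_neurons: int
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    synapse_params: SynapseParams = field(default_factory=SynapseParams)
    background: BackgroundDrive = field(default_factory=BackgroundDrive)

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")
        if self.name in SHARED and self.channel != "shared":
            raise ValueError(f"{self.name} must be shared")
        if self.name not in SHARED and self.channel not in CHANNELS:
            raise ValueError(f"{self.name} must be channelized")

    @property
    def key(self) -> str:
        return self.name if self.channel == "shared" else f"{self.name}_{self.channel}"


@dataclass
class ConnectivitySpec:
    """One projection. ``within_channel=True`` connects matching channels
    only; ``False`` connects every source instance to every target instance
    (diffuse). Shared populations ignore the flag on their side."""

    source: str
    target: str
    receptor: str
    connection_probability: float
    synaptic_weight: float
    within_channel: bool = True
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.source not in POPULATIONS or self.target not in POPULATIONS:
            raise ValueError(f"unknown population in {self.source}->{self.target}")
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not (0.0 <= self.connection_probability <= 1.0):
            raise ValueError("connection probability outside [0, 1]")


@dataclass
class PlasticityParams:
    """Dopamine-modulated STDP at corticostriatal synapses.

    Spike-timing traces A_pre/A_post feed a signed eligibility E; reward
    prediction errors from a Q-update drive phasic dopamine K_DA, which is
    converted to a plasticity impact by f_X (identity for dSPN, saturating
    for iSPN) and multiplies E in the soft-bounded weight update. All values
    are implementation defaults.
    """

    tau_pre: float = 20.0     # ms
    tau_post: float = 20.0    # ms
    delta_pre: float = 10.0   # spike impact on A_pre (unitless)
    delta_post: float = 6.0   # spike impact on A_post
    tau_e: float = 150.0      # ms, eligibility decay
    tau_dop: float = 20.0     # ms, dopamine decay
    c_scale: float = 20.0     # RPE -> dopamine scaling (jump = c_scale*RPE/tau_dop)
    half_max_c: float = 0.5   # iSPN transfer half-maximum dopamine level
    alpha_w_dspn: float = 5.0   # 1/ms scale of potentiation drive (dSPN; > 0)
    alpha_w_ispn: float = -5.0  # iSPN learning rate (< 0)
    w_max_dspn: float = 0.60
    w_max_ispn: float = 0.60
    w_min: float = 0.001
    alpha_q: float = 0.15     # Q-learning rate
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_w_dspn <= 0 or self.alpha_w_ispn >= 0:
            raise ValueError("alpha_w must be > 0 for dSPN and < 0 for iSPN")
        if not (0.0 < self.alpha_q <= 1.0):
            raise ValueError("alpha_q must lie in (0, 1]")
        if self.half_max_c <= 0:
            raise ValueError("half_max_c must be positive")


@dataclass
class ReadoutConfig:
    """Decision readout from thalamic population rates."""

    threshold_hz: float = 30.0     # decision threshold on channel rate
    window_ms: float = 20.0        # sliding boxcar length (default, not printed)
    step_ms: float = 1.0           # boxcar step
    max_rt_ms: float = 1000.0      # trials exceeding this are dropped
    feature_window: str = "rt"     # 'rt' = [onset, decision]; 'fixed' = fixed span
    fixed_window_ms: float = 300.0


@dataclass
class TaskTiming:
    inter_trial_ms: float = 600.0
    stim_amplitude: float = 0.0    # pA added to Cx during the decision phase
    stim_ramp_ms: float = 60.0     # linear rise time of the stimulus drive


@dataclass
class NetworkConfig:
    populations: list[PopulationSpec]
    connections: list[ConnectivitySpec]
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    timing: TaskTiming = field(default_factory=TaskTiming)
    dt: float = 0.1  # ms, fixed-step exponential-Euler
    # rescale realized static in-weights to their expectation per target
    # neuron (suppresses frozen channel asymmetries from the Bernoulli draw)
    normalize_in_degree: bool = True

    def population(self, key: str) -> PopulationSpec:
        for p in self.populations:
            if p.key == key:
                return p
        raise KeyError(key)

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(_HEADER + yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pops = [
            PopulationSpec(
                name=p["name"],
                channel=p["channel"],
                n_neurons=p["n_neurons"],
                neuron_params=NeuronParams(**p["neuron_params"]),
                synapse_params=SynapseParams(**p["synapse_params"]),
                background=BackgroundDrive(**p["background"]),
            )
            for p in raw["populations"]
        ]
        conns = [ConnectivitySpec(**c) for c in raw["connections"]]
        return cls(
            populations=pops,
            connections=conns,
            plasticity=PlasticityParams(**raw["plasticity"]),
            readout=ReadoutConfig(**raw["readout"]),
            timing=TaskTiming(**raw["timing"]),
            dt=raw["dt"],
            normalize_in_degree=raw.get("normalize_in_degree", True),
        )


_HEADER = """\
# CBGT network configuration.
# Units: capacitance nF, conductance nS, voltage mV, time ms, current pA.
# Every numeric value in this file is an implementation default ("default,
# not printed"): chosen from standard conductance-based integrate-and-fire
# practice and calibrated to produce plausible baseline firing rates and the
# target reaction-time distribution. The only field-fixed constants are the
# NMDA magnesium-block formula, the 30 Hz decision threshold, the 1000 ms
# decision deadline, and the weight floor w_min = 0.001.
"""


def _bursty() -> NeuronParams:
    return NeuronParams(gT=60.0)


def default_config() -> NetworkConfig:
    """The intermediate-regime network used throughout the package."""
    pops: list[PopulationSpec] = []

    def add(name, n, neuron=None, syn=None, bg=None):
        chans = ("shared",) if name in SHARED else CHANNELS
        for ch in chans:
            pops.append(
                PopulationSpec(
                    name=name,
                    channel=ch,
                    n_neurons=n,
                    neuron_params=dataclasses.replace(neuron) if neuron else NeuronParams(),
                    synapse_params=dataclasses.replace(syn) if syn else SynapseParams(),
                    background=dataclasses.replace(bg) if bg else BackgroundDrive(),
                )
            )

    # background means calibrated to baseline rates of roughly
    # Cx 5, CxI 10, dSPN/iSPN 4, FSI 20, GPe 60, STN 20, GPi 60, Th 5 Hz
    bg = BackgroundDrive
    add("Cx", 120, bg=bg(mean_level=150.0, noise_sd=22.0, neuron_noise_sd=100.0, hetero_sd=60.0))
    add("CxI", 80, bg=bg(mean_level=224.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=60.0))
    add("dSPN", 40, bg=bg(mean_level=136.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=50.0))
    add("iSPN", 40, bg=bg(mean_level=134.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=50.0))
    add("FSI", 40, bg=bg(mean_level=234.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=60.0))
    add("GPe", 40, neuron=_bursty(), bg=bg(mean_level=56.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=80.0))
    add("STN", 16, neuron=_bursty(), bg=bg(mean_level=10.0, noise_sd=10.0, neuron_noise_sd=100.0, hetero_sd=60.0))
    add("GPi", 32, bg=bg(mean_level=450.0, noise_sd=10.0, neuron_noise_sd=60.0, hetero_sd=80.0))
    add("Th", 32, bg=bg(mean_level=416.0, noise_sd=6.0, neuron_noise_sd=25.0, hetero_sd=40.0))

    C = ConnectivitySpec
    conns = [
        C("Cx", "Cx", "AMPA", 0.13, 0.25),
        C("Cx", "Cx", "NMDA", 0.13, 0.15),
        C("Cx", "CxI", "AMPA", 0.20, 0.30, within_channel=False),
        C("CxI", "Cx", "GABA", 0.30, 0.45, within_channel=False),
        C("CxI", "CxI", "GABA", 0.30, 0.30, within_channel=False),
        # plastic corticostriatal synapses: one learned weight per synapse
        # drives both the AMPA and the NMDA gating variable
        C("Cx", "dSPN", "AMPA", 0.40, 0.30, plastic=True),
        C("Cx", "iSPN", "AMPA", 0.40, 0.30, plastic=True),
        C("Cx", "FSI", "AMPA", 0.25, 0.15, within_channel=False),
        C("Cx", "STN", "AMPA", 0.25, 0.15),
        # thalamic cortical drive is split within/across channels: the
        # cross-channel share co-activates the competing representation
        C("Cx", "Th", "AMPA", 0.25, 0.18),
        C("Cx", "Th", "AMPA", 0.25, 0.12, within_channel=False),
        C("FSI", "dSPN", "GABA", 0.30, 0.30, within_channel=False),
        C("FSI", "iSPN", "GABA", 0.30, 0.30, within_channel=False),
        C("dSPN", "dSPN", "GABA", 0.15, 0.20),
        C("iSPN", "iSPN", "GABA", 0.15, 0.20),
        C("iSPN", "dSPN", "GABA", 0.15, 0.20),
        C("dSPN", "GPi", "GABA", 0.50, 3.00),  # direct-pathway suppression of output
        C("iSPN", "GPe", "GABA", 0.50, 2.50),
        C("GPe", "STN", "GABA", 0.50, 0.20),
        C("GPe", "GPi", "GABA", 0.40, 0.90),
        C("GPe", "GPe", "GABA", 0.10, 0.10),
        C("STN", "GPe", "AMPA", 0.50, 0.20),
        C("STN", "GPe", "NMDA", 0.50, 0.05),
        C("STN", "GPi", "AMPA", 0.50, 0.15, within_channel=False),
        C("STN", "GPi", "NMDA", 0.50, 0.04, within_channel=False),
        C("GPi", "Th", "GABA", 0.80, 1.00),
        C("Th", "Cx", "AMPA", 0.25, 0.60),
        C("Th", "Cx", "NMDA", 0.25, 0.10),
        C("Th", "dSPN", "AMPA", 0.25, 0.20),
        C("Th", "iSPN", "AMPA", 0.25, 0.20),
    ]
    return NetworkConfig(
        populations=pops,
        connections=conns,
        timing=TaskTiming(stim_amplitude=54.0),
    )


def load_default_yaml() -> NetworkConfig:
    return NetworkConfig.from_yaml(Path(__file__).parent / "data" / "default_network.yaml")
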