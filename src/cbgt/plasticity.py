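"""Dopamine-modulated spike-timing-dependent plasticity at corticostriatal
synapses.

The rule has three interacting parts:

* **Eligibility.** Each neuron keeps a filtered record of its own spiking,
  ``tau dA/dt = Delta X(t) - A`` (a spike adds ``Delta/tau``). Per synapse,
  the signed eligibility integrates timing coincidences,
  ``tau_E dE/dt = X_post A_pre - X_pre A_post - E``: post-after-pre pairings
  raise E, pre-after-post pairings lower it, and with asymmetric spike
  impacts (``delta_pre > delta_post``) E grows with the product of pre- and
  postsynaptic rates during co-activation.
* **Dopamine.** A Q-update tracks the expected reward of each action; the
  reward prediction error of the chosen action sets the phasic dopamine
  increment, ``tau_dop dK/dt = C_scale (DA_inc - K) delta(t) - K``. Negative
  prediction errors produce dopamine dips (K < 0).
* **Weights.** ``dw/dt = [alpha_w E f_X(K) (W_max - w)]_+ +
  [alpha_w E f_X(K) (w - W_min)]_-`` with ``f_dSPN(K) = K`` and
  ``f_iSPN(K) = K / (c + |K|)``; ``alpha_w`` is positive for dSPNs and
  negative for iSPNs, so a dopamine burst potentiates eligible direct-pathway
  synapses and depresses indirect-pathway ones, and a dip does the reverse.
  The soft bounds keep every weight in [W_min, W_max].

These functions are the reference semantics; the fused simulation kernel
replicates them and is cross-checked against them in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PlasticityParams


@dataclass
class TraceState:
    """Per-neuron activity traces and per-synapse eligibility."""

    a_pre: np.ndarray
    a_post: np.ndarray
    e: np.ndarray  # (n_pre, n_post)

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre), np.zeros(n_post), np.zeros((n_pre, n_post)))


@dataclass
class DopamineState:
    k_da: float = 0.0


@dataclass
class QState:
    q: dict = field(default_factory=lambda: {"left": 0.5, "right": 0.5})


def update_traces(
    traces: TraceState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    params: PlasticityParams,
) -> TraceState:
    """Advance A_pre/A_post one step: exponential decay plus ``Delta/tau``
    per spike (the impulse response of the printed trace dynamics)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.a_pre *= np.exp(-dt / params.tau_pre)
    traces.a_post *= np.exp(-dt / params.tau_post)
    traces.a_pre += np.asarray(pre_spikes, dtype=float) * (params.delta_pre / params.tau_pre)
    traces.a_post += np.asarray(post_spikes, dtype=float) * (params.delta_post / params.tau_post)
    return traces


def update_eligibility(
    traces: TraceState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    params: PlasticityParams,
) -> np.ndarray:
    """Advance the per-synapse eligibility one step.

    A postsynaptic spike adds ``A_pre / tau_E`` to its column; a presynaptic
    spike subtracts ``A_post / tau_E`` from its row; otherwise E decays.
    Spike contributions use the trace values before this step's spikes are
    added (call before :func:`update_traces` for the same step).
    """
    traces.e *= np.exp(-dt / params.tau_e)
    post = np.asarray(post_spikes, dtype=float)
    pre = np.asarray(pre_spikes, dtype=float)
    traces.e += np.outer(traces.a_pre, post) / params.tau_e
    traces.e -= np.outer(pre, traces.a_post) / params.tau_e
    return traces.e


def q_update(q_state: QState, choice: str, reward: float, params: PlasticityParams):
    """Update the chosen action's value estimate; return the prediction error
    (the phasic dopamine increment DA_inc = r - Q_chosen, computed before the
    update)."""
    if choice not in q_state.q:
        return q_state, None
    rpe = reward - q_state.q[choice]
    q_state.q[choice] += params.alpha_q * rpe
    return q_state, rpe


def dopamine_step(
    state: DopamineState,
    dt: float,
    params: PlasticityParams,
    rpe_event: float | None = None,
) -> DopamineState:
    """Advance the dopamine level: exponential decay with ``tau_dop``; a
    phasic event jumps K by ``C_scale (DA_inc - K) / tau_dop``."""
    state.k_da *= np.exp(-dt / params.tau_dop)
    if rpe_event is not None:
        state.k_da += params.c_scale * (rpe_event - state.k_da) / params.tau_dop
    return state


def transfer_f(k_da: float | np.ndarray, target_class: str, params: PlasticityParams):
    """Dopamine-to-plasticity transfer: identity for dSPN, saturating
    (sign-preserving, half-maximum at |K| = c) for iSPN."""
    k = np.asarray(k_da, dtype=float)
    if target_class == "dSPN":
        out = k
    elif target_class == "iSPN":
        out = k / (params.half_max_c + np.abs(k))
    else:
        raise ValueError(f"unknown SPN class {target_class!r}")
    return float(out) if out.ndim == 0 else out


def weight_update(
    w: np.ndarray,
    e: np.ndarray,
    k_da: float,
    dt: float,
    target_class: str,
    params: PlasticityParams,
) -> np.ndarray:
    """One soft-bounded weight step. Potentiation drive (positive) relaxes w
    toward W_max; depression drive (negative) relaxes it toward W_min."""
    if target_class == "dSPN":
        alpha, w_max = params.alpha_w_dspn, params.w_max_dspn
    else:
        alpha, w_max = params.alpha_w_ispn, params.w_max_ispn
    if np.any(w < params.w_min - 1e-12) or np.any(w > w_max + 1e-12):
        raise ValueError("weights outside [W_min, W_max] on input")
    drive = alpha * np.asarray(e) * transfer_f(k_da, target_class, params)
    dw = np.where(drive > 0, drive * (w_max - w), drive * (w - params.w_min))
    w = w + dt * dw
    return np.clip(w, params.w_min, w_max)
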