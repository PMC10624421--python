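"""Reduced-Bayesian ideal observer for change-point bandit sequences.

On every trial the observer sees the outcome of the chosen arm and produces

* ``omega`` — the change-point probability: the posterior probability, under a
  constant switch hazard ``H``, that the outcome was generated by a fresh
  reward regime rather than the regime tracked so far, and
* ``delta_B`` — the belief advantage of the objectively optimal arm,
  ``B_optimal - B_suboptimal``.

The belief about the chosen arm follows a delta rule whose learning rate is
omega-modulated through the expected run length: the full run-length
posterior of Bayesian online change-point detection is collapsed onto its
expectation ``ERL``, updated as ``ERL <- (1-omega)(ERL+1) + omega``, and the
chosen arm's value is the run-weighted running mean, updated at rate
``1/(ERL+2)``. A suspected change collapses ERL and produces fast
relearning; long stable runs anneal the rate so beliefs converge to the
arm's true expected reward. The exact filter is retained as a test oracle
(:func:`bocpd_bernoulli`).

Outcome likelihoods are Bernoulli for binary rewards and Gaussian for the
point-valued human protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import LEFT, RIGHT

_EPS = 1e-6


@dataclass
class ObserverConfig:
    """Hazard and outcome model of the reduced observer.

    hazard:
        Prior per-trial change probability ``H``; defaults to the generative
        ``1/k`` of the running condition.
    reward_model:
        ``"bernoulli"`` for 0/1 rewards, ``"gaussian"`` for point rewards.
    prior_mean:
        Arm value beliefs are reset toward this after an inferred change.
    outcome_sd:
        Observation noise of the Gaussian outcome model (point units).
    prior_sd:
        Spread of the new-regime prior in the Gaussian model.
    """

    hazard: float = 0.1
    reward_model: str = "bernoulli"
    prior_mean: float = 0.5
    outcome_sd: float = 1.5
    prior_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.hazard < 1.0):
            raise ValueError("hazard must lie in (0, 1)")
        if self.reward_model not in ("bernoulli", "gaussian"):
            raise ValueError(f"unknown reward_model {self.reward_model!r}")


@dataclass
class ObserverState:
    B: dict = field(default_factory=dict)   # per-arm value beliefs
    erl: float = 1.0                        # expected run length


def _norm_pdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


class IdealObserver:
    """Sequential reduced-Bayesian observer over a two-armed choice/reward log."""

    def __init__(self, config: ObserverConfig | None = None):
        self.config = config if config is not None else ObserverConfig()
        m = self.config.prior_mean
        self.state = ObserverState(B={LEFT: m, RIGHT: m})

    def _likelihoods(self, reward: float, belief: float) -> tuple[float, float]:
        """(likelihood under current belief, likelihood under a new regime)."""
        cfg = self.config
        if cfg.reward_model == "bernoulli":
            p = min(max(belief, _EPS), 1.0 - _EPS)
            lik_cur = p if reward >= 0.5 else 1.0 - p
            lik_new = 0.5  # uniform prior on the new regime's reward rate
        else:
            lik_cur = _norm_pdf(reward, belief, cfg.outcome_sd)
            sd_new = np.hypot(cfg.outcome_sd, cfg.prior_sd)
            lik_new = _norm_pdf(reward, cfg.prior_mean, sd_new)
        return lik_cur, lik_new

    def observe(self, choice: str, reward: float, optimal_side: str) -> tuple[float, float]:
        """Consume one trial; return ``(omega, delta_B)`` for that trial."""
        cfg, st = self.config, self.state
        if choice not in (LEFT, RIGHT):
            # no response: beliefs carry over, omega undefined -> 0
            other = RIGHT if optimal_side == LEFT else LEFT
            return 0.0, st.B[optimal_side] - st.B[other]
        lik_cur, lik_new = self._likelihoods(reward, st.B[choice])
        h = cfg.hazard
        omega = (h * lik_new) / (h * lik_new + (1.0 - h) * lik_cur)
        # omega-modulated delta rule, acting through the expected run length:
        # a suspected change collapses ERL toward 1, which raises the
        # learning rate 1/(ERL+2) for the following outcomes, while long
        # stable runs grow ERL and anneal the rate toward the running mean
        # (which keeps Bernoulli beliefs unbiased at the reward rate).
        st.erl = (1.0 - omega) * (st.erl + 1.0) + omega * 1.0
        st.B[choice] += (reward - st.B[choice]) / (st.erl + 2.0)
        unchosen = RIGHT if choice == LEFT else LEFT
        # a suspected change also discredits what was learned about the other arm
        st.B[unchosen] += omega * (cfg.prior_mean - st.B[unchosen])
        suboptimal = RIGHT if optimal_side == LEFT else LEFT
        delta_b = st.B[optimal_side] - st.B[suboptimal]
        return float(omega), float(delta_b)

    def run(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Process a trial table (columns ``choice``, ``reward``,
        ``optimal_side``) and return per-trial observer estimates."""
        rows = []
        for row in trials.itertuples(index=False):
            omega, delta_b = self.observe(row.choice, row.reward, row.optimal_side)
            rows.append(
                dict(
                    omega=omega,
                    B_left=self.state.B[LEFT],
                    B_right=self.state.B[RIGHT],
                    delta_B=delta_b,
                )
            )
        return pd.DataFrame(rows)


def run_observer(trials: pd.DataFrame, config: ObserverConfig | None = None) -> pd.DataFrame:
    """Convenience wrapper: fresh observer over a full trial table."""
    return IdealObserver(config).run(trials)


def bocpd_bernoulli(
    rewards: np.ndarray, hazard: float, max_run: int | None = None
) -> np.ndarray:
    """Full Bayesian online change-point detector for a Bernoulli sequence.

    Maintains the exact run-length posterior with a Beta(1, 1) prior on the
    reward rate of each regime and returns the change-point probability per
    step (posterior mass assigned to run length zero). Used as the
    independent oracle for the reduced observer; not part of the production
    path.
    """
    rewards = np.asarray(rewards, dtype=float)
    n = len(rewards)
    if max_run is None:
        max_run = n + 1
    # run-length posterior and per-run-length sufficient statistics
    p_run = np.zeros(max_run + 1)
    p_run[0] = 1.0
    successes = np.zeros(max_run + 1)
    counts = np.zeros(max_run + 1)
    omega = np.empty(n)
    for t in range(n):
        r = rewards[t]
        # Beta(1,1) posterior predictive per run length
        pred = (successes + 1.0) / (counts + 2.0)
        lik = np.where(r >= 0.5, pred, 1.0 - pred)
        growth = p_run * lik * (1.0 - hazard)
        # under a change the outcome is scored by the new regime's prior
        # predictive, which is 1/2 for Beta(1, 1) regardless of the outcome
        cp = np.sum(p_run * hazard) * 0.5
        new_p = np.zeros_like(p_run)
        new_p[0] = cp
        new_p[1:] = growth[:-1]
        new_p /= new_p.sum()
        omega[t] = new_p[0]
        new_s = np.zeros_like(successes)
        new_c = np.zeros_like(counts)
        new_s[1:] = successes[:-1] + r
        new_c[1:] = counts[:-1] + 1.0
        p_run, successes, counts = new_p, new_s, new_c
    return omega
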