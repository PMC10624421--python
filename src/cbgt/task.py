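"""Dynamic two-armed bandit environments with reversal (change-point) structure.

Two protocols are provided:

* ``network`` mode — the deterministic protocol used for the spiking-circuit
  simulations: binary rewards at (75%, 25%) conflict and a contingency switch
  exactly every ``k`` trials.
* ``human`` mode — the behavioral protocol: integer point rewards drawn from
  ``round(N(3, 1))``, a 1-point loss on unrewarded choices, probabilistic
  switches with geometric block lengths of mean ``k``, and reaction-time
  deadlines that cost 5 points when violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"

#: points each session starts with in the human protocol
START_POINTS = 60
#: reaction-time window (s); responses at or outside the bounds are penalized
RT_WINDOW = (0.1, 0.75)
#: points lost on a reaction-time violation
RT_PENALTY = 5


@dataclass
class BanditConfig:
    """Reward schedule for a change-point two-armed bandit session.

    Parameters
    ----------
    n_trials:
        Session length in trials.
    p_optimal:
        Probability that a choice of the currently optimal side is rewarded.
    p_suboptimal:
        Reward probability of the other side; defaults to ``1 - p_optimal``
        (the complementary "conflict" convention, e.g. 75%/25%).
    switch_mode:
        ``"every_k"`` — deterministic block boundaries every ``k`` trials
        (network protocol); ``"geometric_mean_k"`` — i.i.d. geometric block
        lengths with mean ``k``, minimum 1 (human protocol).
    k:
        Block length (or mean block length).
    reward_model:
        ``"binary"`` (0/1 rewards) or ``"gaussian_points"`` (integer points
        from round(N(3,1)) when rewarded, -1 when not).
    first_optimal:
        Side that is optimal in the first block.
    """

    n_trials: int
    p_optimal: float = 0.75
    p_suboptimal: float | None = None
    switch_mode: str = "every_k"
    k: int = 10
    reward_model: str = "binary"
    first_optimal: str = LEFT
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p_suboptimal is None:
            self.p_suboptimal = round(1.0 - self.p_optimal, 12)
        if not (0.0 <= self.p_suboptimal <= 1.0 and 0.0 <= self.p_optimal <= 1.0):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if self.p_optimal <= self.p_suboptimal:
            raise ValueError("p_optimal must exceed p_suboptimal")
        if self.k <= 0:
            raise ValueError("block length k must be positive")
        if self.switch_mode not in ("every_k", "geometric_mean_k"):
            raise ValueError(f"unknown switch_mode {self.switch_mode!r}")
        if self.reward_model not in ("binary", "gaussian_points"):
            raise ValueError(f"unknown reward_model {self.reward_model!r}")
        if self.first_optimal not in (LEFT, RIGHT):
            raise ValueError("first_optimal must be 'left' or 'right'")


@dataclass
class TrialRecord:
    """One logged bandit trial."""

    trial: int
    block: int
    optimal_side: str
    choice: str
    reward: float
    rt: float | None = None
    dropped: bool = False
    rt_violation: bool = False
    points_after: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def schedule_switches(config: BanditConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Trial indices at which a new block begins (the first block starts at 0
    and is not listed).

    In ``every_k`` mode boundaries fall exactly at ``k, 2k, ...``; in
    ``geometric_mean_k`` mode block lengths are i.i.d. geometric with mean
    ``k`` (support {1, 2, ...}), matching a constant switch hazard of 1/k.
    """
    if config.switch_mode == "every_k":
        return np.arange(config.k, config.n_trials, config.k, dtype=int)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    boundaries = []
    t = 0
    while True:
        t += int(rng.geometric(1.0 / config.k))
        if t >= config.n_trials:
            break
        boundaries.append(t)
    return np.asarray(boundaries, dtype=int)


def optimal_sides(config: BanditConfig, boundaries: Sequence[int]) -> np.ndarray:
    """Per-trial identity of the optimal side, flipping at each boundary."""
    sides = np.empty(config.n_trials, dtype=object)
    current = config.first_optimal
    prev = 0
    for b in list(boundaries) + [config.n_trials]:
        sides[prev:b] = current
        current = RIGHT if current == LEFT else LEFT
        prev = b
    return sides


def _round_points(x: float) -> int:
    """Round-half-to-even to an integer, floored at 0."""
    return max(int(np.round(x)), 0)


def sample_reward(
    config: BanditConfig, choice: str, optimal_side: str, rng: np.random.Generator
) -> float:
    """Draw one reward outcome for ``choice`` given the block's optimal side."""
    if choice not in (LEFT, RIGHT):
        raise ValueError(f"invalid choice {choice!r}")
    p = config.p_optimal if choice == optimal_side else config.p_suboptimal
    rewarded = rng.random() < p
    if config.reward_model == "binary":
        return float(rewarded)
    if rewarded:
        return float(_round_points(rng.normal(3.0, 1.0)))
    return -1.0


def apply_rt_rules(rt: float | None, points: float) -> tuple[float, bool]:
    """Apply the human-protocol reaction-time deadline to a point total.

    Responses in ``(0.1, 0.75)`` s are accepted; responses at or outside the
    bounds, or missing responses, cost ``RT_PENALTY`` points.
    """
    if rt is not None and rt < 0:
        raise ValueError("negative reaction time")
    lo, hi = RT_WINDOW
    if rt is None or rt <= lo or rt >= hi:
        return points - RT_PENALTY, True
    return points, False


class BanditEnv:
    """Stateful session: call :meth:`step` once per trial with the agent's choice."""

    def __init__(self, config: BanditConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.boundaries = schedule_switches(config, self.rng)
        self.sides = optimal_sides(config, self.boundaries)
        self.trial = 0
        self.points = float(START_POINTS)
        self.records: list[TrialRecord] = []

    @property
    def done(self) -> bool:
        return self.trial >= self.config.n_trials

    def optimal_side(self) -> str:
        return self.sides[self.trial]

    def step(self, choice: str, rt: float | None = None, dropped: bool = False) -> TrialRecord:
        if self.done:
            raise RuntimeError("session exhausted")
        side = self.sides[self.trial]
        block = int(np.searchsorted(self.boundaries, self.trial, side="right"))
        violation = False
        if dropped or choice == "none":
            if self.config.reward_model == "gaussian_points":
                self.points, violation = apply_rt_rules(None, self.points)
            rec = TrialRecord(self.trial, block, side, "none", 0.0, rt, True, violation, self.points)
        else:
            reward = sample_reward(self.config, choice, side, self.rng)
            if self.config.reward_model == "gaussian_points":
                self.points += reward
                self.points, violation = apply_rt_rules(rt, self.points)
            rec = TrialRecord(
                self.trial, block, side, choice, reward, rt, False, violation, self.points
            )
        self.records.append(rec)
        self.trial += 1
        return rec

    def to_frame(self) -> pd.DataFrame:
        return trials_to_frame(self.records)


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def replay_points(frame: pd.DataFrame) -> np.ndarray:
    """Recompute the running point total from a logged human-mode trial table."""
    points = float(START_POINTS)
    out = np.empty(len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        if not row.dropped:
            points += row.reward
        if row.rt_violation:
            points -= RT_PENALTY
        out[i] = points
    return out


def condition_grid() -> list[BanditConfig]:
    """The nine human sessions: every (p, k) combination at 300 trials each."""
    grid = []
    for p in (0.65, 0.75, 0.85):
        for k in (10, 20, 30):
            grid.append(
                BanditConfig(
                    n_trials=300,
                    p_optimal=p,
                    switch_mode="geometric_mean_k",
                    k=k,
                    reward_model="gaussian_points",
                )
            )
    return grid
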