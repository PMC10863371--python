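"""Generative model of the two-stage sequential choice task.

A trial has two stages: a binary first-stage choice leads probabilistically
(common vs. rare transition) to one of two second-stage states, where a second
binary choice is rewarded stochastically.  Reward probabilities for the four
second-stage options drift as Gaussian random walks reflected at fixed bounds,
which keeps subjects (and agents) learning throughout a session.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

COMMON = "common"
RARE = "rare"

#: column order of a serialized trial table
TRIAL_COLUMNS = [
    "subject_id",
    "intervention",
    "session_order",
    "trial",
    "choice1",
    "state2",
    "choice2",
    "transition",
    "reward",
    "missing",
]

_SESSION_COLUMNS = TRIAL_COLUMNS[3:]


class ContractError(ValueError):
    """An agent or caller violated an interface contract."""


@dataclasses.dataclass(frozen=True)
class TaskConfig:
    """Immutable description of the task environment.

    Defaults reproduce the standard task variant: 201 trials per session, 70/30
    transition structure, reward-probability walks reflected at [0.25, 0.75],
    and a 20-cent reward per rewarded trial.
    """

    n_trials: int = 201
    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    reward_magnitude: float = 20.0
    init_probs: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n_trials, (int, np.integer)) and self.n_trials > 0):
            raise ValueError(f"n_trials must be a positive integer, got {self.n_trials!r}")
        lo, hi = self.walk_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 < lower < upper < 1, got {self.walk_bounds!r}")
        if not (0.5 < self.p_common < 1.0):
            raise ValueError(f"p_common must lie in (0.5, 1), got {self.p_common!r}")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        if self.init_probs is not None:
            probs = tuple(self.init_probs)
            if len(probs) != 4 or any(not (lo <= p <= hi) for p in probs):
                raise ValueError("init_probs must be four probabilities inside walk_bounds")
            object.__setattr__(self, "init_probs", probs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["walk_bounds"] = list(self.walk_bounds)
        if self.init_probs is not None:
            d["init_probs"] = list(self.init_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "walk_bounds" in d:
            d["walk_bounds"] = tuple(d["walk_bounds"])
        if d.get("init_probs") is not None:
            d["init_probs"] = tuple(d["init_probs"])
        return cls(**d)


@dataclasses.dataclass
class RewardWalkState:
    """Current reward probabilities, one per second-stage option.

    ``probs`` has shape (2, 2): probs[state, option].
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float).reshape(2, 2)


def _fold(x: float, lo: float, hi: float) -> float:
    """Fold a value back inside [lo, hi] by repeated reflection at the bounds."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalkState:
    """Draw the four initial reward probabilities.

    Uses ``config.init_probs`` if given, otherwise independent uniforms over
    the walk bounds.
    """
    lo, hi = config.walk_bounds
    if config.init_probs is not None:
        return RewardWalkState(np.array(config.init_probs, dtype=float))
    return RewardWalkState(rng.uniform(lo, hi, size=4))


def step_walk(state: RewardWalkState, config: TaskConfig, rng: np.random.Generator) -> RewardWalkState:
    """Advance each reward probability by one reflected Gaussian step."""
    lo, hi = config.walk_bounds
    eps = rng.normal(0.0, config.walk_sd, size=(2, 2))
    new = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            new[i, j] = _fold(state.probs[i, j] + eps[i, j], lo, hi)
    return RewardWalkState(new)


def simulate_walk(config: TaskConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n_steps`` of the reward walk; returns an (n_steps, 4) array."""
    state = init_walks(config, rng)
    out = np.empty((n_steps, 4))
    for t in range(n_steps):
        state = step_walk(state, config, rng)
        out[t] = state.probs.ravel()
    return out


def common_state(choice1: int) -> int:
    """The second-stage state commonly reached from a first-stage action.

    The action-to-state mapping is fixed (action a -> state a); on-screen
    counterbalancing is presentation-level and does not affect the statistics.
    """
    return int(choice1)


def sample_transition(choice1: int, config: TaskConfig, rng: np.random.Generator) -> tuple[int, str]:
    if choice1 not in (0, 1):
        raise ContractError(f"choice1 must be 0 or 1, got {choice1!r}")
    if rng.random() < config.p_common:
        return common_state(choice1), COMMON
    return 1 - common_state(choice1), RARE


def sample_reward(prob: float, config: TaskConfig, rng: np.random.Generator) -> int:
    return int(rng.random() < prob)


class AgentPolicy(Protocol):
    """What ``run_session`` needs from an agent."""

    def reset(self) -> None: ...

    def stage1_probs(self) -> Sequence[float]: ...

    def stage2_probs(self, state2: int) -> Sequence[float]: ...

    def update(self, choice1: int, state2: int, choice2: int, reward: int) -> None: ...


class UniformRandomPolicy:
    """Value-free policy choosing uniformly at both stages (testing aid)."""

    def reset(self) -> None:
        pass

    def stage1_probs(self):
        return (0.5, 0.5)

    def stage2_probs(self, state2: int):
        return (0.5, 0.5)

    def update(self, choice1, state2, choice2, reward) -> None:
        pass


def _checked_choice(probs: Sequence[float], rng: np.random.Generator, where: str) -> int:
    p0, p1 = float(probs[0]), float(probs[1])
    if not (math.isfinite(p0) and math.isfinite(p1)) or p0 < 0 or p1 < 0:
        raise ContractError(f"{where}: invalid probabilities {probs!r}")
    if abs(p0 + p1 - 1.0) > 1e-9:
        raise ContractError(f"{where}: probabilities must sum to 1, got {p0 + p1}")
    return int(rng.random() >= p0)


def run_session(
    agent: AgentPolicy,
    config: TaskConfig,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one full session of the task for a single agent.

    Each trial the reward walk is stepped, first- and second-stage choices are
    sampled from the agent, the transition and reward are sampled from the
    environment, and the agent's learning update is applied.  With probability
    ``missing_rate`` a trial is missing: no choices are recorded, the agent's
    values are frozen, and the walk still drifts.

    Returns a trial table with columns trial, choice1, state2, choice2,
    transition, reward, missing (choices/transition are NA on missing trials).
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    agent.reset()
    walk = init_walks(config, rng)
    rows = []
    for t in range(config.n_trials):
        walk = step_walk(walk, config, rng)
        if missing_rate > 0.0 and rng.random() < missing_rate:
            rows.append((t, pd.NA, pd.NA, pd.NA, pd.NA, 0, True))
            continue
        choice1 = _checked_choice(agent.stage1_probs(), rng, "stage1_probs")
        state2, transition = sample_transition(choice1, config, rng)
        choice2 = _checked_choice(agent.stage2_probs(state2), rng, "stage2_probs")
        prob = float(walk.probs[state2, choice2])
        reward = sample_reward(prob, config, rng)
        agent.update(choice1, state2, choice2, reward)
        rows.append((t, choice1, state2, choice2, transition, reward, False))
    df = pd.DataFrame(rows, columns=_SESSION_COLUMNS)
    for col in ("choice1", "state2", "choice2"):
        df[col] = df[col].astype("Int64")
    df["transition"] = df["transition"].astype("string")
    df["reward"] = df["reward"].astype(int)
    df["missing"] = df["missing"].astype(bool)
    return df
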