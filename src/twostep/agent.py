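"""Seven-parameter hybrid model-free/model-based reinforcement-learning agent.

The model-free component learns first- and second-stage action values by a
SARSA temporal-difference rule, with second-stage prediction errors passed
back to the first stage through the stage-skipping weight ``lam``.  The
model-based component plans over the known transition structure.  First-stage
choice follows a softmax over the ``omega``-weighted mixture of the two value
systems plus a perseveration bonus ``pi`` for repeating the previous
first-stage action.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .task import ContractError, common_state

PARAM_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "omega", "pi")

#: value all Q entries start at; midpoint of the reward-probability range
DEFAULT_Q_INIT = 0.5


@dataclasses.dataclass(frozen=True)
class AgentParams:
    """The seven free parameters of the hybrid agent.

    beta1/beta2 are the stage-specific softmax inverse temperatures,
    alpha1/alpha2 the stage-specific learning rates, ``lam`` the
    stage-skipping eligibility weight, ``omega`` the model-based weight
    (0 = pure model-free, 1 = pure model-based) and ``pi`` the first-stage
    repetition bias (unbounded; added to the chosen logit, indicator-coded
    0/1 — an offset recoding only re-parameterizes pi).
    """

    beta1: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    omega: float
    pi: float

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a finite non-negative real, got {v!r}")
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not math.isfinite(self.pi):
            raise ValueError(f"pi must be finite, got {self.pi!r}")

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**{name: d[name] for name in PARAM_NAMES})

    def astuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in PARAM_NAMES)


@dataclasses.dataclass
class QState:
    """Learned values: two first-stage MF values and 2x2 second-stage values."""

    q_mf1: np.ndarray
    q2: np.ndarray
    prev_choice1: int | None = None

    @classmethod
    def fresh(cls, q_init: float = DEFAULT_Q_INIT) -> "QState":
        return cls(q_mf1=np.full(2, q_init, dtype=float), q2=np.full((2, 2), q_init, dtype=float))

    def copy(self) -> "QState":
        return QState(self.q_mf1.copy(), self.q2.copy(), self.prev_choice1)


def mb_values(qstate: QState, p_common: float) -> np.ndarray:
    """Model-based first-stage values: expected best second-stage value under
    the true transition probabilities."""
    best = qstate.q2.max(axis=1)  # best option value per second-stage state
    out = np.empty(2)
    for a in (0, 1):
        cs = common_state(a)
        out[a] = p_common * best[cs] + (1.0 - p_common) * best[1 - cs]
    return out


def _softmax2(logits: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(logits)):
        raise ContractError(f"non-finite choice logits: {logits!r}")
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def stage1_choice_probs(qstate: QState, params: AgentParams, p_common: float) -> np.ndarray:
    """Softmax over the omega-weighted MB/MF mixture plus perseveration."""
    net = params.omega * mb_values(qstate, p_common) + (1.0 - params.omega) * qstate.q_mf1
    logits = params.beta1 * net
    if qstate.prev_choice1 is not None:
        logits = logits.copy()
        logits[qstate.prev_choice1] += params.pi
    return _softmax2(logits)


def stage2_choice_probs(qstate: QState, state2: int, params: AgentParams) -> np.ndarray:
    if state2 not in (0, 1):
        raise ContractError(f"state2 must be 0 or 1, got {state2!r}")
    return _softmax2(params.beta2 * qstate.q2[state2])


def update_mf(qstate: QState, choice1: int, state2: int, choice2: int, reward: float, params: AgentParams) -> QState:
    """One SARSA update after a completed (non-missing) trial.

    First the stage-1 value moves toward the chosen stage-2 value (delta1),
    then the stage-2 value moves toward the reward (delta2) and delta2 is
    passed back to stage 1 scaled by alpha1*lam.  Unchosen entries untouched.
    Returns a new QState; the input is not modified.
    """
    for name, v in (("choice1", choice1), ("state2", state2), ("choice2", choice2)):
        if v not in (0, 1):
            raise ContractError(f"{name} must be 0 or 1 (missing trials must be skipped by the caller), got {v!r}")
    out = qstate.copy()
    delta1 = out.q2[state2, choice2] - out.q_mf1[choice1]
    out.q_mf1[choice1] += params.alpha1 * delta1
    delta2 = reward - out.q2[state2, choice2]
    out.q2[state2, choice2] += params.alpha2 * delta2
    out.q_mf1[choice1] += params.alpha1 * params.lam * delta2
    out.prev_choice1 = int(choice1)
    return out


class HybridAgent:
    """Stateful policy binding AgentParams + QState to the session interface."""

    def __init__(self, params: AgentParams, p_common: float = 0.7, q_init: float = DEFAULT_Q_INIT):
        self.params = params
        self.p_common = p_common
        self.q_init = q_init
        self.qstate = QState.fresh(q_init)

    def reset(self) -> None:
        self.qstate = QState.fresh(self.q_init)

    def stage1_probs(self) -> np.ndarray:
        return stage1_choice_probs(self.qstate, self.params, self.p_common)

    def stage2_probs(self, state2: int) -> np.ndarray:
        return stage2_choice_probs(self.qstate, state2, self.params)

    def update(self, choice1: int, state2: int, choice2: int, reward: int) -> None:
        self.qstate = update_mf(self.qstate, choice1, state2, choice2, reward, self.params)


def make_agent(params: AgentParams, p_common: float = 0.7, q_init: float = DEFAULT_Q_INIT) -> HybridAgent:
    return HybridAgent(params, p_common=p_common, q_init=q_init)
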