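"""Hybrid model-based / model-free reinforcement-learning agent.

The agent carries five parameters:

* ``alpha`` — learning rate in (0, 1);
* ``beta_mb`` — weight of the model-based stage-1 values (>= 0);
* ``beta_mf`` — weight of the model-free stage-1 values (>= 0);
* ``beta_2`` — stage-2 softmax inverse temperature;
* ``rho`` — perseveration weight on repeating the previous stage-1 choice.

Stage-2 values ``Q2[s, c]`` update with the decay-plus-reward rule
``Q <- (1 - alpha) * Q + r`` (the conventional error-driven rule
``Q <- Q + alpha * (r - Q)`` is available via ``TaskConfig.delta_rule``).
Model-based stage-1 values mix the best chest value on each island by the
transition probabilities; model-free stage-1 values apply the same update
rule to the chosen ship with the end-of-trial reward. Stage-1 choice
probabilities are a unit-temperature softmax of
``beta_mb * Qmb + beta_mf * Qmf + rho * repeat-indicator``.

All value functions start at 0.5. Note the decay-plus-reward rule has
fixed point ``1 / alpha`` under constant reward, so values may exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .task import TaskConfig, init_walks, sample_reward, sample_transition, step_walks

__all__ = [
    "AgentParams",
    "AgentState",
    "update_stage2_value",
    "update_stage1_mf",
    "compute_mb_values",
    "stage2_choice_probs",
    "stage1_choice_probs",
    "simulate_condition",
]

Q_INIT = 0.5


class ParameterError(ValueError):
    """Raised for agent parameters outside their support."""


@dataclass(frozen=True)
class AgentParams:
    """The five free parameters of the hybrid agent."""

    alpha: float
    beta_mb: float
    beta_mf: float
    beta_2: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.beta_mb < 0 or self.beta_mf < 0:
            raise ParameterError("beta_mb and beta_mf must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta_mb, self.beta_mf, self.beta_2, self.rho])


@dataclass(frozen=True)
class AgentState:
    """Mutable quantities of the agent, held immutably between updates.

    ``q2`` is the 2x2 array of stage-2 state-action values, ``q_mf`` the
    2-vector of stage-1 model-free ship values, ``prev_choice`` the last
    stage-1 choice (None on the first trial).
    """

    q2: np.ndarray
    q_mf: np.ndarray
    prev_choice: Optional[int] = None

    @classmethod
    def initial(cls) -> "AgentState":
        return cls(q2=np.full((2, 2), Q_INIT), q_mf=np.full(2, Q_INIT), prev_choice=None)


def _update(q: float, reward: float, alpha: float, delta_rule: bool) -> float:
    if delta_rule:
        return q + alpha * (reward - q)
    return (1.0 - alpha) * q + reward


def update_stage2_value(
    state: AgentState, s2: int, c2: int, reward: float, alpha: float, delta_rule: bool = False
) -> AgentState:
    """Update the visited stage-2 (island, chest) value with the trial reward."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    q2 = state.q2.copy()
    q2[s2, c2] = _update(q2[s2, c2], reward, alpha, delta_rule)
    return replace(state, q2=q2)


def update_stage1_mf(
    state: AgentState, c1: int, reward: float, alpha: float, delta_rule: bool = False
) -> AgentState:
    """Update the chosen ship's model-free value with the end-of-trial reward."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    q_mf = state.q_mf.copy()
    q_mf[c1] = _update(q_mf[c1], reward, alpha, delta_rule)
    return replace(state, q_mf=q_mf)


def compute_mb_values(state: AgentState, p_common: float = 0.7) -> np.ndarray:
    """Model-based ship values: transition-weighted best chest per island.

    ``Qmb[L] = p_common * max_c Q2[island 0, c] + (1 - p_common) * max_c
    Q2[island 1, c]`` and symmetrically for the right ship. Both entries
    are recomputed from the current stage-2 values every trial.
    """
    best = state.q2.max(axis=1)
    return np.array(
        [
            p_common * best[0] + (1.0 - p_common) * best[1],
            p_common * best[1] + (1.0 - p_common) * best[0],
        ]
    )


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def stage2_choice_probs(state: AgentState, s2: int, beta_2: float) -> np.ndarray:
    """Softmax over the two chests on island ``s2`` at inverse temperature beta_2."""
    return _softmax2(beta_2 * state.q2[s2])


def stage1_choice_probs(
    state: AgentState, params: AgentParams, p_common: float = 0.7
) -> np.ndarray:
    """Softmax over ships of the combined MB + MF + perseveration values.

    The softmax has implicit unit temperature; the previous-choice
    indicator is zero for both ships on the first trial.
    """
    q_mb = compute_mb_values(state, p_common)
    repeat = np.zeros(2)
    if state.prev_choice is not None:
        repeat[state.prev_choice] = 1.0
    logits = params.beta_mb * q_mb + params.beta_mf * state.q_mf + params.rho * repeat
    return _softmax2(logits)


def simulate_condition(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    record_probs: bool = False,
) -> dict:
    """Simulate one condition (fresh walks, fresh agent state).

    Returns a dict of per-trial arrays: ``choice1``, ``state2``,
    ``choice2``, ``reward`` (ints), ``transition`` (str array), ``block``
    (1-based), and optionally the stage-1/stage-2 probabilities assigned
    to the choices actually made (``p_choice1``, ``p_choice2``) for
    likelihood cross-checks.
    """
    n = config.n_trials_per_condition
    choice1 = np.empty(n, dtype=np.int64)
    state2 = np.empty(n, dtype=np.int64)
    choice2 = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=np.int64)
    transition = np.empty(n, dtype=object)
    p1_rec = np.empty(n) if record_probs else None
    p2_rec = np.empty(n) if record_probs else None

    state = AgentState.initial()
    walks = init_walks(config, rng)
    for t in range(n):
        p1 = stage1_choice_probs(state, params, config.p_common)
        c1 = int(rng.random() < p1[1])
        s2, label = sample_transition(c1, config, rng)
        p2 = stage2_choice_probs(state, s2, params.beta_2)
        c2 = int(rng.random() < p2[1])
        r = sample_reward(s2, c2, walks, rng)

        state = update_stage2_value(state, s2, c2, r, params.alpha, config.delta_rule)
        state = update_stage1_mf(state, c1, r, params.alpha, config.delta_rule)
        state = replace(state, prev_choice=c1)
        walks = step_walks(walks, config, rng)

        choice1[t], state2[t], choice2[t], reward[t] = c1, s2, c2, r
        transition[t] = label
        if record_probs:
            p1_rec[t] = p1[c1]
            p2_rec[t] = p2[c2]

    out = {
        "choice1": choice1,
        "state2": state2,
        "choice2": choice2,
        "reward": reward,
        "transition": transition,
        "block": 1 + np.arange(n) // config.block_length,
    }
    if record_probs:
        out["p_choice1"] = p1_rec
        out["p_choice2"] = p2_rec
    return out
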