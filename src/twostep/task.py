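"""Generative model of the two-step task environment.

The task is the classic two-stage decision paradigm: a first-stage choice
between two options (ships) leads probabilistically to one of two
second-stage states (islands), each offering two options (chests) that pay
a unit reward with a probability that drifts over trials.

The environment has two pieces of structure:

* a fixed transition matrix — each first-stage option reaches its majority
  ("common") second-stage state with probability ``p_common`` (default 0.7)
  and the other ("rare") state otherwise;
* four independent reward-probability random walks, one per
  (island, chest) slot, driven by Gaussian increments of standard
  deviation ``sigma_walk`` and kept inside ``[walk_lower, walk_upper]``
  by reflection at the bounds (clipping is available as an option).

Two of the four walks start in a high band and two in a low band, with the
assignment of bands to (island, chest) slots randomised per initialisation.

Internally choices and states are coded 0/1 (0 = left ship / blue island);
exported logs use the labels ``L``/``R`` and 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "TaskConfig",
    "RewardWalks",
    "init_walks",
    "step_walks",
    "generate_walks",
    "sample_transition",
    "sample_reward",
    "walks_to_frame",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Fixed structure of the two-step environment.

    Parameters
    ----------
    p_common
        Probability that a first-stage choice reaches its majority
        second-stage state. Must lie in (0.5, 1].
    sigma_walk
        Standard deviation of the per-trial Gaussian increment of each
        reward-probability walk.
    walk_lower, walk_upper
        Hard bounds of the reward probabilities.
    start_range_high, start_range_low
        Intervals from which the four walks draw their starting values:
        two walks start uniformly in the high band, two in the low band.
    n_trials_per_condition
        Trials per condition (two blocks with a break in between).
    block_length
        Trials per block; ``n_trials_per_condition`` must be a multiple.
    boundary
        ``"reflect"`` (default) or ``"clip"`` — how walk values are mapped
        back into the bounds.
    delta_rule
        If True, value updates use the conventional error-driven form
        ``Q <- Q + alpha * (r - Q)``; if False (default) the decay-plus-
        reward form ``Q <- (1 - alpha) * Q + r``.
    """

    p_common: float = 0.7
    sigma_walk: float = 0.0275
    walk_lower: float = 0.25
    walk_upper: float = 0.75
    start_range_high: Tuple[float, float] = (0.58, 0.72)
    start_range_low: Tuple[float, float] = (0.31, 0.45)
    n_trials_per_condition: int = 150
    block_length: int = 75
    n_stage2_states: int = 2
    n_choices_per_stage: int = 2
    boundary: str = "reflect"
    delta_rule: bool = False

    def __post_init__(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise ConfigurationError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.sigma_walk < 0:
            raise ConfigurationError("sigma_walk must be non-negative")
        if not (self.walk_lower < self.walk_upper):
            raise ConfigurationError("walk_lower must be below walk_upper")
        for name, (lo, hi) in (
            ("start_range_high", self.start_range_high),
            ("start_range_low", self.start_range_low),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name} is empty: {(lo, hi)}")
            if lo < self.walk_lower or hi > self.walk_upper:
                raise ConfigurationError(f"{name} must lie within the walk bounds")
        if self.n_trials_per_condition % self.block_length != 0:
            raise ConfigurationError(
                "n_trials_per_condition must be an integer multiple of block_length"
            )
        if self.boundary not in ("reflect", "clip"):
            raise ConfigurationError(f"unknown boundary mode {self.boundary!r}")

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common

    @property
    def n_blocks(self) -> int:
        return self.n_trials_per_condition // self.block_length


@dataclass(frozen=True)
class RewardWalks:
    """Current reward probabilities, one per (island, chest) slot.

    ``probs[s, c]`` is the probability that chest ``c`` on island ``s``
    pays a reward on the current trial.
    """

    probs: np.ndarray  # shape (2, 2)
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.probs.shape != (2, 2):
            raise ConfigurationError("walk probabilities must form a 2x2 array")


def init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalks:
    """Draw the four starting reward probabilities.

    Two slots are assigned the high starting band and two the low band,
    with the pairing chosen uniformly at random among the six possible
    assignments; within each band starts are uniform.
    """
    lo_h, hi_h = config.start_range_high
    lo_l, hi_l = config.start_range_low
    starts = np.empty(4)
    high_slots = rng.choice(4, size=2, replace=False)
    is_high = np.zeros(4, dtype=bool)
    is_high[high_slots] = True
    starts[is_high] = rng.uniform(lo_h, hi_h, size=2)
    starts[~is_high] = rng.uniform(lo_l, hi_l, size=2)
    return RewardWalks(probs=starts.reshape(2, 2), trial_index=0)


def _fold(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Map values into [lower, upper] by repeated reflection at the bounds."""
    width = upper - lower
    y = np.mod(x - lower, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lower + y


def step_walks(walks: RewardWalks, config: TaskConfig, rng: np.random.Generator) -> RewardWalks:
    """Advance all four walks by one Gaussian increment.

    Out-of-bound values are reflected back into the interval (or clipped,
    per ``config.boundary``), so the output is always valid.
    """
    raw = walks.probs + rng.normal(0.0, config.sigma_walk, size=(2, 2))
    if config.boundary == "reflect":
        new = _fold(raw, config.walk_lower, config.walk_upper)
    else:
        new = np.clip(raw, config.walk_lower, config.walk_upper)
    return RewardWalks(probs=new, trial_index=walks.trial_index + 1)


def generate_walks(
    config: TaskConfig, rng: np.random.Generator, n_trials: int | None = None
) -> np.ndarray:
    """Full walk trajectory of shape ``(n_trials, 2, 2)``."""
    n = config.n_trials_per_condition if n_trials is None else int(n_trials)
    out = np.empty((n, 2, 2))
    walks = init_walks(config, rng)
    for t in range(n):
        out[t] = walks.probs
        if t < n - 1:
            walks = step_walks(walks, config, rng)
    return out


def sample_transition(
    stage1_choice: int, config: TaskConfig, rng: np.random.Generator
) -> Tuple[int, str]:
    """Sample the second-stage state reached by a first-stage choice.

    Choice 0 (left ship) reaches state 0 with probability ``p_common``;
    choice 1 reaches state 1 with the same probability. Returns the state
    and the label ``"common"``/``"rare"``.
    """
    if stage1_choice not in (0, 1):
        raise ValueError(f"stage-1 choice must be 0 or 1, got {stage1_choice}")
    common = rng.random() < config.p_common
    state = stage1_choice if common else 1 - stage1_choice
    return state, ("common" if common else "rare")


def sample_reward(
    state: int, stage2_choice: int, walks: RewardWalks, rng: np.random.Generator
) -> int:
    """Bernoulli reward draw at the current (island, chest) walk probability."""
    p = walks.probs[state, stage2_choice]
    return int(rng.random() < p)


def walks_to_frame(trajectory: np.ndarray):
    """Export a walk trajectory as a tidy table (trial, state, chest, p_reward).

    Trials are 1-based and states 1/2 in the export, matching the trial logs.
    """
    import pandas as pd

    n = trajectory.shape[0]
    rows = {
        "trial": np.repeat(np.arange(1, n + 1), 4),
        "state": np.tile(np.repeat([1, 2], 2), n),
        "chest": np.tile(["L", "R"], 2 * n),
        "p_reward": trajectory.reshape(n, 4).ravel(),
    }
    return pd.DataFrame(rows)
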