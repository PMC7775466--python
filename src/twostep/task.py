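"""Two-step task structure and stochastic environment.

The task has a single first-stage state with two actions.  Each action leads
*commonly* (probability ``p_common``, default 0.7) to its majority second-stage
state and *rarely* (``1 - p_common``) to the other.  Action 0's majority
destination is second-stage state 0; action 1's is state 1.  Each second-stage
state offers two stimuli whose reward probabilities drift over trials as
Gaussian random walks reflected at fixed bounds, shared by every subject of a
cohort so that all agents face the same environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "SessionData",
    "make_reward_walks",
    "sample_transition",
    "sample_reward",
]

COMMON = "common"
RARE = "rare"


@dataclass(frozen=True)
class TaskConfig:
    """Structural constants of the two-step task.

    Parameters
    ----------
    n_trials : int
        Trials per session (default 201).
    p_common : float
        Probability of the majority ("common") transition; must be in (0.5, 1).
    walk_lower, walk_upper : float
        Reflecting bounds of the reward-probability random walks.
    walk_sd : float
        Standard deviation of the per-trial Gaussian walk step.
    reward_value : float
        Payoff units per rewarded trial; the monetary framing is presentation
        only, so outcomes are coded 0/1.
    """

    n_trials: int = 201
    p_common: float = 0.7
    walk_lower: float = 0.25
    walk_upper: float = 0.75
    walk_sd: float = 0.025
    reward_value: float = 1.0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_common < 1:
            raise ValueError(f"p_common must lie in (0.5, 1), got {self.p_common}")
        if not 0 <= self.walk_lower < self.walk_upper <= 1:
            raise ValueError(
                "walk bounds must satisfy 0 <= lower < upper <= 1, got "
                f"[{self.walk_lower}, {self.walk_upper}]"
            )
        if self.n_trials < 2:
            raise ValueError(f"n_trials must be >= 2, got {self.n_trials}")
        if self.walk_sd < 0:
            raise ValueError(f"walk_sd must be non-negative, got {self.walk_sd}")


@dataclass(frozen=True)
class RewardWalk:
    """Per-trial reward probabilities for the four second-stage stimuli.

    ``probs`` has shape ``(n_trials, 4)``; column ``2*state + action`` is the
    reward probability of choosing `action` in second-stage `state`.
    """

    probs: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, second_state: int, second_choice: int, trial: int) -> float:
        if not 0 <= trial < self.n_trials:
            raise IndexError(f"trial {trial} outside walk of length {self.n_trials}")
        return float(self.probs[trial, 2 * second_state + second_choice])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=["p0", "p1", "p2", "p3"])
        df.insert(0, "trial", np.arange(self.n_trials))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1) -> "RewardWalk":
        probs = df.sort_values("trial")[["p0", "p1", "p2", "p3"]].to_numpy(float)
        return cls(probs=probs, seed=seed)


def _reflect(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    # fold values back into [lower, upper]; repeat in case a step overshoots
    # more than one full width (cannot happen for realistic walk_sd, but cheap)
    while np.any((x < lower) | (x > upper)):
        x = np.where(x < lower, 2 * lower - x, x)
        x = np.where(x > upper, 2 * upper - x, x)
    return x


def make_reward_walks(
    config: TaskConfig,
    seed: int,
    init: np.ndarray | None = None,
    n_trials: int | None = None,
) -> RewardWalk:
    """Generate the four reflected Gaussian reward-probability walks.

    Parameters
    ----------
    config : TaskConfig
        Supplies bounds and step SD.
    seed : int
        Seeds both the initial values and the steps; identical seeds give
        bit-identical walks.
    init : array-like of 4 floats, optional
        Initial probabilities.  Defaults to independent uniform draws within
        the bounds, the convention of the original task.
    n_trials : int, optional
        Override ``config.n_trials`` (e.g. for long-run checks).
    """
    n = config.n_trials if n_trials is None else int(n_trials)
    rng = np.random.default_rng(seed)
    if init is None:
        start = rng.uniform(config.walk_lower, config.walk_upper, size=4)
    else:
        start = np.asarray(init, dtype=float)
        if start.shape != (4,):
            raise ValueError("init must contain exactly 4 probabilities")
        if np.any((start < config.walk_lower) | (start > config.walk_upper)):
            raise ValueError("initial probabilities must lie within the walk bounds")
    probs = np.empty((n, 4))
    probs[0] = start
    for t in range(1, n):
        step = rng.normal(0.0, config.walk_sd, size=4)
        probs[t] = _reflect(probs[t - 1] + step, config.walk_lower, config.walk_upper)
    return RewardWalk(probs=probs, seed=seed)


def sample_transition(
    first_choice: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the second-stage state reached after a first-stage choice.

    Returns ``(second_state, label)`` where the label is ``"common"`` when the
    majority destination was reached (probability ``p_common``).
    """
    if first_choice not in (0, 1):
        raise ValueError(f"first_choice must be 0 or 1, got {first_choice}")
    common = rng.random() < config.p_common
    second_state = first_choice if common else 1 - first_choice
    return second_state, (COMMON if common else RARE)


def sample_reward(
    second_state: int,
    second_choice: int,
    trial_index: int,
    walk: RewardWalk,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward for the chosen second-stage stimulus at a trial."""
    p = walk.prob(second_state, second_choice, trial_index)
    return int(rng.random() < p)


@dataclass(frozen=True)
class TrialRecord:
    """One completed two-step trial (0-indexed states and actions)."""

    index: int
    first_choice: int
    transition: str
    second_state: int
    second_choice: int
    reward: int


@dataclass
class SessionData:
    """A subject's trial log.

    Trials are stored as parallel integer arrays (fast paths for likelihood
    and simulation); the ``trials`` property exposes them as records.  The
    transition label is derived: a transition is common iff the second-stage
    state equals the first choice's majority destination.
    """

    subject_id: str
    first_choice: np.ndarray
    second_state: np.ndarray
    second_choice: np.ndarray
    reward: np.ndarray
    group: str | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        for name in ("first_choice", "second_state", "second_choice", "reward"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
        n = len(self.first_choice)
        if not all(
            len(getattr(self, f)) == n
            for f in ("second_state", "second_choice", "reward")
        ):
            raise ValueError("trial arrays must have equal length")
        for name in ("first_choice", "second_state", "second_choice"):
            if not np.isin(getattr(self, name), (0, 1)).all():
                raise ValueError(f"{name} must contain only 0/1 entries")
        if not np.isin(self.reward, (0, 1)).all():
            raise ValueError("reward must contain only 0/1 entries")

    @property
    def n_trials(self) -> int:
        return len(self.first_choice)

    @property
    def transition(self) -> np.ndarray:
        return np.where(self.second_state == self.first_choice, COMMON, RARE)

    @property
    def trials(self) -> list[TrialRecord]:
        labels = self.transition
        return [
            TrialRecord(
                index=t,
                first_choice=int(self.first_choice[t]),
                transition=str(labels[t]),
                second_state=int(self.second_state[t]),
                second_choice=int(self.second_choice[t]),
                reward=int(self.reward[t]),
            )
            for t in range(self.n_trials)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group if self.group is not None else "",
                "bmi": self.bmi if self.bmi is not None else np.nan,
                "trial": np.arange(self.n_trials),
                "first_choice": self.first_choice,
                "transition": self.transition,
                "second_state": self.second_state,
                "second_choice": self.second_choice,
                "reward": self.reward,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionData":
        df = df.sort_values("trial")
        sid = str(df["subject_id"].iloc[0])
        group = str(df["group"].iloc[0]) if "group" in df and str(df["group"].iloc[0]) else None
        bmi = float(df["bmi"].iloc[0]) if "bmi" in df and np.isfinite(df["bmi"].iloc[0]) else None
        return cls(
            subject_id=sid,
            group=group,
            bmi=bmi,
            first_choice=df["first_choice"].to_numpy(np.int64),
            second_state=df["second_state"].to_numpy(np.int64),
            second_choice=df["second_choice"].to_numpy(np.int64),
            reward=df["reward"].to_numpy(np.int64),
        )
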