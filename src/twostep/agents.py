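"""Hybrid model-based/model-free agent for the two-step task.

The model-free controller is SARSA(λ) with stage-specific learning rates
(α₁, α₂); the model-based controller plans forward through the known 70/30
transition structure from the current second-stage values.  First-stage
decision values mix the two systems,

    Q_net(s_A, a) = ω · Q_MB(s_A, a) + (1 − ω) · Q_MF(s_A, a),

and choices follow a softmax over β_i · [Q_net + ρ·rep(a)], where rep(a)
indicates a repeat of the previous first-stage choice (perseveration applies
at the first stage only).  At the second stage the two systems coincide
(Q_net = Q_MB = Q_MF).  All Q values start at 0 and the planner uses the true
transition probabilities, on which participants are explicitly instructed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .task import COMMON, RewardWalk, SessionData, TaskConfig, TrialRecord

__all__ = [
    "PARAM_NAMES",
    "Parameters",
    "ModelSpec",
    "AgentState",
    "HYBRID",
    "HYBRID_NO_LAMBDA",
    "MODEL_BASED",
    "MODEL_FREE",
    "MODEL_FREE_NO_LAMBDA",
    "DEFAULT_MODEL_SET",
    "mb_values",
    "net_values",
    "choice_probabilities",
    "update_model_free",
    "simulate_session",
    "session_neg_log_likelihood",
    "likelihood_trace",
]

PARAM_NAMES = ("alpha1", "alpha2", "lam", "omega", "beta1", "beta2", "rho")


@dataclass(frozen=True)
class Parameters:
    """The seven agent parameters in natural space.

    α₁, α₂, λ, ω lie in (0, 1); β₁, β₂ are positive inverse temperatures;
    ρ is an unbounded first-stage perseveration weight.
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    lam: float = 0.5
    omega: float = 0.5
    beta1: float = 5.0
    beta2: float = 5.0
    rho: float = 0.0

    def validate(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.rho):
            raise ValueError(f"rho must be finite, got {self.rho}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "Parameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    def replace(self, **kwargs) -> "Parameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelSpec:
    """One of the five model variants compared in the study.

    ``fix_omega``/``fix_lambda`` pin ω and λ to a constant (``None`` = free).
    The variants are the full hybrid; the hybrid with λ fixed at 0 (ω free —
    the sensible reading of a "hybrid without λ"); the purely model-based
    model (ω = 1, under which λ *and* α₁ have no effect on choice and are
    therefore not fitted); and the purely model-free models with and without
    λ (ω = 0).
    """

    name: str
    fix_omega: float | None = None
    fix_lambda: float | None = None

    @property
    def free_names(self) -> tuple[str, ...]:
        names = list(PARAM_NAMES)
        if self.fix_omega is not None:
            names.remove("omega")
        if self.fix_omega == 1:
            # stage-1 MF values never reach the softmax: α₁ and λ are inert
            names.remove("alpha1")
            names.remove("lam")
        elif self.fix_lambda is not None:
            names.remove("lam")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def apply(self, params: Parameters) -> Parameters:
        out = params
        if self.fix_omega is not None:
            out = out.replace(omega=float(self.fix_omega))
        if self.fix_lambda is not None:
            out = out.replace(lam=float(self.fix_lambda))
        return out


HYBRID = ModelSpec("hybrid")
HYBRID_NO_LAMBDA = ModelSpec("hybrid_no_lambda", fix_lambda=0.0)
MODEL_BASED = ModelSpec("model_based", fix_omega=1.0)
MODEL_FREE = ModelSpec("model_free", fix_omega=0.0)
MODEL_FREE_NO_LAMBDA = ModelSpec("model_free_no_lambda", fix_omega=0.0, fix_lambda=0.0)

DEFAULT_MODEL_SET = (
    HYBRID,
    HYBRID_NO_LAMBDA,
    MODEL_BASED,
    MODEL_FREE,
    MODEL_FREE_NO_LAMBDA,
)


@dataclass
class AgentState:
    """Learner state: stage-1 MF values, shared stage-2 values, last choice."""

    q_mf_stage1: np.ndarray
    q_stage2: np.ndarray
    last_first_choice: int | None = None

    @classmethod
    def initial(cls) -> "AgentState":
        return cls(q_mf_stage1=np.zeros(2), q_stage2=np.zeros((2, 2)))


def mb_values(state: AgentState, p_common: float) -> np.ndarray:
    """Model-based first-stage values by forward planning.

    Q_MB(s_A, a) weights the best attainable second-stage value of each
    destination by its transition probability.
    """
    best = state.q_stage2.max(axis=1)
    return np.array(
        [
            p_common * best[0] + (1 - p_common) * best[1],
            p_common * best[1] + (1 - p_common) * best[0],
        ]
    )


def net_values(q_mb: np.ndarray, q_mf: np.ndarray, omega: float) -> np.ndarray:
    """Convex combination ω·Q_MB + (1 − ω)·Q_MF."""
    if not 0 <= omega <= 1:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    return omega * np.asarray(q_mb, float) + (1 - omega) * np.asarray(q_mf, float)


def choice_probabilities(
    values: np.ndarray,
    beta: float,
    rho: float = 0.0,
    last_choice: int | None = None,
) -> np.ndarray:
    """Softmax over β·(value + ρ·rep(a)); rep(a)=1 iff a repeats last_choice."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    x = beta * (np.asarray(values, float) + rho * _rep(last_choice))
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def _rep(last_choice: int | None) -> np.ndarray:
    rep = np.zeros(2)
    if last_choice is not None and last_choice >= 0:
        rep[last_choice] = 1.0
    return rep


def update_model_free(
    state: AgentState, trial: TrialRecord, params: Parameters
) -> AgentState:
    """SARSA(λ) update after one completed trial (mutates and returns state).

    The stage-1 prediction error uses the visited second-stage value; the
    stage-2 reward prediction error additionally feeds back to the visited
    stage-1 value with eligibility α₁·λ.
    """
    a1, s, a2, r = trial.first_choice, trial.second_state, trial.second_choice, trial.reward
    d1 = state.q_stage2[s, a2] - state.q_mf_stage1[a1]
    state.q_mf_stage1[a1] += params.alpha1 * d1
    d2 = r - state.q_stage2[s, a2]
    state.q_stage2[s, a2] += params.alpha2 * d2
    state.q_mf_stage1[a1] += params.alpha1 * params.lam * d2
    state.last_first_choice = a1
    return state


def simulate_session(
    params: Parameters,
    spec: ModelSpec,
    walk: RewardWalk,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    group: str | None = None,
    bmi: float | None = None,
) -> SessionData:
    """Generative rollout of a full session; reproducible given ``seed``."""
    if walk.n_trials < config.n_trials:
        raise ValueError(
            f"walk provides {walk.n_trials} trials but config requires {config.n_trials}"
        )
    params.validate()
    theta = spec.apply(params).as_vector()
    a1, s2, a2, r = _kernels.simulate(
        theta, config.p_common, walk.probs[: config.n_trials], int(seed)
    )
    return SessionData(
        subject_id=subject_id,
        group=group,
        bmi=bmi,
        first_choice=a1,
        second_state=s2,
        second_choice=a2,
        reward=r,
    )


def session_neg_log_likelihood(
    params: Parameters,
    spec: ModelSpec,
    session: SessionData,
    config: TaskConfig,
) -> float:
    """−log likelihood (nats) of both choices on every trial of a session."""
    params.validate()
    theta = spec.apply(params).as_vector()
    nll = _kernels.session_nll(
        theta,
        config.p_common,
        session.first_choice,
        session.second_state,
        session.second_choice,
        session.reward,
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood; malformed session?")
    return float(nll)


def likelihood_trace(
    params: Parameters,
    spec: ModelSpec,
    session: SessionData,
    config: TaskConfig,
) -> pd.DataFrame:
    """Per-trial likelihood trace (debugging aid; pure-python replay).

    Columns: trial, p_stage1, p_stage2, cumulative −LL.  The final cumulative
    value equals :func:`session_neg_log_likelihood` up to rounding.
    """
    p = spec.apply(params)
    state = AgentState.initial()
    rows = []
    cum = 0.0
    for trial in session.trials:
        q_net = net_values(mb_values(state, config.p_common), state.q_mf_stage1, p.omega)
        p1 = choice_probabilities(q_net, p.beta1, p.rho, state.last_first_choice)
        p2 = choice_probabilities(state.q_stage2[trial.second_state], p.beta2)
        cum -= np.log(p1[trial.first_choice]) + np.log(p2[trial.second_choice])
        rows.append(
            {
                "trial": trial.index,
                "p_stage1": p1[trial.first_choice],
                "p_stage2": p2[trial.second_choice],
                "cum_neg_log_lik": cum,
            }
        )
        update_model_free(state, trial, p)
    return pd.DataFrame(rows)
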