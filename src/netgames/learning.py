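"""Action-value (Rescorla-Wagner) and actor-critic learning for two actions.

Both rules are pure one-step updates of a small per-individual state:

* Action-value learning keeps one estimated value per action
  (Q_A, Q_B); after performing an action the chosen value moves toward
  the perceived reward by the learning rate alpha times the surprise
  R - Q, and the probability of choosing action A is the logistic of
  beta * (Q_A - Q_B).

* Actor-critic learning keeps a critic's estimate w of the value of a
  round under the current behaviour, and an action preference theta
  defined as the logit of the probability of choosing action A.  The
  critic is updated Rescorla-Wagner style from the surprise
  delta = R - w, and the actor moves theta in the direction of the
  chosen action by alpha_pref * delta * (1 - p_chosen) — the standard
  two-action policy-gradient form, where (1 - p_chosen) is the
  derivative of the log-policy.

"Action A" is the first-named game action (produce / call / hawk).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ActionValueState:
    """Estimated values of the two actions, in reward units."""

    q_a: float = 0.0
    q_b: float = 0.0


@dataclass(frozen=True)
class ActorCriticState:
    """Actor-critic state: action preference ``theta`` (the logit of the
    probability of choosing action A) and critic value ``w`` (estimated
    reward of a round, in reward units)."""

    theta: float = 0.0
    w: float = 0.0


@dataclass(frozen=True)
class LearnerParams:
    """Learning-rule parameters.

    ``alpha`` is the value learning rate in [0, 1] (0 switches learning
    off); ``beta >= 0`` the sensitivity to the value difference in the
    choice probability (action-value rule only); ``alpha_pref`` the
    actor's preference learning rate (defaults to ``alpha``);
    ``theta_clamp`` bounds the preference so logit(p) stays finite even
    under extreme polarization.  ``q_init`` is the common starting value
    of both action estimates (and of the actor-critic's critic); when
    None the simulation engine derives it from the game as the expected
    one-round reward of the unbiased starting population, which keeps
    early surprises on the scale of the game instead of the arbitrary
    origin (starting far below the reward scale acts as pessimistic
    initialization: the first action sampled looks good and exploration
    collapses).  Both action estimates start equal either way, so every
    individual begins at p = 0.5.
    """

    alpha: float = 0.1
    beta: float = 8.0
    alpha_pref: float | None = None
    theta_clamp: float = 12.0
    q_init: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.alpha_pref is not None and not (0.0 <= self.alpha_pref <= 1.0):
            raise ValueError("alpha_pref must be in [0, 1]")
        if self.theta_clamp <= 0:
            raise ValueError("theta_clamp must be positive")

    @property
    def pref_rate(self) -> float:
        return self.alpha if self.alpha_pref is None else self.alpha_pref


def choice_probability_av(state: ActionValueState, beta: float) -> float:
    """Probability of action A: logistic of beta * (Q_A - Q_B)."""
    return float(expit(beta * (state.q_a - state.q_b)))


def update_action_value(
    state: ActionValueState, chose_a: bool, reward: float, alpha: float
) -> ActionValueState:
    """Rescorla-Wagner update of the chosen action's value.

    Only the chosen action's estimate changes, by alpha * (R - Q); the
    other estimate is untouched.
    """
    if chose_a:
        return replace(state, q_a=state.q_a + alpha * (reward - state.q_a))
    return replace(state, q_b=state.q_b + alpha * (reward - state.q_b))


def choice_probability_ac(state: ActorCriticState) -> float:
    """Probability of action A: logistic of the preference theta."""
    return float(expit(state.theta))


def update_actor_critic(
    state: ActorCriticState, chose_a: bool, reward: float, params: LearnerParams
) -> ActorCriticState:
    """One actor-critic step from a chosen action and perceived reward.

    delta = R - w drives both mechanisms: the critic moves by
    alpha * delta, and the preference by
    +/- alpha_pref * delta * (1 - p_chosen) (sign by chosen action),
    where p_chosen is the pre-update probability of the chosen action.
    theta is then clamped to +/- theta_clamp.
    """
    p_a = choice_probability_ac(state)
    p_chosen = p_a if chose_a else 1.0 - p_a
    delta = reward - state.w
    step = params.pref_rate * delta * (1.0 - p_chosen)
    theta = state.theta + step if chose_a else state.theta - step
    theta = float(np.clip(theta, -params.theta_clamp, params.theta_clamp))
    return ActorCriticState(theta=theta, w=state.w + params.alpha * delta)


# ---- vectorized forms used by the simulation engine ------------------------


def choice_probabilities_av_vec(
    q_a: np.ndarray, q_b: np.ndarray, beta: float
) -> np.ndarray:
    return expit(beta * (q_a - q_b))


def update_action_value_vec(
    q_a: np.ndarray,
    q_b: np.ndarray,
    chose_a: np.ndarray,
    rewards: np.ndarray,
    alpha: float,
    mask: np.ndarray | None = None,
) -> None:
    """In-place Rescorla-Wagner update for many individuals.

    ``mask`` selects the participants; non-participants are untouched.
    """
    upd = chose_a if mask is None else (chose_a & mask)
    q_a[upd] += alpha * (rewards[upd] - q_a[upd])
    upd = ~chose_a if mask is None else (~chose_a & mask)
    q_b[upd] += alpha * (rewards[upd] - q_b[upd])


def update_actor_critic_vec(
    theta: np.ndarray,
    w: np.ndarray,
    chose_a: np.ndarray,
    rewards: np.ndarray,
    params: LearnerParams,
    mask: np.ndarray | None = None,
) -> None:
    """In-place actor-critic update for many individuals."""
    if mask is None:
        mask = np.ones_like(chose_a, dtype=bool)
    p_a = expit(theta[mask])
    p_chosen = np.where(chose_a[mask], p_a, 1.0 - p_a)
    delta = rewards[mask] - w[mask]
    sign = np.where(chose_a[mask], 1.0, -1.0)
    theta[mask] = np.clip(
        theta[mask] + sign * params.pref_rate * delta * (1.0 - p_chosen),
        -params.theta_clamp,
        params.theta_clamp,
    )
    w[mask] += params.alpha * delta
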