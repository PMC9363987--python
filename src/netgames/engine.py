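"""Simulation engine: replicate groups of learners playing a game.

A group is a social network of N individuals that play T rounds of one
game under one learning rule.  For producer-scrounger and
caller-satellite games every individual commits an action
simultaneously each round, the game resolves, and everyone updates from
its perceived reward.  For hawk-dove, time is counted per capita: the
group experiences N*T/2 sequential contest events so that each member
has an expected number T of contests, and only the two contestants of
an event act, receive payoffs and update.  Choice probabilities are
recorded for all individuals on the common per-capita round grid.

Reproducibility: a master seed plus the group index deterministically
derive each group's RNG substream (``SeedSequence([seed, g])``), so any
group can be re-run in isolation and ensembles are order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from netgames.games import (
    CallerSatelliteParams,
    HawkDoveParams,
    ProducerScroungerParams,
    hawk_dove_payoffs,
    play_caller_satellite_round,
    play_producer_scrounger_round,
    sample_hawk_dove_contest,
)
from netgames.learning import (
    LearnerParams,
    choice_probabilities_av_vec,
    update_action_value_vec,
    update_actor_critic_vec,
)
from netgames.networks import SocialNetwork, make_ring_lattice, rewire_small_world
from scipy.special import expit

GameParams = Union[ProducerScroungerParams, CallerSatelliteParams, HawkDoveParams]

GAMES = ("producer_scrounger", "caller_satellite", "hawk_dove")
RULES = ("action_value", "actor_critic")

_PARAM_TYPES = {
    "producer_scrounger": ProducerScroungerParams,
    "caller_satellite": CallerSatelliteParams,
    "hawk_dove": HawkDoveParams,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation case.

    ``n`` group size, ``k`` ring-lattice neighbour count, ``p_rew``
    Watts-Strogatz rewiring probability (each group draws its own
    network realization when positive), ``game`` one of
    ``producer_scrounger`` / ``caller_satellite`` / ``hawk_dove`` with
    matching ``game_params``, ``rule`` one of ``action_value`` /
    ``actor_critic`` with ``learner`` parameters, ``t_rounds`` rounds
    per group, ``n_groups`` replicate groups, ``seed`` master RNG seed,
    ``record_interval`` the round spacing of recorded states.
    """

    n: int = 99
    k: int = 4
    p_rew: float = 0.0
    game: str = "producer_scrounger"
    game_params: GameParams = field(default_factory=ProducerScroungerParams)
    rule: str = "action_value"
    learner: LearnerParams = field(default_factory=LearnerParams)
    t_rounds: int = 1000
    n_groups: int = 1
    seed: int = 0
    record_interval: int = 1
    record_rewards: bool = False

    def __post_init__(self) -> None:
        if self.game not in GAMES:
            raise ValueError(f"unknown game {self.game!r}; choose from {GAMES}")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        expected = _PARAM_TYPES[self.game]
        if not isinstance(self.game_params, expected):
            raise TypeError(
                f"game {self.game!r} requires {expected.__name__}, "
                f"got {type(self.game_params).__name__}"
            )
        if self.t_rounds < 0:
            raise ValueError("t_rounds must be non-negative")
        if self.n_groups < 1:
            raise ValueError("n_groups must be at least 1")
        if self.record_interval < 1:
            raise ValueError("record_interval must be at least 1")
        if not (0.0 <= self.p_rew <= 1.0):
            raise ValueError("p_rew must be in [0, 1]")
        # delegate n/k range checks
        make_ring_lattice(self.n, self.k)


@dataclass
class Trajectory:
    """Recorded history of one simulated group.

    ``p[r, i]`` is individual i's probability of choosing the
    first-named action (produce / call / hawk) at recorded round
    ``rounds[r]``; ``actions[r, i]`` the individual's most recent action
    at that point (1 = first-named action, 0 = alternative, -1 = has
    not acted yet).  ``rewards`` (optional) holds the perceived rewards
    of the recorded round.  ``contest_counts`` (hawk-dove only) counts
    each individual's contests over the whole run.
    """

    p: np.ndarray
    actions: np.ndarray
    rounds: np.ndarray
    network: SocialNetwork | None = None
    group_index: int = 0
    rewards: np.ndarray | None = None
    contest_counts: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.p.shape[1]

    @property
    def final_p(self) -> np.ndarray:
        return self.p[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format records: group, individual, round, p, action."""
        n_rec, n = self.p.shape
        return pd.DataFrame(
            {
                "group": np.full(n_rec * n, self.group_index, dtype=np.int64),
                "individual": np.tile(np.arange(n, dtype=np.int64), n_rec),
                "round": np.repeat(self.rounds.astype(np.int64), n),
                "p": self.p.ravel(),
                "action": self.actions.ravel().astype(np.int64),
            }
        )


def _build_network(config: SimulationConfig, rng: np.random.Generator) -> SocialNetwork:
    net = make_ring_lattice(config.n, config.k)
    if config.p_rew > 0.0:
        net = rewire_small_world(net, config.p_rew, rng)
    return net


def default_value_init(game: str, params: GameParams) -> float:
    """Expected one-round reward of the unbiased (p = 0.5) starting population.

    Used as the common starting point of the value estimates so that
    early surprises reflect the game rather than the distance from an
    arbitrary origin.  Closed forms per game:

    * producer-scrounger: half the group produces, a producer finds
      with probability ``lambda_find`` and a discovery distributes
      ``v1 + v2`` in total, so the per-capita rate is
      ``lambda_find * (v1 + v2) / 2``.
    * caller-satellite: half call with mean strength ``1 - gamma0/2``,
      each attracting ``f`` females per unit strength worth ``v1``
      each, shared over the group: ``f * (1 - gamma0/2) * v1 / 2``.
    * hawk-dove: the average over the four equally likely action pairs
      of a contestant's expected payoff, ``v/2 - c/8``.
    """
    if game == "producer_scrounger":
        return params.lambda_find * (params.v1 + params.v2) / 2.0
    if game == "caller_satellite":
        return params.f * (1.0 - params.gamma0 / 2.0) * params.v1 / 2.0
    return params.v / 2.0 - params.c / 8.0


class _LearnerArray:
    """Vectorized learner state for one group (all individuals)."""

    def __init__(self, n: int, rule: str, params: LearnerParams, init: float = 0.0):
        self.rule = rule
        self.params = params
        if rule == "action_value":
            self.q_a = np.full(n, init, dtype=float)
            self.q_b = np.full(n, init, dtype=float)
        else:
            self.theta = np.zeros(n)
            self.w = np.full(n, init, dtype=float)

    def probabilities(self) -> np.ndarray:
        if self.rule == "action_value":
            return choice_probabilities_av_vec(self.q_a, self.q_b, self.params.beta)
        return expit(self.theta)

    def update(
        self, chose_a: np.ndarray, rewards: np.ndarray, mask: np.ndarray | None = None
    ) -> None:
        if self.rule == "action_value":
            update_action_value_vec(
                self.q_a, self.q_b, chose_a, rewards, self.params.alpha, mask
            )
        else:
            update_actor_critic_vec(
                self.theta, self.w, chose_a, rewards, self.params, mask
            )


def run_group(
    config: SimulationConfig,
    rng: np.random.Generator,
    network: SocialNetwork | None = None,
    group_index: int = 0,
) -> Trajectory:
    """Simulate one group and return its trajectory.

    The network is built from ``rng`` first (ring lattice, then
    rewiring if ``p_rew > 0``) unless one is supplied.  All individuals
    start unbiased at p = 0.5: both action values (or the critic value,
    with theta = 0) start at ``learner.q_init``, defaulting to the
    game's expected one-round reward (:func:`default_value_init`).  The
    initial state is recorded as round 0.

    Per-round RNG draw order for producer-scrounger / caller-satellite:
    one ``rng.random(n)`` vector deciding every individual's action
    (u_i < p_i means the first-named action), then the game's own
    documented draws.  Hawk-dove instead runs floor(n*t/2) contest
    events, each drawing the contest pair, one uniform per contestant
    for its action, then the payoff coin where needed.
    """
    net = network if network is not None else _build_network(config, rng)
    n = config.n
    init = config.learner.q_init
    if init is None:
        init = default_value_init(config.game, config.game_params)
    learner = _LearnerArray(n, config.rule, config.learner, init=init)

    rec_rounds = list(range(0, config.t_rounds + 1, config.record_interval))
    if rec_rounds[-1] != config.t_rounds:
        rec_rounds.append(config.t_rounds)
    n_rec = len(rec_rounds)
    p_rec = np.empty((n_rec, n))
    a_rec = np.full((n_rec, n), -1, dtype=np.int8)
    r_rec = np.zeros((n_rec, n)) if config.record_rewards else None

    last_action = np.full(n, -1, dtype=np.int8)
    last_reward = np.zeros(n)
    cursor = 0

    def record(round_no: int) -> None:
        nonlocal cursor
        p_rec[cursor] = learner.probabilities()
        a_rec[cursor] = last_action
        if r_rec is not None:
            r_rec[cursor] = last_reward
        cursor += 1

    record(0)

    if config.game == "hawk_dove":
        traj_counts = _run_hawk_dove(
            config, net, learner, rng, rec_rounds, record, last_action, last_reward
        )
    else:
        play = (
            play_producer_scrounger_round
            if config.game == "producer_scrounger"
            else play_caller_satellite_round
        )
        for t in range(1, config.t_rounds + 1):
            p = learner.probabilities()
            actions = rng.random(n) < p
            outcome = play(actions, net, config.game_params, rng)
            learner.update(actions, outcome.rewards)
            last_action[:] = actions
            last_reward[:] = outcome.rewards
            if t == rec_rounds[cursor]:
                record(t)
        traj_counts = None

    return Trajectory(
        p=p_rec,
        actions=a_rec,
        rounds=np.asarray(rec_rounds, dtype=np.int64),
        network=net,
        group_index=group_index,
        rewards=r_rec,
        contest_counts=traj_counts,
    )


def _run_hawk_dove(config, net, learner, rng, rec_rounds, record, last_action, last_reward):
    """Sequential contest events on the per-capita time grid.

    Recorded round r corresponds to floor(r * n / 2) elapsed contest
    events, so that one "round" is N/2 contests and each individual
    accumulates an expected T contests over the run.
    """
    n = config.n
    total_events = math.floor(n * config.t_rounds / 2 + 1e-9)
    thresholds = [math.floor(r * n / 2 + 1e-9) for r in rec_rounds[1:]]
    counts = np.zeros(n, dtype=np.int64)
    params = config.game_params
    next_idx = 0
    chose = np.zeros(n, dtype=bool)
    rew = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for e in range(1, total_events + 1):
        focal, opp = sample_hawk_dove_contest(net, rng)
        p = learner.probabilities()
        a1 = rng.random() < p[focal]
        a2 = rng.random() < p[opp]
        r1, r2 = hawk_dove_payoffs(a1, a2, params, rng)
        mask[:] = False
        mask[focal] = mask[opp] = True
        chose[focal], chose[opp] = a1, a2
        rew[focal], rew[opp] = r1, r2
        if focal == opp:  # cannot happen (no self-loops), defensive
            raise RuntimeError("contest with self")
        learner.update(chose, rew, mask)
        counts[focal] += 1
        counts[opp] += 1
        last_action[focal], last_action[opp] = int(a1), int(a2)
        last_reward[focal], last_reward[opp] = r1, r2
        while next_idx < len(thresholds) and e == thresholds[next_idx]:
            record(rec_rounds[1 + next_idx])
            next_idx += 1
    # degenerate grids (e.g. t_rounds=0 or thresholds of 0 events)
    while next_idx < len(thresholds):
        record(rec_rounds[1 + next_idx])
        next_idx += 1
    return counts


def group_rng(seed: int, group_index: int) -> np.random.Generator:
    """The RNG substream of group ``group_index`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([seed, group_index]))


def run_ensemble(
    config: SimulationConfig, progress: bool = False
) -> list[Trajectory]:
    """Simulate ``config.n_groups`` independent replicate groups.

    Each group gets its own network realization (when ``p_rew > 0``)
    and its own RNG substream derived from the master seed and the
    group index, so results are reproducible and order-independent.
    """
    trajectories = []
    for g in range(config.n_groups):
        traj = run_group(config, group_rng(config.seed, g), group_index=g)
        trajectories.append(traj)
        if progress:
            print(
                f"group {g + 1}/{config.n_groups}: {config.t_rounds} rounds done",
                flush=True,
            )
    return trajectories


def trajectories_to_dataframe(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Concatenate group trajectories into one long table."""
    return pd.concat([t.to_dataframe() for t in trajectories], ignore_index=True)
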