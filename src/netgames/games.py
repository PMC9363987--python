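"""Per-round payoffs for the three negatively frequency-dependent games.

Each game takes every individual's committed action plus the social
network and returns a :class:`RoundOutcome` with the per-individual
rewards for the round.  Payoffs are negatively frequency dependent: an
action pays less the more neighbours use it, which is what drives
learned specialization.

Actions are encoded as booleans: ``True`` is the first-named action of a
game (produce, call, hawk) and ``False`` the second (scrounge,
satellite, dove).

RNG draw order within a round is part of each function's contract (it is
documented in the docstrings) so that simulations are reproducible and
can be checked against straight-line traces using the same stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netgames.networks import SocialNetwork

PRODUCE = CALL = HAWK = True
SCROUNGE = SATELLITE = DOVE = False


@dataclass(frozen=True)
class ProducerScroungerParams:
    """Producer-scrounger payoff parameters.

    A producer finds food with probability ``lambda_find`` per round,
    keeps the finder's advantage ``v1`` and shares the remaining amount
    ``v2`` equally with up to ``max_scroungers`` joining neighbours.
    By default a scrounger can join every neighbouring discovery it is
    selected for within a round, which is what makes scrounging
    lucrative when scroungers are rare (the negative frequency
    dependence that drives specialization); ``exclusive_joining`` caps
    each scrounger at one discovery per round instead, for sensitivity
    checks.
    """

    lambda_find: float = 0.5
    v1: float = 1.0
    v2: float = 3.0
    max_scroungers: int = 2
    exclusive_joining: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_find <= 1.0):
            raise ValueError("lambda_find must be in [0, 1]")
        if self.v1 < 0 or self.v2 < 0:
            raise ValueError("v1 and v2 must be non-negative")
        if self.max_scroungers < 0:
            raise ValueError("max_scroungers must be non-negative")


@dataclass(frozen=True)
class CallerSatelliteParams:
    """Caller-satellite payoff parameters.

    A caller's effective call strength is reduced by calling neighbours
    (interference coefficient ``gamma0``); the expected number of females
    attracted to the group is ``f`` times the summed call strengths, and
    each mating pays ``v1``.  With ``deterministic_females`` the round
    pays every individual its expected reward instead of sampling female
    arrivals and matings.
    """

    gamma0: float = 0.75
    f: float = 2.0
    v1: float = 2.0
    deterministic_females: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma0 <= 1.0):
            raise ValueError("gamma0 must be in [0, 1]")
        if self.f < 0 or self.v1 < 0:
            raise ValueError("f and v1 must be non-negative")


@dataclass(frozen=True)
class HawkDoveParams:
    """Hawk-dove contest parameters: benefit ``v`` of winning, cost ``c``
    of losing an escalated hawk-hawk fight."""

    v: float = 1.0
    c: float = 2.0

    def __post_init__(self) -> None:
        if self.v < 0 or self.c < 0:
            raise ValueError("v and c must be non-negative")


@dataclass
class RoundOutcome:
    """Result of one game round.

    ``rewards[i]`` is individual i's perceived reward this round;
    ``participants`` lists the individuals whose learner state should be
    updated from it (everyone for producer-scrounger and
    caller-satellite, only the two contestants for hawk-dove).
    ``events`` is an optional structured log of discoveries / matings /
    contests for diagnostics.
    """

    rewards: np.ndarray
    participants: np.ndarray
    events: list = field(default_factory=list)


def call_strength(k: int, k_c: int, gamma0: float) -> float:
    """Effective call strength s = 1 - gamma0 * k_C / k.

    ``k`` is the caller's neighbour count and ``k_c`` how many of those
    neighbours are currently calling.  An isolated caller (k = 0) has no
    interfering neighbours and gets strength 1 by convention.
    """
    if k_c < 0 or (k > 0 and k_c > k):
        raise ValueError(f"need 0 <= k_c <= k, got k={k}, k_c={k_c}")
    if k == 0:
        return 1.0
    return 1.0 - gamma0 * k_c / k


def mating_split(k_s: int) -> tuple[float, float]:
    """Mating probabilities (caller, per-satellite) for one approaching female.

    A female that has approached a caller mates with the caller for
    certain when it has no satellite neighbours; with ``k_s >= 1``
    satellites the caller mates with probability 0.5 and each satellite
    with probability 0.5/k_s, so exactly one individual mates per female.
    """
    if k_s < 0:
        raise ValueError("k_s must be non-negative")
    if k_s == 0:
        return 1.0, 0.0
    return 0.5, 0.5 / k_s


def play_producer_scrounger_round(
    actions: np.ndarray,
    net: SocialNetwork,
    params: ProducerScroungerParams,
    rng: np.random.Generator,
) -> RoundOutcome:
    """Resolve one producer-scrounger round.

    Each producer independently finds food with probability
    ``lambda_find``.  On a find, up to ``max_scroungers`` of its
    neighbours whose action is scrounge are selected uniformly without
    replacement as joiners; the producer earns ``v1 + v2/(n_join + 1)``
    and each joiner ``v2/(n_join + 1)`` (the shareable amount is split
    equally among producer and joiners).  Unsuccessful producers and
    unselected scroungers earn 0, and every individual is a participant
    (learns from its reward) every round.

    Successful producers are processed in a random order.  By default a
    scrounger may join several neighbouring discoveries in the same
    round; with ``exclusive_joining`` it is removed from the available
    pool once selected.

    RNG draw order: (1) one uniform per individual for the find draws
    (used only for producers); (2) a permutation of all individuals
    fixing the processing order; (3) per discovery with more available
    scroungers than the cap, ``rng.choice`` without replacement on the
    sorted available-scrounger list.
    """
    n = net.n_individuals
    actions = np.asarray(actions, dtype=bool)
    if actions.shape != (n,):
        raise ValueError(f"actions must have shape ({n},)")
    rewards = np.zeros(n)
    finds = rng.random(n) < params.lambda_find
    order = rng.permutation(n)
    successful = actions & finds
    joined = np.zeros(n, dtype=bool)
    events = []
    for i in order:
        if not successful[i]:
            continue
        avail = [j for j in net.adjacency[i] if not actions[j]]
        if params.exclusive_joining:
            avail = [j for j in avail if not joined[j]]
        if len(avail) > params.max_scroungers:
            joiners = rng.choice(np.array(avail), size=params.max_scroungers, replace=False)
        else:
            joiners = np.array(avail, dtype=np.int64)
        share = params.v2 / (len(joiners) + 1)
        rewards[i] += params.v1 + share
        for j in joiners:
            rewards[j] += share
            joined[j] = True
        events.append(("discovery", int(i), [int(j) for j in joiners]))
    return RoundOutcome(rewards=rewards, participants=np.arange(n), events=events)


def _caller_strengths(
    actions: np.ndarray, net: SocialNetwork, gamma0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Calling individuals and their call strengths."""
    callers = np.flatnonzero(actions)
    strengths = np.empty(len(callers))
    for idx, i in enumerate(callers):
        nbrs = net.adjacency[i]
        k = len(nbrs)
        k_c = sum(1 for j in nbrs if actions[j])
        strengths[idx] = call_strength(k, k_c, gamma0)
    return callers, strengths


def play_caller_satellite_round(
    actions: np.ndarray,
    net: SocialNetwork,
    params: CallerSatelliteParams,
    rng: np.random.Generator,
) -> RoundOutcome:
    """Resolve one caller-satellite round.

    Every caller's strength s = 1 - gamma0*k_C/k is computed from its own
    neighbourhood.  The number of arriving females is Poisson with mean
    ``f * sum(s)`` (or exactly the expected rewards are paid out when
    ``deterministic_females`` is set).  Each female independently
    approaches caller j with probability s_j / sum(s) and then mates with
    the caller or one of the caller's satellite neighbours according to
    :func:`mating_split`; each mating pays ``v1``.  Rewards accumulate
    over females within the round and every individual is a participant.

    RNG draw order (stochastic mode): (1) ``rng.poisson`` for the female
    count, skipped when no caller has positive strength; per female:
    (2) ``rng.choice`` over callers weighted by strength; (3) if the
    approached caller has satellites, one uniform for the caller-vs-
    satellite coin and, on satellite interception, ``rng.integers`` into
    the sorted satellite list.
    """
    n = net.n_individuals
    actions = np.asarray(actions, dtype=bool)
    if actions.shape != (n,):
        raise ValueError(f"actions must have shape ({n},)")
    rewards = np.zeros(n)
    events = []
    callers, strengths = _caller_strengths(actions, net, params.gamma0)
    total = strengths.sum()
    if len(callers) == 0 or total <= 0.0:
        return RoundOutcome(rewards=rewards, participants=np.arange(n), events=events)
    satellites = {
        int(i): [j for j in net.adjacency[i] if not actions[j]] for i in callers
    }
    if params.deterministic_females:
        # expected rewards: f * s_j females reach caller j on average
        for i, s in zip(callers, strengths):
            sats = satellites[int(i)]
            p_caller, p_sat = mating_split(len(sats))
            rewards[i] += params.f * s * p_caller * params.v1
            for j in sats:
                rewards[j] += params.f * s * p_sat * params.v1
        return RoundOutcome(rewards=rewards, participants=np.arange(n), events=events)
    n_females = rng.poisson(params.f * total)
    events.append(("females", int(n_females)))
    probs = strengths / total
    for _ in range(n_females):
        i = int(rng.choice(callers, p=probs))
        sats = satellites[i]
        if not sats:
            rewards[i] += params.v1
            events.append(("mating", i))
            continue
        if rng.random() < 0.5:
            rewards[i] += params.v1
            events.append(("mating", i))
        else:
            j = sats[rng.integers(len(sats))]
            rewards[j] += params.v1
            events.append(("mating", int(j)))
    return RoundOutcome(rewards=rewards, participants=np.arange(n), events=events)


def sample_hawk_dove_contest(
    net: SocialNetwork, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw a (focal, opponent) pair for one hawk-dove contest.

    The focal individual is uniform among individuals with at least one
    neighbour (isolated individuals are never sampled) and the opponent
    uniform among the focal's neighbours.

    RNG draw order: ``rng.integers`` into the sorted eligible-individual
    list, then ``rng.integers`` into the focal's sorted neighbour list.
    """
    eligible = [i for i in range(net.n_individuals) if net.adjacency[i]]
    if not eligible:
        raise ValueError("network has no edges: cannot sample a contest")
    focal = eligible[rng.integers(len(eligible))]
    nbrs = net.adjacency[focal]
    opponent = nbrs[rng.integers(len(nbrs))]
    return int(focal), int(opponent)


def hawk_dove_payoffs(
    a1: bool, a2: bool, params: HawkDoveParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Payoffs of a single hawk-dove contest.

    Hawk against dove takes the full benefit ``v``; two hawks escalate
    and a fair coin picks the winner (``v``) and the loser (``-c``); two
    doves split by a fair coin, the winner taking ``v`` and the loser 0.

    RNG draw order: one uniform, only for the symmetric H-H and D-D
    cases (player 1 wins if it is below 0.5).
    """
    if a1 == HAWK and a2 == DOVE:
        return params.v, 0.0
    if a1 == DOVE and a2 == HAWK:
        return 0.0, params.v
    first_wins = rng.random() < 0.5
    if a1 == HAWK:  # hawk vs hawk
        return (params.v, -params.c) if first_wins else (-params.c, params.v)
    return (params.v, 0.0) if first_wins else (0.0, params.v)
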