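"""YAML configuration files for simulation cases.

A config file has four sections::

    network:            # group structure
      n: 99
      k: 4
      p_rew: 0.1
    game:               # which game and its payoff parameters
      name: producer_scrounger
      lambda_find: 0.5
      v1: 1.0
      v2: 3.0
      max_scroungers: 2
    learning:           # learning rule and rates
      rule: action_value
      alpha: 0.1
      beta: 8.0
    run:                # ensemble bookkeeping
      t_rounds: 1000
      n_groups: 50
      seed: 42
      record_interval: 1

Unknown sections or keys are errors, so typos fail loudly instead of
silently running defaults.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from netgames.engine import SimulationConfig, _PARAM_TYPES
from netgames.learning import LearnerParams

_GAME_KEYS = {
    "producer_scrounger": ("lambda_find", "v1", "v2", "max_scroungers", "exclusive_joining"),
    "caller_satellite": ("gamma0", "f", "v1", "deterministic_females"),
    "hawk_dove": ("v", "c"),
}
_LEARNING_KEYS = ("rule", "alpha", "beta", "alpha_pref", "theta_clamp", "q_init")
_NETWORK_KEYS = ("n", "k", "p_rew")
_RUN_KEYS = ("t_rounds", "n_groups", "seed", "record_interval", "record_rewards")


def _take(section: dict, allowed: tuple[str, ...], where: str) -> dict:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in [{where}] section")
    return dict(section)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed config mapping."""
    unknown = set(data) - {"network", "game", "learning", "run"}
    if unknown:
        raise ValueError(f"unknown section(s) {sorted(unknown)}")
    net = _take(data.get("network", {}), _NETWORK_KEYS, "network")
    game_sec = dict(data.get("game", {}))
    name = game_sec.pop("name", "producer_scrounger")
    if name not in _PARAM_TYPES:
        raise ValueError(f"unknown game {name!r}")
    game_kwargs = _take(game_sec, _GAME_KEYS[name], "game")
    learn_sec = _take(data.get("learning", {}), _LEARNING_KEYS, "learning")
    rule = learn_sec.pop("rule", "action_value")
    run = _take(data.get("run", {}), _RUN_KEYS, "run")
    return SimulationConfig(
        game=name,
        game_params=_PARAM_TYPES[name](**game_kwargs),
        rule=rule,
        learner=LearnerParams(**learn_sec),
        **net,
        **run,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Inverse of :func:`config_from_dict` (exact round trip)."""
    return {
        "network": {"n": config.n, "k": config.k, "p_rew": config.p_rew},
        "game": {"name": config.game, **asdict(config.game_params)},
        "learning": {"rule": config.rule, **asdict(config.learner)},
        "run": {
            "t_rounds": config.t_rounds,
            "n_groups": config.n_groups,
            "seed": config.seed,
            "record_interval": config.record_interval,
            "record_rewards": config.record_rewards,
        },
    }


def load_config(path) -> SimulationConfig:
    """Read a YAML config file into a :class:`SimulationConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as YAML, loadable by :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
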