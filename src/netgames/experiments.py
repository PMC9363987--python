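"""Pre-packaged ensemble designs and miniature test fixtures.

The registry bundles the named study cases: producer-scrounger,
caller-satellite and hawk-dove ensembles of N = 99 individuals on ring
lattices with various neighbour counts K, fast (alpha = 0.1) versus
slow (alpha = 0.01) action-value learning, plus small-world variants
(p_rew = 0.1) and long steady-state runs (t = 5000) for the
consistency analysis.  Full ensembles use 500 replicate groups; each
case also carries a reduced replicate count (50 groups, or the native
5 for consistency cases) at which ensemble means are still stable
enough for ordering comparisons.

:func:`make_fixture` builds deterministic miniature objects for tests:
the 21-individual, K = 4 ring; a 5-individual hand-traceable
producer-scrounger group; and synthetic trajectories with prescribed
AR(1) persistence in logit space for validating the consistency
metric (a test instrument only — no claim that the learning model
produces AR(1) dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from netgames.engine import SimulationConfig, Trajectory, run_group
from netgames.games import CallerSatelliteParams, HawkDoveParams, ProducerScroungerParams
from netgames.learning import LearnerParams
from netgames.networks import SocialNetwork, make_ring_lattice, rewire_small_world


@dataclass(frozen=True)
class ExperimentSpec:
    """A named ensemble design.

    ``config`` holds the full-replicate design; ``reduced_groups`` is
    the bundled scaled-down replicate count for quick runs; ``metrics``
    names the statistics the case was designed for.
    """

    label: str
    config: SimulationConfig
    metrics: tuple[str, ...] = ("polarization",)
    reduced_groups: int = 50
    autocorr_window: tuple[int, int] | None = None

    def reduced_config(self, n_groups: int | None = None) -> SimulationConfig:
        """The same design at a reduced replicate count."""
        return replace(self.config, n_groups=n_groups or self.reduced_groups)


_FAST, _SLOW = 0.1, 0.01


def _case(label, game, game_params, k, alpha, p_rew=0.0, t=1000, groups=500,
          metrics=("polarization",), reduced=50, window=None, record_interval=1):
    cfg = SimulationConfig(
        n=99,
        k=k,
        p_rew=p_rew,
        game=game,
        game_params=game_params,
        rule="action_value",
        learner=LearnerParams(alpha=alpha, beta=8.0),
        t_rounds=t,
        n_groups=groups,
        seed=0,
        record_interval=record_interval,
    )
    return ExperimentSpec(
        label=label, config=cfg, metrics=metrics,
        reduced_groups=reduced, autocorr_window=window,
    )


def registry() -> dict[str, ExperimentSpec]:
    """The bundled study cases, keyed by label."""
    ps = ProducerScroungerParams()
    cs = CallerSatelliteParams()
    hd = HawkDoveParams()
    cases = [
        # producer-scrounger polarization, N = 99
        _case("fig2_K4_fast", "producer_scrounger", ps, k=4, alpha=_FAST),
        _case("fig2_K4_slow", "producer_scrounger", ps, k=4, alpha=_SLOW),
        _case("fig2_K8_fast", "producer_scrounger", ps, k=8, alpha=_FAST),
        _case("fig2_K98_fast", "producer_scrounger", ps, k=98, alpha=_FAST),
        _case("fig2_K98_slow", "producer_scrounger", ps, k=98, alpha=_SLOW),
        _case("fig2_K4_fast_smallworld", "producer_scrounger", ps, k=4, alpha=_FAST,
              p_rew=0.1),
        # caller-satellite polarization
        _case("fig3a_cs_K2_fast", "caller_satellite", cs, k=2, alpha=_FAST),
        _case("fig3a_cs_K2_slow", "caller_satellite", cs, k=2, alpha=_SLOW),
        _case("fig3a_cs_K8_fast", "caller_satellite", cs, k=8, alpha=_FAST),
        _case("fig3a_cs_K8_slow", "caller_satellite", cs, k=8, alpha=_SLOW),
        _case("fig3a_cs_K2_fast_smallworld", "caller_satellite", cs, k=2, alpha=_FAST,
              p_rew=0.1),
        _case("fig3a_cs_K8_fast_smallworld", "caller_satellite", cs, k=8, alpha=_FAST,
              p_rew=0.1),
        # hawk-dove polarization
        _case("fig3b_hd_K2_fast", "hawk_dove", hd, k=2, alpha=_FAST),
        _case("fig3b_hd_K2_slow", "hawk_dove", hd, k=2, alpha=_SLOW),
        _case("fig3b_hd_K8_fast", "hawk_dove", hd, k=8, alpha=_FAST),
        _case("fig3b_hd_K8_slow", "hawk_dove", hd, k=8, alpha=_SLOW),
        _case("fig3b_hd_K2_fast_smallworld", "hawk_dove", hd, k=2, alpha=_FAST,
              p_rew=0.1),
        _case("fig3b_hd_K8_fast_smallworld", "hawk_dove", hd, k=8, alpha=_FAST,
              p_rew=0.1),
        # steady-state consistency cases: 5 groups to t = 5000,
        # autocorrelation of logit(p) over rounds 4000-5000
        _case("fig4_ps_K4", "producer_scrounger", ps, k=4, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
        _case("fig4_ps_K98", "producer_scrounger", ps, k=98, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
        _case("fig4_ps_K4_smallworld", "producer_scrounger", ps, k=4, alpha=_FAST,
              p_rew=0.1, t=5000, groups=5, reduced=5,
              metrics=("polarization", "autocorrelation"), window=(4000, 5000)),
        _case("fig4_cs_K2", "caller_satellite", cs, k=2, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
        _case("fig4_cs_K8", "caller_satellite", cs, k=8, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
        _case("fig4_hd_K2", "hawk_dove", hd, k=2, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
        _case("fig4_hd_K8", "hawk_dove", hd, k=8, alpha=_FAST, t=5000,
              groups=5, reduced=5, metrics=("polarization", "autocorrelation"),
              window=(4000, 5000)),
    ]
    out = {c.label: c for c in cases}
    assert len(out) == len(cases), "duplicate labels in registry"
    return out


def make_fixture(kind: str, rng: np.random.Generator, **kwargs):
    """Deterministic miniature objects for tests.

    Kinds
    -----
    ``fig1a_ring``
        The 21-individual, K = 4 regular ring lattice.
    ``fig1b_smallworld``
        Its small-world rewiring at p_rew = 0.1 (uses ``rng``).
    ``ps_small_group``
        A 5-individual, K = 2, 3-round producer-scrounger group run
        with fast action-value learning; hand-traceable.  Keyword
        overrides: ``t_rounds``.
    ``ar1_logit``
        A synthetic trajectory whose logit(p) series follow a
        stationary AR(1) with persistence ``rho`` (keywords: ``rho``,
        ``n_individuals`` default 20, ``t_rounds`` default 200,
        ``sd`` stationary standard deviation, default 1.0).
    """
    if kind == "fig1a_ring":
        return make_ring_lattice(21, 4)
    if kind == "fig1b_smallworld":
        return rewire_small_world(make_ring_lattice(21, 4), 0.1, rng)
    if kind == "ps_small_group":
        cfg = SimulationConfig(
            n=5,
            k=2,
            game="producer_scrounger",
            game_params=ProducerScroungerParams(),
            rule="action_value",
            learner=LearnerParams(alpha=0.1, beta=8.0),
            t_rounds=kwargs.pop("t_rounds", 3),
            n_groups=1,
            seed=0,
        )
        if kwargs:
            raise TypeError(f"unknown fixture options {sorted(kwargs)}")
        return run_group(cfg, rng)
    if kind == "ar1_logit":
        rho = kwargs.pop("rho", 0.9)
        n = kwargs.pop("n_individuals", 20)
        t = kwargs.pop("t_rounds", 200)
        sd = kwargs.pop("sd", 1.0)
        if kwargs:
            raise TypeError(f"unknown fixture options {sorted(kwargs)}")
        if not (-1.0 < rho < 1.0):
            raise ValueError("rho must be in (-1, 1) for a stationary AR(1)")
        x = np.empty((t + 1, n))
        x[0] = rng.normal(0.0, sd, size=n)
        innov_sd = sd * np.sqrt(1.0 - rho**2)
        for i in range(1, t + 1):
            x[i] = rho * x[i - 1] + rng.normal(0.0, innov_sd, size=n)
        return Trajectory(
            p=expit(x),
            actions=np.full((t + 1, n), -1, dtype=np.int8),
            rounds=np.arange(t + 1, dtype=np.int64),
            network=make_ring_lattice(n, 2),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
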