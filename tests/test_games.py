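import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import path_network, star_network
from netgames.games import (
    CallerSatelliteParams,
    HawkDoveParams,
    ProducerScroungerParams,
    call_strength,
    hawk_dove_payoffs,
    mating_split,
    play_caller_satellite_round,
    play_producer_scrounger_round,
    sample_hawk_dove_contest,
)
from netgames.networks import make_ring_lattice


class TestCallStrength:
    @pytest.mark.parametrize(
        "k,k_c,gamma0,expected",
        [(4, 0, 0.75, 1.0), (4, 4, 0.75, 0.25), (4, 2, 0.75, 0.625), (0, 0, 0.75, 1.0)],
    )
    def test_values(self, k, k_c, gamma0, expected):
        assert call_strength(k, k_c, gamma0) == pytest.approx(expected)

    def test_rejects_more_callers_than_neighbours(self):
        with pytest.raises(ValueError):
            call_strength(2, 3, 0.75)


class TestMatingSplit:
    @pytest.mark.parametrize(
        "k_s,caller,satellite",
        [(0, 1.0, 0.0), (1, 0.5, 0.5), (2, 0.5, 0.25), (4, 0.5, 0.125)],
    )
    def test_allocation(self, k_s, caller, satellite):
        assert mating_split(k_s) == (caller, satellite)

    @pytest.mark.parametrize("k_s", range(8))
    def test_unit_probability_mass(self, k_s):
        c, s = mating_split(k_s)
        assert c + k_s * s == pytest.approx(1.0)


class TestProducerScrounger:
    def test_discovery_split_with_two_joiners(self, rng):
        # hub produces and finds for certain; exactly two scrounging neighbours
        net = star_network(2)
        actions = np.array([True, False, False])
        params = ProducerScroungerParams(lambda_find=1.0, v1=1.0, v2=3.0)
        out = play_producer_scrounger_round(actions, net, params, rng)
        assert out.rewards[0] == pytest.approx(2.0)
        assert out.rewards[1] == pytest.approx(1.0)
        assert out.rewards[2] == pytest.approx(1.0)

    def test_lone_producer_keeps_everything(self, rng):
        net = star_network(2)
        actions = np.array([True, True, True])  # no scroungers anywhere
        params = ProducerScroungerParams(lambda_find=1.0)
        out = play_producer_scrounger_round(actions, net, params, rng)
        assert out.rewards[0] == pytest.approx(4.0)

    def test_no_find_no_reward(self, rng):
        net = star_network(2)
        params = ProducerScroungerParams(lambda_find=0.0)
        out = play_producer_scrounger_round(
            np.array([True, False, False]), net, params, rng
        )
        assert np.all(out.rewards == 0.0)

    def test_scrounger_cap_limits_joiners(self, rng):
        # five available scroungers, cap 2: exactly two receive a share
        net = star_network(5)
        actions = np.array([True] + [False] * 5)
        params = ProducerScroungerParams(lambda_find=1.0)
        out = play_producer_scrounger_round(actions, net, params, rng)
        assert int(np.sum(out.rewards[1:] > 0)) == 2
        assert out.rewards[0] == pytest.approx(1.0 + 3.0 / 3.0)

    def test_all_individuals_participate(self, rng):
        net = make_ring_lattice(9, 2)
        out = play_producer_scrounger_round(
            np.zeros(9, dtype=bool), net, ProducerScroungerParams(), rng
        )
        assert np.array_equal(out.participants, np.arange(9))

    def test_multi_join_vs_exclusive(self):
        # middle scrounger flanked by two producers that both find food
        net = path_network(3)
        actions = np.array([True, False, True])
        multi = play_producer_scrounger_round(
            actions, net, ProducerScroungerParams(lambda_find=1.0),
            np.random.default_rng(0),
        )
        assert multi.rewards[1] == pytest.approx(3.0)  # two shares of v2/2
        excl = play_producer_scrounger_round(
            actions, net,
            ProducerScroungerParams(lambda_find=1.0, exclusive_joining=True),
            np.random.default_rng(0),
        )
        assert excl.rewards[1] == pytest.approx(1.5)  # one share only

    def test_conservation_per_discovery(self):
        # total reward handed out equals (v1 + v2) * number of discoveries
        rng = np.random.default_rng(42)
        net = make_ring_lattice(20, 4)
        params = ProducerScroungerParams()
        for _ in range(200):
            actions = rng.random(20) < 0.5
            out = play_producer_scrounger_round(actions, net, params, rng)
            n_disc = sum(1 for e in out.events if e[0] == "discovery")
            assert out.rewards.sum() == pytest.approx(n_disc * (params.v1 + params.v2))

    def test_reproducible(self):
        net = make_ring_lattice(20, 4)
        actions = np.random.default_rng(1).random(20) < 0.5
        a = play_producer_scrounger_round(
            actions, net, ProducerScroungerParams(), np.random.default_rng(9)
        )
        b = play_producer_scrounger_round(
            actions, net, ProducerScroungerParams(), np.random.default_rng(9)
        )
        assert np.array_equal(a.rewards, b.rewards)


class TestCallerSatellite:
    def test_no_callers_no_rewards(self, rng):
        net = make_ring_lattice(6, 2)
        out = play_caller_satellite_round(
            np.zeros(6, dtype=bool), net, CallerSatelliteParams(), rng
        )
        assert np.all(out.rewards == 0.0)

    def test_single_caller_single_satellite_split(self):
        # caller 0 with one satellite neighbour: over many females each
        # mates half the time (checked within 3 SE)
        net = path_network(3)  # 0-1, 1-2; node 2 isolated from 0
        actions = np.array([True, False, False])  # 0 calls; 1, 2 satellites
        params = CallerSatelliteParams(gamma0=0.75, f=50.0, v1=1.0)
        rng = np.random.default_rng(11)
        caller_total = 0.0
        n_females = 0
        sat_total = 0.0
        for _ in range(2000):
            out = play_caller_satellite_round(actions, net, params, rng)
            caller_total += out.rewards[0]
            sat_total += out.rewards[1]
            n_females += sum(e[1] for e in out.events if e[0] == "females")
            assert out.rewards[2] == 0.0  # not a neighbour of the caller
        assert n_females > 50000
        se = np.sqrt(0.25 / n_females)
        assert abs(caller_total / n_females - 0.5) < 3 * se
        assert abs(sat_total / n_females - 0.5) < 3 * se

    def test_each_female_yields_exactly_one_mating(self, rng):
        net = make_ring_lattice(12, 4)
        params = CallerSatelliteParams()
        for _ in range(300):
            actions = rng.random(12) < 0.5
            if not actions.any():
                continue
            out = play_caller_satellite_round(actions, net, params, rng)
            females = sum(e[1] for e in out.events if e[0] == "females")
            matings = sum(1 for e in out.events if e[0] == "mating")
            assert matings == females
            assert out.rewards.sum() == pytest.approx(matings * params.v1)

    def test_deterministic_mode_expected_rewards(self):
        # one caller (k=1 neighbour, none calling: s=1) with one satellite:
        # f*s females expected, caller mates half of them
        net = path_network(2)
        actions = np.array([True, False])
        params = CallerSatelliteParams(gamma0=0.75, f=2.0, v1=2.0,
                                       deterministic_females=True)
        out = play_caller_satellite_round(
            actions, net, params, np.random.default_rng(0)
        )
        assert out.rewards[0] == pytest.approx(2.0 * 1.0 * 0.5 * 2.0)
        assert out.rewards[1] == pytest.approx(2.0 * 1.0 * 0.5 * 2.0)

    def test_interference_lowers_neighbour_caller_strength(self):
        # two adjacent callers with k=1 each: s = 1 - gamma0 = 0.25;
        # deterministic rewards are f * s * v1 each (no satellites)
        net = path_network(2)
        actions = np.array([True, True])
        params = CallerSatelliteParams(gamma0=0.75, f=2.0, v1=2.0,
                                       deterministic_females=True)
        out = play_caller_satellite_round(
            actions, net, params, np.random.default_rng(0)
        )
        assert out.rewards[0] == pytest.approx(2.0 * 0.25 * 2.0)


class TestHawkDove:
    def test_hawk_beats_dove(self, rng):
        params = HawkDoveParams(v=1.0, c=2.0)
        assert hawk_dove_payoffs(True, False, params, rng) == (1.0, 0.0)
        assert hawk_dove_payoffs(False, True, params, rng) == (0.0, 1.0)

    def test_escalated_fight_expected_payoff(self):
        params = HawkDoveParams(v=1.0, c=2.0)
        rng = np.random.default_rng(5)
        totals = np.zeros(2)
        n = 20000
        for _ in range(n):
            totals += hawk_dove_payoffs(True, True, params, rng)
        # each hawk expects (v - c) / 2 = -0.5
        se = 1.5 / np.sqrt(n)  # outcomes are +1 or -2
        assert abs(totals[0] / n + 0.5) < 3 * se
        assert abs(totals[1] / n + 0.5) < 3 * se

    def test_dove_dove_expected_payoff(self):
        params = HawkDoveParams(v=1.0, c=2.0)
        rng = np.random.default_rng(6)
        total = sum(hawk_dove_payoffs(False, False, params, rng)[0] for _ in range(20000))
        assert abs(total / 20000 - 0.5) < 3 * 0.5 / np.sqrt(20000)

    def test_contest_sampling_uniform_on_ring(self):
        # each of the 10 ordered neighbour pairs of the 5-cycle appears
        # with frequency 1/10 within 3 SE
        net = make_ring_lattice(5, 2)
        rng = np.random.default_rng(17)
        n = 100_000
        counts = {}
        for _ in range(n):
            pair = sample_hawk_dove_contest(net, rng)
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 10
        se = np.sqrt(0.1 * 0.9 / n)
        for c in counts.values():
            assert abs(c / n - 0.1) < 3 * se

    def test_star_leaf_always_meets_hub(self):
        net = star_network(4)
        rng = np.random.default_rng(2)
        for _ in range(200):
            focal, opp = sample_hawk_dove_contest(net, rng)
            if focal != 0:
                assert opp == 0

    def test_isolated_nodes_never_focal(self):
        from netgames.networks import SocialNetwork

        net = SocialNetwork(n_individuals=4, edges=frozenset({(0, 1)}))
        rng = np.random.default_rng(3)
        for _ in range(100):
            focal, opp = sample_hawk_dove_contest(net, rng)
            assert {focal, opp} == {0, 1}

    def test_no_edges_is_an_error(self, rng):
        from netgames.networks import SocialNetwork

        net = SocialNetwork(n_individuals=3, edges=frozenset())
        with pytest.raises(ValueError):
            sample_hawk_dove_contest(net, rng)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    frac=st.floats(0.05, 0.95),
    lam=st.floats(0.1, 1.0),
)
def test_producer_scrounger_rewards_nonnegative_and_conserved(seed, frac, lam):
    rng = np.random.default_rng(seed)
    net = make_ring_lattice(15, 4)
    actions = rng.random(15) < frac
    params = ProducerScroungerParams(lambda_find=lam)
    out = play_producer_scrounger_round(actions, net, params, rng)
    assert np.all(out.rewards >= 0.0)
    n_disc = sum(1 for e in out.events if e[0] == "discovery")
    assert out.rewards.sum() == pytest.approx(n_disc * (params.v1 + params.v2))
    assert np.all(out.rewards[~actions & (out.rewards > 0)] <= params.v2 * n_disc)
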