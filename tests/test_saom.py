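"""Choice model and chain engine: statistics, logit probabilities,
micro-steps, and agreement with an independent naive simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netattack.errors import ContractError
from netattack.network import MarketNetwork
from netattack.saom import (
    AlterReputationEffect,
    EffectSet,
    OutdegreeEffect,
    ParameterVector,
    SimState,
    choice_probabilities,
    default_effects,
    effect_statistics,
    micro_step,
    objective,
    simulate_chain,
    simulate_chain_conditional,
    ChainState,
)

from conftest import random_bipartite

EFF = default_effects()


def one_buyer_net(rep=40.0, other_buyers=3):
    """b0 tied to v1; b1..bN also tied to v1 so its degree is 1+N."""
    buyers = {f"b{i}" for i in range(other_buyers + 1)}
    ties = {(b, "v1") for b in buyers}
    return MarketNetwork(buyers, {"v1", "v2"}, ties, {"v1": rep, "v2": 0.0})


class TestEffectStatistics:
    def test_empty_personal_network_is_zero(self):
        net = MarketNetwork({"b"}, {"v"}, set(), {"v": 7.0})
        assert effect_statistics("b", net, EFF).tolist() == [0.0, 0.0, 0.0]

    def test_direct_evaluation_with_sqrt_degree(self):
        # buyer tied to one vendor with reputation 40 and degree 4
        net = one_buyer_net(rep=40.0, other_buyers=3)
        s = effect_statistics("b0", net, EFF)
        assert s.tolist() == [1.0, 40.0, 2.0]

    def test_adding_tie_never_decreases_outdegree_stat(self, rng):
        net = random_bipartite(rng, n_buyers=5, n_vendors=4, density=0.3)
        b = sorted(net.buyers)[0]
        before = effect_statistics(b, net, EFF)[0]
        free = sorted(net.vendors - {v for bb, v in net.ties if bb == b})
        if free:
            net.ties.add((b, free[0]))
            assert effect_statistics(b, net, EFF)[0] == before + 1

    def test_duplicate_effect_names_rejected(self):
        with pytest.raises(Exception):
            EffectSet((OutdegreeEffect(), OutdegreeEffect()))


class TestObjective:
    def test_zero_beta_gives_zero(self, toy_net):
        assert objective("b1", toy_net, np.zeros(3), EFF) == 0.0

    def test_reputation_coefficient_arithmetic(self):
        # beta = (0, .0005, 0), total tied reputation 1000 -> f = 0.5
        buyers = {"b"}
        vendors = {"v1", "v2"}
        net = MarketNetwork(buyers, vendors, {("b", "v1"), ("b", "v2")}, {"v1": 600.0, "v2": 400.0})
        f = objective("b", net, np.array([0.0, 0.0005, 0.0]), EFF)
        assert f == pytest.approx(0.5)

    def test_linearity_in_state_difference(self, rng):
        net = random_bipartite(rng, n_buyers=4, n_vendors=3, density=0.5)
        b = sorted(net.buyers)[0]
        beta = np.array([-0.7, 0.01, 0.3])
        other = net.copy()
        v = sorted(net.vendors)[0]
        tie = (b, v)
        (other.ties.discard if tie in other.ties else other.ties.add)(tie)
        lhs = objective(b, net, beta, EFF) - objective(b, other, beta, EFF)
        rhs = beta @ (effect_statistics(b, net, EFF) - effect_statistics(b, other, EFF))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_dimension_mismatch_rejected(self, toy_net):
        with pytest.raises(ContractError):
            objective("b1", toy_net, np.zeros(2), EFF)


class TestChoiceProbabilities:
    def test_zero_beta_uniform_over_candidates(self, toy_net):
        p = choice_probabilities("b1", toy_net, np.zeros(3), EFF)
        assert len(p) == 4  # 3 vendors + no change
        for prob in p.values():
            assert prob == pytest.approx(1 / 4)

    def test_hand_logit_two_vendors(self):
        """Reputation effect only, beta_rep chosen so the objective gap
        between creating a tie to v1 vs v2 is exactly 1; no-change has
        the same objective as the v2-candidate (buyer has no ties, rep
        of v2 is 0): P(v1) = e/(e+2)."""
        net = MarketNetwork({"b"}, {"v1", "v2"}, set(), {"v1": 2.0, "v2": 0.0})
        eff = EffectSet((AlterReputationEffect(),))
        p = choice_probabilities("b", net, np.array([0.5]), eff)
        assert p["v1"] == pytest.approx(math.e / (math.e + 2))
        assert p["v2"] == pytest.approx(1 / (math.e + 2))
        assert p[None] == pytest.approx(1 / (math.e + 2))

    def test_empty_vendor_set_degenerate(self):
        net = MarketNetwork({"b"}, set(), set(), {})
        assert choice_probabilities("b", net, np.zeros(3), EFF) == {None: 1.0}

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_normalization_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        net = random_bipartite(rng, n_buyers=5, n_vendors=6, density=0.4)
        beta = rng.normal(0, 1, size=3)
        p = choice_probabilities(sorted(net.buyers)[0], net, beta, EFF)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in p.values())

    def test_overflow_safety_with_extreme_beta(self, toy_net):
        p = choice_probabilities("b1", toy_net, np.array([500.0, 0.0, 0.0]), EFF)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


class TestMicroStep:
    def test_toggle_semantics_and_bipartite_preserved(self, rng):
        net = random_bipartite(rng, n_buyers=6, n_vendors=4, density=0.4)
        state = SimState(network=net.copy(), rng=np.random.default_rng(1))
        for _ in range(60):
            before = set(state.network.ties)
            micro_step(state, np.array([0.0, 0.0, 0.0]), EFF)
            after = set(state.network.ties)
            state.network.validate()
            diff = before ^ after
            assert len(diff) <= 1  # at most one toggle per opportunity
        assert state.elapsed == pytest.approx(60 / 6)

    def test_heavy_dissolution_empties_network(self, rng):
        """With a strongly negative outdegree coefficient the chain loses
        ties: dissolution candidates dominate every choice."""
        net = random_bipartite(rng, n_buyers=5, n_vendors=4, density=0.8)
        params = ParameterVector(beta=np.array([-8.0, 0.0, 0.0]), rate=20.0)
        end = simulate_chain(net, params, EFF, seed=4)
        assert end.tie_count() < net.tie_count() / 4


class TestSimulateChain:
    def test_determinism(self, rng):
        net = random_bipartite(rng, n_buyers=8, n_vendors=5, density=0.3)
        params = ParameterVector(beta=np.array([-1.0, 0.05, 0.1]), rate=3.0)
        a = simulate_chain(net, params, EFF, seed=99)
        b = simulate_chain(net, params, EFF, seed=99)
        assert a == b

    def test_zero_draw_returns_input(self, rng):
        net = random_bipartite(rng, n_buyers=4, n_vendors=3, density=0.4)
        # rate small enough that Poisson(4e-9) draws 0
        params = ParameterVector(beta=np.zeros(3), rate=1e-9)
        assert simulate_chain(net, params, EFF, seed=0) == net

    def test_rate_must_be_positive(self):
        with pytest.raises(ContractError):
            ParameterVector(beta=np.zeros(3), rate=0.0)

    def test_symmetric_toggle_density_half(self):
        """With beta = 0 every candidate is equally likely, so each dyad
        is an unbiased toggle chain whose stationary density is 1/2
        (3 buyers x 2 vendors, long chain, averaged over seeds)."""
        net = MarketNetwork(
            {"b1", "b2", "b3"}, {"v1", "v2"}, set(), {"v1": 0.0, "v2": 0.0}
        )
        params = ParameterVector(beta=np.zeros(3), rate=200.0)
        dens = [
            simulate_chain(net, params, EFF, seed=s).tie_count() / 6 for s in range(200)
        ]
        assert np.mean(dens) == pytest.approx(0.5, abs=0.05)

    def test_reputation_preference_is_monotone_in_beta(self):
        """Increasing the reputation coefficient strictly increases the
        mean reputation of tied vendors (50-seed batches per level)."""
        rng = np.random.default_rng(0)
        net = random_bipartite(rng, n_buyers=20, n_vendors=8, density=0.1)
        means = []
        # coefficients kept below the saturation point: once every
        # positive-reputation vendor clears the tie-cost threshold the
        # mean tied reputation reverts toward the population mean
        for b_rep in (0.0, 0.05, 0.1):
            params = ParameterVector(beta=np.array([-2.5, b_rep, 0.0]), rate=3.0)
            tied_rep = []
            for s in range(50):
                end = simulate_chain(net, params, EFF, seed=s)
                if end.ties:
                    tied_rep.append(np.mean([end.reputation[v] for _, v in end.ties]))
            means.append(np.mean(tied_rep))
        assert means[0] < means[1] < means[2]

    def test_conditional_chain_hits_target_distance(self, rng):
        net = random_bipartite(rng, n_buyers=10, n_vendors=5, density=0.2)
        start = ChainState(net)
        end, steps = simulate_chain_conditional(
            start, np.zeros(3), EFF, np.random.default_rng(3), target_hamming=12
        )
        assert int(np.sum(end.adj != start.adj)) == 12
        assert steps >= 12


class TestEngineConsistency:
    def test_fast_deltas_match_slow_statistics(self, rng):
        """The vectorized candidate deltas must equal differences of the
        slow per-network statistics for every buyer/vendor toggle."""
        net = random_bipartite(rng, n_buyers=5, n_vendors=4, density=0.5)
        state = ChainState(net)
        for bi, b in enumerate(state.buyers):
            for e in EFF:
                deltas = e.candidate_deltas(state, bi)
                for vi, v in enumerate(state.vendors):
                    toggled = net.copy()
                    tie = (b, v)
                    (toggled.ties.discard if tie in toggled.ties else toggled.ties.add)(tie)
                    slow_delta = e.statistic(b, toggled) - e.statistic(b, net)
                    assert deltas[vi] == pytest.approx(slow_delta, abs=1e-12)

    def test_mean_tie_count_matches_naive_simulator(self):
        """Independent oracle: a dictionary-based simulator that
        materializes every candidate network and computes full objective
        values from scratch.  At beta = 0, rate = 1 the mean final tie
        count over 100 chains must agree within 3 Monte-Carlo SEs."""

        def naive_chain(net, seed):
            rng = np.random.default_rng(seed)
            current = {tuple(t) for t in net.ties}
            buyers, vendors = sorted(net.buyers), sorted(net.vendors)
            m = rng.poisson(1.0 * len(buyers))
            for _ in range(m):
                b = buyers[rng.integers(len(buyers))]
                candidates = []
                for v in vendors:  # candidate tie sets after each toggle
                    c = set(current)
                    (c.discard if (b, v) in c else c.add)((b, v))
                    candidates.append(c)
                candidates.append(set(current))
                # full objective at beta=0 is 0 for every candidate
                weights = np.exp([0.0] * len(candidates))
                probs = weights / weights.sum()
                pick = rng.choice(len(candidates), p=probs)
                current = candidates[pick]
            return len(current)

        rng = np.random.default_rng(17)
        net = random_bipartite(rng, n_buyers=6, n_vendors=4, density=0.3)
        params = ParameterVector(beta=np.zeros(3), rate=1.0)
        ours = np.array(
            [simulate_chain(net, params, EFF, seed=s).tie_count() for s in range(100)],
            dtype=float,
        )
        naive = np.array([naive_chain(net, 10_000 + s) for s in range(100)], dtype=float)
        se = math.sqrt(ours.var(ddof=1) / 100 + naive.var(ddof=1) / 100)
        assert abs(ours.mean() - naive.mean()) <= 3 * se
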