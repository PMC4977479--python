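"""Network expansion, ODE steady states, and the stochastic oracle."""

import numpy as np
import pytest

from stericrules.dynamics import (
    SimulationConfig,
    build_network,
    integrate_to_steady_state,
    mean_strand_size,
    region_binding_probabilities,
    simulate,
    ssa_oracle,
    strand_size_distribution,
)
from stericrules.rulegen import RateParameters, generate_rules
from stericrules.geometry import StericAdjacency

from helpers import CHAIN, adjacency_from_edges

RATES = RateParameters(k_f1=1.0, k_f2=0.005, k_r=0.01)


def single_region_ruleset(k_f, k_r):
    adj = StericAdjacency("I", {"A": frozenset()})
    return generate_rules(adj, RateParameters(k_f1=k_f, k_f2=0.0, k_r=k_r))


class TestNetworkStructure:
    def test_six_region_strand_has_64_species_and_192_reactions_each_way(self):
        network = build_network(generate_rules(CHAIN, RATES))
        assert network.n_species == 64 + 1
        assert len(network.fwd_src) == 6 * 2**5
        assert len(network.rev_src) == 6 * 2**5

    def test_single_region_toy_network(self):
        network = build_network(single_region_ruleset(0.01, 1.0))
        assert network.n_species == 3  # free, bound, receptor
        assert len(network.fwd_src) == 1 and len(network.rev_src) == 1
        assert network.fwd_k[0] == 0.01 and network.rev_k[0] == 1.0

    def test_empty_adjacency_all_forward_rates_unhindered(self):
        network = build_network(
            generate_rules(adjacency_from_edges([]), RATES)
        )
        assert np.all(network.fwd_k == RATES.k_f1)

    def test_duplicate_strand_labels_rejected(self):
        ruleset = generate_rules(CHAIN, RATES)
        with pytest.raises(ValueError, match="duplicate"):
            build_network([ruleset, ruleset])


class TestSteadyState:
    def test_zero_receptors_leaves_all_strands_free(self):
        config = SimulationConfig(receptor_count=0, counts={"I": 50})
        state = simulate(generate_rules(CHAIN, RATES), config)
        dist = strand_size_distribution(state, "I")
        assert dist[0] == pytest.approx(1.0, abs=1e-12)
        probs = region_binding_probabilities(state, "I")
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in probs.values())

    def test_single_site_equilibrium_matches_quadratic_root(self):
        # one strand molecule, one receptor, k_f (1-b)^2 = k_r b at equilibrium
        k_f, k_r = 0.01, 1.0
        network = build_network(single_region_ruleset(k_f, k_r))
        config = SimulationConfig(
            counts={"I": 1}, receptor_count=1, t_end=2000.0,
            convergence_tol=1e-9,
        )
        state = integrate_to_steady_state(network, config)
        bound = state.counts_by_strand["I"][1]
        roots = np.roots([k_f, -(2 * k_f + k_r), k_f])
        expected = min(r.real for r in roots if 0 <= r.real <= 1)
        assert bound == pytest.approx(expected, rel=1e-6)
        assert state.converged

    def test_irreversible_binding_saturates_all_regions(self):
        rates = RateParameters(k_f1=1.0, k_f2=0.05, k_r=0.0)
        config = SimulationConfig(
            counts={"I": 10}, receptor_count=10000, t_end=200.0,
            convergence_tol=1e-6,
        )
        state = simulate(generate_rules(CHAIN, rates), config)
        dist = strand_size_distribution(state, "I")
        assert dist[6] == pytest.approx(1.0, abs=1e-6)

    def test_independent_sites_limit_is_binomial(self):
        # No sterics and no receptor depletion: regions fill independently
        # with p = k_f R / (k_f R + k_r).
        k_f, k_r, receptors = 1e-8, 0.01, 1e6
        rates = RateParameters(k_f1=k_f, k_f2=0.0, k_r=k_r)
        ruleset = generate_rules(adjacency_from_edges([]), rates)
        config = SimulationConfig(
            counts={"I": 1}, receptor_count=receptors, t_end=5000.0,
            convergence_tol=1e-9,
        )
        state = simulate(ruleset, config)
        dist = strand_size_distribution(state, "I")
        p = k_f * receptors / (k_f * receptors + k_r)
        from math import comb

        binom = np.array([
            comb(6, n) * p**n * (1 - p) ** (6 - n) for n in range(7)
        ])
        assert np.allclose(dist, binom, atol=2e-6)

    def test_conservation_along_the_trajectory(self):
        network = build_network(
            [
                generate_rules(CHAIN, RATES),
                generate_rules(
                    adjacency_from_edges(
                        [("A", "B"), ("C", "D")], strand="II"
                    ),
                    RATES,
                ),
            ]
        )
        config = SimulationConfig()
        times = np.linspace(0.0, config.t_end, 21)
        state = integrate_to_steady_state(network, config, t_eval=times)
        t, blocks = state.trajectory
        sizes_I = network.bound_counts("I")
        sizes_II = network.bound_counts("II")
        for k in range(len(t)):
            total_I = blocks["I"][:, k].sum()
            total_II = blocks["II"][:, k].sum()
            assert total_I == pytest.approx(100.0, rel=1e-8)
            assert total_II == pytest.approx(100.0, rel=1e-8)
            bound = (
                blocks["I"][:, k] @ sizes_I + blocks["II"][:, k] @ sizes_II
            )
            assert bound + blocks["receptor"][k] == pytest.approx(
                1000.0, rel=1e-8
            )

    def test_separate_pool_mode_conserves_per_pool(self):
        rulesets = [
            generate_rules(CHAIN, RATES),
            generate_rules(
                adjacency_from_edges(
                    [("A", "B"), ("B", "C")], strand="II"
                ),
                RATES,
            ),
        ]
        config = SimulationConfig(shared_receptor_pool=False)
        state = simulate(rulesets, config)
        assert set(state.free_receptors) == {"I", "II"}
        errors = state.conservation_errors()
        assert max(errors.values()) < 1e-8

    def test_forbidden_patterns_have_zero_mass_when_kf2_is_zero(self):
        import networkx

        rates = RateParameters(k_f1=1.0, k_f2=0.0, k_r=0.01)
        state = simulate(generate_rules(CHAIN, rates), SimulationConfig())
        counts = state.counts_by_strand["I"]
        graph = networkx.path_graph(["A", "B", "C", "D", "E", "F"])
        regions = state.regions_by_strand["I"]
        max_size = 0
        for s, count in enumerate(counts):
            bound = {regions[i] for i in range(6) if s & (1 << i)}
            independent = not any(
                graph.has_edge(a, b) for a in bound for b in bound if a != b
            )
            if not independent:
                assert count <= 1e-9
            elif count > 1e-9:
                max_size = max(max_size, len(bound))
        # maximum independent set of a 6-chain
        assert max_size == 3

    def test_mean_size_monotone_in_kf2(self):
        means = []
        for k_f2 in (0.001, 0.01, 0.05):
            rates = RateParameters(k_f1=1.0, k_f2=k_f2, k_r=0.01)
            state = simulate(generate_rules(CHAIN, rates), SimulationConfig())
            means.append(mean_strand_size(state, "I"))
        assert means[0] < means[1] < means[2]

    def test_zero_strand_count_rejected_for_distributions(self):
        config = SimulationConfig(counts={"I": 0})
        state = simulate(generate_rules(CHAIN, RATES), config)
        with pytest.raises(ValueError, match="zero copy number"):
            strand_size_distribution(state, "I")


class TestSSA:
    def test_zero_receptors_matches_ode_trivially(self):
        network = build_network(generate_rules(CHAIN, RATES))
        config = SimulationConfig(receptor_count=0, counts={"I": 20}, seed=1)
        stochastic = ssa_oracle(network, config, n_runs=3)
        assert stochastic.counts_by_strand["I"][0] == 20

    def test_birth_death_toy_matches_analytic_mean(self):
        # Single site, single strand copy, receptor excess held constant:
        # occupancy is a two-state chain with known equilibrium.
        k_f, k_r, receptors = 0.002, 1.0, 1000
        network = build_network(single_region_ruleset(k_f, k_r))
        config = SimulationConfig(
            counts={"I": 1}, receptor_count=receptors, t_end=50.0, seed=42
        )
        stochastic = ssa_oracle(network, config, n_runs=400)
        occupancy = stochastic.counts_by_strand["I"][1]
        sem = stochastic.sem_by_strand["I"][1]
        p = k_f * receptors / (k_f * receptors + k_r)  # ~0.667, depletion ~1e-3
        assert abs(occupancy - p) < max(3 * sem, 0.005)

    def test_requires_integer_copy_numbers(self):
        network = build_network(generate_rules(CHAIN, RATES))
        config = SimulationConfig(counts={"I": 10.5})
        with pytest.raises(ValueError, match="integer"):
            ssa_oracle(network, config, n_runs=1)


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(receptor_count=-1)
    with pytest.raises(ValueError):
        SimulationConfig(t_end=0)
    with pytest.raises(ValueError, match="no copy number"):
        SimulationConfig().count_for("X")
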